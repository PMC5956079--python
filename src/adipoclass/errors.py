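"""Exception hierarchy for the adipoclass pipeline."""


class AdipoclassError(Exception):
    """Base class for all package errors."""


class FormatError(AdipoclassError):
    """A summary-statistics file does not conform to the expected dialect."""


class EmptyInputError(AdipoclassError):
    """No usable records remain after parsing and validation."""


class ContractError(AdipoclassError):
    """Arguments violate an operation's preconditions (mismatched variants,
    strata, or empty estimate lists)."""


class ParameterError(AdipoclassError):
    """A simulation or analysis parameter is outside its feasible range."""


class InstrumentError(ContractError):
    """A variant class was requested as a Mendelian-randomization instrument
    set although it carries no exposure signal (WHRonly- has, by
    construction, no effect on BMI)."""
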