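"""Class-restricted inverse-variance-weighted Mendelian randomization and
joint allele-score risk summaries.

The causal effect of BMI on an outcome is estimated per variant class by
the first-order IVW estimator over the class's variants as instruments,

    slope = sum(bx_i by_i / sey_i^2) / sum(bx_i^2 / sey_i^2),
    se    = 1 / sqrt(sum(bx_i^2 / sey_i^2)),

which equals the zero-intercept weighted least-squares regression of
outcome effects on exposure effects with weights 1/sey^2 -- the
meta-regression line through the class's points on the exposure-outcome
effect plane, interpretable as a genetic-risk-score association.

The WHRonly- class is refused as an instrument set: its variants have, by
definition, no effect on BMI and therefore no exposure signal.

The joint class risk summarizes a class's aligned alleles as the
exponentiated sum of per-allele log-odds on the outcome (carrying one
copy of every aligned risk allele versus none).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .algebra import EffectEstimate
from .classify import BMI_ONLY, CONCORDANT, DISCORDANT, WHR_ONLY, ClassifiedVariant
from .errors import ContractError, InstrumentError

#: classes eligible as BMI instrument sets
ELIGIBLE_CLASSES = (CONCORDANT, BMI_ONLY, DISCORDANT)
DEFAULT_N_TESTS = 60  # 3 eligible classes x 20 outcome traits


@dataclass(frozen=True)
class MRResult:
    class_label: str
    outcome: str
    slope: float  # outcome units per SD of BMI
    se_slope: float
    p_grs: float
    n_instruments: int
    significant_flag: bool = False
    cochran_q: float | None = None


@dataclass(frozen=True)
class JointRiskResult:
    class_label: str
    outcome: str
    joint_log_or: float
    joint_rr: float
    n_variants: int


def ivw_mr(
    b_exposure: Sequence[EffectEstimate],
    b_outcome: Sequence[EffectEstimate],
    class_label: str = "",
    outcome: str = "",
    n_tests: int = DEFAULT_N_TESTS,
) -> MRResult:
    """First-order IVW MR slope of the outcome on the exposure over a
    matched instrument list, with Cochran's Q as a heterogeneity
    diagnostic."""
    if class_label == WHR_ONLY:
        raise InstrumentError(
            f"{WHR_ONLY} variants have no BMI effect and are no effective "
            "instruments for BMI; this class is excluded from MR"
        )
    if len(b_exposure) == 0 or len(b_exposure) != len(b_outcome):
        raise ContractError(
            f"need matched non-empty instrument lists, got {len(b_exposure)} "
            f"exposure vs {len(b_outcome)} outcome estimates"
        )
    for bx, by in zip(b_exposure, b_outcome):
        if bx.variant_id and by.variant_id and bx.variant_id != by.variant_id:
            raise ContractError(f"instrument mismatch: {bx.variant_id} vs {by.variant_id}")
    bx = np.array([e.beta for e in b_exposure])
    by = np.array([e.beta for e in b_outcome])
    sey = np.array([e.se for e in b_outcome])
    w = 1.0 / sey**2
    denom = float(np.sum(bx**2 * w))
    if denom <= 0:
        raise ContractError("all exposure effects are zero; slope undefined")
    slope = float(np.sum(bx * by * w) / denom)
    se = 1.0 / math.sqrt(denom)
    p = max(2.0 * stats.norm.sf(abs(slope / se)), 5e-324)
    q = float(np.sum(w * (by - slope * bx) ** 2)) if len(bx) > 1 else None
    return MRResult(
        class_label=class_label,
        outcome=outcome or (b_outcome[0].trait if b_outcome[0].trait else ""),
        slope=slope,
        se_slope=se,
        p_grs=p,
        n_instruments=len(bx),
        significant_flag=p < 0.05 / n_tests,
        cochran_q=q,
    )


def run_class_mr(
    classified: Sequence[ClassifiedVariant],
    outcomes: Sequence[str],
    n_tests: int | None = None,
) -> list[MRResult]:
    """IVW MR of every outcome on BMI, separately for each eligible class
    (WHRonly- excluded); flags at the Bonferroni level 0.05/n_tests, where
    n_tests defaults to eligible classes x outcomes (0.05/60 for the
    three-class, 20-outcome design)."""
    if n_tests is None:
        n_tests = len(ELIGIBLE_CLASSES) * len(outcomes)
    results = []
    for label in ELIGIBLE_CLASSES:
        members = [v for v in classified if v.class_label == label]
        for outcome in outcomes:
            pairs = [
                (v.b_bmi, v.lookups[outcome]) for v in members if outcome in v.lookups
            ]
            if not pairs:
                continue
            bx, by = zip(*pairs)
            results.append(
                ivw_mr(list(bx), list(by), class_label=label, outcome=outcome, n_tests=n_tests)
            )
    return results


def joint_risk(
    classified: Sequence[ClassifiedVariant], outcome: str, class_label: str | None = None
) -> JointRiskResult:
    """Joint relative risk of one class's aligned alleles on a log-odds
    outcome: exp(sum of per-allele log-odds over variants with an
    available lookup)."""
    members = [
        v
        for v in classified
        if (class_label is None or v.class_label == class_label) and outcome in v.lookups
    ]
    if not members:
        raise ContractError(
            f"no available {outcome!r} effects for class {class_label!r}"
        )
    label = class_label or members[0].class_label
    total = float(sum(v.lookups[outcome].beta for v in members))
    return JointRiskResult(
        class_label=label,
        outcome=outcome,
        joint_log_or=total,
        joint_rr=math.exp(total),
        n_variants=len(members),
    )


def mr_frame(results: Sequence[MRResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [r.class_label for r in results],
            "outcome": [r.outcome for r in results],
            "slope": [r.slope for r in results],
            "se": [r.se_slope for r in results],
            "p_grs": [r.p_grs for r in results],
            "n_instruments": [r.n_instruments for r in results],
            "flag": [r.significant_flag for r in results],
            "cochran_q": [r.cochran_q for r in results],
        }
    )
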