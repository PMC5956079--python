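"""Four-class classification of adiposity variants on the b_WHR-b_BMI plane.

A lead variant is placed in one of four classes from the nominal
significance and direction of its effects on BMI and WHR:

* ``BMI+WHR+``  both effects significant, same direction (concordant);
  WHR effects larger than expected from the BMI effect ("supra-expected")
  also land here.
* ``BMIonly+``  significant BMI effect only.
* ``WHRonly-``  significant WHR effect only.
* ``BMI+WHR-``  both significant, opposite directions (discordant).
* ``unclassified``  neither effect significant (cannot occur for variants
  selected at genome-wide significance on BMI or WHR, but kept for
  completeness).

Class names encode the aligned-allele convention: effects are aligned to
the BMI-increasing allele for the three classes with a BMI effect, and to
the WHR-decreasing allele for WHRonly-, which makes all four classes
hip-increasing-aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy import stats

from .algebra import EffectEstimate
from .errors import ContractError

CONCORDANT = "BMI+WHR+"
BMI_ONLY = "BMIonly+"
WHR_ONLY = "WHRonly-"
DISCORDANT = "BMI+WHR-"
UNCLASSIFIED = "unclassified"

CLASS_LABELS = (CONCORDANT, BMI_ONLY, WHR_ONLY, DISCORDANT)


@dataclass
class ClassifiedVariant:
    """A lead variant with harmonized per-trait effects and class label.

    ``lookups`` maps lookup-trait labels to effect estimates on the same
    (aligned) allele; ``aligned_allele`` names that allele.
    """

    variant_id: str
    class_label: str
    b_bmi: EffectEstimate
    b_whr: EffectEstimate
    b_whradjbmi: EffectEstimate | None = None
    effect_allele: str = ""
    other_allele: str = ""
    aligned_allele: str = ""
    source_scans: set = field(default_factory=set)
    lookups: dict = field(default_factory=dict)
    supra_expected: bool = False
    flipped: bool = False


@dataclass(frozen=True)
class SexDiffResult:
    """Two-sided test of a women-vs-men difference in genetic effect."""

    variant_id: str
    trait: str
    z_diff: float
    p_sexdiff: float


def _significant(est: EffectEstimate, alpha: float) -> bool:
    # an exactly-zero beta carries no direction; degenerate inputs are
    # treated as non-significant for that trait
    p = est.p if est.p is not None else 2.0 * stats.norm.sf(abs(est.z))
    return p < alpha and est.beta != 0.0


def classify(b_bmi: EffectEstimate, b_whr: EffectEstimate, alpha: float = 0.05) -> str:
    """Assign the four-class label from nominal significance and effect
    direction of the BMI and WHR estimates (harmonized to one allele)."""
    if not 0.0 < alpha < 1.0:
        raise ContractError(f"alpha must be in (0,1), got {alpha}")
    if b_bmi.variant_id and b_whr.variant_id and b_bmi.variant_id != b_whr.variant_id:
        raise ContractError(f"variant mismatch: {b_bmi.variant_id} vs {b_whr.variant_id}")
    sig_bmi = _significant(b_bmi, alpha)
    sig_whr = _significant(b_whr, alpha)
    if sig_bmi and sig_whr:
        same = (b_bmi.beta > 0) == (b_whr.beta > 0)
        return CONCORDANT if same else DISCORDANT
    if sig_bmi:
        return BMI_ONLY
    if sig_whr:
        return WHR_ONLY
    return UNCLASSIFIED


def _negate(est: EffectEstimate | None) -> EffectEstimate | None:
    if est is None:
        return None
    return replace(est, beta=-est.beta)


def align_alleles_by_class(v: ClassifiedVariant) -> ClassifiedVariant:
    """Re-sign all effects to the class alignment convention: BMI-increasing
    allele for BMI+WHR+, BMIonly+ and BMI+WHR-; WHR-decreasing allele for
    WHRonly- (consistent with BMI+WHR-, so all four classes end up aligned
    for hip-increasing alleles). Lookup effects are re-signed with the same
    flip so directional enrichment counts stay on one allele."""
    if v.class_label == WHR_ONLY:
        flip = v.b_whr.beta > 0
    elif v.class_label in (CONCORDANT, BMI_ONLY, DISCORDANT):
        flip = v.b_bmi.beta < 0
    else:
        flip = False
    aligned = v.effect_allele if not flip else v.other_allele
    if not flip:
        return replace(v, aligned_allele=aligned, flipped=False)
    return replace(
        v,
        b_bmi=_negate(v.b_bmi),
        b_whr=_negate(v.b_whr),
        b_whradjbmi=_negate(v.b_whradjbmi),
        lookups={k: _negate(e) for k, e in v.lookups.items()},
        aligned_allele=aligned,
        flipped=True,
    )


def flag_supra_expected(
    b_bmi: EffectEstimate, b_whr: EffectEstimate, r: float
) -> bool:
    """Metadata indicator for WHR effects in the BMI direction but larger
    than expected from the phenotype correlation: the adjusted-scale
    residual b_WHR - r*b_BMI exceeds 1.96 propagated SEs in the direction
    of the BMI effect."""
    resid = b_whr.beta - r * b_bmi.beta
    se = math.sqrt(b_whr.se**2 + r**2 * b_bmi.se**2)
    if b_bmi.beta == 0.0:
        return False
    same_direction = (b_whr.beta > 0) == (b_bmi.beta > 0)
    outward = (resid > 0) == (b_bmi.beta > 0)
    return same_direction and outward and abs(resid) / se > 1.96


def reclassify_sensitivity(
    variants: list[ClassifiedVariant], alpha_strict: float, alpha: float = 0.05
) -> "pd.DataFrame":  # noqa: F821
    """Re-classify at a stricter threshold (e.g. Bonferroni 0.05/n_signals)
    and tabulate per-variant class transitions. Returns a frame with
    columns variant_id, class_old, class_new, changed."""
    import pandas as pd

    if not alpha_strict < alpha:
        raise ContractError("alpha_strict must be below the default alpha")
    rows = []
    for v in variants:
        new = classify(v.b_bmi, v.b_whr, alpha=alpha_strict)
        rows.append(
            {
                "variant_id": v.variant_id,
                "class_old": v.class_label,
                "class_new": new,
                "changed": new != v.class_label,
            }
        )
    return pd.DataFrame(rows)


def summarize_transitions(transitions: "pd.DataFrame") -> dict:  # noqa: F821
    """Counts of retained / changed / newly unclassified variants for a
    sensitivity re-classification."""
    retained = int((~transitions["changed"]).sum())
    newly_unclassified = int(
        (transitions["changed"] & (transitions["class_new"] == UNCLASSIFIED)).sum()
    )
    changed = int(transitions["changed"].sum()) - newly_unclassified
    return {
        "retained": retained,
        "changed_class": changed,
        "newly_unclassified": newly_unclassified,
    }


def sexdiff_test(
    b_women: EffectEstimate, b_men: EffectEstimate, rho: float = 0.0
) -> SexDiffResult:
    """Two-sided z test of a sex difference in genetic effect:
    z = (b_W - b_M) / sqrt(se_W^2 + se_M^2 - 2 rho se_W se_M), where rho is
    the between-sex correlation of the estimates (0 for non-overlapping
    strata)."""
    if b_women.variant_id and b_men.variant_id and b_women.variant_id != b_men.variant_id:
        raise ContractError("sexdiff_test requires the same variant in both strata")
    if b_women.trait and b_men.trait and b_women.trait != b_men.trait:
        raise ContractError("sexdiff_test requires the same trait in both strata")
    for est in (b_women, b_men):
        if not (math.isfinite(est.beta) and math.isfinite(est.se)):
            raise ContractError("non-finite effect estimate")
    var = b_women.se**2 + b_men.se**2 - 2.0 * rho * b_women.se * b_men.se
    if var <= 0:
        raise ContractError(f"non-positive difference variance ({var}); check rho")
    z = (b_women.beta - b_men.beta) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return SexDiffResult(
        variant_id=b_women.variant_id or b_men.variant_id,
        trait=b_women.trait or b_men.trait,
        z_diff=z,
        p_sexdiff=max(p, 5e-324),
    )
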