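"""Class-specific directional binomial enrichment tests.

For each class and lookup trait, variants with an available lookup
estimate are counted as trait-increasing or trait-decreasing when the
(aligned-allele) effect is nominally significant (P < 0.05). Under the
null, either directional count is Binomial(n_tested, p_null) with
p_null = alpha/2 = 0.025 (a two-sided nominal test split evenly between
directions). Enrichment is the upper binomial tail P(X >= n_significant),
judged against a Bonferroni level of 0.05 / (classes x traits x 2
directions).

Tails at the observed extremes (e.g. 0.025^82 ~ 4e-132) underflow naive
summation; the implementation uses the regularized incomplete beta
identity with a log-space fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .classify import CLASS_LABELS, ClassifiedVariant
from .errors import ContractError

DEFAULT_P_NULL = 0.025
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    class_label: str
    trait: str
    direction: str  # "increasing" | "decreasing"
    n_tested: int
    n_significant: int
    p_binomial: float
    significant_flag: bool


def binomial_enrichment(n_tested: int, n_significant: int, p_null: float = DEFAULT_P_NULL) -> float:
    """Upper-tail binomial probability P(X >= n_significant) for
    X ~ Binomial(n_tested, p_null).

    Uses the identity P(X >= k) = I_p(k, n-k+1) (regularized incomplete
    beta), which is accurate into the extreme tail; if the result
    underflows to zero it is recomputed by log-sum-exp over log pmf terms.
    """
    if not 0 <= n_significant <= n_tested:
        raise ContractError(
            f"need 0 <= n_significant <= n_tested, got {n_significant}/{n_tested}"
        )
    if not 0.0 < p_null < 1.0:
        raise ContractError(f"p_null must be in (0,1), got {p_null}")
    if n_significant == 0:
        return 1.0
    p = float(special.betainc(n_significant, n_tested - n_significant + 1, p_null))
    if p == 0.0:
        return float(np.exp(log_binomial_enrichment(n_tested, n_significant, p_null)))
    return min(p, 1.0)


def log_binomial_enrichment(
    n_tested: int, n_significant: int, p_null: float = DEFAULT_P_NULL
) -> float:
    """Natural log of the upper binomial tail, by log-sum-exp over the pmf."""
    if n_significant == 0:
        return 0.0
    ks = np.arange(n_significant, n_tested + 1)
    logpmf = stats.binom.logpmf(ks, n_tested, p_null)
    return float(special.logsumexp(logpmf))


def count_directional(
    variants: Sequence[ClassifiedVariant], trait: str, alpha: float = DEFAULT_ALPHA
) -> tuple[int, int, int]:
    """(n_tested, n_increasing, n_decreasing) for one lookup trait over a
    set of aligned variants. Variants without a lookup estimate shrink
    n_tested rather than counting as non-significant."""
    n_tested = n_inc = n_dec = 0
    for v in variants:
        est = v.lookups.get(trait)
        if est is None:
            continue
        n_tested += 1
        p = est.p if est.p is not None else 2.0 * stats.norm.sf(abs(est.z))
        if p < alpha and est.beta > 0:
            n_inc += 1
        elif p < alpha and est.beta < 0:
            n_dec += 1
    return n_tested, n_inc, n_dec


def run_enrichment(
    variants: Sequence[ClassifiedVariant],
    traits: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    p_null: float = DEFAULT_P_NULL,
    n_tests_bonferroni: int | None = None,
) -> list[EnrichmentResult]:
    """One directional binomial test per class x trait x direction.

    The Bonferroni count defaults to (number of classes) x (number of
    traits) x 2; with the four classes and 21 lookup traits this is the
    0.05/168 level."""
    if n_tests_bonferroni is None:
        n_tests_bonferroni = len(CLASS_LABELS) * len(traits) * 2
    level = DEFAULT_ALPHA / n_tests_bonferroni
    results = []
    for label in CLASS_LABELS:
        members = [v for v in variants if v.class_label == label]
        for trait in traits:
            n_tested, n_inc, n_dec = count_directional(members, trait, alpha=alpha)
            for direction, k in (("increasing", n_inc), ("decreasing", n_dec)):
                if n_tested == 0:
                    p = 1.0
                else:
                    p = binomial_enrichment(n_tested, k, p_null)
                results.append(
                    EnrichmentResult(
                        class_label=label,
                        trait=trait,
                        direction=direction,
                        n_tested=n_tested,
                        n_significant=k,
                        p_binomial=p,
                        significant_flag=p < level,
                    )
                )
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular export shaped like a class x trait x direction results table."""
    return pd.DataFrame(
        {
            "class": [r.class_label for r in results],
            "trait": [r.trait for r in results],
            "direction": [r.direction for r in results],
            "n_tested": [r.n_tested for r in results],
            "n": [r.n_significant for r in results],
            "p_binomial": [r.p_binomial for r in results],
            "flag": [r.significant_flag for r in results],
        }
    )
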