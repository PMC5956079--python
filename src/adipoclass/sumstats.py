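"""Reading, validation, harmonization, and writing of GWAS summary statistics.

Tables are plain or gzipped tab-separated files in the GIANT 2015 dialect
(one row per variant with effect/other allele, effect-allele frequency,
beta, SE, P, and N). In memory a table is a :class:`pandas.DataFrame` with
the canonical columns in :data:`CANONICAL_COLUMNS`; every public function
accepts and returns that layout so tables can flow between modules without
conversion.

Effect sizes are per effect-allele copies on the inverse-normal-residual
scale (unitless SD), which is the scale on which all downstream algebra
(adjusted/unadjusted conversion, IVW meta-analysis) operates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, EmptyInputError, FormatError

logger = logging.getLogger(__name__)

#: canonical in-memory column order for a summary-statistics table
CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
    "trait",
    "stratum",
]

#: header synonyms covering the GIANT 2015 files and common lookup dialects;
#: keys are lower-cased source headers, values canonical names
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "markername": "variant_id",
    "snp": "variant_id",
    "rsid": "variant_id",
    "variant_id": "variant_id",
    "chr": "chrom",
    "chromosome": "chrom",
    "chrom": "chrom",
    "pos": "pos",
    "position": "pos",
    "bp": "pos",
    "a1": "effect_allele",
    "allele1": "effect_allele",
    "effect_allele": "effect_allele",
    "ea": "effect_allele",
    "a2": "other_allele",
    "allele2": "other_allele",
    "other_allele": "other_allele",
    "oa": "other_allele",
    "nea": "other_allele",
    "freqallele1hapmapceu": "eaf",
    "freq1.hapmap": "eaf",
    "eaf": "eaf",
    "freq1": "eaf",
    "frq": "eaf",
    "b": "beta",
    "beta": "beta",
    "effect": "beta",
    "se": "se",
    "stderr": "se",
    "p": "p",
    "p-value": "p",
    "pvalue": "p",
    "p_value": "p",
    "n": "n",
    "samplesize": "n",
}

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_AUTOSOMES = {str(i) for i in range(1, 23)}

#: mandatory canonical fields a parsed file must provide
_MANDATORY = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "n"]


@dataclass(frozen=True)
class CorrelationSpec:
    """Phenotype correlation between the covariate trait (BMI) and the
    unadjusted trait (WHR), overall and by sex stratum.

    The sex-combined value of ~0.44-0.50 and the sex-specific values
    (men ~0.60, women ~0.46) are the magnitudes observed in large
    population cohorts; all must lie strictly inside (-1, 1).
    """

    r_combined: float = 0.44
    r_women: float = 0.46
    r_men: float = 0.60

    def __post_init__(self) -> None:
        for name in ("r_combined", "r_women", "r_men"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ContractError(f"{name}={v} outside (-1, 1)")

    def for_stratum(self, stratum: str) -> float:
        return {
            "combined": self.r_combined,
            "women": self.r_women,
            "men": self.r_men,
        }[stratum]


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(np.asarray(beta, float) / np.asarray(se, float))
    return 2.0 * stats.norm.sf(z)


def read_sumstats(
    path,
    trait: str,
    stratum: str = "combined",
    column_map: Mapping[str, str] | None = None,
    p_consistency_rtol: float = 0.10,
) -> pd.DataFrame:
    """Read one summary-statistics file into the canonical table layout.

    Rows violating record invariants (alleles outside A/C/G/T, identical
    alleles, eaf outside (0,1), non-positive SE or N, or a P value
    inconsistent with beta/se beyond ``p_consistency_rtol`` relative
    tolerance on the -log10 scale) are dropped and the per-reason counts
    logged. A missing P column, or missing P entries, are imputed from the
    two-sided normal tail of beta/se.

    Raises
    ------
    FormatError
        if a mandatory column cannot be identified.
    EmptyInputError
        if no valid rows remain.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update({k.lower(): v for k, v in column_map.items()})

    raw = pd.read_csv(path, sep="\t", dtype=str)
    renames = {}
    for col in raw.columns:
        target = cmap.get(col.strip().lower())
        if target is not None and target not in renames.values():
            renames[col] = target
    df = raw.rename(columns=renames)

    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cannot identify mandatory column(s) {missing}")

    for col in ("chrom", "pos", "p"):
        if col not in df.columns:
            df[col] = np.nan

    out = pd.DataFrame(
        {
            "variant_id": df["variant_id"].astype(str).str.strip(),
            "chrom": df["chrom"].astype(str).str.strip().str.removeprefix("chr"),
            "pos": pd.to_numeric(df["pos"], errors="coerce"),
            "effect_allele": df["effect_allele"].astype(str).str.strip().str.upper(),
            "other_allele": df["other_allele"].astype(str).str.strip().str.upper(),
            "eaf": pd.to_numeric(df["eaf"], errors="coerce"),
            "beta": pd.to_numeric(df["beta"], errors="coerce"),
            "se": pd.to_numeric(df["se"], errors="coerce"),
            "p": pd.to_numeric(df["p"], errors="coerce"),
            "n": pd.to_numeric(df["n"], errors="coerce"),
        }
    )
    out["trait"] = trait
    out["stratum"] = stratum

    n_imputed = int(out["p"].isna().sum())
    if n_imputed:
        mask = out["p"].isna()
        out.loc[mask, "p"] = _two_sided_p(out.loc[mask, "beta"], out.loc[mask, "se"])
        logger.info("%s: imputed P from beta/se for %d rows", path, n_imputed)

    out, counts = _validate(out, p_consistency_rtol)
    for reason, k in counts.items():
        if k:
            logger.info("%s: dropped %d rows (%s)", path, k, reason)
    if out.empty:
        raise EmptyInputError(f"{path}: no valid records after filtering")
    out["pos"] = out["pos"].astype("Int64")
    return out.reset_index(drop=True)[CANONICAL_COLUMNS]


def _validate(df: pd.DataFrame, p_rtol: float) -> tuple[pd.DataFrame, dict]:
    counts: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)

    def drop(mask: pd.Series, reason: str) -> None:
        mask = mask & keep
        counts[reason] = int(mask.sum())
        keep[mask] = False

    drop(~df["effect_allele"].isin(_VALID_ALLELES), "invalid effect allele")
    drop(~df["other_allele"].isin(_VALID_ALLELES), "invalid other allele")
    drop(df["effect_allele"] == df["other_allele"], "identical alleles")
    drop(~((df["eaf"] > 0) & (df["eaf"] < 1)), "eaf outside (0,1)")
    drop(~(df["se"] > 0), "non-positive or missing se")
    drop(df["beta"].isna(), "missing beta")
    drop(~(df["n"] > 0), "non-positive or missing n")
    drop(~((df["p"] > 0) & (df["p"] <= 1)), "p outside (0,1]")
    drop(df["pos"].notna() & (df["pos"] < 0), "negative position")

    # P vs beta/se consistency on the -log10 scale; the absolute floor
    # absorbs rounding near p = 1 where the relative criterion degenerates
    expected = _two_sided_p(df["beta"].to_numpy(), df["se"].to_numpy())
    with np.errstate(divide="ignore"):
        l_obs = -np.log10(df["p"].to_numpy(float))
        l_exp = -np.log10(expected)
    tol = np.maximum(p_rtol * np.abs(l_exp), 0.1)
    inconsistent = pd.Series(np.abs(l_obs - l_exp) > tol, index=df.index) & df["p"].notna()
    drop(inconsistent, "p inconsistent with beta/se")

    return df[keep], counts


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a canonical table as tab-separated text (gzipped if the path
    ends in ``.gz``). Floats use shortest round-tripping representation so
    a write/read cycle is lossless."""
    df.to_csv(path, sep="\t", index=False)


def apply_qc(df: pd.DataFrame, min_n: int = 10_000, drop_sex_chroms: bool = True) -> pd.DataFrame:
    """Sample-size and chromosome QC: keep records with n >= ``min_n`` and,
    if requested, drop sex-chromosome (non-autosomal) records."""
    if min_n < 0:
        raise ContractError("min_n must be >= 0")
    keep = df["n"] >= min_n
    logger.info("QC: %d records below n=%d removed", int((~keep).sum()), min_n)
    if drop_sex_chroms:
        autosomal = df["chrom"].astype(str).isin(_AUTOSOMES)
        logger.info("QC: %d non-autosomal records removed", int((keep & ~autosomal).sum()))
        keep &= autosomal
    return df[keep].reset_index(drop=True)


def harmonize_alleles(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Express all tables on a single reference effect allele per variant.

    The reference orientation is the (effect, other) pair of the variant's
    first occurrence across the input tables. Records whose alleles match
    after swapping get their beta negated and eaf complemented; strand
    complements are accepted in either orientation. Variants whose allele
    pair cannot be reconciled by swap and/or complement are dropped
    entirely (all their records), with a log entry. Strand-ambiguous
    variants (A/T or C/G pairs) are kept and flagged in the boolean
    ``ambiguous`` column.
    """
    frames = [t for t in tables if t is not None]
    if not frames:
        raise ContractError("harmonize_alleles needs at least one table")
    combined = pd.concat(frames, ignore_index=True)

    ref: dict[str, tuple[str, str]] = {}
    first = combined.drop_duplicates("variant_id")
    for vid, ea, oa in zip(first["variant_id"], first["effect_allele"], first["other_allele"]):
        ref[vid] = (ea, oa)

    flip = np.zeros(len(combined), dtype=bool)
    bad = np.zeros(len(combined), dtype=bool)
    for i, (vid, ea, oa) in enumerate(
        zip(combined["variant_id"], combined["effect_allele"], combined["other_allele"])
    ):
        r_ea, r_oa = ref[vid]
        pair = (ea, oa)
        if pair == (r_ea, r_oa):
            continue
        if pair == (r_oa, r_ea):
            flip[i] = True
            continue
        comp = (_COMPLEMENT[ea], _COMPLEMENT[oa])
        if comp == (r_ea, r_oa):
            continue
        if comp == (r_oa, r_ea):
            flip[i] = True
            continue
        bad[i] = True

    bad_variants = set(combined.loc[bad, "variant_id"])
    if bad_variants:
        logger.info(
            "harmonize: dropped %d variants with irreconcilable alleles", len(bad_variants)
        )
        keep_mask = ~combined["variant_id"].isin(bad_variants)
        combined, flip = combined[keep_mask.to_numpy()], flip[keep_mask.to_numpy()]
    if combined.empty:
        raise EmptyInputError("no variants survived allele harmonization")

    out = combined.copy().reset_index(drop=True)
    flip = np.asarray(flip)
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
    ea = out["variant_id"].map(lambda v: ref[v][0])
    oa = out["variant_id"].map(lambda v: ref[v][1])
    out["effect_allele"] = ea
    out["other_allele"] = oa
    out["ambiguous"] = [
        (a, b) in _AMBIGUOUS_PAIRS for a, b in zip(out["effect_allele"], out["other_allele"])
    ]
    return out


def split_by_trait(table: pd.DataFrame) -> dict[tuple[str, str], pd.DataFrame]:
    """Partition a (possibly harmonized multi-trait) table into per
    (trait, stratum) tables."""
    return {
        key: sub.reset_index(drop=True)
        for key, sub in table.groupby(["trait", "stratum"], sort=False)
    }
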