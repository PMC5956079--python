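"""Genome-wide significant variant selection and distance/LD clumping.

Candidates are the union, over the three scans (BMI, WHR, WHRadjBMI), of
variants with P < 5e-8 (strict inequality). They are clumped greedily into
non-overlapping independent signals: the unassigned candidate with the
smallest P across scans seeds a region and absorbs every unassigned
candidate within the distance window to either side or in LD (r^2 above
the threshold) with it. Two signals are thus independent only when they
are BOTH farther apart than the window AND below the r^2 threshold.

The lead variant of a region is the variant with the smallest association
P value within it, no matter from which scan; cross-scan P values are
compared directly. Ties are broken by chromosome, position, then variant
ID. The "traits of a region" are the union of scans in which any member
reaches genome-wide significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ContractError

logger = logging.getLogger(__name__)

GWS_THRESHOLD = 5e-8
DEFAULT_WINDOW_BP = 500_000
DEFAULT_R2_MAX = 0.1


@dataclass
class LDSource:
    """Pairwise r^2 lookups; pairs absent from the source fall back to
    ``default_r2`` (0 when clumping by distance only)."""

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    default_r2: float = 0.0

    def __post_init__(self) -> None:
        normalized = {}
        for (a, b), r2 in self.pairs.items():
            if not 0.0 <= r2 <= 1.0:
                raise ContractError(f"r2({a},{b})={r2} outside [0,1]")
            normalized[(a, b) if a <= b else (b, a)] = r2
        self.pairs = normalized

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get((a, b) if a <= b else (b, a), self.default_r2)

    @classmethod
    def from_table(cls, path, default_r2: float = 0.0) -> "LDSource":
        """Load a 3-column TSV (id1, id2, r2)."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        df.columns = ["id1", "id2", "r2"]
        return cls(
            pairs={(a, b): float(r) for a, b, r in zip(df["id1"], df["id2"], df["r2"])},
            default_r2=default_r2,
        )

    @classmethod
    def from_blocks(
        cls, blocks: Iterable[Iterable[str]], r2_within: float = 0.8, default_r2: float = 0.0
    ) -> "LDSource":
        """Equicorrelated LD blocks: every pair within a block gets
        ``r2_within``, all other pairs ``default_r2``."""
        pairs = {}
        for block in blocks:
            members = list(block)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    pairs[(a, b)] = r2_within
        return cls(pairs=pairs, default_r2=default_r2)


@dataclass
class Signal:
    """A clumped independent region."""

    lead: str
    lead_trait: str
    chrom: str
    lead_pos: int
    member_variants: set[str]
    region_start: int
    region_end: int
    traits_of_region: set[str] = field(default_factory=set)


def select_gws(
    tables: Mapping[str, pd.DataFrame], threshold: float = GWS_THRESHOLD
) -> set[tuple[str, str]]:
    """All (variant_id, scan) pairs with P strictly below the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ContractError(f"threshold must be in (0,1), got {threshold}")
    hits: set[tuple[str, str]] = set()
    for scan, table in tables.items():
        sig = table.loc[table["p"] < threshold, "variant_id"]
        hits.update((vid, scan) for vid in sig)
    return hits


def _candidate_frame(
    candidates: set[tuple[str, str]], tables: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-candidate variant annotation with the minimum P across scans and
    the scan attaining it."""
    by_variant: dict[str, dict] = {}
    candidate_ids = {v for v, _ in candidates}
    for scan, table in tables.items():
        sub = table[table["variant_id"].isin(candidate_ids)]
        for vid, chrom, pos, p in zip(sub["variant_id"], sub["chrom"], sub["pos"], sub["p"]):
            rec = by_variant.setdefault(
                vid, {"variant_id": vid, "chrom": str(chrom), "pos": int(pos), "p": float("inf"), "scan": ""}
            )
            if p < rec["p"]:
                rec["p"] = float(p)
                rec["scan"] = scan
    missing = candidate_ids - set(by_variant)
    if missing:
        raise ContractError(f"candidates absent from all tables: {sorted(missing)[:5]}")
    return pd.DataFrame(by_variant.values())


def clump(
    candidates: set[tuple[str, str]],
    tables: Mapping[str, pd.DataFrame],
    ld: LDSource | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
    r2_max: float = DEFAULT_R2_MAX,
) -> list[Signal]:
    """Greedy clumping of candidates into independent signals.

    Repeatedly the unassigned candidate with the smallest cross-scan P
    (ties: smaller chromosome, position, then variant ID) becomes a lead;
    it absorbs every unassigned candidate either within ``window_bp`` to
    either side on the same chromosome or with r^2 > ``r2_max`` against it.
    Without an LD source, clumping is distance-only (r^2 assumed 0).
    """
    if window_bp <= 0:
        raise ContractError("window_bp must be > 0")
    if not 0.0 <= r2_max <= 1.0:
        raise ContractError("r2_max must be in [0,1]")
    if not candidates:
        return []
    if ld is None:
        logger.warning("clump: no LD source supplied; distance-only clumping (r2 = 0 assumed)")
        ld = LDSource()

    def _chrom_key(c: str):
        return (0, int(c)) if str(c).isdigit() else (1, str(c))

    frame = _candidate_frame(candidates, tables)
    order = sorted(
        frame.itertuples(index=False),
        key=lambda r: (r.p, _chrom_key(r.chrom), r.pos, r.variant_id),
    )
    unassigned = {r.variant_id: r for r in order}
    signals: list[Signal] = []
    for rec in order:
        if rec.variant_id not in unassigned:
            continue
        members = {rec.variant_id}
        del unassigned[rec.variant_id]
        positions = [rec.pos]
        for vid in list(unassigned):
            other = unassigned[vid]
            near = other.chrom == rec.chrom and abs(other.pos - rec.pos) <= window_bp
            linked = ld.r2(rec.variant_id, vid) > r2_max
            if near or linked:
                members.add(vid)
                positions.append(other.pos if other.chrom == rec.chrom else rec.pos)
                del unassigned[vid]
        signals.append(
            Signal(
                lead=rec.variant_id,
                lead_trait=rec.scan,
                chrom=rec.chrom,
                lead_pos=rec.pos,
                member_variants=members,
                region_start=min(positions),
                region_end=max(positions),
                traits_of_region=set(),
            )
        )
    for sig in signals:
        sig.traits_of_region = traits_of_region(sig, candidates)
    return signals


def traits_of_region(signal: Signal, gws: set[tuple[str, str]]) -> set[str]:
    """Union of scans in which any member variant is genome-wide
    significant."""
    return {scan for vid, scan in gws if vid in signal.member_variants}


def signals_frame(signals: list[Signal]) -> pd.DataFrame:
    """Tabular export of a clumping result."""
    return pd.DataFrame(
        {
            "lead": [s.lead for s in signals],
            "lead_trait": [s.lead_trait for s in signals],
            "chrom": [s.chrom for s in signals],
            "lead_pos": [s.lead_pos for s in signals],
            "region_start": [s.region_start for s in signals],
            "region_end": [s.region_end for s in signals],
            "n_members": [len(s.member_variants) for s in signals],
            "traits_of_region": [",".join(sorted(s.traits_of_region)) for s in signals],
        }
    )
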