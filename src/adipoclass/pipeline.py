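"""End-to-end orchestration: QC -> selection -> clumping -> effect algebra
-> classification -> enrichment -> Mendelian randomization.

A single declarative :class:`PipelineConfig` drives the run. Scans can be
read from GIANT-dialect files or generated from the bundled synthetic
architecture; when no WHR scan is available its effects are computed from
the WHRadjBMI and BMI scans via the conversion relation (noted in the
manifest). Every stage writes a tabular artifact plus a JSON manifest with
the seed, parameter hash, and per-stage counts so a run is reproducible
and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .algebra import EffectEstimate, convert_table
from .classify import (
    CLASS_LABELS,
    ClassifiedVariant,
    align_alleles_by_class,
    classify,
    flag_supra_expected,
    reclassify_sensitivity,
    summarize_transitions,
)
from .enrichment import enrichment_frame, run_enrichment
from .errors import AdipoclassError, ContractError
from .mr import ELIGIBLE_CLASSES, joint_risk, mr_frame, run_class_mr
from .selection import LDSource, clump, select_gws, signals_frame
from .sumstats import CorrelationSpec, apply_qc, read_sumstats, write_sumstats
from .synthetic import ArchitectureSpec, cohort_to_sumstats, simulate_cohort, write_truth

logger = logging.getLogger(__name__)

SCAN_TRAITS = ("BMI", "WHR", "WHRadjBMI")


@dataclass
class PipelineConfig:
    """Declarative configuration; defaults are the analysis constants of
    the adiposity screen (P < 5e-8 selection, 500 kb / r^2 0.1 clumping,
    n >= 10,000 QC, nominal 0.05 classification)."""

    scan_paths: dict = field(default_factory=dict)  # trait -> path
    lookup_paths: dict = field(default_factory=dict)  # trait -> path
    ld_path: str | None = None
    synthetic: ArchitectureSpec | None = None
    correlation: CorrelationSpec = field(default_factory=CorrelationSpec)
    gws_threshold: float = 5e-8
    nominal_alpha: float = 0.05
    strict_alpha: float | None = None  # default 0.05 / n_signals
    window_bp: int = 500_000
    r2_max: float = 0.1
    min_n: int = 10_000
    enrichment_p_null: float = 0.025
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = ArchitectureSpec(**raw["synthetic"])
        if "correlation" in raw and raw["correlation"] is not None:
            raw["correlation"] = CorrelationSpec(**raw["correlation"])
        return cls(**raw)

    def parameter_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    scans: dict
    lookups: dict
    signals: list
    classified: list
    transitions: pd.DataFrame
    enrichment: pd.DataFrame
    mr: pd.DataFrame
    joint: pd.DataFrame
    manifest: dict


def effect_from_row(row, trait: str | None = None) -> EffectEstimate:
    """Build an :class:`EffectEstimate` from one canonical table row."""
    return EffectEstimate(
        beta=float(row["beta"]),
        se=float(row["se"]),
        p=float(row["p"]) if pd.notna(row["p"]) else None,
        n=float(row["n"]),
        trait=trait if trait is not None else str(row["trait"]),
        stratum=str(row["stratum"]),
        variant_id=str(row["variant_id"]),
    )


def _index_table(table: pd.DataFrame) -> dict[str, pd.Series]:
    return {vid: row for vid, row in zip(table["variant_id"], table.to_dict("records"))}


def classify_leads(
    leads: Sequence[str],
    bmi_table: pd.DataFrame,
    whr_table: pd.DataFrame,
    adj_table: pd.DataFrame | None = None,
    lookups: Mapping[str, pd.DataFrame] | None = None,
    alpha: float = 0.05,
    r: float = 0.44,
    gws: set | None = None,
) -> list[ClassifiedVariant]:
    """Classify lead variants from the BMI and WHR scan effects, align
    alleles by class, flag supra-expected WHR effects, and attach
    adjusted-scan and lookup-trait estimates on the aligned allele."""
    bmi_idx = _index_table(bmi_table)
    whr_idx = _index_table(whr_table)
    adj_idx = _index_table(adj_table) if adj_table is not None else {}
    lookup_idx = {t: _index_table(tab) for t, tab in (lookups or {}).items()}
    out: list[ClassifiedVariant] = []
    for vid in leads:
        if vid not in bmi_idx or vid not in whr_idx:
            logger.warning("lead %s missing from BMI or WHR table; skipped", vid)
            continue
        row_b, row_w = bmi_idx[vid], whr_idx[vid]
        if not np.isfinite(row_b["beta"]) or not np.isfinite(row_w["beta"]):
            logger.warning("lead %s has missing effects; skipped", vid)
            continue
        b_bmi = effect_from_row(row_b, "BMI")
        b_whr = effect_from_row(row_w, "WHR")
        label = classify(b_bmi, b_whr, alpha=alpha)
        v = ClassifiedVariant(
            variant_id=vid,
            class_label=label,
            b_bmi=b_bmi,
            b_whr=b_whr,
            b_whradjbmi=effect_from_row(adj_idx[vid], "WHRadjBMI") if vid in adj_idx else None,
            effect_allele=str(row_b["effect_allele"]),
            other_allele=str(row_b["other_allele"]),
            source_scans={s for w, s in (gws or set()) if w == vid},
            lookups={
                t: effect_from_row(idx[vid], t)
                for t, idx in lookup_idx.items()
                if vid in idx and np.isfinite(idx[vid]["beta"])
            },
            supra_expected=flag_supra_expected(b_bmi, b_whr, r),
        )
        out.append(align_alleles_by_class(v))
    return out


def classification_frame(classified: Sequence[ClassifiedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in classified],
            "class": [v.class_label for v in classified],
            "aligned_allele": [v.aligned_allele for v in classified],
            "b_bmi": [v.b_bmi.beta for v in classified],
            "p_bmi": [v.b_bmi.p for v in classified],
            "b_whr": [v.b_whr.beta for v in classified],
            "p_whr": [v.b_whr.p for v in classified],
            "b_whradjbmi": [
                v.b_whradjbmi.beta if v.b_whradjbmi else np.nan for v in classified
            ],
            "supra_expected": [v.supra_expected for v in classified],
            "source_scans": [",".join(sorted(v.source_scans)) for v in classified],
        }
    )


def _load_scans(config: PipelineConfig, outdir: Path | None) -> tuple[dict, dict, dict]:
    """Returns (scans, lookups, provenance-notes)."""
    notes: dict = {}
    if config.synthetic is not None:
        spec = config.synthetic
        cohort = simulate_cohort(spec)
        tables = cohort_to_sumstats(
            cohort, traits=("BMI", "WHR", "WHRadjBMI", "DISEASE"), strata=("combined",)
        )
        scans = {t: tables[(t, "combined")] for t in SCAN_TRAITS}
        lookups = {"DISEASE": tables[("DISEASE", "combined")]}
        notes["input"] = "synthetic"
        notes["true_class_counts"] = spec.class_counts
        if outdir is not None:
            write_truth(cohort.truth, outdir / "truth.tsv")
            for t, tab in {**scans, **lookups}.items():
                write_sumstats(tab, outdir / f"sumstats_{t}.tsv")
    else:
        scans = {
            t: read_sumstats(p, trait=t) for t, p in config.scan_paths.items()
        }
        lookups = {
            t: read_sumstats(p, trait=t) for t, p in config.lookup_paths.items()
        }
        notes["input"] = "files"
    return scans, lookups, notes


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order; returns the stage outputs and a
    manifest with seed, parameter hash, and per-stage counts. Any stage
    failure is re-raised annotated with the stage name."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
    }
    stage = "load"
    try:
        scans, lookups, notes = _load_scans(config, outdir)
        manifest.update(notes)

        stage = "qc"
        scans = {t: apply_qc(tab, min_n=config.min_n) for t, tab in scans.items()}
        manifest["records_per_scan"] = {t: int(len(tab)) for t, tab in scans.items()}

        stage = "effect_algebra"
        if "WHR" not in scans:
            if "WHRadjBMI" not in scans or "BMI" not in scans:
                raise ContractError("need BMI and WHRadjBMI scans to compute WHR")
            computed = convert_table(
                scans["WHRadjBMI"], scans["BMI"], r=config.correlation.r_combined
            )
            computed = computed.rename(
                columns={"beta_computed": "beta", "se_computed": "se", "p_computed": "p"}
            )
            scans["WHR"] = computed
            manifest["whr_source"] = "computed from WHRadjBMI and BMI"
        else:
            manifest["whr_source"] = "observed"

        stage = "selection"
        gws = select_gws(scans, threshold=config.gws_threshold)
        manifest["n_gws_candidates"] = len({v for v, _ in gws})
        manifest["gws_per_scan"] = {
            t: int(sum(1 for _, s in gws if s == t)) for t in scans
        }

        stage = "clumping"
        ld = LDSource.from_table(config.ld_path) if config.ld_path else None
        signals = clump(
            gws, scans, ld=ld, window_bp=config.window_bp, r2_max=config.r2_max
        )
        manifest["n_signals"] = len(signals)

        stage = "classification"
        classified = classify_leads(
            [s.lead for s in signals],
            scans["BMI"],
            scans["WHR"],
            adj_table=scans.get("WHRadjBMI"),
            lookups=lookups,
            alpha=config.nominal_alpha,
            r=config.correlation.r_combined,
            gws=gws,
        )
        counts = {label: 0 for label in CLASS_LABELS}
        for v in classified:
            counts[v.class_label] = counts.get(v.class_label, 0) + 1
        manifest["class_counts"] = counts
        strict = (
            config.strict_alpha
            if config.strict_alpha is not None
            else (0.05 / len(signals) if signals else 0.05)
        )
        transitions = (
            reclassify_sensitivity(classified, alpha_strict=strict, alpha=config.nominal_alpha)
            if classified
            else pd.DataFrame(columns=["variant_id", "class_old", "class_new", "changed"])
        )
        manifest["strict_alpha"] = strict
        if len(transitions):
            manifest["reclassification"] = summarize_transitions(transitions)

        stage = "enrichment"
        lookup_traits = sorted(lookups)
        enr = enrichment_frame(
            run_enrichment(
                classified, lookup_traits, alpha=config.nominal_alpha,
                p_null=config.enrichment_p_null,
            )
        ) if lookup_traits else pd.DataFrame()

        stage = "mendelian_randomization"
        mr_results = run_class_mr(classified, lookup_traits) if lookup_traits else []
        mr_tab = mr_frame(mr_results) if mr_results else pd.DataFrame()
        joint_rows = []
        for label in ELIGIBLE_CLASSES:
            for trait in lookup_traits:
                try:
                    jr = joint_risk(classified, trait, class_label=label)
                except AdipoclassError:
                    continue
                joint_rows.append(
                    {
                        "class": jr.class_label,
                        "outcome": jr.outcome,
                        "joint_log_or": jr.joint_log_or,
                        "joint_rr": jr.joint_rr,
                        "n_variants": jr.n_variants,
                    }
                )
        joint_tab = pd.DataFrame(joint_rows)
    except AdipoclassError as err:
        logger.error("pipeline stage %s failed: %s", stage, err)
        raise AdipoclassError(f"stage {stage!r}: {err}") from err

    if outdir is not None:
        signals_frame(signals).to_csv(outdir / "signals.tsv", sep="\t", index=False)
        classification_frame(classified).to_csv(
            outdir / "classification.tsv", sep="\t", index=False
        )
        transitions.to_csv(outdir / "transitions.tsv", sep="\t", index=False)
        if len(enr):
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        if len(mr_tab):
            mr_tab.to_csv(outdir / "mr.tsv", sep="\t", index=False)
        if len(joint_tab):
            joint_tab.to_csv(outdir / "joint_risk.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        scans=scans,
        lookups=lookups,
        signals=signals,
        classified=classified,
        transitions=transitions,
        enrichment=enr,
        mr=mr_tab,
        joint=joint_tab,
        manifest=manifest,
    )
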