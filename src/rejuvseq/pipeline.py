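"""End-to-end analysis flows: reversal, genotype dependence, survival.

Each pipeline runs counts -> RPKM -> expression filter -> pairwise contrasts
-> classifier -> partition summary, writes every intermediate to the output
directory when one is given, and records a provenance file (package version,
configuration hash, seed) sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .classify import (
    DependenceThresholds,
    ReversalThresholds,
    classify_dependence,
    classify_reversal,
    summarize_partition,
)
from .differential import ContrastSpec, contrast_test
from .expression import compute_rpkm, filter_expressed
from .survival import summarize_survival

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_reversal_pipeline",
    "run_dependence_pipeline",
    "run_survival_pipeline",
]


@dataclass
class PipelineConfig:
    """File paths, group labels and thresholds driving one pipeline run."""

    counts: str | None = None
    annotation: str | None = None
    sample_sheet: str | None = None
    survival: str | None = None
    outdir: str | None = None
    seed: int = 0
    filter_threshold: float = 4.0
    filter_min_fraction: float = 0.5
    # reversal flow group labels (sample-sheet `group` values)
    young: str = "young_WT"
    old_veh: str = "old_WT_Veh"
    old_hes: str = "old_WT_Hes"
    fdr_set1: float = 0.1
    p_set2: float = 0.05
    p_set3: float = 0.05
    # dependence flow group labels
    wt_veh: str = "WT_Veh"
    wt_hes: str = "WT_Hes"
    ko_veh: str = "mcKO_Veh"
    ko_hes: str = "mcKO_Hes"
    fdr_deg: float = 0.2
    p_ko: float = 0.05
    # survival flow arms
    reference_arm: str = "Veh"
    comparison_arm: str = "Hes"
    exact_permutation: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def digest(self) -> str:
        # outdir is a pure output location: excluded so reruns of the same
        # analysis into different directories share a provenance hash
        d = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _provenance(cfg: PipelineConfig, stage: str, extra: dict | None = None) -> dict:
    rec = {
        "tool": "rejuvseq",
        "version": __version__,
        "stage": stage,
        "config": {k: v for k, v in asdict(cfg).items() if k != "outdir"},
        "config_sha256_16": cfg.digest(),
        "seed": cfg.seed,
    }
    if extra:
        rec.update(extra)
    return rec


def _check_groups(sheet: pd.DataFrame, labels: list[str]) -> None:
    present = set(sheet["group"])
    missing = [g for g in labels if g not in present]
    if missing:
        raise ValueError(f"group label(s) not in sample sheet: {missing}")


def _prepare_expression(counts, annotation, cfg):
    rpkm = compute_rpkm(counts, annotation)
    retained = filter_expressed(
        rpkm, threshold=cfg.filter_threshold, min_fraction=cfg.filter_min_fraction
    )
    return rpkm, retained


def run_reversal_pipeline(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    sheet: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Three-contrast reversal flow; returns calls, summary and intermediates."""
    cfg = cfg or PipelineConfig()
    _check_groups(sheet, [cfg.young, cfg.old_veh, cfg.old_hes])
    rpkm, retained = _prepare_expression(counts, annotation, cfg)
    universe = tuple(retained)
    specs = {
        "set1": ContrastSpec("set1_oldVeh_vs_young", cfg.young, cfg.old_veh, universe),
        "set2": ContrastSpec("set2_oldHes_vs_oldVeh", cfg.old_veh, cfg.old_hes, universe),
        "set3": ContrastSpec("set3_oldHes_vs_young", cfg.young, cfg.old_hes, universe),
    }
    tables = {k: contrast_test(rpkm, sheet, s) for k, s in specs.items()}
    calls = classify_reversal(
        tables["set1"], tables["set2"], tables["set3"],
        ReversalThresholds(cfg.fdr_set1, cfg.p_set2, cfg.p_set3),
    )
    summary = summarize_partition(calls)
    summary["thresholds"] = {"fdr_set1": cfg.fdr_set1, "p_set2": cfg.p_set2, "p_set3": cfg.p_set3}
    summary["retained_genes"] = len(retained)
    summary["total_genes"] = int(counts.shape[0])
    result = {
        "rpkm": rpkm,
        "retained": retained,
        "contrasts": tables,
        "calls": calls,
        "summary": summary,
    }
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_matrix(rpkm, out / "rpkm.tsv")
        io.write_gene_list(retained, out / "retained_genes.txt")
        for key, tbl in tables.items():
            io.write_contrast_table(tbl, out / f"contrast_{key}.tsv")
        calls.to_csv(out / "reversal_calls.tsv", sep="\t", index=False)
        io.write_json(summary, out / "reversal_summary.json")
        io.write_json(
            _provenance(cfg, "run-reversal", {"retained_genes": len(retained)}),
            out / "provenance.json",
        )
    return result


def run_dependence_pipeline(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    sheet: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Factorial (genotype x treatment) dependence flow."""
    cfg = cfg or PipelineConfig()
    _check_groups(sheet, [cfg.wt_veh, cfg.wt_hes, cfg.ko_veh, cfg.ko_hes])
    rpkm, retained = _prepare_expression(counts, annotation, cfg)
    universe = tuple(retained)
    specs = {
        "wt": ContrastSpec("wt_Hes_vs_Veh", cfg.wt_veh, cfg.wt_hes, universe),
        "ko": ContrastSpec("ko_Hes_vs_Veh", cfg.ko_veh, cfg.ko_hes, universe),
    }
    tables = {k: contrast_test(rpkm, sheet, s) for k, s in specs.items()}
    calls = classify_dependence(
        tables["wt"], tables["ko"], DependenceThresholds(cfg.fdr_deg, cfg.p_ko)
    )
    summary = summarize_partition(calls, denominator_categories=("dependent", "independent"))
    summary["thresholds"] = {"fdr_deg": cfg.fdr_deg, "p_ko": cfg.p_ko}
    summary["retained_genes"] = len(retained)
    summary["total_genes"] = int(counts.shape[0])
    result = {
        "rpkm": rpkm,
        "retained": retained,
        "contrasts": tables,
        "calls": calls,
        "summary": summary,
    }
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_matrix(rpkm, out / "rpkm.tsv")
        io.write_gene_list(retained, out / "retained_genes.txt")
        for key, tbl in tables.items():
            io.write_contrast_table(tbl, out / f"contrast_{key}.tsv")
        calls.to_csv(out / "dependence_calls.tsv", sep="\t", index=False)
        io.write_json(summary, out / "dependence_summary.json")
        io.write_json(
            _provenance(cfg, "run-dependence", {"retained_genes": len(retained)}),
            out / "provenance.json",
        )
    return result


def run_survival_pipeline(data: pd.DataFrame, cfg: PipelineConfig | None = None) -> dict:
    """Arm summaries + log-rank comparison; writes summary and KM curves."""
    from .survival import km_curve

    cfg = cfg or PipelineConfig()
    summary = summarize_survival(
        data, cfg.reference_arm, cfg.comparison_arm, exact_permutation=cfg.exact_permutation
    )
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_json(summary, out / "survival_summary.json")
        for arm in (cfg.reference_arm, cfg.comparison_arm):
            km_curve(data, arm).to_csv(out / f"km_curve_{arm}.tsv", sep="\t", index=False)
        io.write_json(_provenance(cfg, "survival"), out / "provenance.json")
    return summary
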