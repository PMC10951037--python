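"""End-to-end orchestration: select -> z-score -> trajectory -> centiles
-> filters -> correlation -> gene sets -> enrichment, with a run manifest.

Every stage writes its tabular output under the configured output
directory; the manifest echoes the configuration and records per-stage
counts so a run is auditable without re-execution.  Any stage failure is
re-raised as :class:`PipelineStageError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import coexpression, enrichment, io, relative, trajectory

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults are the analysis constants
    (4 other regions, z > 1.96, quartile filter, 5 missing z, r beyond
    +/-0.6, alpha 0.05)."""

    matrix: str = "expression_matrix.csv"
    rows_meta: str = "rows_metadata.csv"
    columns_meta: str = "columns_metadata.csv"
    gmt: str | None = None
    out_dir: str = "cbrel_out"
    target_gene: str = "ATM"
    min_other_regions: int = 4
    elevation_threshold: float = 1.96
    infants_in_phase2: bool = True
    log_transform: bool = False
    apply_quartile_filter: bool = True
    max_missing_z: int = 5
    upper_r: float = 0.6
    lower_r: float = -0.6
    min_pairs: int = 3
    enrichment_alpha: float = 0.05
    cerebellar_labels: tuple[str, ...] = tuple(sorted(io.DEFAULT_CEREBELLAR_LABELS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.lower_r < self.upper_r <= 1.0:
            raise ValueError("correlation thresholds out of order or range")
        if not 0.0 < self.enrichment_alpha < 1.0:
            raise ValueError("enrichment_alpha must lie in (0, 1)")
        if self.min_other_regions < 0 or self.max_missing_z < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "cerebellar_labels" in raw:
            raw["cerebellar_labels"] = tuple(raw["cerebellar_labels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cerebellar_labels"] = list(self.cerebellar_labels)
        return d


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to
    ``out_dir/manifest.yaml``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "cbrel",
        "version": __version__,
        "config": cfg.to_dict(),
        "stages": {},
    }

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineStageError(name, exc) from exc
        return _Ctx()

    with stage("load"):
        ds = io.read_brainspan(
            cfg.matrix, cfg.rows_meta, cfg.columns_meta, cfg.cerebellar_labels
        )
        if cfg.target_gene not in ds.values.index:
            raise ValueError(f"target gene {cfg.target_gene!r} absent from dataset")
        manifest["stages"]["load"] = {
            "n_genes": len(ds.genes),
            "n_donors": len(ds.specimens),
        }

    with stage("select_specimens"):
        ds, excluded = io.select_specimens(ds, cfg.min_other_regions)
        io.write_exclusion_report(excluded, out / "excluded_specimens.tsv")
        manifest["stages"]["select_specimens"] = {
            "n_included": len(ds.specimens),
            "n_excluded": len(excluded),
        }

    with stage("drop_never_expressed"):
        ds, dropped = relative.drop_never_expressed(ds)
        pd.Series(dropped, name="gene").to_csv(
            out / "never_expressed_genes.tsv", sep="\t", index=False
        )
        manifest["stages"]["drop_never_expressed"] = {
            "n_dropped": len(dropped),
            "n_retained": len(ds.genes),
        }

    with stage("relative_z"):
        zm = relative.relative_z(ds, log_transform=cfg.log_transform)
        relative.write_zmatrix(zm, out / "zmatrix.tsv", out / "specimens.tsv")
        manifest["stages"]["relative_z"] = {
            "n_genes": len(zm.genes),
            "n_specimens": len(zm.donor_ids),
            "n_degenerate_cells": zm.n_degenerate,
        }

    with stage("trajectory"):
        phases = trajectory.default_phases(cfg.infants_in_phase2)
        fits, combined = trajectory.two_phase_report(
            zm, cfg.target_gene, phases, cfg.elevation_threshold
        )
        trajectory.write_trajectory_report(
            fits, combined, out / "trajectory_fits.tsv", out / "trajectory_specimens.tsv"
        )
        manifest["stages"]["trajectory"] = {
            f.phase.name: {"n": f.n, "r": f.pearson_r, "p": f.p_value} for f in fits
        }
        manifest["stages"]["trajectory"]["n_elevated"] = int(combined["elevated"].sum())

    with stage("centile_benchmark"):
        centiles = relative.centile_benchmark(zm, cfg.target_gene)
        centiles.to_csv(out / "centiles.tsv", sep="\t", index=False)
        manifest["stages"]["centile_benchmark"] = {
            "n_specimens": len(centiles),
            "n_above_p95": int((centiles["centile"] > 95).sum()),
        }

    with stage("filter_genes"):
        retained, report = coexpression.filter_genes(
            ds, zm, cfg.max_missing_z, apply_quartile_filter=cfg.apply_quartile_filter
        )
        manifest["stages"]["filter_genes"] = {
            "n_input": report.n_input,
            "quartile_threshold": None
            if math.isnan(report.quartile_threshold)
            else float(report.quartile_threshold),
            "n_low_expression_dropped": report.n_low_expression_dropped,
            "n_missingness_dropped": report.n_missingness_dropped,
            "n_retained": report.n_retained,
        }

    with stage("correlate"):
        ct = coexpression.correlate_all(zm, cfg.target_gene, retained, cfg.min_pairs)
        ct.to_csv(out / "correlations.tsv", sep="\t", na_rep="")
        manifest["stages"]["correlate"] = {
            "n_genes": len(ct),
            "n_with_r": int(ct["r"].notna().sum()),
        }

    with stage("build_sets"):
        sets = coexpression.build_sets(ct, cfg.upper_r, cfg.lower_r)
        coexpression.write_gene_sets(
            sets,
            out / "positively_correlated.txt",
            out / "negatively_correlated.txt",
            out / "correlated_sets.gmt",
        )
        manifest["stages"]["build_sets"] = {
            "n_positive": len(sets.positive),
            "n_negative": len(sets.negative),
        }

    if cfg.gmt is not None:
        with stage("enrich"):
            ann = enrichment.read_gmt(cfg.gmt)
            universe = frozenset(retained)
            enr = {}
            for label, genes in (
                ("positive", sets.positive),
                ("negative", sets.negative),
            ):
                if not genes:
                    continue
                table = enrichment.enrich(genes, ann, universe)
                table.to_csv(out / f"enrichment_{label}.tsv", sep="\t", index=False)
                enr[label] = {
                    "n_terms_tested": len(table),
                    "n_significant": int((table["fdr"] < cfg.enrichment_alpha).sum()),
                }
            manifest["stages"]["enrich"] = enr

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
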