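"""End-to-end orchestration: normalize -> test -> cluster (+ optional stages).

A run takes a :class:`RawScreenSet`, applies OD normalization, control-based
plate/day correction, significance testing and exhaustive significance
clustering, and returns every intermediate plus a manifest recording the
configuration, package versions, seed and per-stage row counts.  Identical
inputs and config reproduce identical outputs.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .esc_clustering import ClusterSet, cluster_medians, esc_cluster
from .io_formats import ElementPanel, RawScreenSet
from .normalization import (
    PhenotypeTable,
    fit_plate_correction,
    od_normalize,
    summarize_phenotypes,
)
from .significance import CallSet, call_significance

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline"]

_DATASET_PANELS = {"KO": "KO", "KOd": "KO", "OE": "OE"}


@dataclass
class PipelineConfig:
    """Flat configuration of a full analysis run; unknown keys are errors."""

    dataset: str = "KO"
    panel: str | None = None  # preset name; defaults to the dataset's panel
    alpha: float = 0.05
    min_cluster_size: int = 3
    correlation_method: str = "pearson"
    alpha_cond: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.dataset not in _DATASET_PANELS:
            raise ConfigError(f"dataset must be KO, KOd or OE (got {self.dataset!r})")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.min_cluster_size < 1:
            raise ConfigError("min_cluster_size must be >= 1")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ConfigError(
                f"unknown correlation method: {self.correlation_method!r}"
            )

    def resolve_panel(self) -> ElementPanel:
        return ElementPanel.preset(self.panel or _DATASET_PANELS[self.dataset])

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class ResultsBundle:
    pheno: PhenotypeTable
    calls: CallSet
    clusters: ClusterSet
    medians: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _frame_checksum(df: pd.DataFrame) -> str:
    text = df.to_csv(float_format="%.12g").encode()
    return hashlib.sha256(text).hexdigest()


def run_pipeline(raw: RawScreenSet, cfg: PipelineConfig) -> ResultsBundle:
    """Execute normalize -> test -> cluster and assemble the manifest."""
    cfg.validate()
    odn = od_normalize(raw)
    correction = fit_plate_correction(odn)
    pheno = summarize_phenotypes(odn, correction)
    calls = call_significance(pheno, alpha=cfg.alpha)
    clusters = esc_cluster(calls, min_size=cfg.min_cluster_size)
    from .significance import ZTable

    medians = cluster_medians(clusters, ZTable(z=calls.z))

    n_sig_cells = int((calls.sign != 0).to_numpy().sum())
    sig_genes = calls.significant_genes
    manifest = {
        "config": asdict(cfg),
        "versions": {
            "ionoscreen": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": cfg.seed,
        "counts": {
            "n_wells": raw.n_wells,
            "n_genes": len(pheno.genes),
            "n_elements": len(raw.panel),
            "n_significant_cells": n_sig_cells,
            "n_significant_genes": len(sig_genes),
            "n_clusters": clusters.n_clusters,
            "n_clustered_genes": len(clusters.clustered_genes),
            "n_unclustered_genes": len(clusters.unclustered),
        },
        "cutoffs": {
            "neg": calls.cutoffs[0] if calls.cutoffs else None,
            "pos": calls.cutoffs[1] if calls.cutoffs else None,
        },
        "checksums": {
            "D": _frame_checksum(pheno.D),
            "sign": _frame_checksum(calls.sign),
        },
    }
    # bookkeeping invariant carried in every manifest
    assert (
        manifest["counts"]["n_clustered_genes"]
        + manifest["counts"]["n_unclustered_genes"]
        == manifest["counts"]["n_significant_genes"]
    )
    assert n_sig_cells <= len(pheno.genes) * len(raw.panel)
    return ResultsBundle(
        pheno=pheno, calls=calls, clusters=clusters, medians=medians,
        manifest=manifest,
    )
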