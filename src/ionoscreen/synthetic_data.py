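"""Simulate a plate-based ionomic screen with known ground truth.

The generative model mirrors the structure the normalization stage assumes:
on the log-concentration scale, each well value is

    log c = baseline(element) + strain offset + day effect + plate effect
            + spike effect (if this gene x element was perturbed)
            + replicate noise

and the *reported* concentration is ``exp(log c) * OD600``, so OD
normalization is a real, non-trivial step downstream.  Plates follow the
screen geometry: 96-well plates carrying four fixed control strains plus up
to 20 mutant strains, three plates per instrument day, and 4, 8 or 16
biological replicates per mutant (one plate appearance per replicate
batch).  Control strains sit at the element baseline (offset 0) — they are
the reference material every plate shares.

Spiked perturbations are the ground truth: a sparse random subset of
(gene, element) cells receives a multiplicative fold-change with random
sign, recorded in a :class:`TruthTable` so recall and false-discovery rate
of the full pipeline can be measured exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import (
    CONTROL,
    MUTANT,
    PLATE_META_COLUMNS,
    ElementPanel,
    InteractionRecord,
    RawScreenSet,
)

__all__ = [
    "SimConfig",
    "TruthEntry",
    "TruthTable",
    "simulate_screen",
    "simulate_interaction_network",
    "DEFAULT_BASELINE_PPM",
]

#: plausible element baselines (ppm in digest solution) for a yeast screen;
#: macro-nutrients (P, K, S, Mg) high, trace metals low.
DEFAULT_BASELINE_PPM: dict[str, float] = {
    "Ca": 60.0, "Cd": 0.5, "Co": 0.2, "Cu": 1.2, "Fe": 8.0,
    "K": 2500.0, "Mg": 1200.0, "Mn": 2.5, "Mo": 0.6, "Na": 300.0,
    "Ni": 0.3, "P": 4500.0, "S": 1500.0, "Zn": 35.0,
    "As": 0.1, "Cl": 80.0, "Se": 0.2,
}

_CONTROL_IDS = ("CTRL_1", "CTRL_2", "CTRL_3", "CTRL_4")


@dataclass
class SimConfig:
    """Parameters of the simulated screen; defaults match the study geometry."""

    n_genes: int = 100
    n_controls_per_plate: int = 4
    mutants_per_plate: int = 20
    plates_per_day: int = 3
    replicates: int = 4
    panel: ElementPanel = field(default_factory=ElementPanel.knockout)
    baseline_log_mean: Mapping[str, float] | None = None
    baseline_log_sd: float | Mapping[str, float] = 0.05
    plate_effect_sd: float = 0.10
    day_effect_sd: float = 0.10
    replicate_noise_sd: float = 0.15
    od_mean: float = 1.8
    od_sd: float = 0.25
    spike_fraction: float = 0.02
    spike_effect_range: tuple[float, float] = (2.0, 4.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.mutants_per_plate > 20:
            raise ConfigError(
                f"mutants_per_plate must be <= 20 (got {self.mutants_per_plate})"
            )
        if self.n_controls_per_plate < 1:
            raise ConfigError("each plate needs at least one control well")
        if self.n_controls_per_plate + self.mutants_per_plate > 96:
            raise ConfigError("controls + mutants exceed the 96-well grid")
        if self.replicates not in (4, 8, 16):
            raise ConfigError(f"replicates must be 4, 8 or 16 (got {self.replicates})")
        for name in ("plate_effect_sd", "day_effect_sd", "replicate_noise_sd",
                     "od_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        sds = self.baseline_log_sd
        if isinstance(sds, Mapping):
            if any(v < 0 for v in sds.values()):
                raise ConfigError("baseline_log_sd must be >= 0")
        elif sds < 0:
            raise ConfigError("baseline_log_sd must be >= 0")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ConfigError("spike_fraction must lie in [0, 1]")
        lo, hi = self.spike_effect_range
        if not (lo <= hi):
            raise ConfigError("spike_effect_range must be (lo, hi) with lo <= hi")
        if lo <= 1.05:
            # fold-changes must stay away from 1 so truth signs are well defined
            raise ConfigError("spike fold-changes must be bounded away from 1 (> 1.05)")
        if self.od_mean <= 0:
            raise ConfigError("od_mean must be positive")

    def _baseline_log_mean(self) -> dict[str, float]:
        if self.baseline_log_mean is not None:
            return {e: float(self.baseline_log_mean[e]) for e in self.panel}
        return {e: math.log(DEFAULT_BASELINE_PPM[e]) for e in self.panel}

    def _baseline_log_sd(self) -> dict[str, float]:
        if isinstance(self.baseline_log_sd, Mapping):
            return {e: float(self.baseline_log_sd[e]) for e in self.panel}
        return {e: float(self.baseline_log_sd) for e in self.panel}


@dataclass(frozen=True)
class TruthEntry:
    gene_id: str
    element: str
    log_fold: float
    sign: int  # sign(log_fold)


@dataclass
class TruthTable:
    """Ground-truth spiked perturbations of a simulated screen."""

    entries: list[TruthEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.gene_id, t.element, t.log_fold, t.sign) for t in self.entries],
            columns=["gene_id", "element", "log_fold", "sign"],
        )

    def sign_lookup(self) -> dict[tuple[str, str], int]:
        return {(t.gene_id, t.element): t.sign for t in self.entries}

    def patterns_by_gene(self, panel: ElementPanel) -> dict[str, tuple[int, ...]]:
        """Full sign pattern over the panel for every spiked gene."""
        lut = self.sign_lookup()
        genes = sorted({t.gene_id for t in self.entries})
        return {
            g: tuple(lut.get((g, e), 0) for e in panel) for g in genes
        }


def _well_labels() -> list[str]:
    return [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]


def simulate_screen(cfg: SimConfig) -> tuple[RawScreenSet, TruthTable]:
    """Draw a full screen and its ground truth; deterministic per seed.

    Stream-splitting rule: the master seed spawns six named child streams
    (spikes, strain offsets, day effects, plate effects, replicate noise,
    OD), in that fixed order, so changing e.g. the OD draw cannot perturb
    the spiked truth.
    """
    cfg.validate()
    panel = cfg.panel
    elements = list(panel.names)
    n_elem = len(elements)
    ss = np.random.SeedSequence(cfg.seed)
    (rng_spike, rng_offset, rng_day, rng_plate,
     rng_noise, rng_od) = (np.random.default_rng(s) for s in ss.spawn(6))

    genes = [f"G{i+1:04d}" for i in range(cfg.n_genes)]
    controls = list(_CONTROL_IDS[: cfg.n_controls_per_plate])
    if len(controls) < cfg.n_controls_per_plate:
        controls += [
            f"CTRL_{i+1}" for i in range(len(controls), cfg.n_controls_per_plate)
        ]

    # --- ground truth -----------------------------------------------------
    spike_mask = rng_spike.random((cfg.n_genes, n_elem)) < cfg.spike_fraction
    lo, hi = cfg.spike_effect_range
    folds = rng_spike.uniform(lo, hi, size=(cfg.n_genes, n_elem))
    signs = rng_spike.choice([-1, 1], size=(cfg.n_genes, n_elem))
    spike_log = np.where(spike_mask, signs * np.log(folds), 0.0)
    truth = TruthTable(
        [
            TruthEntry(genes[i], elements[j], float(spike_log[i, j]),
                       int(np.sign(spike_log[i, j])))
            for i, j in zip(*np.nonzero(spike_mask))
        ]
    )

    # --- latent effects ---------------------------------------------------
    base_mu = cfg._baseline_log_mean()
    base_sd = cfg._baseline_log_sd()
    gene_offset = rng_offset.standard_normal((cfg.n_genes, n_elem)) * np.array(
        [base_sd[e] for e in elements]
    )

    plates_per_batch = math.ceil(cfg.n_genes / cfg.mutants_per_plate)
    n_plates = cfg.replicates * plates_per_batch
    n_days = math.ceil(n_plates / cfg.plates_per_day)
    day_eff = rng_day.standard_normal((n_days, n_elem)) * cfg.day_effect_sd
    plate_eff = rng_plate.standard_normal((n_plates, n_elem)) * cfg.plate_effect_sd

    wells = _well_labels()
    mu_vec = np.array([base_mu[e] for e in elements])

    rows: list[list] = []
    values: list[np.ndarray] = []
    control_rep = {c: 0 for c in controls}
    plate_global = 0
    for batch in range(cfg.replicates):
        for p in range(plates_per_batch):
            day = plate_global // cfg.plates_per_day
            plate_id = f"P{plate_global+1:03d}"
            run_id = f"D{day+1:03d}"
            gene_slice = genes[p * cfg.mutants_per_plate:(p + 1) * cfg.mutants_per_plate]
            strains = controls + gene_slice
            for w, strain in zip(wells, strains):
                if strain in control_rep:
                    control_rep[strain] += 1
                    rep = control_rep[strain]
                    role = CONTROL
                    offset = np.zeros(n_elem)
                    spike = np.zeros(n_elem)
                else:
                    rep = batch + 1
                    role = MUTANT
                    gi = genes.index(strain)
                    offset = gene_offset[gi]
                    spike = spike_log[gi]
                logc = (
                    mu_vec
                    + offset
                    + spike
                    + day_eff[day]
                    + plate_eff[plate_global]
                    + rng_noise.standard_normal(n_elem) * cfg.replicate_noise_sd
                )
                od = max(float(rng_od.normal(cfg.od_mean, cfg.od_sd)), 0.05)
                rows.append([plate_id, run_id, w, strain, role, rep, od])
                values.append(np.exp(logc) * od)
            plate_global += 1

    meta = pd.DataFrame(rows, columns=list(PLATE_META_COLUMNS))
    conc = pd.DataFrame(np.vstack(values), columns=elements)
    return RawScreenSet(pd.concat([meta, conc], axis=1), panel), truth


def simulate_interaction_network(
    truth: TruthTable,
    n_background_genes: int,
    p_edge_within_pattern: float,
    p_edge_background: float,
    seed: int,
    panel: ElementPanel | None = None,
) -> list[InteractionRecord]:
    """Draw a typed interaction network organized around spiked patterns.

    Gene pairs sharing an identical (non-empty) spiked sign pattern are
    linked with probability ``p_edge_within_pattern``; every other pair —
    including the extra background genes — with ``p_edge_background``.
    Edge types are physical/genetic with equal probability.
    """
    for name, p in (("p_edge_within_pattern", p_edge_within_pattern),
                    ("p_edge_background", p_edge_background)):
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1]")
    panel = panel or ElementPanel.knockout()
    patterns = truth.patterns_by_gene(panel)
    genes = sorted(patterns) + [f"BG{i+1:04d}" for i in range(n_background_genes)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[InteractionRecord] = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            same = (
                a in patterns
                and b in patterns
                and patterns[a] == patterns[b]
            )
            p = p_edge_within_pattern if same else p_edge_background
            if rng.random() < p:
                itype = "physical" if rng.random() < 0.5 else "genetic"
                out.append(InteractionRecord.make(a, b, itype))
    return out


def noise_free(cfg: SimConfig) -> SimConfig:
    """Copy of ``cfg`` with every stochastic spread zeroed (spikes kept)."""
    return replace(
        cfg,
        baseline_log_sd=0.0,
        plate_effect_sd=0.0,
        day_effect_sd=0.0,
        replicate_noise_sd=0.0,
        od_sd=0.0,
    )
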