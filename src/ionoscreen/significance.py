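"""Moderated Z statistics, FDR calls, replicate-consistency filtering,
percent change and effect-size groups.

The moderated Z of gene *g* for element *e* standardizes the phenotype
against the across-gene median trend:

    Z_ge = (D_ge - median_g D_ge) / (1.4826 * median_g |D_ge - median_g D_ge|)

i.e. a robust Z built from the median and the MAD, with 1.4826 rescaling
the MAD to a consistent estimate of the standard deviation under
normality.  Two algebraic identities follow and are enforced by tests:
per element, median_g Z = 0 and median_g |Z| = 1/1.4826.

Z maps to a two-sided standard-normal p-value; Benjamini–Hochberg control
at level alpha is applied jointly over every (gene, element) cell of the
dataset, which yields one (slightly asymmetric) pair of observed
significance cutoffs per dataset: the largest significant negative Z and
the smallest significant positive Z.

A call additionally has to survive the replicate-consistency ("annealing")
filter: at least 75% of the gene's biological replicates must deviate from
the element's pooled replicate median in the call's direction by at least
twice the pooled MAD.

Practical effect size is the percent change

    perCh_ge = (s_ge - mean_g s_ge) / mean_g s_ge,     s_ge = sigma~_ge * D_ge

and genes are binned by their most extreme significant perCh: group C for
>= +100% or <= -50%, group B for >= 20% (in magnitude) otherwise, group A
below 20%.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .normalization import PhenotypeTable

__all__ = [
    "MAD_SCALE",
    "ZTable",
    "CallSet",
    "moderated_z",
    "z_to_q",
    "annealing_filter",
    "percent_change",
    "assign_groups",
    "significance_pattern",
    "call_significance",
]

#: consistency factor turning a MAD into a normal-sd estimate
MAD_SCALE = 1.4826

#: effect-size group bands (fractional change): C beyond (+1.0 / -0.5),
#: B beyond +/-0.2, A inside.
DEFAULT_GROUP_BANDS = {"c_up": 1.0, "c_down": -0.5, "b_abs": 0.2}


@dataclass
class ZTable:
    """Gene x element moderated Z with (optionally) q-values and cutoffs."""

    z: pd.DataFrame
    alpha: float = 0.05
    q: pd.DataFrame | None = None
    cutoffs: tuple[float, float] | None = None  # (neg_cut, pos_cut)


@dataclass
class CallSet:
    """Significance sign matrix plus the statistics behind every call."""

    sign: pd.DataFrame  # values in {-1, 0, +1}
    z: pd.DataFrame
    q: pd.DataFrame
    annealing_pass: pd.DataFrame
    perCh: pd.DataFrame | None = None
    group: pd.Series | None = None
    cutoffs: tuple[float, float] | None = None
    alpha: float = 0.05

    @property
    def significant_genes(self) -> list[str]:
        mask = (self.sign != 0).any(axis=1)
        return list(self.sign.index[mask])


def moderated_z(pheno: PhenotypeTable) -> ZTable:
    """Robust standardization of D against the across-gene median per element.

    Elements whose across-gene MAD is zero get an all-NaN column and a
    warning — with no spread there is no scale to standardize against.
    """
    D = pheno.D
    if len(D.index) < 3:
        raise ValidationError(
            f"moderated Z needs >= 3 genes per element (got {len(D.index)})"
        )
    med = D.median(axis=0)
    mad = (D - med).abs().median(axis=0)
    dead = mad[mad == 0.0].index.tolist()
    if dead:
        warnings.warn(
            f"element(s) with zero MAD across genes, Z undefined: "
            f"{', '.join(map(str, dead))}",
            stacklevel=2,
        )
    denom = MAD_SCALE * mad.replace(0.0, np.nan)
    z = (D - med) / denom
    return ZTable(z=z)


def z_to_q(ztable: ZTable, alpha: float = 0.05) -> ZTable:
    """Two-sided normal p-values, BH-adjusted jointly over all cells.

    The per-dataset significance cutoffs are the observed extremes: the
    largest significant negative Z and the smallest significant positive
    Z; +-inf sentinels when a side has no significant call.
    """
    z = ztable.z
    flat = z.stack(future_stack=True).dropna()
    p = 2.0 * stats.norm.sf(np.abs(flat.to_numpy()))
    if len(p) == 0:
        q = z * np.nan
        return ZTable(z=z, alpha=alpha, q=q, cutoffs=(-np.inf, np.inf))
    _, q_flat, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    q_ser = pd.Series(q_flat, index=flat.index)
    q = q_ser.unstack().reindex(index=z.index, columns=z.columns)

    sig = q_ser <= alpha
    zvals = flat[sig]
    neg = zvals[zvals < 0]
    pos = zvals[zvals > 0]
    neg_cut = float(neg.max()) if len(neg) else -np.inf
    pos_cut = float(pos.min()) if len(pos) else np.inf
    return ZTable(z=z, alpha=alpha, q=q, cutoffs=(neg_cut, pos_cut))


def annealing_filter(
    pheno: PhenotypeTable,
    ztable: ZTable,
    min_fraction: float = 0.75,
    mad_multiple: float = 2.0,
) -> pd.DataFrame:
    """Replicate-consistency filter for candidate calls.

    For element *e*, pool the replicate-level values of every gene and take
    their median ``m_e`` and (raw) MAD ``MAD_e``.  A candidate (g, e)
    passes iff at least ``min_fraction`` of g's replicates deviate from
    ``m_e`` in the direction of Z_ge by at least ``mad_multiple * MAD_e``.
    The fraction threshold is inclusive (3 of 4 replicates passes at 75%).
    """
    z = ztable.z
    out = pd.DataFrame(False, index=z.index, columns=z.columns)
    reps = pheno.replicate_values
    for e in z.columns:
        pooled = reps.loc[reps["element"] == e, "value"].to_numpy(dtype=float)
        if pooled.size == 0:
            continue
        m = np.median(pooled)
        mad = np.median(np.abs(pooled - m))
        thr = mad_multiple * mad
        sub = reps[reps["element"] == e]
        for gene, vals in sub.groupby("gene_id")["value"]:
            if gene not in z.index:
                continue
            direction = np.sign(z.loc[gene, e])
            if not np.isfinite(direction) or direction == 0:
                continue
            dev = vals.to_numpy(dtype=float) - m
            ok = (np.sign(dev) == direction) & (np.abs(dev) >= thr)
            out.loc[gene, e] = bool(ok.mean() >= min_fraction)
    return out


def percent_change(pheno: PhenotypeTable) -> pd.DataFrame:
    """Fractional change of sigma~*D about its across-gene mean, per element."""
    s = pheno.sigma_tilde * pheno.D
    mean = s.mean(axis=0)
    dead = mean[mean == 0.0].index.tolist()
    if dead:
        warnings.warn(
            f"element(s) with zero mean sigma~*D, perCh undefined: "
            f"{', '.join(map(str, dead))}",
            stacklevel=2,
        )
    return (s - mean) / mean.replace(0.0, np.nan)


def assign_groups(
    perCh: pd.DataFrame,
    sign: pd.DataFrame,
    bands: dict[str, float] = DEFAULT_GROUP_BANDS,
) -> pd.Series:
    """Bin each significant gene into effect-size group A, B or C.

    The gene's significant elements are scanned with the band hierarchy:
    any perCh >= c_up or <= c_down puts the gene in C; otherwise any
    |perCh| >= b_abs puts it in B; otherwise A.  Boundaries are inclusive
    toward the more extreme group.
    """
    groups = {}
    for gene in sign.index:
        sig_elems = sign.columns[sign.loc[gene] != 0]
        if len(sig_elems) == 0:
            continue
        vals = perCh.loc[gene, sig_elems].dropna()
        if ((vals >= bands["c_up"]) | (vals <= bands["c_down"])).any():
            groups[gene] = "C"
        elif (vals.abs() >= bands["b_abs"]).any():
            groups[gene] = "B"
        else:
            groups[gene] = "A"
    return pd.Series(groups, dtype="object")


def significance_pattern(
    ztable: ZTable, annealing_pass: pd.DataFrame
) -> CallSet:
    """Combine FDR significance, direction and the annealing filter.

    sign = +1 where q <= alpha, Z > 0 and the filter passed; -1 symmetric;
    0 otherwise.
    """
    if ztable.q is None:
        raise ValidationError("q-values missing; run z_to_q first")
    z, q = ztable.z, ztable.q
    sig = (q <= ztable.alpha) & annealing_pass.reindex_like(q).fillna(False)
    sign = pd.DataFrame(0, index=z.index, columns=z.columns, dtype=int)
    sign[sig & (z > 0)] = 1
    sign[sig & (z < 0)] = -1
    return CallSet(
        sign=sign,
        z=z,
        q=q,
        annealing_pass=annealing_pass.reindex_like(q).fillna(False),
        cutoffs=ztable.cutoffs,
        alpha=ztable.alpha,
    )


def call_significance(pheno: PhenotypeTable, alpha: float = 0.05) -> CallSet:
    """Full significance stage: Z -> q -> annealing -> signs -> perCh -> groups."""
    zt = z_to_q(moderated_z(pheno), alpha=alpha)
    annealing = annealing_filter(pheno, zt)
    calls = significance_pattern(zt, annealing)
    calls.perCh = percent_change(pheno)
    calls.group = assign_groups(calls.perCh, calls.sign)
    return calls
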