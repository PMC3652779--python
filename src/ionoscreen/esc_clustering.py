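"""Exhaustive significance clustering (ESC) and heatmap ordering.

ESC partitions significant genes by their exact per-element significance
pattern — the vector in {-1, 0, +1}^E of significant decrease / no change /
significant increase over the full panel — so a 14-element panel admits
3^14 = 4,782,969 possible clusters.  Patterns with fewer than ``min_size``
members are reported as unclustered.  Each retained cluster is represented
by the per-element median of its members' moderated Z profiles, and the
cluster x element median matrix is ordered for heatmap display by
agglomerative hierarchical clustering (complete linkage, Euclidean) on
rows and columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import ValidationError
from .io_formats import ElementPanel, pattern_key_str
from .significance import CallSet, ZTable

__all__ = [
    "Cluster",
    "ClusterSet",
    "HeatmapTable",
    "pattern_space_size",
    "esc_cluster",
    "cluster_medians",
    "hierarchical_order",
    "export_heatmap_table",
]


def pattern_space_size(n_elements: int) -> int:
    """Number of possible significance patterns over ``n_elements``: 3^E."""
    if n_elements < 1:
        raise ValidationError("panel must have at least one element")
    return 3 ** n_elements


@dataclass
class Cluster:
    cluster_id: str
    pattern: tuple[int, ...]
    members: list[str]
    median_profile: pd.Series | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def pattern_key(self) -> str:
        return pattern_key_str(self.pattern)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    unclustered: list[str]
    panel: ElementPanel
    row_order: list[int] | None = None
    col_order: list[int] | None = None

    @property
    def clustered_genes(self) -> list[str]:
        return [g for c in self.clusters for g in c.members]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def esc_cluster(callset: CallSet, min_size: int = 3) -> ClusterSet:
    """Group genes by exact equality of their significance sign vectors.

    Only genes with at least one nonzero sign participate.  Clusters are
    sorted by descending size, ties broken by lexicographic pattern key,
    and named CLUSTER_1, CLUSTER_2, ... in that order.
    """
    sign = callset.sign
    panel = ElementPanel(tuple(sign.columns))
    groups: dict[tuple[int, ...], list[str]] = {}
    for gene in sign.index:
        pat = tuple(int(v) for v in sign.loc[gene])
        if all(v == 0 for v in pat):
            continue
        groups.setdefault(pat, []).append(gene)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    clusters, unclustered = [], []
    k = 0
    for pat, members in ordered:
        if len(members) >= min_size:
            k += 1
            clusters.append(
                Cluster(cluster_id=f"CLUSTER_{k}", pattern=pat,
                        members=sorted(members))
            )
        else:
            unclustered.extend(members)
    return ClusterSet(clusters=clusters, unclustered=sorted(unclustered),
                      panel=panel)


def cluster_medians(clusterset: ClusterSet, ztable: ZTable) -> pd.DataFrame:
    """Per-cluster, per-element median of members' moderated Z.

    All panel elements contribute, including non-significant ones, so
    sub-threshold trends stay visible in the heatmap.
    """
    z = ztable.z
    rows = {}
    for cl in clusterset.clusters:
        missing = [g for g in cl.members if g not in z.index]
        if missing:
            raise ValidationError(
                f"cluster member(s) absent from Z table: {', '.join(missing)}"
            )
        profile = z.loc[cl.members, list(clusterset.panel.names)].median(axis=0)
        cl.median_profile = profile
        rows[cl.cluster_id] = profile
    return pd.DataFrame(rows).T.reindex(
        [c.cluster_id for c in clusterset.clusters]
    )


def hierarchical_order(medians: pd.DataFrame) -> tuple[list[int], list[int]]:
    """Leaf orders for clusters (rows) and elements (columns).

    Agglomerative clustering with complete linkage on Euclidean distances;
    deterministic given input order (scipy breaks ties by input index).
    A single row or column yields the identity order for that axis.
    """
    def order(mat: np.ndarray) -> list[int]:
        if mat.shape[0] < 2:
            return list(range(mat.shape[0]))
        return [int(i) for i in leaves_list(linkage(mat, method="complete"))]

    vals = medians.to_numpy(dtype=float)
    return order(vals), order(vals.T)


@dataclass
class HeatmapTable:
    """Cluster medians in display order with per-cell significance bands."""

    values: pd.DataFrame  # medians, rows/cols permuted into display order
    bands: pd.DataFrame  # same shape; sig_neg / neg / pos / sig_pos
    sizes: pd.Series = field(default=None)  # cluster sizes in row order


def export_heatmap_table(
    clusterset: ClusterSet,
    thresholds: tuple[float, float],
) -> HeatmapTable:
    """Arrange median profiles for heatmap export and band every cell.

    Bands follow the dataset's significance cutoffs: a median below the
    negative cutoff is ``sig_neg``, above the positive cutoff ``sig_pos``;
    in between, sign splits ``neg`` (< 0) from ``pos`` (>= 0).
    """
    neg_cut, pos_cut = thresholds
    if not (neg_cut < 0 < pos_cut):
        raise ValidationError("thresholds must satisfy neg_cut < 0 < pos_cut")
    medians = pd.DataFrame(
        {c.cluster_id: c.median_profile for c in clusterset.clusters}
    ).T.reindex([c.cluster_id for c in clusterset.clusters])
    if medians.isna().all(axis=None) and len(clusterset.clusters):
        raise ValidationError("median profiles missing; run cluster_medians first")

    row_order, col_order = clusterset.row_order, clusterset.col_order
    if row_order is None or col_order is None:
        row_order, col_order = hierarchical_order(medians)
        clusterset.row_order, clusterset.col_order = row_order, col_order

    ordered = medians.iloc[row_order, col_order]

    def band(v: float) -> str:
        if v < neg_cut:
            return "sig_neg"
        if v > pos_cut:
            return "sig_pos"
        return "neg" if v < 0 else "pos"

    bands = ordered.map(band)
    sizes = pd.Series(
        {c.cluster_id: c.size for c in clusterset.clusters}
    ).reindex(ordered.index)
    return HeatmapTable(values=ordered, bands=bands, sizes=sizes)
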