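"""Interaction subnetworks annotated with ionomic statistics.

Given a gene set (all genes significant for one element, or the members of
significance clusters), the subnetwork keeps every known physical or
genetic interaction with both endpoints in the set.  Genes without any
edge inside the set are not shown as nodes, but they still count as
*tested*: the inclusion rate is the percentage of tested genes that
interact (nodes/tested x 100), and connectivity is edges per node.  Node
direction and size come from the moderated Z of the focal element (or the
max-|Z| element for cluster-derived sets); each edge carries the
correlation of the two endpoint Z profiles across the panel.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import InteractionRecord
from .significance import ZTable

__all__ = [
    "EdgeRecord",
    "Subnetwork",
    "build_subnetwork",
    "edge_correlations",
    "inclusion_rate",
    "connectivity",
    "network_metrics",
]


@dataclass(frozen=True)
class EdgeRecord:
    gene_a: str
    gene_b: str
    itype: str
    r: float | None = None
    r_flagged: bool = False  # True when a profile had zero variance


@dataclass
class Subnetwork:
    """Typed interaction subgraph over a tested gene set."""

    nodes: dict[str, tuple[int, float]]  # gene -> (direction, magnitude)
    edges: list[EdgeRecord]
    tested_genes: frozenset[str]
    focal_element: str | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_counts(self) -> dict[str, int]:
        out = {"physical": 0, "genetic": 0}
        for e in self.edges:
            out[e.itype] += 1
        return out

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for gene, (direction, magnitude) in self.nodes.items():
            g.add_node(gene, direction=direction, magnitude=magnitude)
        for e in self.edges:
            g.add_edge(e.gene_a, e.gene_b, key=e.itype, itype=e.itype,
                       r=np.nan if e.r is None else e.r)
        return g


def _node_annotation(
    z: pd.DataFrame, gene: str, focal_element: str | None
) -> tuple[int, float]:
    if gene not in z.index:
        return (1, 0.0)
    profile = z.loc[gene].fillna(0.0)
    if focal_element is not None:
        v = float(profile[focal_element])
    else:
        v = float(profile.iloc[int(np.argmax(profile.abs().to_numpy()))])
    direction = -1 if v < 0 else 1
    return (direction, abs(v))


def build_subnetwork(
    geneset: set[str],
    interactions: list[InteractionRecord],
    ztable: ZTable,
    focal_element: str | None = None,
) -> Subnetwork:
    """Induced typed subgraph of ``interactions`` on ``geneset``.

    Edges are deduplicated per (pair, itype); a physical and a genetic
    interaction between the same pair remain two edges but the pair's
    genes count once as nodes.  Isolated members of the gene set are
    recorded in ``tested_genes`` only.
    """
    if not geneset:
        raise ValidationError("gene set must be nonempty")
    seen: dict[tuple[str, str, str], None] = {}
    for rec in interactions:
        if rec.gene_a in geneset and rec.gene_b in geneset:
            seen[(rec.gene_a, rec.gene_b, rec.itype)] = None
    edges = [EdgeRecord(a, b, t) for (a, b, t) in seen]
    node_ids = sorted({g for e in edges for g in (e.gene_a, e.gene_b)})
    nodes = {
        g: _node_annotation(ztable.z, g, focal_element) for g in node_ids
    }
    return Subnetwork(
        nodes=nodes,
        edges=edges,
        tested_genes=frozenset(geneset),
        focal_element=focal_element,
    )


def edge_correlations(
    subnetwork: Subnetwork, ztable: ZTable, method: str = "pearson"
) -> Subnetwork:
    """Attach profile correlations to every edge.

    r correlates the two endpoint moderated-Z vectors across all panel
    elements; absent cells are imputed as 0 (the null of the moderated Z,
    matching supplementary tables that blank sub-threshold cells).  Edges
    touching a zero-variance profile get r=None and a flag.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method: {method!r}")
    z = ztable.z
    profiles = {}
    for gene in subnetwork.nodes:
        if gene in z.index:
            profiles[gene] = z.loc[gene].fillna(0.0).to_numpy(dtype=float)
        else:
            profiles[gene] = np.zeros(z.shape[1])
    new_edges = []
    n_flagged = 0
    for e in subnetwork.edges:
        x, y = profiles[e.gene_a], profiles[e.gene_b]
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            new_edges.append(replace(e, r=None, r_flagged=True))
            n_flagged += 1
            continue
        if method == "pearson":
            r = float(stats.pearsonr(x, y).statistic)
        else:
            r = float(stats.spearmanr(x, y).statistic)
        new_edges.append(replace(e, r=r, r_flagged=False))
    if n_flagged:
        warnings.warn(
            f"{n_flagged} edge(s) with a zero-variance profile; r undefined",
            stacklevel=2,
        )
    return replace(subnetwork, edges=new_edges)


def inclusion_rate(subnetwork: Subnetwork) -> float:
    """Percent of tested genes with at least one interaction in the set."""
    if not subnetwork.tested_genes:
        raise ValidationError("tested gene set is empty")
    return 100.0 * subnetwork.n_nodes / len(subnetwork.tested_genes)


def connectivity(subnetwork: Subnetwork) -> float | None:
    """Edges per node; None for an empty (0-node) subnetwork."""
    if subnetwork.n_nodes == 0:
        return None
    return subnetwork.n_edges / subnetwork.n_nodes


def network_metrics(subnetwork: Subnetwork) -> dict:
    counts = subnetwork.edge_counts()
    return {
        "n_tested": len(subnetwork.tested_genes),
        "n_nodes": subnetwork.n_nodes,
        "n_edges_physical": counts["physical"],
        "n_edges_genetic": counts["genetic"],
        "inclusion_rate": inclusion_rate(subnetwork),
        "connectivity": connectivity(subnetwork),
    }
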