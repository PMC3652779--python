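"""Exhaustive significance clustering against brute-force oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest

from ionoscreen import (
    cluster_medians,
    esc_cluster,
    export_heatmap_table,
    hierarchical_order,
    pattern_space_size,
)
from ionoscreen.errors import ValidationError
from ionoscreen.significance import CallSet, ZTable


def make_callset(sign_rows, elements=None):
    genes = [f"g{i}" for i in range(len(sign_rows))]
    elements = elements or [f"E{j}" for j in range(len(sign_rows[0]))]
    sign = pd.DataFrame(sign_rows, index=genes, columns=elements, dtype=int)
    zeros = sign * 0.0
    return CallSet(sign=sign, z=zeros, q=zeros + 1.0,
                   annealing_pass=sign.astype(bool))


def brute_force_partition(sign: pd.DataFrame, min_size: int):
    """Dictionary-of-tuples grouping oracle."""
    groups = {}
    for gene in sign.index:
        pat = tuple(int(v) for v in sign.loc[gene])
        if any(pat):
            groups.setdefault(pat, set()).add(gene)
    clustered = {p: m for p, m in groups.items() if len(m) >= min_size}
    unclustered = set().union(*(m for p, m in groups.items()
                                if len(m) < min_size)) if groups else set()
    unclustered -= set().union(*clustered.values()) if clustered else set()
    return clustered, unclustered


class TestEscCluster:
    def test_min_size_split(self):
        cs = esc_cluster(
            make_callset([[1, 0], [1, 0], [1, 0], [0, -1], [0, -1]]),
            min_size=3,
        )
        assert cs.n_clusters == 1
        assert cs.clusters[0].size == 3
        assert len(cs.unclustered) == 2

    def test_pattern_space_of_14_elements(self):
        assert pattern_space_size(14) == 3 ** 14 == 4782969
        assert pattern_space_size(17) == 3 ** 17

    @pytest.mark.parametrize("min_size", [1, 2, 3])
    def test_matches_dictionary_oracle_on_random_matrices(self, min_size):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_genes = int(rng.integers(1, 30))
            n_elems = int(rng.integers(1, 6))
            rows = rng.choice([-1, 0, 1], size=(n_genes, n_elems),
                              p=[0.2, 0.6, 0.2])
            rows = rows[np.abs(rows).sum(axis=1) > 0]
            if len(rows) == 0:
                continue
            callset = make_callset(rows.tolist())
            cs = esc_cluster(callset, min_size=min_size)
            oracle_clusters, oracle_unclustered = brute_force_partition(
                callset.sign, min_size
            )
            got = {c.pattern: set(c.members) for c in cs.clusters}
            assert got == oracle_clusters
            assert set(cs.unclustered) == oracle_unclustered

    def test_partition_property(self, small_screen):
        from ionoscreen import PipelineConfig, run_pipeline

        _, raw, _ = small_screen
        bundle = run_pipeline(raw, PipelineConfig())
        cs = bundle.clusters
        all_members = cs.clustered_genes + cs.unclustered
        assert sorted(all_members) == sorted(set(all_members))
        assert set(all_members) == set(bundle.calls.significant_genes)
        for c in cs.clusters:
            for g in c.members:
                assert tuple(bundle.calls.sign.loc[g]) == c.pattern

    def test_gene_order_invariance(self):
        rows = [[1, 0], [0, 1], [1, 0], [1, 0], [0, 1], [0, 1]]
        a = esc_cluster(make_callset(rows), min_size=3)
        callset_b = make_callset(rows)
        callset_b.sign = callset_b.sign.iloc[::-1]
        b = esc_cluster(callset_b, min_size=3)
        assert {c.pattern: set(c.members) for c in a.clusters} == \
            {c.pattern: set(c.members) for c in b.clusters}

    def test_sorted_by_size_then_pattern(self):
        rows = [[0, 1]] * 3 + [[1, 0]] * 3 + [[-1, 0]] * 4
        cs = esc_cluster(make_callset(rows), min_size=3)
        assert [c.size for c in cs.clusters] == [4, 3, 3]
        # equal-size tie broken lexicographically on the pattern tuple
        assert cs.clusters[1].pattern < cs.clusters[2].pattern

    def test_empty_input(self):
        cs = esc_cluster(make_callset([[0, 0]]))
        assert cs.n_clusters == 0 and cs.unclustered == []


class TestClusterMedians:
    def test_median_of_three(self):
        cs = esc_cluster(make_callset([[1], [1], [1]], elements=["Mn"]),
                         min_size=3)
        z = ZTable(z=pd.DataFrame({"Mn": [4.0, 6.0, 8.0]},
                                  index=["g0", "g1", "g2"]))
        med = cluster_medians(cs, z)
        assert med.iloc[0]["Mn"] == 6.0

    def test_identical_profiles(self):
        cs = esc_cluster(make_callset([[1, -1]] * 3), min_size=3)
        z = ZTable(z=pd.DataFrame([[5.0, -2.0]] * 3,
                                  index=["g0", "g1", "g2"],
                                  columns=["E0", "E1"]))
        med = cluster_medians(cs, z)
        np.testing.assert_allclose(med.iloc[0].to_numpy(), [5.0, -2.0])

    def test_random_clusters_match_sort_oracle(self):
        rng = np.random.default_rng(3)
        rows = [[1, 1]] * 25
        cs = esc_cluster(make_callset(rows), min_size=3)
        z = ZTable(z=pd.DataFrame(rng.normal(size=(25, 2)),
                                  index=[f"g{i}" for i in range(25)],
                                  columns=["E0", "E1"]))
        med = cluster_medians(cs, z)
        for e in ("E0", "E1"):
            vals = np.sort(z.z[e].to_numpy())
            oracle = (vals[12])  # odd count: middle of the sorted values
            assert med.iloc[0][e] == pytest.approx(oracle)

    def test_missing_member_named(self):
        cs = esc_cluster(make_callset([[1]] * 3, elements=["Mn"]), min_size=3)
        z = ZTable(z=pd.DataFrame({"Mn": [1.0, 2.0]}, index=["g0", "g1"]))
        with pytest.raises(ValidationError, match="g2"):
            cluster_medians(cs, z)


def brute_force_complete_linkage_heights(points: np.ndarray) -> list[float]:
    """Naive agglomeration: merge the closest pair under max-linkage."""
    clusters = [{i} for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a]
                for j in clusters[b]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return heights


class TestHierarchicalOrder:
    def test_close_pair_adjacent(self):
        med = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]],
                           index=["c1", "c2", "c3"], columns=["E0", "E1"])
        row_order, _ = hierarchical_order(med)
        pos = {i: k for k, i in enumerate(row_order)}
        assert abs(pos[0] - pos[1]) == 1

    def test_duplicate_profiles_merge_at_zero(self):
        from scipy.cluster.hierarchy import linkage

        med = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        Z = linkage(med, method="complete")
        assert Z[0, 2] == 0.0

    def test_merge_heights_match_brute_force(self):
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            pts = rng.normal(size=(n, 3))
            Z = linkage(pts, method="complete")
            np.testing.assert_allclose(
                np.sort(Z[:, 2]),
                np.sort(brute_force_complete_linkage_heights(pts)),
                rtol=1e-9,
            )

    def test_leaf_orders_are_permutations(self):
        rng = np.random.default_rng(5)
        med = pd.DataFrame(rng.normal(size=(6, 4)))
        row_order, col_order = hierarchical_order(med)
        assert sorted(row_order) == list(range(6))
        assert sorted(col_order) == list(range(4))

    def test_single_cluster_identity(self):
        med = pd.DataFrame([[1.0, 2.0]], index=["c1"], columns=["E0", "E1"])
        row_order, col_order = hierarchical_order(med)
        assert row_order == [0]


class TestHeatmapExport:
    def _clusterset(self, values):
        cs = esc_cluster(
            make_callset([[1, 1]] * 3 + [[-1, -1]] * 3), min_size=3
        )
        z = ZTable(z=pd.DataFrame(
            [values[0]] * 3 + [values[1]] * 3,
            index=[f"g{i}" for i in range(6)], columns=["E0", "E1"],
        ))
        cluster_medians(cs, z)
        return cs

    def test_band_labels(self):
        cs = self._clusterset([[3.5, 0.0], [-4.0, -1.0]])
        hm = export_heatmap_table(cs, thresholds=(-3.328, 3.473))
        flat = {
            (r, c): hm.bands.loc[r, c]
            for r in hm.bands.index for c in hm.bands.columns
        }
        values = hm.values
        for (r, c), band in flat.items():
            v = values.loc[r, c]
            if v < -3.328:
                assert band == "sig_neg"
            elif v > 3.473:
                assert band == "sig_pos"
            elif v < 0:
                assert band == "neg"
            else:
                assert band == "pos"
        assert "sig_neg" in hm.bands.to_numpy()
        assert "sig_pos" in hm.bands.to_numpy()

    def test_zero_is_pos_band(self):
        cs = self._clusterset([[0.0, 0.0], [-1.0, -1.0]])
        hm = export_heatmap_table(cs, thresholds=(-3.0, 3.0))
        zero_cells = hm.values == 0.0
        assert (hm.bands[zero_cells] == "pos").any(axis=None)

    def test_boundary_cell_above_cutoff_is_sig(self):
        cs = self._clusterset([[3.5, 3.473], [-3.328, -3.4]])
        hm = export_heatmap_table(cs, thresholds=(-3.328, 3.473))
        arr = hm.values
        assert (hm.bands[arr == 3.5] == "sig_pos").any(axis=None)
        # exactly at the cutoff stays inside the non-significant band
        assert (hm.bands[arr == 3.473] == "pos").any(axis=None)
        assert (hm.bands[arr == -3.328] == "neg").any(axis=None)

    def test_sizes_follow_row_order(self):
        cs = self._clusterset([[3.0, 1.0], [-3.0, -1.0]])
        hm = export_heatmap_table(cs, thresholds=(-3.3, 3.4))
        assert hm.sizes.tolist() == [3, 3]
        assert list(hm.sizes.index) == list(hm.values.index)
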