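"""Distance, complete-linkage agglomeration, sweep and lineage labelling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnalineage.clustering import (
    Dendrogram,
    SamplePair,
    complete_linkage,
    label_lineages,
    linkage_from_distance,
    pairwise_uncentred_distance,
    sweep_gene_size,
    uncentred_correlation_distance,
)
from cnalineage.profile import GeneMatrix

from _oracles import naive_complete_linkage, naive_cut, naive_siblings


class TestUncentredDistance:
    def test_self_distance_zero(self):
        assert uncentred_correlation_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_antiproportional_is_two(self):
        assert uncentred_correlation_distance([1, -1], [-1, 1]) == pytest.approx(2.0)

    def test_hand_derived_value(self):
        # r = (1*2 + 2*1) / (sqrt(5) * sqrt(5)) = 4/5
        assert uncentred_correlation_distance([1, 2], [2, 1]) == pytest.approx(0.2)

    def test_symmetry_and_scale_invariance(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(size=6)
            d = uncentred_correlation_distance(x, y)
            assert uncentred_correlation_distance(y, x) == pytest.approx(d)
            a = float(rng.uniform(0.1, 10))
            assert uncentred_correlation_distance(a * x, y) == pytest.approx(d)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_range_zero_to_two(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=5), rng.normal(size=5)
        assert 0.0 <= uncentred_correlation_distance(x, y) <= 2.0

    def test_all_zero_vector_undefined(self):
        with pytest.raises(ValueError, match="undefined distance"):
            uncentred_correlation_distance([0, 0, 0], [1, 2, 3])

    def test_pairwise_complete_positions(self):
        x = np.array([1.0, 2.0, np.nan, 4.0])
        y = np.array([2.0, 1.0, 3.0, np.nan])
        assert uncentred_correlation_distance(x, y) == pytest.approx(
            uncentred_correlation_distance([1, 2], [2, 1])
        )
        with pytest.raises(ValueError, match="complete pairs"):
            uncentred_correlation_distance([np.nan, 1, np.nan], [1, np.nan, 2])

    def test_pairwise_matrix_agrees_with_elementwise(self, rng):
        X = rng.normal(size=(6, 9))
        X[1, 3] = np.nan
        X[4, 0] = np.nan
        D = pairwise_uncentred_distance(X)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                assert D[i, j] == pytest.approx(
                    uncentred_correlation_distance(X[i], X[j]), abs=1e-12
                )


SPEC_D4 = np.array([
    [0.0, 0.1, 0.5, 0.9],
    [0.1, 0.0, 0.6, 0.8],
    [0.5, 0.6, 0.0, 0.2],
    [0.9, 0.8, 0.2, 0.0],
])


class TestCompleteLinkage:
    def test_two_items_single_merge(self):
        D = np.array([[0.0, 0.3], [0.3, 0.0]])
        tree = linkage_from_distance(D, ["a", "b"])
        assert tree.merges == ((0, 1, 0.3),)
        assert tree.are_siblings("a", "b")

    def test_four_item_bruteforce_example(self):
        tree = linkage_from_distance(SPEC_D4, ["s1", "s2", "s3", "s4"])
        assert tree.merges[0] == (0, 1, 0.1)
        assert tree.merges[1] == (2, 3, 0.2)
        assert tree.merges[2][2] == pytest.approx(0.9)
        assert tree.cut(2) == [frozenset({"s1", "s2"}), frozenset({"s3", "s4"})]
        assert tree.are_siblings("s1", "s2")
        assert not tree.are_siblings("s2", "s3")
        with pytest.raises(KeyError, match="unknown leaf"):
            tree.are_siblings("s1", "nope")

    def test_cut_extremes(self):
        tree = linkage_from_distance(SPEC_D4, ["s1", "s2", "s3", "s4"])
        assert tree.cut(1) == [frozenset({"s1", "s2", "s3", "s4"})]
        assert len(tree.cut(4)) == 4
        with pytest.raises(ValueError):
            tree.cut(0)
        with pytest.raises(ValueError):
            tree.cut(5)

    def test_matches_naive_oracle_on_random_instances(self, rng):
        for trial in range(100):
            n = int(rng.integers(2, 9))
            X = rng.normal(size=(n, 5))
            D = pairwise_uncentred_distance(X)
            labels = [f"i{k}" for k in range(n)]
            tree = linkage_from_distance(D, labels)
            oracle = naive_complete_linkage(D.tolist())
            assert [m[:2] for m in tree.merges] == [m[:2] for m in oracle]
            assert np.allclose([m[2] for m in tree.merges],
                               [m[2] for m in oracle])
            k = int(rng.integers(1, n + 1))
            got = frozenset(
                frozenset(labels.index(l) for l in c) for c in tree.cut(k)
            )
            assert got == naive_cut(oracle, n, k)
            i, j = rng.choice(n, size=2, replace=False)
            assert tree.are_siblings(labels[i], labels[j]) == naive_siblings(
                oracle, n, int(i), int(j)
            )

    def test_heights_agree_with_scipy(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        for _ in range(10):
            X = rng.normal(size=(7, 4))
            D = pairwise_uncentred_distance(X)
            tree = linkage_from_distance(D, list("abcdefg"))
            Z = linkage(squareform(D, checks=False), method="complete")
            assert np.allclose(sorted(m[2] for m in tree.merges), sorted(Z[:, 2]))

    def test_heights_monotone_rootward(self, default_matrix):
        tree = complete_linkage(default_matrix.filter_min_probes(4))
        heights = [m[2] for m in tree.merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_partition_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(10, 6))
        labels = [f"s{k}" for k in range(10)]
        df = pd.DataFrame(X, index=labels)
        perm = rng.permutation(10)
        t1 = complete_linkage(df)
        t2 = complete_linkage(df.iloc[perm])
        assert frozenset(t1.cut(3)) == frozenset(t2.cut(3))

    def test_gene_axis_clustering(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 8)),
                          index=[f"s{k}" for k in range(5)],
                          columns=[f"g{k}" for k in range(8)])
        tree = complete_linkage(df, axis="genes")
        assert set(tree.leaves) == set(df.columns)


def _sweep_fixture():
    """Six samples; gene bands engineered so the k=3 partition changes
    between >=6 and >=4 but is constant from >=4 down."""
    samples = ["a", "b", "c", "d", "e", "f"]
    genes = [f"g{k}" for k in range(1, 12)]
    pc = {f"g{k}": c for k, c in zip(range(1, 12),
                                     [10, 10, 10, 6, 6, 6, 4, 4, 4, 3, 2])}
    V = pd.DataFrame(0.0, index=samples, columns=genes)
    V.loc["a", ["g1", "g4", "g7"]] = [1, 5, 20]
    V.loc["b", ["g1", "g5", "g8"]] = [1, 5, 20]
    V.loc["c", ["g2", "g4", "g8"]] = [1, 5, 20]
    V.loc["d", ["g2", "g5", "g7"]] = [1, 5, 20]
    V.loc["e", ["g3", "g6", "g9"]] = [1, 5, 20]
    V.loc["f", ["g3", "g6", "g9"]] = [1, 5, 20]  # identical same-tumour pair
    V[["g10", "g11"]] = 0.001
    info = pd.DataFrame({"chrom": "chr1", "start": 0, "end": 10}, index=genes)
    return GeneMatrix(V, pd.Series(pc).loc[genes], info)


class TestSweep:
    def test_gene_counts_non_increasing(self):
        res = sweep_gene_size(_sweep_fixture(), (10, 6, 4, 3, 2), [], k=3)
        counts = list(res.table["n_genes"])
        assert counts == sorted(counts)
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_identical_pair_adjacent_at_every_threshold(self):
        pairs = [SamplePair("e", "f", "same_tumour")]
        res = sweep_gene_size(_sweep_fixture(), (10, 6, 4, 3, 2), pairs, k=3)
        assert (res.table["same_tumour_adjacent"] == 1).all()

    def test_selected_threshold_is_largest_stable_partition(self):
        pairs = [SamplePair("e", "f", "same_tumour")]
        res = sweep_gene_size(_sweep_fixture(), (10, 6, 4, 3, 2), pairs, k=3)
        parts = res.partitions
        # constructed: partitions at 10, 6 and 4 all differ; 4 == 3 == 2
        assert parts[10] != parts[6]
        assert parts[6] != parts[4]
        assert parts[4] == parts[3] == parts[2]
        assert parts[4] == frozenset({frozenset({"a", "d"}), frozenset({"b", "c"}),
                                      frozenset({"e", "f"})})
        assert res.selected == 4

    def test_threshold_leaving_too_few_genes_skipped(self, caplog):
        m = _sweep_fixture()
        with caplog.at_level("WARNING"):
            res = sweep_gene_size(m, (99, 4, 3), [], k=3)
        assert 99 not in set(res.table["min_probes"])
        assert "skipped" in caplog.text

    def test_leaf_order_adjacency_mode(self):
        pairs = [SamplePair("e", "f", "same_tumour")]
        res = sweep_gene_size(_sweep_fixture(), (4,), pairs, k=3,
                              adjacency="leaf-order")
        assert res.table["same_tumour_adjacent"].iloc[0] == 1


class TestLabelLineages:
    def test_study_scale_example(self):
        """Burden means 9370/15262/15727 with sizes 11/28/4 label as
        stable/unstable/intermediate."""
        clusters = [
            frozenset(f"a{i}" for i in range(11)),
            frozenset(f"b{i}" for i in range(28)),
            frozenset(f"c{i}" for i in range(4)),
        ]
        burdens = pd.Series(
            {**{f"a{i}": 9370.0 for i in range(11)},
             **{f"b{i}": 15262.0 for i in range(28)},
             **{f"c{i}": 15727.0 for i in range(4)}}
        )
        got = label_lineages(clusters, burdens)
        assert got.labels["a0"] == "stable"
        assert got.labels["b0"] == "unstable"
        assert got.labels["c0"] == "intermediate"
        assert got.cluster_sizes["unstable"] == 28

    def test_larger_of_remaining_is_unstable(self):
        clusters = [frozenset(f"a{i}" for i in range(5)),
                    frozenset(f"b{i}" for i in range(4)),
                    frozenset(f"c{i}" for i in range(3))]
        burdens = pd.Series({**{f"a{i}": 0.0 for i in range(5)},
                             **{f"b{i}": 100.0 for i in range(4)},
                             **{f"c{i}": 200.0 for i in range(3)}})
        got = label_lineages(clusters, burdens)
        assert got.labels["a0"] == "stable"
        assert got.labels["b0"] == "unstable"  # larger cluster
        assert got.labels["c0"] == "intermediate"

    def test_burden_tie_demands_manual_mode(self):
        clusters = [frozenset({"a"}), frozenset({"b"}), frozenset({"c"})]
        burdens = pd.Series({"a": 1.0, "b": 1.0, "c": 2.0})
        with pytest.raises(ValueError, match="manual"):
            label_lineages(clusters, burdens)

    def test_manual_mode_requires_complete_map(self):
        clusters = [frozenset({"a"}), frozenset({"b"}), frozenset({"c"})]
        burdens = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        got = label_lineages(clusters, burdens, mode="manual",
                             manual_map={0: "unstable", 1: "stable", 2: "intermediate"})
        assert got.labels["a"] == "unstable"
        with pytest.raises(ValueError, match="complete"):
            label_lineages(clusters, burdens, mode="manual",
                           manual_map={0: "stable"})

    def test_non_three_partition_rejected(self):
        with pytest.raises(ValueError, match="k=3"):
            label_lineages([frozenset({"a"}), frozenset({"b"})],
                           pd.Series({"a": 1.0, "b": 2.0}))
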