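import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

from ebvar.composition import (
    CompositionMatrix,
    cluster_proportions,
    clusters_by_individual,
    dendrogram_to_newick,
    hclust_samples,
    topic_mean_loadings,
)
from ebvar.synthetic import default_config, simulate_composition


def naive_complete_linkage(X):
    """O(n^3) agglomeration oracle; ties resolve to the lowest index pair.

    Returns the cophenetic distance matrix, which is invariant to the
    merge bookkeeping the fast implementation uses.
    """
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    dist = lambda a, b: max(  # noqa: E731
        np.linalg.norm(X[i] - X[j]) for i in clusters[a] for j in clusters[b]
    )
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                d = dist(a, b)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def _comp(values, individuals, replicates):
    df = pd.DataFrame(np.atleast_2d(values))
    meta = pd.DataFrame({"individual": individuals, "replicate": replicates})
    return CompositionMatrix(df, meta)


class TestProportions:
    def test_hand_counted_proportions(self):
        cells = pd.DataFrame(
            {
                "barcode": [f"c{i}" for i in range(10)],
                "individual": ["i1"] * 10,
                "replicate": ["r1"] * 10,
                "cluster": ["k0"] * 8 + ["k1"] * 2,
            }
        )
        comp = cluster_proportions(cells)
        assert comp.values.loc["i1:r1", "k0"] == pytest.approx(0.8)
        assert comp.values.loc["i1:r1", "k1"] == pytest.approx(0.2)

    def test_single_cluster_rows_are_one(self):
        cells = pd.DataFrame(
            {
                "barcode": ["a", "b"],
                "individual": ["i1", "i2"],
                "replicate": ["r1", "r1"],
                "cluster": ["k0", "k0"],
            }
        )
        comp = cluster_proportions(cells)
        np.testing.assert_allclose(comp.values.to_numpy(), 1.0)

    def test_rows_on_simplex(self, small_sim):
        _, cells, _ = small_sim
        comp = cluster_proportions(cells)
        v = comp.values.to_numpy()
        assert np.all(v >= 0)
        np.testing.assert_allclose(v.sum(axis=1), 1.0, atol=1e-12)

    def test_low_efficiency_individual_shows_dominant_pluripotent_share(self):
        from ebvar.synthetic import simulate_counts

        cfg = default_config(
            n_genes=30,
            cells_per_group=400,
            low_efficiency_individual=(0, 0.89),
            seed=17,
        )
        _, cells, _ = simulate_counts(cfg)
        comp = cluster_proportions(cells)
        plur = comp.values.loc[
            comp.sample_meta["individual"].to_numpy() == "ind0", "pluripotent"
        ]
        assert plur.mean() == pytest.approx(0.89, abs=0.03)


class TestTopicLoadings:
    def test_identical_loadings_pass_through(self):
        cells = pd.DataFrame(
            {
                "barcode": ["a", "b", "c"],
                "individual": ["i1"] * 3,
                "replicate": ["r1"] * 3,
                "topic_0": [0.3] * 3,
                "topic_1": [0.7] * 3,
            }
        )
        comp = topic_mean_loadings(cells)
        np.testing.assert_allclose(comp.values.to_numpy(), [[0.3, 0.7]])

    def test_mean_of_two_pure_cells(self):
        cells = pd.DataFrame(
            {
                "barcode": ["a", "b"],
                "individual": ["i1"] * 2,
                "replicate": ["r1"] * 2,
                "topic_0": [1.0, 0.0],
                "topic_1": [0.0, 1.0],
            }
        )
        comp = topic_mean_loadings(cells)
        np.testing.assert_allclose(comp.values.to_numpy(), [[0.5, 0.5]])

    def test_missing_loadings_error(self):
        cells = pd.DataFrame(
            {"barcode": ["a"], "individual": ["i"], "replicate": ["r"]}
        )
        with pytest.raises(ValueError, match="topic"):
            topic_mean_loadings(cells)


class TestHclust:
    def test_points_on_a_line_merge_in_order(self):
        comp = _comp(
            np.array([[0.0], [1.0], [10.0]]), ["a", "b", "c"], ["r"] * 3
        )
        Z = hclust_samples(comp)
        # first merge (0,1) at height 1; complete linkage puts the next at 10
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(10.0)

    def test_identical_rows_merge_at_zero(self):
        comp = _comp(
            np.array([[0.2, 0.8], [0.2, 0.8], [0.9, 0.1]]),
            ["a", "b", "c"],
            ["r"] * 3,
        )
        Z = hclust_samples(comp)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_oracle_on_twelve_samples(self, rng):
        X = rng.uniform(size=(12, 4))
        comp = _comp(X, [f"i{j}" for j in range(12)], ["r"] * 12)
        Z = hclust_samples(comp)
        coph_fast = sch.cophenet(Z)
        coph_naive = naive_complete_linkage(X)
        iu = np.triu_indices(12, k=1)
        np.testing.assert_allclose(coph_fast, coph_naive[iu], atol=1e-10)

    def test_merge_heights_monotone(self, rng):
        X = rng.uniform(size=(10, 3))
        Z = hclust_samples(_comp(X, [f"i{j}" for j in range(10)], ["r"] * 10))
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_non_finite_entries_rejected(self):
        comp = _comp(np.array([[0.0], [np.nan]]), ["a", "b"], ["r", "r"])
        with pytest.raises(ValueError, match="finite"):
            hclust_samples(comp)

    def test_newick_serialization_has_all_leaves(self, rng):
        X = rng.uniform(size=(5, 2))
        names = [f"s{j}" for j in range(5)]
        comp = _comp(X, names, ["r"] * 5)
        nwk = dendrogram_to_newick(hclust_samples(comp), names)
        assert nwk.endswith(";") and all(n in nwk for n in names)


class TestClustersByIndividual:
    def test_duplicated_rows_per_individual_are_perfect(self):
        base = np.array([[0.9, 0.1], [0.1, 0.9], [0.5, 0.5]])
        X = np.repeat(base, 2, axis=0) + 0.0
        inds = np.repeat(["i1", "i2", "i3"], 2)
        comp = _comp(X, inds, ["r1", "r2"] * 3)
        exact, ari = clusters_by_individual(hclust_samples(comp), comp.sample_meta)
        assert exact and ari == pytest.approx(1.0)

    def test_strong_individual_signal_in_simulation(self):
        cfg = default_config(
            n_individuals=3,
            n_replicates=3,
            mixing_proportions=np.array(
                [
                    [0.80, 0.05, 0.05, 0.025, 0.025, 0.025, 0.025],
                    [0.05, 0.80, 0.05, 0.025, 0.025, 0.025, 0.025],
                    [0.05, 0.05, 0.80, 0.025, 0.025, 0.025, 0.025],
                ]
            ),
            composition_concentration=500.0,
            seed=23,
        )
        comp_long = simulate_composition(cfg)
        wide = comp_long.pivot_table(
            index=["individual", "replicate"], columns="cell_type", values="proportion"
        )
        meta = wide.index.to_frame(index=False)
        comp = CompositionMatrix(wide.reset_index(drop=True), meta)
        exact, ari = clusters_by_individual(hclust_samples(comp), meta)
        assert exact and ari == pytest.approx(1.0)

    def test_shuffled_composition_has_low_ari(self, rng):
        aris = []
        for seed in range(15):
            r = np.random.default_rng(seed)
            X = r.uniform(size=(8, 5))
            comp = _comp(X, np.repeat([f"i{j}" for j in range(4)], 2), ["r1", "r2"] * 4)
            _, ari = clusters_by_individual(hclust_samples(comp), comp.sample_meta)
            aris.append(ari)
        assert np.mean(aris) < 0.4
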