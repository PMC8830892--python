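import numpy as np
import pandas as pd
import pytest

from ebvar.synthetic import simulate_gaussian_genes
from ebvar.varpart import (
    _WoodburyREML,
    fit_crossed_lmm,
    partition_matrix,
    partition_per_cluster,
    summarize_fractions,
)


def anova_one_way(y2d):
    """Balanced one-way ANOVA closed-form variance components."""
    k, n = y2d.shape
    ybar = y2d.mean(axis=1)
    msb = n * ((ybar - y2d.mean()) ** 2).sum() / (k - 1)
    msw = ((y2d - ybar[:, None]) ** 2).sum() / (k * (n - 1))
    return max((msb - msw) / n, 0.0), msw


class TestREMLOracles:
    @pytest.mark.parametrize("seed,sd_b", [(7, 2.0), (21, 0.6), (99, 0.05)])
    def test_balanced_one_way_matches_anova_closed_form(self, seed, sd_b):
        rng = np.random.default_rng(seed)
        k, n = 6, 8
        y2d = rng.normal(0, sd_b, k)[:, None] + rng.normal(0, 1.0, (k, n))
        sb2, se2 = anova_one_way(y2d)
        fit = fit_crossed_lmm(y2d.ravel(), {"grp": np.repeat(np.arange(k), n)})
        if sb2 > 0:
            # interior optimum: REML equals the method-of-moments closed form
            assert fit.components["grp"] == pytest.approx(sb2, abs=1e-8)
            assert fit.components["residual"] == pytest.approx(se2, abs=1e-8)
        else:
            # negative ANOVA estimator: REML pins the component at zero and
            # pools all variation into the residual
            assert fit.components["grp"] == 0.0
            assert fit.singular
            y = y2d.ravel()
            pooled = ((y - y.mean()) ** 2).sum() / (len(y) - 1)
            assert fit.components["residual"] == pytest.approx(pooled, abs=1e-8)

    def test_crossed_design_beats_grid_search(self):
        rng = np.random.default_rng(1)
        A, B = 4, 5
        ia, ib = np.meshgrid(np.arange(A), np.arange(B), indexing="ij")
        y = (
            rng.normal(0, 1.2, A)[ia]
            + rng.normal(0, 0.7, B)[ib]
            + rng.normal(0, 1.0, (A, B))
        ).ravel()
        fa, fb = ia.ravel(), ib.ravel()
        fit = fit_crossed_lmm(y, {"a": fa, "b": fb})
        prob = _WoodburyREML(y, [fa, fb], [A, B])
        g_hat = np.array(
            [
                fit.components["a"] / fit.components["residual"],
                fit.components["b"] / fit.components["residual"],
            ]
        )
        ours = prob.neg2_profiled_reml(g_hat)
        grid = np.arange(0.0, 6.0, 1e-3)
        # profile each ratio across the grid holding the other at our optimum
        for axis in range(2):
            for val in grid[:: 10]:
                probe = g_hat.copy()
                probe[axis] = val
                assert ours <= prob.neg2_profiled_reml(probe) + 1e-9
        # fine scan near the optimum
        for axis in range(2):
            lo = max(g_hat[axis] - 0.05, 0.0)
            for val in np.arange(lo, g_hat[axis] + 0.05, 1e-3):
                probe = g_hat.copy()
                probe[axis] = val
                assert ours <= prob.neg2_profiled_reml(probe) + 1e-9

    def test_zero_individual_effect_estimated_near_zero(self):
        y, meta, _ = simulate_gaussian_genes(
            200,
            {"cluster": 4.0, "individual": 0.0, "replicate": 0.5, "residual": 2.0},
            {"cluster": 7, "individual": 3, "replicate": 3},
            seed=5,
        )
        res = partition_matrix(y, meta)
        assert res.fractions["individual"].median() < 0.02

    def test_weighted_fit_reduces_to_unweighted_on_unit_weights(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        f = {"a": rng.integers(0, 3, 30), "b": rng.integers(0, 4, 30)}
        f1 = fit_crossed_lmm(y, f)
        f2 = fit_crossed_lmm(y, f, weights=np.ones(30))
        for k in f1.components:
            assert f1.components[k] == pytest.approx(f2.components[k], abs=1e-10)

    def test_factor_with_one_level_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_crossed_lmm(np.arange(6.0), {"a": np.zeros(6, int)})


class TestPartitionMatrix:
    def test_constant_gene_gets_residual_one(self):
        y = np.vstack([np.ones(20), np.random.default_rng(0).normal(size=20)])
        meta = pd.DataFrame(
            {
                "cluster": np.tile(["a", "b"], 10),
                "individual": np.repeat(["i", "j"], 10),
                "replicate": np.tile(np.repeat(["r", "s"], 5), 2),
            }
        )
        res = partition_matrix(y, meta)
        assert res.fractions.iloc[0].tolist() == [0.0, 0.0, 0.0, 1.0]
        assert res.flags.iloc[0] == "constant"

    def test_fraction_simplex_invariant(self):
        y, meta, _ = simulate_gaussian_genes(
            30,
            {"cluster": 6.0, "individual": 0.5, "replicate": 0.5, "residual": 3.0},
            {"cluster": 7, "individual": 3, "replicate": 3},
            seed=2,
        )
        res = partition_matrix(y, meta)
        fr = res.fractions.to_numpy()
        assert np.all(fr >= 0) and np.allclose(fr.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(res.components.to_numpy() >= 0)

    def test_column_permutation_invariance(self):
        y, meta, _ = simulate_gaussian_genes(
            5,
            {"cluster": 2.0, "individual": 0.3, "replicate": 0.3, "residual": 1.0},
            {"cluster": 4, "individual": 3, "replicate": 2},
            seed=9,
        )
        perm = np.random.default_rng(1).permutation(y.shape[1])
        res1 = partition_matrix(y, meta)
        res2 = partition_matrix(y[:, perm], meta.iloc[perm].reset_index(drop=True))
        pd.testing.assert_frame_equal(res1.fractions, res2.fractions, atol=1e-7, rtol=0)

    def test_parameter_recovery_on_default_scenario(self):
        # truth fractions 0.60 / 0.05 / 0.05 / 0.30 at components (6, .5, .5, 3)
        y, meta, truth = simulate_gaussian_genes(
            300,
            {"cluster": 6.0, "individual": 0.5, "replicate": 0.5, "residual": 3.0},
            {"cluster": 7, "individual": 3, "replicate": 3},
            seed=42,
        )
        res = partition_matrix(y, meta)
        med = res.fractions.median()
        for factor, target in truth.items():
            assert med[factor] == pytest.approx(target, abs=0.05)


class TestPerCluster:
    def test_dominant_individual_effect_detected_per_cluster(self):
        y, meta, _ = simulate_gaussian_genes(
            80,
            {"individual": 2.0, "replicate": 0.1, "residual": 1.0},
            {"individual": 4, "replicate": 4},
            seed=8,
        )
        meta = meta.assign(cluster="c0")
        results, skipped = partition_per_cluster(y, meta)
        assert not skipped
        fr = results["c0"].fractions
        assert fr["individual"].median() > fr["replicate"].median()

    def test_single_replicate_cluster_skipped_with_reason(self):
        y = np.random.default_rng(0).normal(size=(3, 12))
        meta = pd.DataFrame(
            {
                "cluster": ["solo"] * 4 + ["ok"] * 8,
                "individual": ["i1", "i2"] * 2 + ["i1", "i2"] * 4,
                "replicate": ["r1"] * 4 + ["r1", "r1", "r2", "r2"] * 2,
            }
        )
        results, skipped = partition_per_cluster(y, meta)
        assert "solo" in skipped and "replicate" in skipped["solo"]
        assert "ok" in results


class TestSummaries:
    def test_single_gene_summary_equals_its_fractions(self):
        y, meta, _ = simulate_gaussian_genes(
            1,
            {"cluster": 1.0, "individual": 0.5, "replicate": 0.2, "residual": 1.0},
            {"cluster": 4, "individual": 3, "replicate": 3},
            seed=0,
        )
        res = partition_matrix(y, meta)
        summ = summarize_fractions(res).set_index("factor")
        for factor in res.fractions.columns:
            assert summ.loc[factor, "median"] == pytest.approx(
                res.fractions[factor].iloc[0]
            )

    def test_identical_fractions_have_zero_iqr(self):
        y, meta, _ = simulate_gaussian_genes(
            1,
            {"cluster": 1.0, "individual": 0.5, "replicate": 0.2, "residual": 1.0},
            {"cluster": 4, "individual": 3, "replicate": 3},
            seed=0,
        )
        res = partition_matrix(np.vstack([y, y, y]), meta)
        summ = summarize_fractions(res).set_index("factor")
        assert (summ["q75"] - summ["q25"]).abs().max() == pytest.approx(0.0, abs=1e-9)
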