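import numpy as np
import pytest
from scipy.stats import nct, norm, t as t_dist

from ebvar.power import (
    DecayFit,
    PowerParams,
    bonferroni_alpha,
    estimate_sigma_curve,
    fit_decay,
    mc_power_oracle,
    power,
    power_grid,
)
from ebvar.synthetic import default_config, simulate_counts
from ebvar.varpart import partition_matrix
from ebvar.pseudobulk import log_cpm, make_pseudobulk, tmm_factors


def exact_two_sided_power(beta, alpha, n, sigma=1.0):
    """Noncentral-t rejection rate of the regression t-test (exact oracle)."""
    df = n - 2
    tcrit = t_dist.ppf(1 - alpha / 2, df)
    ncp = beta * np.sqrt(n) / sigma
    return float(nct.sf(tcrit, df, ncp) + nct.cdf(-tcrit, df, ncp))


class TestAnalyticFormula:
    def test_zero_effect_power_is_half_alpha_exactly(self):
        for alpha in (0.05, 5e-6, 0.3):
            got = power(PowerParams(beta=0.0, alpha=alpha, n=50))
            assert got == pytest.approx(alpha / 2, rel=1e-9)

    def test_limit_to_one_for_large_signal(self):
        assert power(PowerParams(beta=50.0, alpha=1e-6, n=100)) == pytest.approx(1.0)

    def test_monotonicity_in_each_argument(self):
        base = PowerParams(beta=0.4, alpha=1e-4, n=60, sigma=1.0)
        p0 = power(base)
        assert power(PowerParams(0.5, 1e-4, 60, 1.0)) > p0
        assert power(PowerParams(0.4, 1e-4, 90, 1.0)) > p0
        assert power(PowerParams(0.4, 1e-4, 60, 1.3)) < p0
        assert power(PowerParams(0.4, 1e-3, 60, 1.0)) > p0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            PowerParams(beta=0.5, alpha=0.0, n=10)
        with pytest.raises(ValueError):
            PowerParams(beta=0.5, alpha=0.5, n=1)
        with pytest.raises(ValueError):
            PowerParams(beta=0.5, alpha=0.5, n=10, sigma=0.0)


class TestBonferroni:
    def test_printed_value_ten_thousand_genes(self):
        assert bonferroni_alpha(0.05, 10_000) == pytest.approx(5e-6, rel=1e-12)

    def test_single_test_unchanged(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_direct_division(self):
        assert bonferroni_alpha(0.01, 100) == pytest.approx(1e-4, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestMonteCarloOracle:
    def test_size_of_the_test_under_the_null(self):
        rate, se = mc_power_oracle(0.0, 0.05, n=40, n_sims=20_000, seed=3)
        assert abs(rate - 0.05) <= 3 * se

    def test_rate_matches_exact_noncentral_t(self):
        beta, alpha, n = 0.4, 0.05, 50
        rate, se = mc_power_oracle(beta, alpha, n, n_sims=40_000, seed=4)
        assert abs(rate - exact_two_sided_power(beta, alpha, n)) <= 3 * se + 0.002

    def test_rate_nondecreasing_in_sample_size(self):
        r1, _ = mc_power_oracle(0.5, 0.01, n=30, n_sims=20_000, seed=5)
        r2, _ = mc_power_oracle(0.5, 0.01, n=60, n_sims=20_000, seed=5)
        assert r2 >= r1

    def test_formula_approximation_error_at_the_pilot_design(self):
        """At 58 individuals and alpha = 5e-6 the one-tail normal formula
        overstates the true two-sided t-test power substantially; the
        oracle exists to quantify exactly this gap."""
        beta, alpha, n = 0.6, 5e-6, 58
        analytic = power(PowerParams(beta=beta, alpha=alpha, n=n))
        exact = exact_two_sided_power(beta, alpha, n)
        rate, se = mc_power_oracle(beta, alpha, n, n_sims=40_000, seed=6)
        assert abs(rate - exact) <= 3 * se + 0.002  # MC agrees with exact law
        assert analytic - rate > 0.1  # documented approximation gap


class TestDecayFit:
    def test_exact_model_recovered_to_machine_precision(self):
        a, b, c = 2.0, 1e-4, 0.5
        E = np.array([2700, 5400, 9000, 13500, 18000, 21600], float)
        v = a * np.exp(-b * E) + c
        fit = fit_decay(E, v)
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.c == pytest.approx(c, rel=1e-6)

    def test_constant_variances_degenerate_to_flat(self):
        E = np.array([1000.0, 2000.0, 3000.0, 4000.0])
        v = np.full(4, 0.7)
        fit = fit_decay(E, v)
        assert fit.a == pytest.approx(0.0, abs=1e-6)
        assert fit.c == pytest.approx(0.7, abs=1e-6)

    def test_noisy_data_within_noise_envelope(self):
        rng = np.random.default_rng(11)
        a, b, c = 1.5, 2e-4, 0.4
        E = np.linspace(2000, 20000, 8)
        v = (a * np.exp(-b * E) + c) * (1 + rng.normal(0, 0.05, len(E)))
        fit = fit_decay(E, v)
        assert np.all(np.abs(fit.predict(E) / v - 1) < 0.15)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_decay([1.0, 2.0], [1.0, 0.5])


@pytest.fixture(scope="module")
def sim():
    cfg = default_config(n_genes=120, cells_per_group=60, seed=13)
    counts, cells, _ = simulate_counts(cfg)
    return counts, cells


class TestSigmaCurve:
    def test_full_size_single_draw_equals_direct_partition(self, sim):
        counts, cells = sim
        n = counts.n_cells
        curve = estimate_sigma_curve(counts, cells, sizes=[n], n_draws=1, seed=1)
        from ebvar.qc import filter_genes_cluster_fraction

        mask = filter_genes_cluster_fraction(counts, cells["cluster"])
        sub = counts.subset_genes(mask)
        pb = make_pseudobulk(sub, cells)
        tmm_factors(pb)
        res = partition_matrix(
            log_cpm(pb), pb.group_meta, factors=("cluster", "individual", "replicate")
        )
        assert curve["median_residual_variance"].iloc[0] == pytest.approx(
            float(res.components["residual"].median()), rel=1e-9
        )

    def test_residual_variance_tends_down_with_experiment_size(self, sim):
        counts, cells = sim
        n = counts.n_cells
        curve = estimate_sigma_curve(
            counts, cells, sizes=[n // 4, n], n_draws=3, seed=2
        )
        v_small = curve["median_residual_variance"].iloc[0]
        v_large = curve["median_residual_variance"].iloc[1]
        assert v_large <= v_small * 1.05

    def test_reseeding_is_stable(self, sim):
        counts, cells = sim
        n = counts.n_cells
        a = estimate_sigma_curve(counts, cells, sizes=[n // 2], n_draws=3, seed=3)
        b = estimate_sigma_curve(counts, cells, sizes=[n // 2], n_draws=3, seed=4)
        va = a["median_residual_variance"].iloc[0]
        vb = b["median_residual_variance"].iloc[0]
        assert abs(va - vb) / va < 0.5

    def test_oversized_request_rejected(self, sim):
        counts, cells = sim
        with pytest.raises(ValueError, match="exceeds"):
            estimate_sigma_curve(counts, cells, sizes=[counts.n_cells + 1], n_draws=1, seed=0)


class TestPowerGrid:
    def _flat_decay(self, var=1.0):
        return DecayFit(
            a=0.0, b=1.0, c=var, sizes=np.array([1e3, 2e3, 3e3]),
            variances=np.full(3, var), rss=0.0, converged=True,
        )

    def test_monotone_in_n_and_beta_with_constant_sigma(self):
        grid = power_grid(
            betas=[0.2, 0.4, 0.6],
            ns=[20, 40, 80],
            cells_per_individual=[100],
            decay=self._flat_decay(),
        )
        wide = grid.pivot_table(index="beta", columns="n", values="power")
        assert (wide.diff(axis=0).iloc[1:] > 0).all().all()  # in beta
        assert (wide.diff(axis=1).iloc[:, 1:] > 0).all().all()  # in n
        assert grid["power"].between(0, 1).all()

    def test_more_genes_never_increases_power(self):
        kw = dict(betas=[0.3, 0.6], ns=[30, 60], cells_per_individual=[100],
                  decay=self._flat_decay())
        g1 = power_grid(n_genes=10_000, **kw)
        g2 = power_grid(n_genes=20_000, **kw)
        assert (g2["power"].to_numpy() <= g1["power"].to_numpy() + 1e-15).all()

    def test_experiment_size_and_alpha_columns(self):
        grid = power_grid([0.6], [58], [3000], decay=self._flat_decay(),
                          extrapolation_factor=1e9)
        row = grid.iloc[0]
        assert row["experiment_size"] == 174_000
        assert row["alpha"] == pytest.approx(5e-6, rel=1e-12)

    def test_extrapolation_warning(self):
        with pytest.warns(UserWarning, match="extrapolates"):
            power_grid([0.6], [58], [3000], decay=self._flat_decay())
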