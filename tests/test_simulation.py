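"""Tests for data generation, outlier injection and the Monte-Carlo engine."""

import numpy as np
import pytest
from scipy import stats

from robustewas import (
    SimConfig,
    fit_marker_association,
    generate_fixture_ewas,
    generate_pair,
    inflation_lambda,
    inject_bivariate_outlier,
    inject_univariate_outliers,
    run_power_study,
    run_type1_study,
    t_to_signed_z,
)
from robustewas._rng import substream
from robustewas.comparators import full_sample_ewas
from robustewas.simulation import (
    _fold_sizes,
    _robust_meta_p,
    _rowwise_corr_t,
    _simulate_replicates,
)


class TestGeneratePair:
    @pytest.mark.parametrize("rho", [0.0, 0.3])
    def test_sample_correlation_matches_population(self, rho):
        rng = np.random.default_rng(0)
        y, x = generate_pair(10**6, rho, rng)
        assert np.corrcoef(y, x)[0, 1] == pytest.approx(rho, abs=0.005)
        assert np.std(x) == pytest.approx(1.0, abs=0.01)

    def test_same_seed_same_draws(self):
        y1, x1 = generate_pair(100, 0.3, np.random.default_rng(42))
        y2, x2 = generate_pair(100, 0.3, np.random.default_rng(42))
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_array_equal(x1, x2)

    def test_rho_domain(self):
        with pytest.raises(ValueError):
            generate_pair(10, 1.0, np.random.default_rng(0))


class TestInjectUnivariateOutliers:
    def test_zero_count_is_noop(self, rng):
        y, x = rng.standard_normal(20), rng.standard_normal(20)
        y2, x2, ids = inject_univariate_outliers(y, x, 0, 6.0, rng)
        np.testing.assert_array_equal(y, y2)
        np.testing.assert_array_equal(x, x2)
        assert ids.size == 0

    def test_five_outliers_never_hit_both_variables(self, rng):
        y, x = rng.standard_normal(50), rng.standard_normal(50)
        y2, x2, ids = inject_univariate_outliers(y, x, 5, 6.0, rng)
        assert len(set(ids)) == 5
        changed_y = np.flatnonzero(y2 != y)
        changed_x = np.flatnonzero(x2 != x)
        assert len(np.intersect1d(changed_y, changed_x)) == 0
        assert sorted(np.union1d(changed_y, changed_x)) == sorted(ids)
        assert np.all(np.abs(np.concatenate([y2[changed_y], x2[changed_x]])) == 6.0)

    def test_alternation_split_with_marker_first(self, rng):
        y, x = rng.standard_normal(50), rng.standard_normal(50)
        y2, x2, _ = inject_univariate_outliers(
            y, x, 5, 6.0, rng, first_variable="x"
        )
        assert np.count_nonzero(x2 != x) == 3
        assert np.count_nonzero(y2 != y) == 2

    def test_magnitude_zero_replaces_with_mean(self, rng):
        y, x = rng.standard_normal(30), rng.standard_normal(30)
        y2, x2, ids = inject_univariate_outliers(y, x, 4, 0.0, rng)
        # each affected individual has exactly one variable set to the mean (0)
        for i in ids:
            assert (y2[i] == 0.0) != (x2[i] == 0.0)

    def test_count_exceeding_n_raises(self, rng):
        with pytest.raises(ValueError):
            inject_univariate_outliers(np.zeros(3), np.zeros(3), 4, 6.0, rng)


class TestInjectBivariateOutlier:
    def test_concordant_hits_both_variables_same_sign(self, rng):
        y, x = rng.standard_normal(40), rng.standard_normal(40)
        y2, x2, ids = inject_bivariate_outlier(y, x, 1, 6.0, rng, concordant=True)
        (i,) = ids
        assert abs(y2[i]) == 6.0 and abs(x2[i]) == 6.0
        assert np.sign(y2[i]) == np.sign(x2[i])
        # only that individual changed
        mask = np.ones(40, bool)
        mask[i] = False
        np.testing.assert_array_equal(y[mask], y2[mask])
        np.testing.assert_array_equal(x[mask], x2[mask])

    def test_discordant_signs_oppose(self, rng):
        y, x = rng.standard_normal(40), rng.standard_normal(40)
        y2, x2, ids = inject_bivariate_outlier(y, x, 2, 5.0, rng, concordant=False)
        for i in ids:
            assert np.sign(y2[i]) == -np.sign(x2[i])

    def test_single_concordant_outlier_inflates_full_sample(self):
        cfg = SimConfig(
            n_sims=4000, n_bivariate_outliers=1, outlier_magnitude=6.0,
            methods=("full",), k_values=(), seed=0,
        )
        res = run_type1_study(cfg)
        rate = res.rate("full")
        assert rate > 0.05 + 5 * np.sqrt(0.05 * 0.95 / 4000)

    def test_discordant_outlier_still_inflates_two_sided_rate(self):
        cfg = SimConfig(
            n_sims=4000, n_bivariate_outliers=1, outlier_magnitude=6.0,
            concordant_bivariate=False, methods=("full",), k_values=(), seed=0,
        )
        rate = run_type1_study(cfg).rate("full")
        assert rate > 0.05 + 5 * np.sqrt(0.05 * 0.95 / 4000)


class TestSimConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_sims=0)
        with pytest.raises(ValueError):
            SimConfig(rho=1.0)
        with pytest.raises(ValueError):
            SimConfig(alpha=0.0)
        with pytest.raises(ValueError):
            SimConfig(n=10, k_values=(6,))
        with pytest.raises(ValueError):
            SimConfig(methods=("bogus",))

    def test_scenario_labels(self):
        assert SimConfig().scenario == "no_outliers"
        assert SimConfig(n_univariate_outliers=5).scenario == "univariate_5"
        assert (
            SimConfig(n_bivariate_outliers=1).scenario == "bivariate_1_concordant"
        )


class TestEngineAgreesWithModelPath:
    """The vectorized correlation engine must match the OLS fitting path."""

    def test_rowwise_t_equals_regression_t(self, rng):
        Y = rng.standard_normal((5, 40))
        X = rng.standard_normal((5, 40))
        t_vec, df = _rowwise_corr_t(Y, X)
        assert df == 38
        for i in range(5):
            stat = fit_marker_association(Y[i], X[i])
            assert t_vec[i] == pytest.approx(stat.t_stat, rel=1e-10)

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_robust_meta_p_matches_per_fold_fits(self, k):
        """Whitebox: replay the engine's permutation and recompute each fold
        with the statsmodels path, then Stouffer-combine by hand."""
        seed, n = 9, 100
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((3, n))
        X = rng.standard_normal((3, n))
        p_engine = _robust_meta_p(Y, X, k, seed)
        perm = np.argsort(substream(seed, "sim_engine", k).random((3, n)), axis=1)
        for i in range(3):
            yp, xp = Y[i, perm[i]], X[i, perm[i]]
            z = []
            start = 0
            for size in _fold_sizes(n, k):
                stat = fit_marker_association(yp[start : start + size], xp[start : start + size])
                z.append(t_to_signed_z(stat.t_stat, stat.df))
                start += size
            z_meta = np.sum(z) / np.sqrt(k)
            p_oracle = 2 * stats.norm.sf(abs(z_meta))
            assert p_engine[i] == pytest.approx(p_oracle, rel=1e-9)

    def test_full_rates_are_exact_counts(self):
        cfg = SimConfig(n_sims=777, seed=2, k_values=(2, 5))
        res = run_type1_study(cfg)
        for _, row in res.table.iterrows():
            count = row["rate"] * row["n_used"]
            assert count == pytest.approx(round(count), abs=1e-9)
            expect_se = np.sqrt(row["rate"] * (1 - row["rate"]) / row["n_used"])
            assert row["se"] == pytest.approx(expect_se)


class TestStudies:
    def test_bit_reproducible_given_seed(self):
        cfg = SimConfig(n_sims=500, n_bivariate_outliers=1, k_values=(2, 5), seed=5)
        a = run_type1_study(cfg)
        b = run_type1_study(cfg)
        assert a.table.equals(b.table)

    def test_type1_requires_null_rho(self):
        with pytest.raises(ValueError):
            run_type1_study(SimConfig(rho=0.3))

    def test_power_contract(self):
        with pytest.raises(ValueError):
            run_power_study(SimConfig(rho=0.0))
        with pytest.raises(ValueError):
            run_power_study(SimConfig(rho=0.3, n_bivariate_outliers=1))

    def test_robust_inflation_decreases_in_k(self):
        cfg = SimConfig(
            n_sims=4000, n_bivariate_outliers=1, outlier_magnitude=6.0,
            methods=("robust",), k_values=(2, 5, 10, 20), seed=0,
        )
        res = run_type1_study(cfg)
        rates = [res.rate("robust", k) for k in (2, 5, 10, 20)]
        assert all(a > b for a, b in zip(rates, rates[1:]))


class TestGenerateFixtureEwas:
    def test_null_fixture_is_calibrated(self):
        data, truth = generate_fixture_ewas(m=600, n=120, n_true=0, effect_rho=0.0, seed=0)
        assert not truth["is_true"].any()
        table = full_sample_ewas(data, adjust="bonferroni")
        assert int((table["p_adjusted"] < 0.05).sum()) == 0
        lam = inflation_lambda(table["p"].to_numpy())
        assert lam == pytest.approx(1.0, abs=0.3)

    def test_true_effects_recovered_by_full_sample(self):
        # power of r=0.5 at n=250 against Bonferroni 0.05/1000 is ~1
        data, truth = generate_fixture_ewas(
            m=1000, n=250, n_true=10, effect_rho=0.5, seed=1
        )
        table = full_sample_ewas(data, adjust="bonferroni").set_index("feature_id")
        hits = set(table.index[table["p_adjusted"] < 0.05])
        assert set(truth.loc[truth["is_true"], "feature_id"]) <= hits

    def test_deterministic_given_seed(self):
        d1, t1 = generate_fixture_ewas(m=20, n=50, n_true=2, effect_rho=0.4, seed=7)
        d2, t2 = generate_fixture_ewas(m=20, n=50, n_true=2, effect_rho=0.4, seed=7)
        np.testing.assert_array_equal(d1.markers, d2.markers)
        assert t1.equals(t2)

    def test_outlier_spec_recorded_in_truth(self):
        data, truth = generate_fixture_ewas(
            m=50, n=100, n_true=0, effect_rho=0.0,
            outlier_spec={"kind": "bivariate", "n_features": 3, "count": 1,
                          "magnitude": 6.0},
            seed=4,
        )
        hit = truth[truth["outlier_kind"] == "bivariate"]
        assert len(hit) == 3
        for _, row in hit.iterrows():
            i = int(row["feature_id"][1:])
            (s,) = row["outlier_samples"]
            assert abs(data.markers[i, s]) == 6.0
            # concordant with the most extreme outcome
            assert np.sign(data.markers[i, s]) == np.sign(data.outcome[s])

    def test_covariate_loading_confounds_unadjusted_scan(self):
        data, _ = generate_fixture_ewas(
            m=200, n=150, n_true=0, effect_rho=0.0,
            covariate_spec={"n_covariates": 2, "loading": 0.0},
            seed=3,
        )
        assert data.covariates is not None and data.covariates.shape == (150, 2)
        table = full_sample_ewas(data, adjust="none")
        lam = inflation_lambda(table["p"].to_numpy())
        assert lam == pytest.approx(1.0, abs=0.4)

    def test_bounds(self):
        with pytest.raises(ValueError):
            generate_fixture_ewas(m=5, n=50, n_true=6, effect_rho=0.3)
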