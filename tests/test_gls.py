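"""Heteroscedastic GLS: likelihood oracles, selection, LRTs and the bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thermocomm as tc
from thermocomm.gls import ModelSpec, SingularDesignError, _profile_logl, fit_gls

from conftest import linear_index_records


def toy_changes(n=60, seed=0, noise=5.0, delta=0.0, sigma=None, shape=(40.0, -0.02)):
    """Change-set frame with shift = a0 + a1*(alt-500) + heteroscedastic noise."""
    rng = np.random.default_rng(seed)
    alt = np.linspace(300, 2700, n)
    rich = rng.uniform(5, 60, n)
    sd = (sigma if sigma is not None else noise) * rich**delta
    shift = shape[0] + shape[1] * (alt - 500) + rng.normal(0, sd)
    return pd.DataFrame({
        "square_id": [f"s{i}" for i in range(n)], "shift_m": shift,
        "altitude_m": alt, "altitudinal_range_m": rng.uniform(50, 400, n),
        "richness": rich,
    })


class TestBuildDesign:
    def test_centering_identity_at_500m(self):
        ch = toy_changes(5)
        ch.loc[0, "altitude_m"] = 500.0
        X, y, r = tc.build_design(ch, ModelSpec())
        assert np.allclose(X[0, 1:4], 0.0)
        assert X[0, 0] == 1.0

    def test_forced_arithmetic_at_2350m(self):
        ch = toy_changes(5)
        ch.loc[0, "altitude_m"] = 2350.0
        X, _, _ = tc.build_design(ch, ModelSpec())
        assert X[0, 1] == pytest.approx(1850.0)
        assert X[0, 2] == pytest.approx(3_422_500.0)

    def test_shape_matches_term_count(self, butterfly_changes):
        changes, _ = butterfly_changes
        for spec in (ModelSpec(), ModelSpec(poly_degree=1, include_range=False)):
            X, y, r = tc.build_design(changes, spec)
            assert X.shape == (len(changes), len(spec.term_names))
            assert y.shape == r.shape == (len(changes),)

    def test_missing_covariates_error_lists_squares(self):
        ch = toy_changes(6)
        ch.loc[2, "altitudinal_range_m"] = np.nan
        with pytest.raises(ValueError, match="s2"):
            tc.build_design(ch, ModelSpec())


class TestFitGls:
    def test_fixed_variance_ml_equals_ols(self):
        ch = toy_changes(80, seed=1)
        X, y, r = tc.build_design(ch, ModelSpec())
        fit = fit_gls(X, y, r, "fixed", "ML")
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-8)
        resid = y - X @ ols
        assert fit.variance.sigma == pytest.approx(
            np.sqrt(resid @ resid / len(y)), abs=1e-8)

    def test_power_likelihood_matches_density_oracle_on_six_points(self):
        ch = toy_changes(6, seed=2, delta=0.4)
        spec = ModelSpec(poly_degree=1, include_range=False)
        X, y, r = tc.build_design(ch, spec)
        fit = fit_gls(X, y, r, "power", "ML")
        # independent oracle: sum of normal log-densities at the fitted params
        sd = fit.variance.sigma * r**fit.variance.delta
        mu = X @ fit.beta
        oracle = stats.norm.logpdf(y, mu, sd).sum()
        assert fit.logl_ml == pytest.approx(oracle, abs=1e-8)
        # grid search over delta never beats the returned optimum
        for d in np.linspace(-2, 2, 161):
            g = r**d
            _, _, logl, _ = _profile_logl(X, y, g, "ML")
            assert logl <= fit.logl_ml + 1e-8

    def test_power_parameter_recovery(self):
        # delta and sigma trade off within one fit (sigma*r^delta), so check
        # delta per replicate and both on the replicate average
        deltas, sigmas = [], []
        for rep in range(20):
            ch = toy_changes(500, seed=3 + rep, delta=0.5, sigma=2.0)
            spec = ModelSpec(poly_degree=1, include_range=False)
            X, y, r = tc.build_design(ch, spec)
            fit = fit_gls(X, y, r, "power", "ML")
            deltas.append(fit.variance.delta)
            sigmas.append(fit.variance.sigma)
        assert 0.35 <= deltas[0] <= 0.65
        assert 0.45 <= np.mean(deltas) <= 0.55
        assert 1.7 <= np.median(sigmas) <= 2.3

    def test_ml_deviance_monotone_in_added_column(self):
        ch = toy_changes(80, seed=4)
        small = ModelSpec(poly_degree=1, include_range=False)
        big = ModelSpec(poly_degree=2, include_range=False)
        f_small = tc.fit_model(ch, small, criterion="ML")
        f_big = tc.fit_model(ch, big, criterion="ML")
        assert f_big.logl_ml >= f_small.logl_ml - 1e-9

    def test_singular_design_rejected(self):
        ch = toy_changes(30)
        ch["altitudinal_range_m"] = 100.0  # collinear with intercept
        with pytest.raises(SingularDesignError):
            tc.fit_model(ch, ModelSpec(), criterion="ML")

    def test_richness_must_be_positive_for_power(self):
        ch = toy_changes(30)
        ch.loc[0, "richness"] = 0.0
        with pytest.raises(ValueError):
            tc.fit_model(ch, ModelSpec(variance="power"))


class TestVarianceSelection:
    def test_homoscedastic_data_selects_fixed(self):
        # AIC prefers a spurious extra variance parameter with probability
        # ~P(chi2_1 > 2) = 0.16 (power) resp. ~P(chi2_2 > 4) = 0.14
        # (const+power), so the achievable three-way consistency is ~75-80%;
        # require a clear modal majority over 200 replicates
        counts: dict[str, int] = {}
        for rep in range(200):
            ch = toy_changes(500, seed=100 + rep, delta=0.0)
            X, y, r = tc.build_design(ch, ModelSpec(poly_degree=1, include_range=False))
            kind, _ = tc.select_variance_structure(X, y, r)
            counts[kind] = counts.get(kind, 0) + 1
        assert counts.get("fixed", 0) >= 140  # >= 70% of replicates
        assert counts["fixed"] == max(counts.values())

    def test_strong_heteroscedasticity_detected(self):
        wins = 0
        for rep in range(50):
            ch = toy_changes(500, seed=200 + rep, delta=1.0, sigma=0.3)
            X, y, r = tc.build_design(ch, ModelSpec(poly_degree=1, include_range=False))
            kind, _ = tc.select_variance_structure(X, y, r)
            wins += kind in ("power", "constpower")
        assert wins >= 48  # >= 95% of replicates

    def test_single_candidate_returned_unchanged(self):
        ch = toy_changes(60, seed=5)
        X, y, r = tc.build_design(ch, ModelSpec())
        kind, fits = tc.select_variance_structure(X, y, r, kinds=("power",))
        assert kind == "power" and set(fits) == {"power"}


class TestBackwardSelection:
    def test_pure_noise_selects_intercept_only(self):
        intercept_only = 0
        for rep in range(50):
            ch = toy_changes(200, seed=300 + rep, shape=(0.0, 0.0))
            spec, fit, _ = tc.backward_select(ch, variance="fixed")
            intercept_only += spec.poly_degree == 0 and not spec.include_range
        assert intercept_only > 25

    def test_strong_cubic_term_retained(self):
        rng = np.random.default_rng(6)
        ch = toy_changes(300, seed=6)
        a = ch["altitude_m"] - 500
        ch["shift_m"] = 1e-8 * a**3 * 5 + rng.normal(0, 1.0, len(ch))
        spec, _, _ = tc.backward_select(ch, variance="fixed")
        assert spec.poly_degree == 3

    def test_hierarchy_never_violated(self):
        for rep in range(10):
            ch = toy_changes(100, seed=400 + rep)
            spec, _, trail = tc.backward_select(ch, variance="fixed")
            for step in trail:
                s = step["spec"]
                assert "intercept" in s.term_names
                if "altitude^2" in s.term_names:
                    assert "altitude" in s.term_names
                if "altitude^3" in s.term_names:
                    assert "altitude^2" in s.term_names


class TestLrtReml:
    def _pair(self, seed=0, delta=0.0, n=100):
        ch = toy_changes(n, seed=seed, delta=delta)
        X, y, r = tc.build_design(ch, ModelSpec(poly_degree=1, include_range=False))
        full = fit_gls(X, y, r, "power", "REML")
        reduced = fit_gls(X, y, r, "fixed", "REML")
        return full, reduced

    def test_identical_models_give_stat_zero(self):
        full, _ = self._pair(seed=1)
        stat, df, p = tc.lrt_reml(full, full)
        assert stat == 0.0
        assert df == 0
        assert p == 1.0

    def test_definitional_identity_and_chi2_reference(self):
        full, reduced = self._pair(seed=2)
        stat, df, p = tc.lrt_reml(full, reduced)
        assert stat == pytest.approx(
            max(0.0, 2 * (full.logl_reml - reduced.logl_reml)), abs=1e-10)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(stat, 1) if stat > 0 else 1.0, abs=1e-12)

    def test_non_nested_rejected(self):
        full, reduced = self._pair(seed=3)
        with pytest.raises(ValueError):
            tc.lrt_reml(reduced, full)

    def test_type_one_error_under_null(self):
        # data truly homoscedastic: testing power vs fixed rejects ~alpha
        rejections = 0
        for rep in range(500):
            full, reduced = self._pair(seed=1000 + rep, delta=0.0)
            _, _, p = tc.lrt_reml(full, reduced)
            rejections += p < 0.05
        assert 0.02 * 500 <= rejections <= 0.09 * 500


class TestBootstrap:
    def test_zero_noise_data_gives_degenerate_interval(self):
        records = linear_index_records(b=-0.001, downhill_m=50.0)
        changes, _ = tc.standardized_changes(records)
        spec = ModelSpec(poly_degree=1, include_range=False, variance="fixed")
        boot = tc.bootstrap_predictions(changes, spec, targets=(500.0,), B=50, seed=0)
        assert boot.point[0] == pytest.approx(50.0, abs=1e-6)
        assert (boot.ci_high[0] - boot.ci_low[0]) < 1e-6 * abs(boot.point[0])

    def test_p_value_and_interval_consistency(self, butterfly_changes):
        changes, _ = butterfly_changes
        spec = ModelSpec(poly_degree=1, include_range=False, variance="power")
        boot = tc.bootstrap_predictions(changes, spec, targets=(500.0, 2350.0),
                                        B=199, seed=1)
        for j in range(2):
            excludes_zero = boot.ci_low[j] > 0 or boot.ci_high[j] < 0
            if boot.p_value[j] < 0.04:
                assert excludes_zero
            if boot.p_value[j] > 0.06:
                assert not excludes_zero

    def test_point_prediction_independent_of_iteration_count(self, butterfly_changes):
        changes, _ = butterfly_changes
        spec = ModelSpec(poly_degree=1, include_range=False, variance="power")
        b10 = tc.bootstrap_predictions(changes, spec, B=10, seed=2)
        b50 = tc.bootstrap_predictions(changes, spec, B=50, seed=3)
        assert np.allclose(b10.point, b50.point)
        assert not np.allclose(b10.ci_low, b50.ci_low)

    def test_deterministic_given_seed(self, butterfly_changes):
        changes, _ = butterfly_changes
        spec = ModelSpec(poly_degree=1, include_range=False, variance="fixed")
        a = tc.bootstrap_predictions(changes, spec, B=25, seed=9)
        b = tc.bootstrap_predictions(changes, spec, B=25, seed=9)
        assert np.array_equal(a.draws, b.draws)

    def test_null_rejection_rate_calibrated(self):
        # intercept-only truth at zero: two-sided bootstrap p rejects ~alpha
        rejections = 0
        for rep in range(200):
            ch = toy_changes(50, seed=2000 + rep, shape=(0.0, 0.0), noise=3.0)
            spec = ModelSpec(poly_degree=0, include_range=False, variance="fixed")
            boot = tc.bootstrap_predictions(ch, spec, targets=(500.0,), B=199, seed=rep)
            rejections += boot.p_value[0] < 0.05
        assert 0.01 * 200 <= rejections <= 0.10 * 200

    def test_prediction_at_500_equals_intercept_with_centred_range(self, butterfly_changes):
        changes, _ = butterfly_changes
        spec = ModelSpec(poly_degree=2, include_range=True, center_range=True,
                         variance="fixed")
        fit = tc.fit_model(changes, spec)
        pred = tc.predict(fit, [500.0], range_value=0.0)
        assert pred[0] == pytest.approx(fit.beta[0], abs=1e-10)


def test_bootstrap_with_slope_refit_sensitivity(butterfly_indices, butterfly_changes):
    # re-estimating b inside each resample widens (or at least changes) the
    # interval but leaves the full-data point prediction untouched
    changes, _ = butterfly_changes
    spec = ModelSpec(poly_degree=1, include_range=False, variance="fixed")
    fixed_b = tc.bootstrap_predictions(changes, spec, targets=(500.0,), B=30, seed=5)
    refit_b = tc.bootstrap_predictions(changes, spec, targets=(500.0,), B=30, seed=5,
                                       index_records=butterfly_indices)
    assert np.allclose(fixed_b.point, refit_b.point)
    assert not np.allclose(fixed_b.draws, refit_b.draws)


def test_refit_without_outliers(butterfly_changes):
    changes, _ = butterfly_changes
    spec = ModelSpec(poly_degree=1, include_range=False, variance="power")
    full = tc.fit_model(changes, spec)
    robust, n_excluded = tc.refit_without_outliers(changes, spec, (-500.0, 500.0))
    assert robust.n + n_excluded == full.n
    # altitude effect keeps its sign without the extreme shifts
    assert np.sign(robust.beta[1]) == np.sign(full.beta[1])
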