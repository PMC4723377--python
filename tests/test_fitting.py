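"""Unit tests for the objective, the fit metrics and the GA fitter."""

import numpy as np
import pytest

import sirdiffusion as sd
from sirdiffusion.fitting import FAILURE_PENALTY, default_bounds, objective

from conftest import S0_STAR, series_from

SMALL = dict(population_size=20, generations=30, local_polish=False)


def theta_vector(params: sd.SIRParams, s0: float) -> np.ndarray:
    return np.array([params.alpha, params.beta, params.mu, s0, params.K])


class TestObjective:
    def test_self_fit_near_zero(self, theta_star, init_star, noiseless_series):
        theta = theta_vector(theta_star, init_star.S0)
        value = objective(theta, noiseless_series, i0=init_star.I0)
        assert value <= 1e-6 * np.sum(noiseless_series.counts**2)

    def test_closed_form_decay_candidate(self):
        # alpha = mu = 0: the model is I(t) = I0 * exp(-beta t), so the
        # residual sum has a closed form against any observed series
        y = np.array([4.0, 2.5, 2.0, 1.0, 0.5])
        beta, i0 = 0.4, 4.0
        theta = np.array([0.0, beta, 0.0, 50.0, 100.0])
        expected = float(np.sum((y - i0 * np.exp(-beta * np.arange(5))) ** 2))
        assert objective(theta, y) == pytest.approx(expected, rel=1e-6)

    def test_default_i0_is_first_count(self):
        y = np.array([4.0, 2.5, 2.0, 1.0, 0.5])
        theta = np.array([0.0, 0.4, 0.0, 50.0, 100.0])
        assert objective(theta, y) == objective(theta, y, i0=4.0)

    def test_initial_population_above_capacity_penalized(self):
        y = np.ones(6)
        theta = np.array([0.01, 0.5, 0.1, 200.0, 100.0])  # N0 > K
        assert objective(theta, y) == FAILURE_PENALTY


class TestFitMetrics:
    def test_perfect_fit(self):
        mse, r2 = sd.fit_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert mse == 0.0 and r2 == 1.0

    def test_mean_predictor_scores_zero(self):
        y = [1.0, 2.0, 3.0, 6.0]
        mse, r2 = sd.fit_metrics(y, [3.0] * 4)
        assert r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        mse, r2 = sd.fit_metrics([1.0, 2.0, 3.0], [1.0, 1.0, 3.0])
        assert mse == pytest.approx(1.0 / 3.0)
        assert r2 == pytest.approx(0.5)

    def test_constant_offset(self):
        y = np.array([3.0, 5.0, 9.0, 4.0])
        c = 1.7
        mse, _ = sd.fit_metrics(y, y + c)
        assert mse == pytest.approx(c**2)

    def test_constant_series_r2_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            mse, r2 = sd.fit_metrics([2.0, 2.0, 2.0], [2.0, 3.0, 2.0])
        assert np.isnan(r2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            sd.fit_metrics([1.0, 2.0], [1.0])

    def test_negative_r2_for_bad_fit(self):
        _, r2 = sd.fit_metrics([1.0, 2.0, 3.0], [30.0, -10.0, 50.0])
        assert r2 < 0.0


class TestDefaultBounds:
    def test_shape_and_feasibility(self):
        y = np.array([1.0, 5.0, 20.0, 8.0, 2.0])
        bounds = default_bounds(y, i0=1.0)
        assert len(bounds) == 5
        assert all(lo <= hi for lo, hi in bounds)
        # S0 lower bound is I(0); K lower bound covers the initial population
        assert bounds[3][0] == 1.0
        assert bounds[4][0] >= bounds[3][0] + 1.0


class TestGASIRFitter:
    def test_determinism(self, noiseless_series):
        a = sd.GASIRFitter(random_state=3, **SMALL).fit(noiseless_series.counts)
        b = sd.GASIRFitter(random_state=3, **SMALL).fit(noiseless_series.counts)
        assert a.alpha_ == b.alpha_ and a.beta_ == b.beta_ and a.mu_ == b.mu_
        assert a.s0_ == b.s0_ and a.k_ == b.k_
        assert a.objective_ == b.objective_
        assert np.array_equal(a.history_, b.history_)

    def test_functional_wrapper_matches_estimator(self, noiseless_series):
        cfg = sd.GAConfig(
            population_size=20, generations=30, local_polish=False, seed=3
        )
        result = sd.fit(noiseless_series, cfg)
        est = sd.GASIRFitter(random_state=3, **SMALL).fit(noiseless_series.counts)
        assert result.objective == est.objective_
        assert result.params == est.params_
        assert result.seed == 3

    def test_history_non_increasing_with_elitism(self, noiseless_series):
        est = sd.GASIRFitter(random_state=1, **SMALL).fit(noiseless_series.counts)
        assert np.all(np.diff(est.history_) <= 0.0)

    def test_result_within_bounds(self, noiseless_series):
        est = sd.GASIRFitter(random_state=1, **SMALL).fit(noiseless_series.counts)
        bounds = default_bounds(noiseless_series.counts, est.i0_)
        genes = [est.alpha_ * est.s0_, est.beta_, est.mu_, est.s0_, est.k_]
        for g, (lo, hi) in zip(genes, bounds):
            assert lo - 1e-9 <= g <= hi + 1e-9

    def test_objective_equals_mse_times_n(self, default_fit):
        n = default_fit.n_periods_
        assert default_fit.objective_ == pytest.approx(
            default_fit.mse_ * n, rel=1e-9, abs=1e-12
        )

    def test_beats_generator_parameters(
        self, default_fit, theta_star, init_star, noiseless_series
    ):
        at_truth = objective(
            theta_vector(theta_star, init_star.S0),
            noiseless_series,
            i0=init_star.I0,
        )
        assert default_fit.objective_ <= at_truth

    def test_infeasible_bounds_rejected(self, noiseless_series):
        bounds = [(0.0, 10.0), (0.0, 0.99), (0.0, 2.0), (50.0, 100.0), (1.0, 10.0)]
        with pytest.raises(ValueError, match="infeasible"):
            sd.GASIRFitter(bounds=bounds, **SMALL).fit(noiseless_series.counts)

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sd.GASIRFitter(**SMALL).fit(np.zeros(10))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            sd.GASIRFitter(**SMALL).fit(np.array([1.0, 2.0, 3.0]))

    def test_leading_zeros_trimmed(self, noiseless_series):
        padded = np.concatenate([np.zeros(3), noiseless_series.counts])
        est = sd.GASIRFitter(random_state=2, **SMALL).fit(padded)
        plain = sd.GASIRFitter(random_state=2, **SMALL).fit(noiseless_series.counts)
        assert est.offset_ == 3
        assert est.objective_ == plain.objective_
        assert est.params_ == plain.params_

    def test_time_index_accepted(self, noiseless_series):
        y = noiseless_series.counts
        est = sd.GASIRFitter(random_state=2, **SMALL).fit(np.arange(len(y)), y)
        plain = sd.GASIRFitter(random_state=2, **SMALL).fit(y)
        assert est.objective_ == plain.objective_

    def test_non_unit_spacing_rejected(self, noiseless_series):
        y = noiseless_series.counts
        with pytest.raises(ValueError, match="consecutive"):
            sd.GASIRFitter(**SMALL).fit(np.arange(len(y)) * 2, y)

    def test_predict_matches_fitted_curve(self, default_fit):
        t = np.arange(default_fit.n_periods_)
        assert np.allclose(default_fit.predict(t), default_fit.fitted_curve_)

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError, match="fit"):
            sd.GASIRFitter().predict([0, 1, 2])

    def test_sklearn_param_round_trip(self):
        est = sd.GASIRFitter(population_size=7)
        params = est.get_params()
        assert params["population_size"] == 7
        est.set_params(generations=11)
        assert est.generations == 11

    def test_result_as_dict_layout(self, default_fit):
        d = default_fit.result_().as_dict()
        assert list(d) == ["MSE", "R2", "S0", "alpha", "beta", "mu", "K", "I0", "seed"]

    def test_frozen_genes_stay_fixed(self, theta_star, init_star, noiseless_series):
        # freeze mu, S0 and K at truth; only lambda0 and beta evolve
        bounds = [
            (0.0, 10.0),
            (0.0, 1.0 - 1e-6),
            (theta_star.mu, theta_star.mu),
            (init_star.S0, init_star.S0),
            (theta_star.K, theta_star.K),
        ]
        est = sd.GASIRFitter(bounds=bounds, random_state=0, **SMALL).fit(
            noiseless_series.counts
        )
        assert est.mu_ == theta_star.mu
        assert est.s0_ == init_star.S0
        assert est.k_ == theta_star.K


class TestDefaultFitQuality:
    def test_noiseless_recovery_is_tight(self, default_fit):
        # the canonical noiseless series should be recovered essentially
        # exactly by the default configuration (seed 0)
        assert abs(default_fit.beta_ - 0.7) / 0.7 < 0.10
        assert abs(default_fit.alpha_ * default_fit.s0_ - 0.008 * S0_STAR) / (
            0.008 * S0_STAR
        ) < 0.10
        assert default_fit.r_square_ > 0.99
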