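import numpy as np
import pytest
from scipy.special import expit, logit

from pampipe.stats.glm import (
    ContrastResult,
    design_from_factor,
    fit_firth,
    fit_logistic,
    pairwise_contrasts,
    predict_response,
    tipping_point,
)


def table_2x2(n11, n10, n01, n00):
    """x=1: n11 successes / n10 failures; x=0: n01 / n00."""
    x = np.array([1] * (n11 + n10) + [0] * (n01 + n00))
    y = np.array([1] * n11 + [0] * n10 + [1] * n01 + [0] * n00)
    return np.column_stack([np.ones_like(x, dtype=float), x]), y


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        f = fit_logistic(np.ones((10, 1)), np.array([1] * 3 + [0] * 7))
        assert f.coef[0] == pytest.approx(np.log(3 / 7), abs=1e-10)

    def test_saturated_2x2_odds_ratio(self):
        X, y = table_2x2(10, 5, 5, 10)
        f = fit_logistic(X, y)
        assert f.coef[1] == pytest.approx(np.log(4.0), abs=1e-8)
        assert f.converged and not f.separation

    def test_separation_flagged(self):
        x = np.arange(10.0)
        y = (x > 4).astype(float)
        f = fit_logistic(np.column_stack([np.ones(10), x]), y)
        assert f.separation and not f.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((5, 1)), np.ones(5))

    def test_n_not_greater_than_p_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.eye(3), np.array([0, 1, 0]))

    def test_fitted_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(100), rng.standard_normal(100)])
        y = (rng.random(100) < 0.4).astype(float)
        f = fit_logistic(X, y)
        assert np.all((f.fitted > 0) & (f.fitted < 1))
        assert np.allclose(f.cov, f.cov.T)
        assert np.all(np.linalg.eigvalsh(f.cov) > -1e-10)

    def test_deviance_monotone_nested(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.standard_normal(80), rng.standard_normal(80)
        y = (rng.random(80) < expit(0.5 * x1)).astype(float)
        f1 = fit_logistic(np.column_stack([np.ones(80), x1]), y)
        f2 = fit_logistic(np.column_stack([np.ones(80), x1, x2]), y)
        assert f2.deviance <= f1.deviance + 1e-8


class TestFitFirth:
    def test_2x2_add_half_closed_form(self):
        X, y = table_2x2(5, 0, 3, 4)
        f = fit_firth(X, y)
        expect = np.log((5.5 * 4.5) / (0.5 * 3.5))
        assert f.coef[1] == pytest.approx(expect, abs=1e-6)

    def test_add_half_sweep_random_separated_tables(self):
        # 50 random 2x2 tables with a zero cell: Firth == add-1/2 closed form
        rng = np.random.default_rng(7)
        done = 0
        while done < 50:
            n11, n01, n00 = rng.integers(1, 20, 3)
            cells = [int(n11), 0, int(n01), int(n00)]
            rng.shuffle(cells)
            a, b, c, d = cells
            if a + b == 0 or c + d == 0:
                continue
            X, y = table_2x2(a, b, c, d)
            if len(np.unique(y)) < 2:
                continue
            f = fit_firth(X, y)
            slope = np.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
            intercept = np.log((c + 0.5) / (d + 0.5))
            assert f.coef[1] == pytest.approx(slope, abs=1e-5)
            assert f.coef[0] == pytest.approx(intercept, abs=1e-5)
            done += 1

    def test_close_to_ml_without_separation(self):
        rng = np.random.default_rng(2)
        n = 500
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.3 + 0.8 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        ml = fit_logistic(X, y)
        fr = fit_firth(X, y)
        assert np.max(np.abs(ml.coef - fr.coef)) < 0.05  # O(1/n)

    def test_all_success_intercept_finite(self):
        f = fit_firth(np.ones((10, 1)), np.ones(10))
        assert f.coef[0] == pytest.approx(np.log(10.5 / 0.5), abs=1e-6)

    def test_finite_under_complete_separation(self):
        x = np.arange(10.0)
        y = (x > 4).astype(float)
        f = fit_firth(np.column_stack([np.ones(10), x]), y)
        assert np.all(np.isfinite(f.coef)) and f.converged


class TestParameterRecovery:
    def test_recovery_within_2se(self):
        # both fitters recover beta within 2 SE in >= 93% of replicates
        beta = np.array([-0.5, 0.8])
        n, reps = 341, 100
        hits_ml = hits_fr = 0
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(n)
            X = np.column_stack([np.ones(n), x])
            y = (rng.random(n) < expit(X @ beta)).astype(float)
            ml = fit_logistic(X, y)
            fr = fit_firth(X, y)
            hits_ml += np.all(np.abs(ml.coef - beta) <= 2 * ml.se)
            hits_fr += np.all(np.abs(fr.coef - beta) <= 2 * fr.se)
        assert hits_ml >= 0.93 * reps
        assert hits_fr >= 0.93 * reps


class TestContrasts:
    def _fit(self, seed=0, effects=(0.0, 1.0, -1.0)):
        rng = np.random.default_rng(seed)
        levels = np.repeat(["a", "b", "c"], 60)
        eta = np.repeat(effects, 60)
        y = (rng.random(180) < expit(eta)).astype(float)
        X, names, uniq = design_from_factor(levels)
        return fit_logistic(X, y, names), uniq

    def test_bonferroni_scaling(self):
        fit, levels = self._fit()
        res = pairwise_contrasts(fit, levels)
        assert len(res) == 3
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))

    def test_cap_at_one(self):
        fit, levels = self._fit()
        res = pairwise_contrasts(fit, levels, m=1000)
        assert any(r.p_adjusted == 1.0 for r in res)

    def test_identical_levels_null_contrast(self):
        rng = np.random.default_rng(3)
        levels = np.repeat(["a", "b"], 200)
        y = (rng.random(400) < 0.5).astype(float)
        X, names, uniq = design_from_factor(levels)
        fit = fit_logistic(X, y, names)
        res = pairwise_contrasts(fit, uniq)
        assert abs(res[0].estimate) < 0.5 and res[0].p_raw > 0.05

    def test_single_level_rejected(self):
        fit, levels = self._fit()
        with pytest.raises(ValueError):
            pairwise_contrasts(fit, ["a"])


class TestPredictResponse:
    def test_centred_intercept(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        x = x - x.mean()
        y = (rng.random(200) < expit(0.4 + 0.9 * x)).astype(float)
        fit = fit_logistic(np.column_stack([np.ones(200), x]), y)
        p, lo, hi = predict_response(fit, np.array([[1.0, 0.0]]))
        assert p[0] == pytest.approx(expit(fit.coef[0]), abs=1e-12)

    def test_ci_endpoints_inside_unit_interval(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(80)
        y = (rng.random(80) < expit(1.2 * x)).astype(float)
        fit = fit_logistic(np.column_stack([np.ones(80), x]), y)
        assert not fit.separation
        grid = np.column_stack([np.ones(50), np.linspace(-3, 3, 50)])
        p, lo, hi = predict_response(fit, grid)
        assert np.all((lo > 0) & (hi < 1) & (lo <= p) & (p <= hi))

    def test_column_mismatch_rejected(self):
        fit = fit_logistic(np.ones((10, 1)), np.array([0, 1] * 5))
        with pytest.raises(ValueError):
            predict_response(fit, np.ones((3, 2)))

    def test_se_against_parametric_bootstrap(self):
        rng = np.random.default_rng(6)
        n = 200
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        y = (rng.random(n) < expit(0.2 + 0.7 * x)).astype(float)
        fit = fit_logistic(X, y)
        point = np.array([[1.0, 1.0]])
        p_hat = predict_response(fit, point)[0][0]
        eta_se = np.sqrt(point @ fit.cov @ point.T).item()
        delta_sd = p_hat * (1 - p_hat) * eta_se  # response-scale delta SE
        boots = []
        for b in range(1000):
            yb = (rng.random(n) < fit.fitted).astype(float)
            if yb.min() == yb.max():
                continue
            fb = fit_logistic(X, yb)
            boots.append(predict_response(fb, point)[0][0])
        assert delta_sd == pytest.approx(np.std(boots), rel=0.10)


class TestTippingPoint:
    def test_presence_above_boundary(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([85.0, 92.0, 99.0, 10.0, 40.0, 83.0])
        tp = tipping_point(y, x, "presence-above", name="forest_cover")
        assert tp.boundary == 85.0
        # no absence sits at or above the boundary in this configuration
        assert tp.n_absences_beyond == 0

    def test_presence_below(self):
        y = np.array([1, 1, 0, 0])
        x = np.array([0.2, 0.5, 0.4, 0.9])
        tp = tipping_point(y, x, "presence-below")
        assert tp.boundary == 0.5 and tp.n_absences_beyond == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tipping_point(np.ones(5), np.arange(5.0), "presence-above")

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError):
            tipping_point(np.array([0, 1]), np.array([1.0, 1.0]), "presence-above")

    def test_recovery_of_80_percent_threshold(self):
        # hard 80%-cover threshold truth, n=341: boundary in [78, 84] >= 90/100
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cover = rng.uniform(0, 100, 341)
            y = (rng.random(341) < np.where(cover > 80, 0.7, 0.0)).astype(int)
            if y.sum() == 0:
                continue
            b = tipping_point(y, cover, "presence-above").boundary
            hits += 78.0 <= b <= 84.0
        assert hits >= 90
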