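import math

import numpy as np
import pytest

from hbmeta.dose_assignment import assign_doses_table
from hbmeta.effect_math import Z95
from hbmeta.errors import HbmetaError, IdentifiabilityError, InsufficientDataError
from hbmeta.gl_trend import gl_slope
from hbmeta.pooling import METHOD_FIXED, pool
from hbmeta.remr_spline import (
    DoseResponseCurve, SplineModel, fit_remr, predict_curve, rcs_basis,
    threshold_dose, weighted_percentile_knots,
)
from hbmeta.study_table import ExposureCategory, StudyRecord, StudyTable
from hbmeta.synthetic_data import SyntheticConfig, generate


def rcs_scalar_oracle(x, knots):
    """Textbook restricted-cubic-spline evaluation, scalar arithmetic only."""
    k = len(knots)
    t = sorted(knots)
    out = [x]
    norm = (t[-1] - t[0]) ** 2
    plus = lambda v: max(v, 0.0) ** 3
    for j in range(k - 2):
        term = (plus(x - t[j])
                - plus(x - t[k - 2]) * (t[-1] - t[j]) / (t[-1] - t[k - 2])
                + plus(x - t[-1]) * (t[k - 2] - t[j]) / (t[-1] - t[k - 2]))
        out.append(term / norm)
    return out


class TestRcsBasis:
    def test_matches_scalar_formula_oracle(self):
        knots = (5.2, 6.8, 8.9)
        xs = np.linspace(4.0, 10.5, 10)
        B = rcs_basis(xs, knots)
        expected = np.array([rcs_scalar_oracle(x, knots) for x in xs])
        assert B == pytest.approx(expected, abs=1e-10)

    def test_k_knots_give_k_minus_1_columns(self):
        for knots in [(5.5, 7, 8.5), (5, 6, 7, 8), (4.5, 5.5, 6.5, 8, 9.5)]:
            B = rcs_basis(np.linspace(5, 9, 5), knots)
            assert B.shape == (5, len(knots) - 1)

    def test_nonlinear_columns_vanish_at_and_below_first_knot(self):
        B = rcs_basis([4.0, 5.5], (5.5, 7.0, 8.5))
        assert B[:, 1:] == pytest.approx(0.0)

    def test_linear_tails(self):
        # second differences vanish outside the boundary knots
        knots = (5.5, 7.0, 8.5)
        for lo in (3.0, 9.0):
            xs = np.array([lo, lo + 0.5, lo + 1.0])
            B = rcs_basis(xs, knots)
            second_diff = B[2] - 2 * B[1] + B[0]
            assert second_diff == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_three_knots_rejected(self):
        with pytest.raises(HbmetaError):
            rcs_basis([5.0], (5.0, 6.0))


def _study(sid, doses, log_rrs, ses, ref_dose):
    cats = [ExposureCategory(rr=1.0, is_reference=True, assigned_dose=ref_dose)]
    for d, l, s in zip(doses, log_rrs, ses):
        lo, hi = math.exp(l - Z95 * s), math.exp(l + Z95 * s)
        cats.append(ExposureCategory(rr=math.exp(l), ci_lower=lo, ci_upper=hi,
                                     assigned_dose=d))
    return StudyRecord(sid, sid, "no_known_diabetes", "AF", categories=cats)


class TestFitRemr:
    def test_linear_collapse_equals_pooled_inverse_variance_slope(self):
        # one contrast per study: the linear one-stage fit must equal the
        # fixed-effect pool of the per-study two-point slopes
        recs = [_study("a", [7.0], [0.30], [0.10], 5.0),
                _study("b", [8.0], [0.50], [0.15], 5.0),
                _study("c", [6.5], [0.20], [0.08], 5.0)]
        table = StudyTable(recs)
        model = fit_remr(table, linear=True)
        slopes = [gl_slope(r).as_effect() for r in recs]
        # weight two-point slopes by the contrast information (se_L/x)^-2 = x^2/se^2
        x = np.array([2.0, 3.0, 1.5])
        L = np.array([0.30, 0.50, 0.20])
        se = np.array([0.10, 0.15, 0.08])
        w = x ** 2 / se ** 2
        expected = float(np.sum(w * (L / x)) / np.sum(w))
        assert model.coefficients[0] == pytest.approx(expected, rel=1e-10)

    def test_identifiability_guard(self):
        recs = [_study("a", [6.0, 7.0], [0.1, 0.2], [0.1, 0.1], 5.0)]
        with pytest.raises(InsufficientDataError):
            fit_remr(StudyTable(recs))

    def test_more_coefficients_than_clusters_rejected(self):
        recs = [_study("a", [6.0, 7.0], [0.1, 0.2], [0.1, 0.1], 5.0),
                _study("b", [6.5, 8.0], [0.1, 0.3], [0.1, 0.1], 5.2)]
        with pytest.raises(IdentifiabilityError):
            fit_remr(StudyTable(recs), knots=(5.5, 6.0, 6.5, 7.0, 7.5))

    def test_sandwich_matches_model_based_variance_in_expectation(self):
        # every study contributes one observation with exact inverse-variance
        # weights: E[CR1 sandwich] ~= model-based (X'WX)^-1
        rng = np.random.default_rng(2718)
        x = np.linspace(1.0, 3.0, 20)
        se = np.full(20, 0.2)
        XtWX_inv = 1.0 / np.sum(x ** 2 / se ** 2)
        sandwich_vars = []
        for _ in range(300):
            L = 0.1 * x + rng.normal(0, se)
            recs = [_study(f"s{i}", [5.0 + xi], [li], [si], 5.0)
                    for i, (xi, li, si) in enumerate(zip(x, L, se))]
            model = fit_remr(StudyTable(recs), linear=True)
            sandwich_vars.append(model.robust_cov[0, 0])
        assert np.mean(sandwich_vars) == pytest.approx(XtWX_inv, rel=0.15)


class TestPredictCurve:
    def _linear_model(self, coef, ref):
        return SplineModel(knots=(), coefficients=np.array([coef]),
                           robust_cov=np.array([[1e-4]]), ref_dose=ref,
                           n_obs=5, n_clusters=3, p_nonlinear=float("nan"),
                           dose_span=(4.5, 10.0))

    def test_anchor_has_unit_rr_and_zero_width(self):
        m = self._linear_model(math.log(1.15), 5.0)
        c = predict_curve(m, grid=[5.0])
        assert (c.rr[0], c.lo[0], c.hi[0]) == (1.0, 1.0, 1.0)

    def test_linear_model_closed_form(self):
        m = self._linear_model(math.log(1.15), 5.0)
        c = predict_curve(m, grid=[7.0])
        assert c.rr[0] == pytest.approx(1.15 ** 2)

    def test_rr_ratios_invariant_to_anchor_choice(self, dosed_table1):
        t = dosed_table1.subset(
            lambda r: r.population == "no_known_diabetes" and r.n_dosed_categories >= 2)
        model = fit_remr(t)
        grid = np.array([5.5, 6.5, 7.5])
        c1 = predict_curve(model, grid=grid, ref_dose=5.0)
        c2 = predict_curve(model, grid=grid, ref_dose=6.0)
        assert c1.rr / c1.rr[0] == pytest.approx(c2.rr / c2.rr[0], rel=1e-10)

    def test_ci_brackets_point_estimate(self, dosed_table1):
        t = dosed_table1.subset(
            lambda r: r.population == "no_known_diabetes" and r.n_dosed_categories >= 2)
        c = predict_curve(fit_remr(t), step=0.05)
        assert np.all(c.lo <= c.rr + 1e-12) and np.all(c.rr <= c.hi + 1e-12)


class TestThresholdDose:
    def _curve(self, grid, lo, ref):
        g = np.asarray(grid, dtype=float)
        return DoseResponseCurve(grid=g, rr=np.maximum(np.asarray(lo), 1.0) + 0.5,
                                 lo=np.asarray(lo, dtype=float),
                                 hi=np.full(len(g), 9.0), ref_dose=ref)

    def test_everywhere_significant_gives_first_grid_point_above_ref(self):
        c = self._curve([5.0, 5.5, 6.0, 6.5], [1.1, 1.2, 1.3, 1.4], 5.0)
        assert threshold_dose(c) == 5.5

    def test_never_significant_gives_none(self):
        c = self._curve([5.0, 6.0, 7.0], [0.8, 0.9, 0.99], 5.0)
        assert threshold_dose(c) is None

    def test_isolated_crossing_is_ignored(self):
        c = self._curve([5, 5.5, 6, 6.5, 7], [0.9, 1.05, 0.95, 1.1, 1.2], 5.0)
        assert threshold_dose(c) == 6.5


class TestWeightedKnots:
    def test_equal_weights_match_unweighted_percentiles(self):
        d = np.linspace(5, 9, 41)
        k = weighted_percentile_knots(d, np.ones_like(d), (10, 50, 90))
        assert k[1] == pytest.approx(7.0, abs=0.1)
        assert k[0] < k[1] < k[2]

    def test_nonlinearity_detected_on_threshold_truth(self):
        cfg = SyntheticConfig(n_studies=8, categories_per_study=4,
                              n_per_category=5000, truth="threshold",
                              change_point=6.3, slope_above=0.3, seed=314159)
        table = assign_doses_table(generate(cfg).table)
        model = fit_remr(table)
        assert model.p_nonlinear < 0.05
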