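"""Dilution-curve fitting, evaluation and between-group comparison."""

import numpy as np
import pytest

import cndc


def power_points(a, b, ldm, noise=None, rng=None):
    nc = a * np.asarray(ldm, dtype=float) ** (-b)
    if noise:
        nc = nc * np.exp(rng.normal(0.0, noise, len(nc)))
    return np.column_stack([ldm, nc])


def grid_search_loglog(points, a0, b0, span=0.5, steps=41, rounds=4):
    """Independent nested grid minimiser of log-scale SSE."""
    ldm, nc = points[:, 0], points[:, 1]
    best = (a0, b0)
    for _ in range(rounds):
        a_grid = np.linspace(best[0] * (1 - span), best[0] * (1 + span), steps)
        b_grid = np.linspace(best[1] - span, best[1] + span, steps)
        sse = np.array([[np.sum((np.log(nc) - np.log(a) + b * np.log(ldm)) ** 2)
                         for b in b_grid] for a in a_grid])
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (a_grid[i], b_grid[j])
        span /= 8.0
    return best


class TestFit:
    @pytest.mark.parametrize("method", ["loglog_ols", "nonlinear_ls"])
    def test_exact_recovery(self, method):
        pts = power_points(3.0, 0.5, [0.5, 1.0, 1.7, 2.4, 3.0])
        c = cndc.fit_curve(pts, method=method)
        assert c.a == pytest.approx(3.0, abs=1e-8)
        assert c.b == pytest.approx(0.5, abs=1e-8)
        assert c.r2 == pytest.approx(1.0, abs=1e-10)

    def test_loglog_matches_grid_search_oracle(self):
        rng = np.random.default_rng(19)
        pts = power_points(2.7, 0.8, np.linspace(0.6, 3.2, 12),
                           noise=0.08, rng=rng)
        c = cndc.fit_curve(pts, method="loglog_ols")
        a_g, b_g = grid_search_loglog(pts, c.a * 1.3, c.b + 0.3)
        assert c.a == pytest.approx(a_g, abs=1e-4)
        assert c.b == pytest.approx(b_g, abs=1e-4)

    def test_r2_reported_on_original_scale(self):
        rng = np.random.default_rng(4)
        pts = power_points(3.0, 0.6, np.linspace(0.5, 3, 10),
                           noise=0.1, rng=rng)
        c = cndc.fit_curve(pts)
        pred = c.a * pts[:, 0] ** (-c.b)
        expected = 1 - np.sum((pts[:, 1] - pred) ** 2) / \
            np.sum((pts[:, 1] - pts[:, 1].mean()) ** 2)
        assert c.r2 == pytest.approx(expected, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        pts = power_points(3.0, 0.7, np.linspace(0.5, 3, 9),
                           noise=0.05, rng=rng)
        k = 2.5
        scaled = pts.copy()
        scaled[:, 0] *= k
        c0 = cndc.fit_curve(pts)
        c1 = cndc.fit_curve(scaled)
        assert c1.b == pytest.approx(c0.b, abs=1e-10)
        assert c1.a == pytest.approx(c0.a * k ** c0.b, rel=1e-10)

    def test_errors(self):
        with pytest.raises(cndc.InsufficientDataError):
            cndc.fit_curve([(1, 2), (2, 1)])
        with pytest.raises(cndc.ValidationError):
            cndc.fit_curve([(1, 2), (2, -1), (3, 1)])
        with pytest.raises(cndc.DegenerateFitError):
            cndc.fit_curve([(1, 2), (1, 1.5), (1, 1.2)])


class TestEvaluate:
    @pytest.mark.parametrize("a,b", [(2.66, 0.79), (7.46, 1.42), (5.0, 0.0)])
    def test_value_at_unit_ldm_is_a(self, a, b):
        curve = cndc.DilutionCurve(a=a, b=b, r2=1.0, n_points=5,
                                   fit_method="loglog_ols")
        assert cndc.evaluate_nc(curve, 1.0) == pytest.approx(a)

    def test_strictly_decreasing_for_positive_b(self):
        curve = cndc.DilutionCurve(a=2.66, b=0.79, r2=1.0, n_points=5,
                                   fit_method="loglog_ols")
        grid = np.linspace(0.3, 4.0, 50)
        vals = cndc.evaluate_nc(curve, grid)
        assert np.all(np.diff(vals) < 0)

    def test_domain_error_and_extrapolation_warning(self):
        curve = cndc.DilutionCurve(a=3.0, b=0.5, r2=1.0, n_points=5,
                                   fit_method="loglog_ols",
                                   ldm_range=(1.0, 3.0))
        with pytest.raises(cndc.ValidationError):
            cndc.evaluate_nc(curve, 0.0)
        with pytest.warns(cndc.ExtrapolationWarning):
            cndc.evaluate_nc(curve, 0.5)


class TestCompare:
    def test_identical_sets_not_different(self):
        pts = power_points(3.0, 0.5, [0.5, 1.0, 1.8, 2.5, 3.2])
        cmp_ = cndc.compare_curves(pts, pts.copy())
        assert cmp_.p_slope >= 0.99
        assert cmp_.verdict == "not_different"

    def test_strong_slope_difference_detected(self):
        rng = np.random.default_rng(2)
        ldm = np.linspace(0.5, 3.5, 20)
        A = power_points(3.0, 0.5, ldm, noise=0.05, rng=rng)
        B = power_points(3.0, 1.2, ldm, noise=0.05, rng=rng)
        cmp_ = cndc.compare_curves(A, B)
        assert cmp_.p_slope < 0.01
        assert cmp_.verdict == "different"

    def test_errors(self):
        pts = power_points(3.0, 0.5, [1.0, 2.0, 3.0])
        with pytest.raises(cndc.InsufficientDataError):
            cndc.compare_curves(pts, pts[:2])
        degen = np.array([[2.0, 1.5], [2.0, 1.6], [2.0, 1.7]])
        with pytest.raises(cndc.DegenerateFitError):
            cndc.compare_curves(pts, degen)
        with pytest.raises(cndc.ValidationError):
            cndc.compare_curves(pts, pts, alpha=1.5)
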