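"""NNI, RMSE/n-RMSE validation, relative yield and the yield response."""

import math

import numpy as np
import pytest

import cndc


def make_curve(a=3.0, b=0.5):
    return cndc.DilutionCurve(a=a, b=b, r2=1.0, n_points=5,
                              fit_method="loglog_ols")


class TestNNI:
    @pytest.mark.parametrize("na,nc,nni,status", [
        (1.5, 1.5, 1.0, "optimal"),
        (1.2, 0.8, 1.5, "surplus"),
        (0.6, 1.2, 0.5, "deficient")])
    def test_examples(self, na, nc, nni, status):
        rec = cndc.compute_nni(na, nc)
        assert rec.nni == pytest.approx(nni, abs=1e-12)
        assert rec.status == status

    def test_band_is_configurable(self):
        assert cndc.compute_nni(1.04, 1.0).status == "optimal"
        assert cndc.compute_nni(1.04, 1.0, band=(1.0, 1.0)).status == "surplus"
        assert cndc.compute_nni(0.97, 1.0, band=(0.99, 1.01)).status == "deficient"

    def test_domain_errors(self):
        with pytest.raises(cndc.ValidationError):
            cndc.compute_nni(0.0, 1.0)
        with pytest.raises(cndc.ValidationError):
            cndc.compute_nni(1.0, -2.0)

    def test_on_curve_measurement_gives_unity(self):
        curve = make_curve()
        for ldm in (0.5, 1.0, 2.7):
            na = cndc.evaluate_nc(curve, ldm)
            assert cndc.compute_nni(na, cndc.evaluate_nc(curve, ldm)).nni == 1.0


class TestRMSE:
    def test_perfect_fit_zero(self):
        assert cndc.rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_arithmetic(self):
        assert cndc.rmse([2, 4], [1, 2]) == pytest.approx(
            math.sqrt(2.5), abs=1e-12)
        assert cndc.rmse([3], [5]) == pytest.approx(2.0, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(cndc.ValidationError):
            cndc.rmse([1, 2], [1])
        with pytest.raises(cndc.ValidationError):
            cndc.rmse([], [])

    def test_n_rmse_hand_arithmetic(self):
        pct, cls = cndc.n_rmse([2, 4], [1, 2])
        assert pct == pytest.approx(100 * math.sqrt(2.5) / 3, abs=1e-9)
        assert cls == "poor"

    def test_n_rmse_scale_invariance(self):
        obs = np.array([1.5, 2.5, 3.0])
        pred = np.array([1.2, 2.9, 2.7])
        base, _ = cndc.n_rmse(obs, pred)
        for k in (0.1, 3.0, 250.0):
            scaled, _ = cndc.n_rmse(k * obs, k * pred)
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_nonpositive_observed_mean(self):
        with pytest.raises(cndc.ValidationError):
            cndc.n_rmse([-2.0, 1.0], [1.0, 1.0])


class TestStabilityClasses:
    @pytest.mark.parametrize("value,expected", [
        (0.0, "excellent"), (9.99, "excellent"), (10.0, "good"),
        (10.78, "good"), (19.99, "good"), (20.0, "moderate"),
        (29.99, "moderate"), (30.0, "poor"), (100.0, "poor")])
    def test_boundaries(self, value, expected):
        assert cndc.stability_class(value) == expected

    def test_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        for v in rng.uniform(0, 80, 500):
            assert cndc.stability_class(v) in (
                "excellent", "good", "moderate", "poor")


class TestRelativeYield:
    def test_examples(self):
        assert cndc.relative_yield([4, 5]) == pytest.approx([0.8, 1.0])
        assert cndc.relative_yield([6.2]) == pytest.approx([1.0])

    def test_permutation_equivariance(self):
        y = np.array([4.0, 5.0, 3.0, 4.5])
        perm = np.array([2, 0, 3, 1])
        assert cndc.relative_yield(y[perm]) == pytest.approx(
            cndc.relative_yield(y)[perm])

    def test_errors(self):
        with pytest.raises(cndc.ValidationError):
            cndc.relative_yield([])
        with pytest.raises(cndc.ValidationError):
            cndc.relative_yield([4.0, 0.0])


class TestYieldResponse:
    def test_noiseless_vertex(self):
        nni = np.linspace(0.2, 1.8, 9)
        ry = 1 - (nni - 1) ** 2
        resp = cndc.fit_yield_response(nni, ry)
        assert (resp.c0, resp.c1, resp.c2) == pytest.approx((0, 2, -1),
                                                            abs=1e-10)
        assert (resp.nni_opt, resp.ry_max) == pytest.approx((1, 1), abs=1e-10)
        assert resp.r2 == pytest.approx(1.0, abs=1e-12)
        assert resp.is_maximum

    def test_vertex_matches_grid_argmax(self):
        rng = np.random.default_rng(21)
        nni = rng.uniform(0.3, 1.7, 24)
        ry = 0.4 + 1.1 * nni - 0.55 * nni ** 2 + rng.normal(0, 0.02, 24)
        resp = cndc.fit_yield_response(nni, ry)
        grid = np.linspace(nni.min(), nni.max(), 2_000_001)
        fitted = resp.c0 + resp.c1 * grid + resp.c2 * grid ** 2
        assert resp.nni_opt == pytest.approx(grid[np.argmax(fitted)],
                                             abs=1e-6)
        # vertex dominance: any epsilon away is strictly lower
        for eps in (1e-3, 0.1, 0.5):
            for x in (resp.nni_opt - eps, resp.nni_opt + eps):
                assert resp.c0 + resp.c1 * x + resp.c2 * x ** 2 < resp.ry_max

    def test_upward_parabola_flagged(self):
        nni = np.linspace(0.2, 1.8, 8)
        ry = 0.5 + (nni - 1) ** 2
        resp = cndc.fit_yield_response(nni, ry)
        assert not resp.is_maximum
        assert resp.ry_max == pytest.approx(0.5, abs=1e-10)  # a minimum

    def test_errors(self):
        with pytest.raises(cndc.InsufficientDataError):
            cndc.fit_yield_response([1, 2, 3], [1, 2, 3])
        with pytest.raises(cndc.DegenerateFitError):
            cndc.fit_yield_response([1, 1, 1, 1], [1, 2, 3, 4])


class TestValidateCurve:
    def test_points_on_curve_are_excellent(self):
        curve = make_curve()
        pts = [(l, cndc.evaluate_nc(curve, l)) for l in (0.6, 1.1, 2.0, 3.0)]
        rep = cndc.validate_curve(curve, pts)
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)
        assert rep.n_rmse == pytest.approx(0.0, abs=1e-12)
        assert rep.stability == "excellent"
        assert rep.n == 4

    def test_reports_paired_values_for_plotting(self):
        curve = make_curve()
        pts = [(1.0, 3.2), (2.0, 2.0)]
        rep = cndc.validate_curve(curve, pts)
        assert rep.observed == pytest.approx([3.2, 2.0])
        assert rep.predicted == pytest.approx(
            [cndc.evaluate_nc(curve, 1.0), cndc.evaluate_nc(curve, 2.0)])

    def test_needs_two_points(self):
        with pytest.raises(cndc.InsufficientDataError):
            cndc.validate_curve(make_curve(), [(1.0, 3.0)])
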