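"""Fitting and comparing critical nitrogen dilution curves.

The dilution curve is the power law ``Nc% = a * LDM^(-b)``: *a* is the
critical N concentration at a leaf dry matter of 1 t/ha and *b* the
dilution exponent, i.e. how fast the critical concentration declines as
the canopy accumulates dry matter.  The default fit linearises the law
(``ln Nc = ln a - b ln LDM``) and runs OLS on the log scale, which is
also the scale on which curves of two groups are compared by ANCOVA-type
F-tests (equal slopes first, then equal intercepts under a common
slope).  A nonlinear least-squares fit on the original scale is provided
as an alternative; either way the reported R^2 is computed on the
original Nc scale so fits are comparable across methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize

from .critical import CriticalPoint
from .errors import (DegenerateFitError, ExtrapolationWarning,
                     InsufficientDataError, ValidationError)

FIT_METHODS = ("loglog_ols", "nonlinear_ls")


@dataclass
class DilutionCurve:
    """Fitted power law ``Nc% = a * LDM^(-b)`` for one group of points."""

    a: float
    b: float
    r2: float
    n_points: int
    fit_method: str
    label: str = ""
    ldm_range: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if not (self.a > 0):
            raise ValidationError(f"coefficient a must be > 0, got {self.a}")

    def predict(self, ldm):
        """Alias for :func:`evaluate_nc` on this curve."""
        return evaluate_nc(self, ldm)


@dataclass
class CurveComparison:
    """ANCOVA-type comparison of two dilution curves on the log-log scale."""

    p_slope: float
    p_intercept: float
    alpha: float

    @property
    def verdict(self) -> str:
        different = (self.p_slope < self.alpha
                     or self.p_intercept < self.alpha)
        return "different" if different else "not_different"


def _point_arrays(points: Sequence) -> Tuple[np.ndarray, np.ndarray]:
    if len(points) and isinstance(points[0], CriticalPoint):
        ldm = np.array([p.ldm_max for p in points], dtype=float)
        nc = np.array([p.nc for p in points], dtype=float)
    else:
        arr = np.asarray(points, dtype=float).reshape(-1, 2)
        ldm, nc = arr[:, 0], arr[:, 1]
    return ldm, nc


def fit_curve(points: Sequence, method: str = "loglog_ols",
              label: str = "") -> DilutionCurve:
    """Fit the dilution power law to critical points.

    ``points`` is a sequence of :class:`~cndc.critical.CriticalPoint` or
    of (ldm, nc) pairs; at least 3 points with positive coordinates are
    required.  With ``loglog_ols`` the parameters come from OLS on
    ``ln nc ~ ln ldm``; with ``nonlinear_ls`` from Levenberg-Marquardt on
    the original scale, initialised at the log-log solution.
    """
    if method not in FIT_METHODS:
        raise ValidationError(
            f"unknown fit method {method!r}; choose from {FIT_METHODS}")
    ldm, nc = _point_arrays(points)
    if ldm.size < 3:
        raise InsufficientDataError(
            f"curve fit needs >= 3 critical points, got {ldm.size}")
    if (ldm <= 0).any() or (nc <= 0).any():
        raise ValidationError("curve fit needs ldm > 0 and nc > 0 everywhere")
    if np.ptp(np.log(ldm)) == 0:
        raise DegenerateFitError("all critical points share one LDM value")

    slope, intercept = np.polyfit(np.log(ldm), np.log(nc), 1)
    a, b = float(np.exp(intercept)), float(-slope)
    if method == "nonlinear_ls":
        popt, _ = optimize.curve_fit(
            lambda x, a_, b_: a_ * x ** (-b_), ldm, nc, p0=[a, b],
            maxfev=20000)
        a, b = float(popt[0]), float(popt[1])

    pred = a * ldm ** (-b)
    ss_res = float(np.sum((nc - pred) ** 2))
    ss_tot = float(np.sum((nc - nc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return DilutionCurve(a=a, b=b, r2=r2, n_points=int(ldm.size),
                         fit_method=method, label=label,
                         ldm_range=(float(ldm.min()), float(ldm.max())))


def evaluate_nc(curve: DilutionCurve, ldm):
    """Critical N concentration (%) predicted at leaf dry matter ``ldm``.

    Accepts a scalar or array; warns when evaluating outside the LDM range
    of the fitting points (the law is applied without a low-biomass cap).
    """
    arr = np.asarray(ldm, dtype=float)
    if (arr <= 0).any():
        raise ValidationError("ldm must be > 0")
    if curve.ldm_range is not None:
        lo, hi = curve.ldm_range
        if (arr < lo).any() or (arr > hi).any():
            warnings.warn(
                f"evaluating curve {curve.label or '(unlabelled)'} outside "
                f"its fitted LDM range [{lo:.3g}, {hi:.3g}]",
                ExtrapolationWarning, stacklevel=2)
    out = curve.a * arr ** (-curve.b)
    return float(out) if np.isscalar(ldm) else out


def compare_curves(points_a: Sequence, points_b: Sequence,
                   alpha: float = 0.05) -> CurveComparison:
    """Test whether two groups of critical points share one dilution curve.

    On the linearised scale, fits ``ln nc ~ ln ldm * group`` and F-tests
    the slope-by-group interaction (equal dilution exponents); then, under
    a common slope, F-tests the group main effect (equal ``ln a``).  The
    verdict is 'different' iff either p-value is below ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    frames = []
    for name, pts in (("A", points_a), ("B", points_b)):
        ldm, nc = _point_arrays(pts)
        if ldm.size < 3:
            raise InsufficientDataError(
                f"group {name} needs >= 3 points, got {ldm.size}")
        if np.ptp(np.log(ldm)) == 0:
            raise DegenerateFitError(
                f"group {name}: all ln(ldm) values equal")
        frames.append(pd.DataFrame({
            "log_ldm": np.log(ldm), "log_nc": np.log(nc), "group": name}))
    data = pd.concat(frames, ignore_index=True)

    full = smf.ols("log_nc ~ log_ldm * C(group)", data=data).fit()
    common = smf.ols("log_nc ~ log_ldm + C(group)", data=data).fit()
    single = smf.ols("log_nc ~ log_ldm", data=data).fit()

    # Numerically exact fits (e.g. two copies of points generated on one
    # power law) leave only rounding noise in the residuals; F would be a
    # 0/0 ratio.  Decide directly from the sums of squares instead.
    sst = float(np.sum((data["log_nc"] - data["log_nc"].mean()) ** 2))
    tol = 1e-10 * max(sst, 1e-30)
    if full.ssr < tol:
        p_slope = 1.0 if common.ssr - full.ssr < tol else 0.0
        p_int = 1.0 if single.ssr - common.ssr < tol else 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_slope = float(sm.stats.anova_lm(common, full).iloc[1]["Pr(>F)"])
            p_int = float(sm.stats.anova_lm(single, common).iloc[1]["Pr(>F)"])
        p_slope = 1.0 if np.isnan(p_slope) else p_slope
        p_int = 1.0 if np.isnan(p_int) else p_int
    return CurveComparison(p_slope=p_slope, p_intercept=p_int, alpha=alpha)
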