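"""Critical-point extraction: stages (b)-(d) of the Justes construction.

Per usable sampling date, an ordinary least-squares line ("oblique") is
fitted to (LDM, PNC) of the N-limited treatments, a vertical line is
placed at the mean LDM of the non-limited treatments (the date's maximum
attainable leaf dry matter), and their intersection gives the date's
critical point (ldm_max, Nc): the minimum plant N concentration
compatible with maximum leaf growth at that date.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .classify import LimitationResult, classify_table
from .errors import (DegenerateFitError, ExtrapolationWarning,
                     InsufficientDataError, ObliqueSlopeWarning,
                     UnusableDateError)
from .model import ExperimentTable


@dataclass
class CriticalPoint:
    """One date's critical point plus the construction that produced it."""

    variety: str
    season: str
    year: Optional[int]
    stage: str
    ldm_max: float      # t/ha, vertical line position
    nc: float           # %, critical N concentration at ldm_max
    oblique_slope: float
    oblique_intercept: float
    n_limited: int

    @property
    def group_key(self) -> tuple:
        return (self.variety, self.season, self.year, self.stage)


def fit_oblique(limited_points: Sequence[Tuple[float, float]]) -> Tuple[float, float]:
    """OLS line of PNC on LDM through the N-limited treatment points.

    Returns (slope, intercept).  Requires >= 2 points with distinct LDM.
    """
    pts = np.asarray(limited_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise InsufficientDataError(
            "oblique fit needs >= 2 (ldm, pnc) points, got "
            f"{0 if pts.ndim != 2 else pts.shape[0]}")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateFitError("all limited-treatment LDM values are equal")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def vertical_ldm(non_limited_ldm: Sequence[float]) -> float:
    """Mean LDM of the non-limited treatments: the date's maximum LDM."""
    vals = np.asarray(list(non_limited_ldm), dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("no non-limited treatments")
    return float(vals.mean())


def extract_point(classified: LimitationResult) -> CriticalPoint:
    """Intersect the oblique and vertical lines of one classified date.

    Warns (without failing) when the oblique slope is non-positive or the
    intersection falls outside the range of PNC observed at the date;
    raises :class:`UnusableDateError` when the date lacks the required
    two-limited/one-non-limited contrast.
    """
    if not classified.usable:
        raise UnusableDateError(
            f"date {classified.group_key} has no usable limited/non-limited "
            "contrast")
    lim = [(classified.ldm_means[r], classified.pnc_means[r])
           for r in classified.limited_rates]
    slope, intercept = fit_oblique(lim)
    ldm_max = vertical_ldm(
        [classified.ldm_means[r] for r in classified.non_limited_rates])
    nc = intercept + slope * ldm_max

    if slope <= 0:
        warnings.warn(
            f"date {classified.group_key}: oblique slope {slope:.4g} <= 0",
            ObliqueSlopeWarning, stacklevel=2)
    pnc_vals = list(classified.pnc_means.values())
    if not (min(pnc_vals) <= nc <= max(pnc_vals)):
        warnings.warn(
            f"date {classified.group_key}: critical N {nc:.3f}% outside the "
            f"observed PNC range [{min(pnc_vals):.3f}, {max(pnc_vals):.3f}]",
            ExtrapolationWarning, stacklevel=2)
    return CriticalPoint(
        variety=classified.variety, season=classified.season,
        year=classified.year, stage=classified.stage,
        ldm_max=float(ldm_max), nc=float(nc),
        oblique_slope=slope, oblique_intercept=intercept,
        n_limited=len(lim),
    )


def points_to_frame(points: Sequence[CriticalPoint]):
    """Tabular view of critical points (the critical_points.csv layout)."""
    import pandas as pd

    return pd.DataFrame([{
        "variety": p.variety, "season": p.season, "year": p.year,
        "stage": p.stage, "ldm_max": p.ldm_max, "nc": p.nc,
        "oblique_slope": p.oblique_slope,
        "oblique_intercept": p.oblique_intercept,
        "n_limited": p.n_limited,
    } for p in points])


def points_from_frame(frame) -> list:
    """Rebuild :class:`CriticalPoint` objects from a critical-points table."""
    import pandas as pd

    out = []
    for rec in frame.to_dict("records"):
        year = rec.get("year")
        out.append(CriticalPoint(
            variety=str(rec["variety"]), season=str(rec["season"]),
            year=None if year is None or pd.isna(year) else int(year),
            stage=str(rec["stage"]), ldm_max=float(rec["ldm_max"]),
            nc=float(rec["nc"]),
            oblique_slope=float(rec.get("oblique_slope", float("nan"))),
            oblique_intercept=float(rec.get("oblique_intercept", float("nan"))),
            n_limited=int(rec.get("n_limited", 0)),
        ))
    return out


def extract_points(table: ExperimentTable, method: str = "auto",
                   alpha: float = 0.05) -> list:
    """Classify every sampling date of ``table`` and extract its critical
    point, silently skipping unusable dates (the Justes convention)."""
    points = []
    for res in classify_table(table, method=method, alpha=alpha):
        if not res.usable:
            continue
        points.append(extract_point(res))
    return points
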