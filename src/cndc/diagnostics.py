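"""Nitrogen-nutrition diagnostics built on a fitted dilution curve.

* NNI, the nitrogen nutrition index, is the ratio of measured plant N
  concentration to the critical concentration at the same leaf dry
  matter: NNI = Na / Nc.  1 means optimal supply, below 1 deficiency,
  above 1 surplus; in practice a band around 1 (default 0.95-1.05) is
  treated as optimal.
* Model validation reports RMSE and the normalised RMSE
  (n-RMSE = 100 * RMSE / mean(observed), %), classed by the usual
  agronomic stability thresholds at 10/20/30%.
* Yield response: relative yield (each treatment's yield over the best
  yield of its season-year) regressed quadratically on NNI; the vertex
  gives the NNI at which relative yield peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .curve import DilutionCurve, evaluate_nc
from .errors import (DegenerateFitError, InsufficientDataError,
                     ValidationError)
from .model import ExperimentTable

#: Half-open n-RMSE stability classes: [0,10) excellent, [10,20) good,
#: [20,30) moderate, [30,inf) poor.
STABILITY_BOUNDS = ((10.0, "excellent"), (20.0, "good"), (30.0, "moderate"))

DEFAULT_NNI_BAND = (0.95, 1.05)


@dataclass
class NNIRecord:
    """Measured vs critical N for one treatment at one sampling date."""

    na: float           # measured PNC, %
    nc: float           # critical PNC at the same LDM, %
    nni: float
    status: str         # deficient | optimal | surplus
    variety: str = ""
    season: str = ""
    year: Optional[int] = None
    stage: str = ""
    n_rate: Optional[float] = None


@dataclass
class ValidationReport:
    """Observed-vs-predicted agreement of a curve on holdout points."""

    rmse: float
    n_rmse: float       # percent
    stability: str
    n: int
    observed: np.ndarray = field(repr=False, default=None)
    predicted: np.ndarray = field(repr=False, default=None)


@dataclass
class YieldResponse:
    """Quadratic fit of relative yield on NNI, with its vertex."""

    c0: float
    c1: float
    c2: float
    r2: float
    nni_opt: float      # vertex abscissa: -c1 / (2 c2)
    ry_max: float       # fitted RY at the vertex
    stage: str = ""
    n: int = 0

    @property
    def is_maximum(self) -> bool:
        """True when the parabola opens downward (c2 < 0), so the vertex
        is a maximum; otherwise the vertex is a minimum and the fit is
        flagged as diagnostically suspect."""
        return self.c2 < 0


def compute_nni(na: float, nc: float,
                band: Tuple[float, float] = DEFAULT_NNI_BAND) -> NNIRecord:
    """NNI = na / nc with a three-way status by the optimal band.

    ``band=(1, 1)`` recovers the strict rule (optimal iff NNI == 1).
    """
    if not (na > 0 and nc > 0):
        raise ValidationError(f"na and nc must be > 0 (got {na}, {nc})")
    lo, hi = band
    if not lo <= hi:
        raise ValidationError(f"invalid NNI band {band}")
    nni = na / nc
    if nni < lo:
        status = "deficient"
    elif nni > hi:
        status = "surplus"
    else:
        status = "optimal"
    return NNIRecord(na=float(na), nc=float(nc), nni=float(nni), status=status)


def nni_records(table: ExperimentTable, curve: DilutionCurve,
                band: Tuple[float, float] = DEFAULT_NNI_BAND,
                ldm_basis: str = "own") -> list:
    """NNI of every treatment mean in ``table`` against ``curve``.

    ``ldm_basis`` chooses the LDM at which the critical concentration is
    evaluated: 'own' (default) uses each treatment's own mean LDM;
    'date_max' uses the maximal mean LDM of the treatment's sampling
    date for all treatments of that date.
    """
    if ldm_basis not in ("own", "date_max"):
        raise ValidationError(f"unknown ldm_basis {ldm_basis!r}")
    frame = table.to_frame()
    means = frame.groupby(["variety", "season", "year", "stage", "n_rate"],
                          dropna=False, sort=False, as_index=False).agg(
        ldm=("ldm", "mean"), pnc=("pnc", "mean"))
    date_max = means.groupby(["variety", "season", "year", "stage"],
                             dropna=False)["ldm"].transform("max")
    out = []
    for (_, row), dmax in zip(means.iterrows(), date_max):
        ldm = row["ldm"] if ldm_basis == "own" else dmax
        rec = compute_nni(row["pnc"], evaluate_nc(curve, float(ldm)), band)
        rec.variety = row["variety"]
        rec.season = row["season"]
        rec.year = None if pd.isna(row["year"]) else int(row["year"])
        rec.stage = row["stage"]
        rec.n_rate = float(row["n_rate"])
        out.append(rec)
    return out


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean square error sqrt(sum((P - O)^2) / n)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValidationError(
            f"observed/predicted must be equal-length and non-empty "
            f"(got {obs.shape} vs {pred.shape})")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def stability_class(n_rmse_pct: float) -> str:
    """Stability class of an n-RMSE value (percent)."""
    if n_rmse_pct < 0:
        raise ValidationError("n-RMSE cannot be negative")
    for bound, name in STABILITY_BOUNDS:
        if n_rmse_pct < bound:
            return name
    return "poor"


def n_rmse(observed: Sequence[float],
           predicted: Sequence[float]) -> Tuple[float, str]:
    """Normalised RMSE (percent of the observed mean) and its class."""
    obs = np.asarray(observed, dtype=float)
    value = rmse(observed, predicted)
    mean_obs = float(obs.mean())
    if mean_obs <= 0:
        raise ValidationError(
            f"mean of observed values must be > 0, got {mean_obs}")
    pct = 100.0 * value / mean_obs
    return pct, stability_class(pct)


def relative_yield(yields: Sequence[float]) -> np.ndarray:
    """Each yield divided by the maximum of its group; the best plot is 1."""
    arr = np.asarray(yields, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty yield group")
    if (arr <= 0).any():
        raise ValidationError("yields must be > 0")
    return arr / arr.max()


def relative_yield_table(table: ExperimentTable) -> pd.DataFrame:
    """Treatment-mean relative yield per (season, year) group.

    Yields are averaged over replicates and stages within a treatment
    (the same harvest yield is attached to every sampling row of a plot),
    then scaled by the best treatment of the same season-year.
    """
    frame = table.to_frame()
    frame = frame[frame["yield"].notna()]
    if frame.empty:
        raise ValidationError("table carries no yield values")
    means = frame.groupby(["variety", "season", "year", "n_rate"],
                          dropna=False, sort=False, as_index=False)["yield"].mean()
    means["relative_yield"] = means.groupby(["season", "year"], dropna=False)[
        "yield"].transform(lambda y: y / y.max())
    return means


def fit_yield_response(nni: Sequence[float], ry: Sequence[float],
                       stage: str = "") -> YieldResponse:
    """OLS quadratic of relative yield on NNI, with closed-form vertex."""
    x = np.asarray(nni, dtype=float)
    y = np.asarray(ry, dtype=float)
    if x.size < 4 or x.shape != y.shape:
        raise InsufficientDataError(
            f"need >= 4 paired (nni, ry) values, got {x.size}")
    if np.unique(x).size < 3:
        raise DegenerateFitError(
            "nni values must take >= 3 distinct values for a quadratic fit")
    c2, c1, c0 = np.polyfit(x, y, 2)
    if c2 == 0:
        raise DegenerateFitError("quadratic coefficient is exactly zero")
    pred = c0 + c1 * x + c2 * x ** 2
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    nni_opt = -c1 / (2.0 * c2)
    ry_max = c0 + c1 * nni_opt + c2 * nni_opt ** 2
    return YieldResponse(c0=float(c0), c1=float(c1), c2=float(c2), r2=r2,
                         nni_opt=float(nni_opt), ry_max=float(ry_max),
                         stage=stage, n=int(x.size))


def validate_curve(curve: DilutionCurve,
                   holdout_points: Sequence) -> ValidationReport:
    """RMSE/n-RMSE of ``curve`` against independent critical points.

    Predictions are the curve evaluated at each holdout point's maximum
    LDM; observations are the holdout critical concentrations.  The
    paired arrays are returned for 1:1 plotting.
    """
    from .curve import _point_arrays  # shared point coercion

    ldm, nc_obs = _point_arrays(list(holdout_points))
    if ldm.size < 2:
        raise InsufficientDataError(
            f"validation needs >= 2 holdout points, got {ldm.size}")
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # holdout may extend past fit range
        pred = np.asarray(evaluate_nc(curve, ldm), dtype=float)
    pct, cls = n_rmse(nc_obs, pred)
    return ValidationReport(rmse=rmse(nc_obs, pred), n_rmse=pct,
                            stability=cls, n=int(ldm.size),
                            observed=nc_obs, predicted=pred)
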