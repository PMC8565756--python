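"""Standard figures: dilution curve, 1:1 validation, NNI, yield response."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .curve import DilutionCurve
from .diagnostics import ValidationReport, YieldResponse


def plot_dilution_curve(curve: DilutionCurve, points: Sequence, ax=None):
    """Critical points with the fitted power law overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ldm = np.array([p.ldm_max for p in points])
    nc = np.array([p.nc for p in points])
    ax.scatter(ldm, nc, c="k", s=25, zorder=3, label="critical points")
    grid = np.linspace(ldm.min(), ldm.max(), 200)
    ax.plot(grid, curve.a * grid ** (-curve.b), "r-",
            label=(f"$N_c$% = {curve.a:.2f} LDM$^{{-{curve.b:.2f}}}$"
                   f"  ($R^2$={curve.r2:.2f})"))
    ax.set_xlabel("leaf dry matter (t ha$^{-1}$)")
    ax.set_ylabel("critical N concentration (%)")
    if curve.label:
        ax.set_title(curve.label)
    ax.legend(frameon=False)
    return ax


def plot_validation_11(report: ValidationReport, ax=None):
    """Observed vs predicted critical N with the 1:1 line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    obs, pred = report.observed, report.predicted
    lim = (0, 1.1 * max(obs.max(), pred.max()))
    ax.plot(lim, lim, "k--", lw=1, label="1:1")
    ax.scatter(obs, pred, c="tab:blue", s=25)
    ax.set_xlim(lim), ax.set_ylim(lim)
    ax.set_xlabel("observed $N_c$ (%)")
    ax.set_ylabel("simulated $N_c$ (%)")
    ax.set_title(f"RMSE={report.rmse:.2f}, n-RMSE={report.n_rmse:.1f}% "
                 f"({report.stability})")
    ax.legend(frameon=False)
    return ax


def plot_nni(nni_frame, ax=None, stage_order=("TS", "JS", "BS", "HS", "FHS")):
    """NNI trajectories over stages, one line per nitrogen rate."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4))
    frame = nni_frame.copy()
    order = {s: i for i, s in enumerate(stage_order)}
    frame["_ord"] = frame["stage"].map(order)
    for rate, sub in frame.groupby("n_rate"):
        sub = sub.sort_values("_ord").groupby("stage", sort=False).agg(
            _ord=("_ord", "first"), nni=("nni", "mean")).sort_values("_ord")
        ax.plot(sub.index, sub["nni"], "o-", label=f"N{rate:g}")
    ax.axhline(1.0, color="k", ls=":", lw=1)
    ax.set_xlabel("growth stage")
    ax.set_ylabel("nitrogen nutrition index")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_yield_response(resp: YieldResponse, nni, ry, ax=None):
    """Relative yield vs NNI with the fitted parabola and its vertex."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    nni = np.asarray(nni, dtype=float)
    ry = np.asarray(ry, dtype=float)
    ax.scatter(nni, ry, c="k", s=25, zorder=3)
    grid = np.linspace(nni.min(), nni.max(), 200)
    ax.plot(grid, resp.c0 + resp.c1 * grid + resp.c2 * grid ** 2, "r-",
            label=f"$R^2$={resp.r2:.2f}")
    ax.scatter([resp.nni_opt], [resp.ry_max], marker="*", c="tab:red", s=120,
               zorder=4, label=f"vertex ({resp.nni_opt:.2f}, {resp.ry_max:.2f})")
    ax.set_xlabel("nitrogen nutrition index")
    ax.set_ylabel("relative yield")
    if resp.stage:
        ax.set_title(f"stage {resp.stage}")
    ax.legend(frameon=False)
    return ax


def save(fig_or_ax, path) -> None:
    ax = fig_or_ax if hasattr(fig_or_ax, "figure") else fig_or_ax
    fig = ax.figure if hasattr(ax, "figure") else ax
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
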