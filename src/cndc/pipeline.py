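"""End-to-end orchestration: classify -> extract -> fit -> diagnose.

:func:`run_pipeline` chains the whole workflow on one or more observation
files (or in-memory tables): limitation classification per sampling date,
critical-point extraction, dilution-curve fitting per pooling group,
optional curve comparison, validation against holdout data, the NNI
table, and the quadratic yield response.  All artifacts are returned in
a :class:`PipelineResult` and optionally written as CSV reports plus a
plain-text summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .classify import classify_table
from .critical import CriticalPoint, extract_point
from .curve import CurveComparison, DilutionCurve, compare_curves, fit_curve
from .diagnostics import (DEFAULT_NNI_BAND, ValidationReport, YieldResponse,
                          fit_yield_response, nni_records,
                          relative_yield_table, validate_curve)
from .errors import CndcError, InsufficientDataError, ValidationError
from .io import read_observations
from .model import ExperimentTable

log = logging.getLogger("cndc.pipeline")

POOLING_RULES = ("pooled-by-season", "per-variety")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``inputs`` may hold file paths or in-memory
    :class:`~cndc.model.ExperimentTable` objects; ``validation_inputs``
    supplies independent holdout data for RMSE/n-RMSE validation.
    """

    inputs: Sequence[Union[str, Path, ExperimentTable]]
    validation_inputs: Sequence[Union[str, Path, ExperimentTable]] = ()
    method: str = "auto"            # letters | anova | auto
    alpha: float = 0.05
    fit_method: str = "loglog_ols"
    pooling: str = "pooled-by-season"
    nni_band: Tuple[float, float] = DEFAULT_NNI_BAND
    yield_stage: Optional[str] = None   # None: pick the best-R2 stage
    nni_ldm_basis: str = "own"
    compare: bool = True
    outdir: Optional[Union[str, Path]] = None

    def validate(self) -> None:
        if not self.inputs:
            raise ValidationError("PipelineConfig.inputs is empty")
        if self.method not in ("auto", "letters", "anova"):
            raise ValidationError(f"unknown method {self.method!r}")
        if not 0 < self.alpha < 1:
            raise ValidationError(
                f"alpha must be in (0, 1), got {self.alpha}")
        if self.pooling not in POOLING_RULES:
            raise ValidationError(
                f"pooling must be one of {POOLING_RULES}, got {self.pooling!r}")
        if self.fit_method not in ("loglog_ols", "nonlinear_ls"):
            raise ValidationError(
                f"unknown fit method {self.fit_method!r}")
        lo, hi = self.nni_band
        if not 0 < lo <= hi:
            raise ValidationError(f"invalid NNI band {self.nni_band}")
        if self.nni_ldm_basis not in ("own", "date_max"):
            raise ValidationError(
                f"unknown nni_ldm_basis {self.nni_ldm_basis!r}")


@dataclass
class PipelineResult:
    """Everything one pipeline run computed."""

    table: ExperimentTable
    classifications: list
    points: List[CriticalPoint]
    curves: Dict[str, DilutionCurve]
    comparisons: Dict[Tuple[str, str], CurveComparison] = field(
        default_factory=dict)
    validation: Dict[str, ValidationReport] = field(default_factory=dict)
    nni: Optional[pd.DataFrame] = None
    yield_response: Dict[str, YieldResponse] = field(default_factory=dict)

    # -- tabular views ----------------------------------------------------

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "variety": p.variety, "season": p.season, "year": p.year,
            "stage": p.stage, "ldm_max": p.ldm_max, "nc": p.nc,
            "oblique_slope": p.oblique_slope,
            "oblique_intercept": p.oblique_intercept,
            "n_limited": p.n_limited,
        } for p in self.points])

    def curves_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "group": label, "a": c.a, "b": c.b, "r2": c.r2,
            "n_points": c.n_points, "fit_method": c.fit_method,
        } for label, c in self.curves.items()])

    def validation_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "group": label, "rmse": r.rmse, "n_rmse": r.n_rmse,
            "stability": r.stability, "n": r.n,
        } for label, r in self.validation.items()])

    def yield_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "group": label, "stage": y.stage, "c0": y.c0, "c1": y.c1,
            "c2": y.c2, "r2": y.r2, "nni_opt": y.nni_opt,
            "ry_max": y.ry_max, "is_maximum": y.is_maximum, "n": y.n,
        } for label, y in self.yield_response.items()])

    def summary_text(self) -> str:
        lines = [f"observations: {len(self.table)}",
                 f"usable dates: {sum(r.usable for r in self.classifications)}"
                 f" / {len(self.classifications)}",
                 f"critical points: {len(self.points)}"]
        for label, c in self.curves.items():
            lines.append(
                f"curve [{label}]: Nc% = {c.a:.4g} * LDM^(-{c.b:.4g})"
                f"  R2={c.r2:.4g}  (n={c.n_points}, {c.fit_method})")
        for pair, cmp_ in self.comparisons.items():
            lines.append(
                f"compare {pair[0]} vs {pair[1]}: p_slope={cmp_.p_slope:.4g} "
                f"p_intercept={cmp_.p_intercept:.4g} -> {cmp_.verdict}")
        for label, r in self.validation.items():
            lines.append(
                f"validation [{label}]: RMSE={r.rmse:.4g} "
                f"n-RMSE={r.n_rmse:.4g}% ({r.stability}, n={r.n})")
        for label, y in self.yield_response.items():
            kind = "max" if y.is_maximum else "MIN (upward parabola)"
            lines.append(
                f"yield response [{label}] at {y.stage}: RY = {y.c0:.4g} + "
                f"{y.c1:.4g} NNI {y.c2:+.4g} NNI^2, R2={y.r2:.4g}, "
                f"vertex ({kind}) NNI={y.nni_opt:.4g}, RY={y.ry_max:.4g}")
        return "\n".join(lines) + "\n"

    def write(self, outdir: Union[str, Path]) -> None:
        """Write all report CSVs (full precision) and the text summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.points_frame().to_csv(outdir / "critical_points.csv", index=False)
        self.curves_frame().to_csv(outdir / "curve.csv", index=False)
        if self.nni is not None:
            self.nni.to_csv(outdir / "nni.csv", index=False)
        if self.validation:
            self.validation_frame().to_csv(
                outdir / "validation.csv", index=False)
        if self.yield_response:
            self.yield_frame().to_csv(
                outdir / "yield_response.csv", index=False)
        if self.comparisons:
            pd.DataFrame([{
                "group_a": a, "group_b": b, "p_slope": c.p_slope,
                "p_intercept": c.p_intercept, "alpha": c.alpha,
                "verdict": c.verdict,
            } for (a, b), c in self.comparisons.items()]).to_csv(
                outdir / "comparison.csv", index=False)
        (outdir / "summary.txt").write_text(self.summary_text(),
                                            encoding="utf-8")


def _load_inputs(inputs) -> ExperimentTable:
    observations, meta = [], []
    for item in inputs:
        table = item if isinstance(item, ExperimentTable) \
            else read_observations(item)
        observations.extend(table.observations)
        meta.append(table.metadata)
    return ExperimentTable(observations, metadata="; ".join(m for m in meta if m))


def _group_label(point: CriticalPoint, pooling: str) -> str:
    if pooling == "per-variety":
        return f"{point.variety}/{point.season}"
    return point.season


def _subset_for_label(table: ExperimentTable, label: str,
                      pooling: str) -> ExperimentTable:
    if pooling == "per-variety":
        variety, season = label.rsplit("/", 1)
        return table.subset(variety=variety, season=season)
    return table.subset(season=label)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow described by ``config``."""
    config.validate()
    table = _load_inputs(config.inputs)
    log.info("loaded %d observations", len(table))

    classifications = classify_table(table, method=config.method,
                                     alpha=config.alpha)
    usable = [c for c in classifications if c.usable]
    log.info("classified %d dates (%d usable, %d skipped)",
             len(classifications), len(usable),
             len(classifications) - len(usable))

    points = [extract_point(c) for c in usable]
    log.info("extracted %d critical points", len(points))

    grouped: Dict[str, List[CriticalPoint]] = {}
    for p in points:
        grouped.setdefault(_group_label(p, config.pooling), []).append(p)

    curves: Dict[str, DilutionCurve] = {}
    for label, pts in grouped.items():
        try:
            curves[label] = fit_curve(pts, method=config.fit_method,
                                      label=label)
            log.info("curve [%s]: a=%.4g b=%.4g r2=%.4g (n=%d)", label,
                     curves[label].a, curves[label].b, curves[label].r2,
                     len(pts))
        except CndcError as exc:
            log.warning("curve fit failed for group %s: %s", label, exc)

    result = PipelineResult(table=table, classifications=classifications,
                            points=points, curves=curves)

    if config.compare and len(grouped) >= 2:
        labels = sorted(grouped)
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                try:
                    result.comparisons[(la, lb)] = compare_curves(
                        grouped[la], grouped[lb], alpha=config.alpha)
                except CndcError as exc:
                    log.warning("comparison %s vs %s failed: %s", la, lb, exc)

    if config.validation_inputs:
        holdout = _load_inputs(config.validation_inputs)
        holdout_points = [
            extract_point(c)
            for c in classify_table(holdout, method=config.method,
                                    alpha=config.alpha) if c.usable]
        log.info("holdout: %d critical points", len(holdout_points))
        for label, curve in curves.items():
            season = label.rsplit("/", 1)[-1]
            pts = [p for p in holdout_points if p.season == season]
            if len(pts) >= 2:
                result.validation[label] = validate_curve(curve, pts)

    nni_frames = []
    for label, curve in curves.items():
        subset = _subset_for_label(table, label, config.pooling)
        records = nni_records(subset, curve, band=config.nni_band,
                              ldm_basis=config.nni_ldm_basis)
        frame = pd.DataFrame([{
            "group": label, "variety": r.variety, "season": r.season,
            "year": r.year, "stage": r.stage, "n_rate": r.n_rate,
            "na": r.na, "nc": r.nc, "nni": r.nni, "status": r.status,
        } for r in records])
        nni_frames.append(frame)
    if nni_frames:
        result.nni = pd.concat(nni_frames, ignore_index=True)

    has_yield = any(o.yield_t_ha is not None for o in table)
    if has_yield and result.nni is not None:
        ry = relative_yield_table(table)
        for label in curves:
            merged = result.nni[result.nni["group"] == label].merge(
                ry, on=["variety", "season", "year", "n_rate"], how="inner")
            best = None
            stages = ([config.yield_stage] if config.yield_stage
                      else sorted(merged["stage"].unique()))
            for stage in stages:
                sub = merged[merged["stage"] == stage]
                if len(sub) < 4 or sub["nni"].nunique() < 3:
                    continue
                try:
                    fit = fit_yield_response(sub["nni"], sub["relative_yield"],
                                             stage=stage)
                except CndcError as exc:
                    log.warning("yield response [%s] at %s failed: %s",
                                label, stage, exc)
                    continue
                if best is None or fit.r2 > best.r2:
                    best = fit
            if best is not None:
                result.yield_response[label] = best
                log.info("yield response [%s]: stage=%s nni_opt=%.4g "
                         "ry_max=%.4g r2=%.4g", label, best.stage,
                         best.nni_opt, best.ry_max, best.r2)

    if config.outdir is not None:
        result.write(config.outdir)
    return result
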