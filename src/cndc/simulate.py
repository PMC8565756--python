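"""Synthetic nitrogen-rate trials with known ground truth.

The generator emulates the statistical structure the dilution-curve
analysis assumes, so the whole pipeline can be tested against known
parameters:

* a true power-law dilution curve ``Nc% = a_true * LDM^(-b_true)``;
* a saturating (Michaelis-type) leaf-biomass response to nitrogen rate,
  so high rates plateau and form a non-limited group;
* N-limited treatments whose mean PNC lies on a locally linear
  sub-critical relation strictly below the curve (so the oblique/vertical
  construction recovers the true critical point exactly in the noiseless
  limit);
* luxury uptake (PNC above the curve) for non-limited treatments;
* independent multiplicative lognormal replicate noise on LDM and PNC;
* grain yield generated from a quadratic relative-yield response to the
  true NNI at a reference stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .model import ExperimentTable, PlotObservation, Season, Stage

#: A treatment is non-limited when its biomass reaches this fraction of
#: the stage's potential LDM.
NON_LIMITED_FRACTION = 0.95

#: Default per-stage potential (non-limited) leaf dry matter, t/ha,
#: shaped like an early-rice season: monotone rise to heading, slight
#: senescence decline at full heading.
DEFAULT_STAGE_POTENTIALS = {
    "TS": 0.9, "JS": 1.5, "BS": 2.2, "HS": 2.6, "FHS": 2.4,
}


@dataclass
class SyntheticConfig:
    """Parameters of one simulated nitrogen-rate trial.

    ``seed`` is required: reproducibility is explicit, not hidden state.
    """

    seed: int
    a_true: float = 3.0
    b_true: float = 0.5
    n_rates: Tuple[float, ...] = (0.0, 25.0, 150.0, 225.0)
    stage_potentials: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_POTENTIALS))
    biomass_halfsat: float = 10.0   # kg/ha closing half the gap to potential
    baseline_frac: float = 0.25     # fraction of potential LDM at zero N
    luxury_margin: float = 1.1      # multiplicative PNC surplus, non-limited
    sub_slope_factor: float = 0.8   # steepness of the sub-critical relation
    noise_cv: float = 0.05          # replicate CV, multiplicative lognormal
    replicates: int = 3
    ry_coeffs: Tuple[float, float, float] = (0.40, 1.10, -0.55)
    max_yield: float = 8.0          # t/ha at the vertex of the RY parabola
    yield_stage: Optional[str] = None  # default: stage of max potential LDM
    variety: str = "synthetic"
    season: str = "early"
    year: int = 2000

    def validate(self) -> None:
        checks = [
            ("a_true", self.a_true > 0, "must be > 0"),
            ("b_true", self.b_true > 0, "must be > 0"),
            ("n_rates", len(self.n_rates) >= 3 and 0 in self.n_rates
             and all(r >= 0 for r in self.n_rates)
             and len(set(self.n_rates)) == len(self.n_rates),
             "needs >= 3 distinct non-negative levels including 0"),
            ("stage_potentials", len(self.stage_potentials) >= 1
             and all(v > 0 for v in self.stage_potentials.values())
             and all(s in Stage.__members__ for s in self.stage_potentials),
             "needs positive potentials keyed by stage codes"),
            ("biomass_halfsat", self.biomass_halfsat > 0, "must be > 0"),
            ("baseline_frac", 0 < self.baseline_frac < 1,
             "must be in (0, 1)"),
            ("luxury_margin", self.luxury_margin >= 1, "must be >= 1"),
            ("sub_slope_factor", self.sub_slope_factor > 0, "must be > 0"),
            ("noise_cv", 0 <= self.noise_cv <= 0.3, "must be in [0, 0.3]"),
            ("replicates", self.replicates >= 2, "must be >= 2"),
            ("ry_coeffs", len(self.ry_coeffs) == 3 and self.ry_coeffs[2] < 0,
             "needs (c0, c1, c2) with c2 < 0"),
            ("max_yield", self.max_yield > 0, "must be > 0"),
            ("yield_stage", self.yield_stage is None
             or self.yield_stage in self.stage_potentials,
             "must be one of the configured stages"),
            ("season", self.season in ("early", "late"),
             "must be 'early' or 'late'"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ValidationError(f"SyntheticConfig.{name} {msg} "
                                      f"(got {getattr(self, name)!r})")


@dataclass
class TruthRecord:
    """Noise-free state of one (stage, rate) treatment."""

    stage: str
    n_rate: float
    ldm: float          # true mean LDM, t/ha
    pnc: float          # true mean PNC, %
    limited: bool
    nni: float          # pnc / (a_true * ldm^-b_true)


@dataclass
class SyntheticTruth:
    """Generating configuration plus per-treatment noise-free state."""

    config: SyntheticConfig
    records: list

    def record(self, stage: str, n_rate: float) -> TruthRecord:
        for r in self.records:
            if r.stage == stage and r.n_rate == n_rate:
                return r
        raise KeyError((stage, n_rate))


def rate_effect(n_rate, halfsat: float, baseline: float):
    """Saturating fraction of potential biomass reached at ``n_rate``.

    ``(baseline * K + r) / (K + r)``: equals ``baseline`` at zero N,
    tends to 1 as the rate grows, and closes half the remaining gap at
    ``r = K`` (the half-saturation rate).
    """
    r = np.asarray(n_rate, dtype=float)
    out = (baseline * halfsat + r) / (halfsat + r)
    return float(out) if np.isscalar(n_rate) else out


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def simulate_experiment(config: SyntheticConfig
                        ) -> Tuple[ExperimentTable, SyntheticTruth]:
    """Draw one replicate-level trial from ``config``.

    Per stage the treatment-mean LDM is the stage potential scaled by the
    saturating rate effect.  Treatments at >= 95% of potential are
    non-limited: their mean PNC is ``luxury_margin`` times the curve at
    their own LDM.  The rest are limited: their mean PNC falls on the
    line through the stage's critical point ``(LDM*, Nc*)`` with positive
    slope ``sub_slope_factor * Nc* / LDM*``, hence strictly below the
    curve.  Replicates multiply the means by independent lognormal noise
    of the configured CV; plot yields follow the quadratic relative-yield
    response evaluated at the true NNI of the yield stage.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a, b = config.a_true, config.b_true
    rates = sorted(config.n_rates)
    stages = [s for s in Stage.__members__ if s in config.stage_potentials]
    yield_stage = config.yield_stage or max(
        stages, key=lambda s: config.stage_potentials[s])

    truth_records = []
    per_stage_means: Dict[str, Dict[float, Tuple[float, float, bool]]] = {}
    for stage in stages:
        pot = config.stage_potentials[stage]
        eff = {r: rate_effect(r, config.biomass_halfsat,
                              config.baseline_frac) for r in rates}
        ldm = {r: pot * eff[r] for r in rates}
        nonlim = [r for r in rates if eff[r] >= NON_LIMITED_FRACTION]
        anchor_ldm = (float(np.mean([ldm[r] for r in nonlim])) if nonlim
                      else ldm[max(rates)])
        nc_star = a * anchor_ldm ** (-b)
        sub_slope = config.sub_slope_factor * nc_star / anchor_ldm
        per_stage_means[stage] = {}
        for r in rates:
            limited = r not in nonlim
            if limited:
                pnc = nc_star + sub_slope * (ldm[r] - anchor_ldm)
            else:
                pnc = config.luxury_margin * a * ldm[r] ** (-b)
            nni = pnc / (a * ldm[r] ** (-b))
            truth_records.append(TruthRecord(
                stage=stage, n_rate=float(r), ldm=float(ldm[r]),
                pnc=float(pnc), limited=limited, nni=float(nni)))
            per_stage_means[stage][r] = (ldm[r], pnc, limited)

    truth = SyntheticTruth(config=config, records=truth_records)

    # Plot yields: one value per (rate, replicate), shared across stages.
    ry_true = {}
    c0, c1, c2 = config.ry_coeffs
    for r in rates:
        nni_y = truth.record(yield_stage, float(r)).nni
        ry_true[r] = max(c0 + c1 * nni_y + c2 * nni_y ** 2, 0.05)
    yield_noise = _lognormal_factors(
        rng, config.noise_cv, len(rates) * config.replicates)
    plot_yield = {}
    k = 0
    for r in rates:
        for rep in range(1, config.replicates + 1):
            plot_yield[(r, rep)] = ry_true[r] * config.max_yield * yield_noise[k]
            k += 1

    observations = []
    for stage in stages:
        for r in rates:
            mean_ldm, mean_pnc, _ = per_stage_means[stage][r]
            f_ldm = _lognormal_factors(rng, config.noise_cv, config.replicates)
            f_pnc = _lognormal_factors(rng, config.noise_cv, config.replicates)
            for rep in range(1, config.replicates + 1):
                observations.append(PlotObservation(
                    variety=config.variety, season=Season(config.season),
                    year=config.year, stage=Stage(stage), n_rate=float(r),
                    replicate=rep,
                    ldm=float(mean_ldm * f_ldm[rep - 1]),
                    pnc=float(mean_pnc * f_pnc[rep - 1]),
                    yield_t_ha=float(plot_yield[(r, rep)]),
                ))
    table = ExperimentTable(
        observations,
        metadata=f"synthetic trial (seed={config.seed})")
    return table, truth


def true_limitation_results(truth: SyntheticTruth) -> list:
    """Oracle classification: the generator's own limitation labels.

    Returns one :class:`~cndc.classify.LimitationResult` per stage built
    from the noise-free treatment means and true limited/non-limited
    status, bypassing any statistical test.  On noiseless data the
    critical point extracted from these labels reproduces the true curve
    exactly.
    """
    from .classify import LIMITED, NON_LIMITED, LimitationResult

    cfg = truth.config
    stages = [s for s in Stage.__members__ if s in cfg.stage_potentials]
    out = []
    for stage in stages:
        recs = [r for r in truth.records if r.stage == stage]
        out.append(LimitationResult(
            variety=cfg.variety, season=cfg.season, year=cfg.year,
            stage=stage,
            labels={r.n_rate: (LIMITED if r.limited else NON_LIMITED)
                    for r in recs},
            ldm_means={r.n_rate: r.ldm for r in recs},
            pnc_means={r.n_rate: r.pnc for r in recs},
            method="truth", alpha=0.0,
        ))
    return out


def write_truth(truth: SyntheticTruth, path) -> None:
    """Emit the ground truth as a plain-text key=value sidecar file."""
    cfg = truth.config
    lines = []
    for name in ("seed", "a_true", "b_true", "biomass_halfsat",
                 "baseline_frac", "luxury_margin", "sub_slope_factor",
                 "noise_cv", "replicates", "max_yield", "variety",
                 "season", "year"):
        lines.append(f"config.{name}={getattr(cfg, name)}")
    lines.append("config.n_rates=" + ",".join(str(r) for r in cfg.n_rates))
    lines.append("config.ry_coeffs=" + ",".join(str(c) for c in cfg.ry_coeffs))
    for s, p in cfg.stage_potentials.items():
        lines.append(f"config.stage_potential.{s}={p}")
    for rec in truth.records:
        key = f"truth.{rec.stage}.N{rec.n_rate:g}"
        lines.append(f"{key}.ldm={rec.ldm!r}")
        lines.append(f"{key}.pnc={rec.pnc!r}")
        lines.append(f"{key}.limited={str(rec.limited).lower()}")
        lines.append(f"{key}.nni={rec.nni!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
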