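"""Core data model for nitrogen-rate field trials.

A trial is a collection of plot-level observations: at each sampling
(growth stage) under each nitrogen rate, leaf dry matter (LDM, t/ha) and
plant nitrogen concentration (PNC, % of dry weight) are measured, either
per replicate plot or as treatment means (published tables report means
with standard errors and post-hoc grouping letters).

Units are fixed throughout the package: LDM and grain yield in t/ha,
PNC in % of dry weight, nitrogen rate in kg N/ha.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .errors import ValidationError


class Season(str, enum.Enum):
    """Cropping season of a double-cropped rice system."""

    EARLY = "early"
    LATE = "late"


class Stage(str, enum.Enum):
    """Ordered phenological sampling stages.

    TS tillering, JS jointing, BS booting, HS heading, FHS full heading.
    """

    TS = "TS"
    JS = "JS"
    BS = "BS"
    HS = "HS"
    FHS = "FHS"

    @property
    def order(self) -> int:
        return list(Stage).index(self)


#: Column order of the canonical CSV observation format.
CSV_COLUMNS = [
    "variety", "season", "year", "stage", "n_rate", "replicate",
    "ldm", "pnc", "yield", "ldm_se", "pnc_se", "sig_letter",
    "pnc_sig_letter",
]

#: Columns that must be present in any observation file.
MANDATORY_COLUMNS = ["variety", "season", "stage", "n_rate", "ldm", "pnc"]


@dataclass
class PlotObservation:
    """One measurement record: a replicate plot or a treatment mean.

    ``replicate`` is ``None`` for mean-level records (published treatment
    means); replicate-level records carry an integer >= 1.  ``sig_letter``
    holds the compact-letter-display group of the LDM mean within its
    sampling date, ``pnc_sig_letter`` the analogous letters for PNC.
    """

    variety: str
    season: Season
    stage: Stage
    n_rate: float
    ldm: float
    pnc: float
    year: Optional[int] = None
    replicate: Optional[int] = None
    yield_t_ha: Optional[float] = None
    ldm_se: Optional[float] = None
    pnc_se: Optional[float] = None
    sig_letter: Optional[str] = None
    pnc_sig_letter: Optional[str] = None

    def __post_init__(self):
        self.season = Season(self.season)
        self.stage = Stage(self.stage)
        problems = self.problems()
        if problems:
            raise ValidationError(
                f"invalid observation: {'; '.join(problems)}", details=problems
            )

    def problems(self) -> list[str]:
        """Return invariant violations as human-readable strings."""
        out = []
        if not (self.ldm > 0):
            out.append(f"ldm must be > 0 (got {self.ldm})")
        if not (self.pnc > 0):
            out.append(f"pnc must be > 0 (got {self.pnc})")
        if not (self.n_rate >= 0):
            out.append(f"n_rate must be >= 0 (got {self.n_rate})")
        if self.replicate is not None and self.replicate < 1:
            out.append(f"replicate must be >= 1 (got {self.replicate})")
        if self.yield_t_ha is not None and not (self.yield_t_ha > 0):
            out.append(f"yield must be > 0 (got {self.yield_t_ha})")
        for name in ("ldm_se", "pnc_se"):
            v = getattr(self, name)
            if v is not None and v < 0:
                out.append(f"{name} must be >= 0 (got {v})")
        return out

    @property
    def group_key(self) -> tuple:
        """(variety, season, year, stage): one sampling date of one variety."""
        return (self.variety, self.season.value, self.year, self.stage.value)


class ExperimentTable:
    """Ordered, validated collection of :class:`PlotObservation`.

    Enforces uniqueness of (variety, season, year, stage, n_rate, replicate)
    and that all sampling dates of one (variety, season, year) were run on
    the same set of nitrogen rates.
    """

    def __init__(self, observations: Iterable[PlotObservation],
                 metadata: str = ""):
        self.observations: list[PlotObservation] = list(observations)
        self.metadata = metadata
        self._validate()

    def _validate(self) -> None:
        seen = {}
        problems = []
        for i, obs in enumerate(self.observations):
            key = obs.group_key + (obs.n_rate, obs.replicate)
            if key in seen:
                problems.append(
                    f"row {i}: duplicate key {key} (first at row {seen[key]})"
                )
            seen[key] = i
        rate_sets: dict[tuple, dict] = {}
        for i, obs in enumerate(self.observations):
            trial = (obs.variety, obs.season.value, obs.year)
            rate_sets.setdefault(trial, {}).setdefault(
                obs.stage, set()).add(obs.n_rate)
        for trial, per_stage in rate_sets.items():
            sets = {frozenset(s) for s in per_stage.values()}
            if len(sets) > 1:
                problems.append(
                    f"trial {trial}: stages disagree on nitrogen-rate levels"
                )
        if problems:
            raise ValidationError(
                f"invalid experiment table ({len(problems)} problem(s))",
                details=problems,
            )

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[PlotObservation]:
        return iter(self.observations)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExperimentTable):
            return NotImplemented
        return self.approx_equal(other, tol=0.0)

    def approx_equal(self, other: "ExperimentTable", tol: float = 1e-9) -> bool:
        """Field-by-field equality with numeric tolerance ``tol``."""
        if len(self) != len(other):
            return False
        for a, b in zip(self.observations, other.observations):
            for f in fields(PlotObservation):
                va, vb = getattr(a, f.name), getattr(b, f.name)
                if isinstance(va, float) and isinstance(vb, float):
                    if not math.isclose(va, vb, rel_tol=0.0, abs_tol=tol):
                        return False
                elif va != vb:
                    return False
        return True

    # -- pandas bridge -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Return the observations as a DataFrame in canonical column order."""
        rows = []
        for o in self.observations:
            rows.append({
                "variety": o.variety,
                "season": o.season.value,
                "year": o.year,
                "stage": o.stage.value,
                "n_rate": o.n_rate,
                "replicate": o.replicate,
                "ldm": o.ldm,
                "pnc": o.pnc,
                "yield": o.yield_t_ha,
                "ldm_se": o.ldm_se,
                "pnc_se": o.pnc_se,
                "sig_letter": o.sig_letter,
                "pnc_sig_letter": o.pnc_sig_letter,
            })
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: str = "") -> "ExperimentTable":
        """Build a validated table from a DataFrame with canonical columns."""
        obs = []
        problems = []
        for i, row in enumerate(frame.to_dict("records")):
            try:
                obs.append(observation_from_record(row))
            except (ValidationError, ValueError) as exc:
                problems.append(f"row {i}: {exc}")
        if problems:
            raise ValidationError(
                f"{len(problems)} invalid row(s)", details=problems
            )
        return cls(obs, metadata=metadata)

    def subset(self, **criteria) -> "ExperimentTable":
        """Observations matching all keyword criteria, e.g. season='early'.

        A criterion value may be a scalar or a collection of admissible
        values.
        """
        def match(obs, name, want):
            have = getattr(obs, "yield_t_ha" if name == "yield" else name)
            if isinstance(have, enum.Enum):
                have = have.value
            if isinstance(want, (list, tuple, set, frozenset)):
                return have in want
            return have == want

        kept = [o for o in self.observations
                if all(match(o, k, v) for k, v in criteria.items())]
        return ExperimentTable(kept, metadata=self.metadata)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _opt_int(value) -> Optional[int]:
    v = _opt_float(value)
    return None if v is None else int(v)


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def observation_from_record(rec: dict) -> PlotObservation:
    """Build one :class:`PlotObservation` from a raw CSV record (dict)."""
    return PlotObservation(
        variety=str(rec["variety"]).strip(),
        season=str(rec["season"]).strip(),
        stage=str(rec["stage"]).strip(),
        n_rate=float(rec["n_rate"]),
        ldm=float(rec["ldm"]),
        pnc=float(rec["pnc"]),
        year=_opt_int(rec.get("year")),
        replicate=_opt_int(rec.get("replicate")),
        yield_t_ha=_opt_float(rec.get("yield")),
        ldm_se=_opt_float(rec.get("ldm_se")),
        pnc_se=_opt_float(rec.get("pnc_se")),
        sig_letter=_opt_str(rec.get("sig_letter")),
        pnc_sig_letter=_opt_str(rec.get("pnc_sig_letter")),
    )
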