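"""Splitting nitrogen treatments into N-limited and non-N-limited groups.

For each sampling date (one variety x stage combination) the treatments
are partitioned by whether their leaf dry matter is significantly below
the maximum observed at that date.  Two routes are provided:

* :func:`classify_anova` for replicate-level data: one-way ANOVA of LDM on
  nitrogen rate followed by Tukey HSD comparisons against the
  maximal-LDM treatment;
* :func:`classify_letters` for published treatment means carrying
  compact-letter-display groupings: a treatment is non-limited iff it
  shares at least one letter with the maximal-LDM treatment.

A date is *usable* for critical-point extraction only if it has at least
two limited and one non-limited treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .model import ExperimentTable

LIMITED = "limited"
NON_LIMITED = "non_limited"


@dataclass
class LimitationResult:
    """Per-date limited/non-limited partition plus the treatment means.

    ``labels`` maps nitrogen rate -> 'limited' | 'non_limited'.
    ``ldm_means``/``pnc_means`` map rate -> treatment mean, on which the
    critical-point construction operates.
    """

    variety: str
    season: str
    year: Optional[int]
    stage: str
    labels: Dict[float, str]
    ldm_means: Dict[float, float]
    pnc_means: Dict[float, float]
    method: str
    alpha: float
    anova_p: Optional[float] = None

    @property
    def usable(self) -> bool:
        n_lim = sum(1 for v in self.labels.values() if v == LIMITED)
        n_non = sum(1 for v in self.labels.values() if v == NON_LIMITED)
        return n_lim >= 2 and n_non >= 1

    @property
    def limited_rates(self) -> list:
        return sorted(r for r, v in self.labels.items() if v == LIMITED)

    @property
    def non_limited_rates(self) -> list:
        return sorted(r for r, v in self.labels.items() if v == NON_LIMITED)

    @property
    def group_key(self) -> tuple:
        return (self.variety, self.season, self.year, self.stage)


def _as_group_frame(observations) -> pd.DataFrame:
    if isinstance(observations, ExperimentTable):
        frame = observations.to_frame()
    elif isinstance(observations, pd.DataFrame):
        frame = observations
    else:
        frame = ExperimentTable(list(observations)).to_frame()
    keys = frame[["variety", "season", "year", "stage"]].drop_duplicates()
    if len(keys) != 1:
        raise ValidationError(
            "classification operates on a single (variety, season, year, "
            f"stage) group; got {len(keys)} distinct keys"
        )
    return frame


def _result_skeleton(frame: pd.DataFrame, method: str, alpha: float):
    means = frame.groupby("n_rate", sort=True).agg(
        ldm=("ldm", "mean"), pnc=("pnc", "mean"))
    first = frame.iloc[0]
    year = first["year"]
    year = None if pd.isna(year) else int(year)
    return means, dict(
        variety=first["variety"], season=first["season"], year=year,
        stage=first["stage"], method=method, alpha=alpha,
        ldm_means=means["ldm"].to_dict(), pnc_means=means["pnc"].to_dict(),
    )


def _top_rates(means: pd.DataFrame) -> list:
    """Rates tied for the maximal mean LDM (exact ties share the top)."""
    top = means["ldm"].max()
    return list(means.index[means["ldm"] == top])


@lru_cache(maxsize=128)
def _tukey_qcrit(alpha: float, k: int, df: int) -> float:
    """Upper-alpha studentized-range quantile for k groups, df error df."""
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def _tukey_lower_than_top(frame: pd.DataFrame, means: pd.DataFrame,
                          top: set, alpha: float) -> set:
    """Rates whose mean LDM is significantly below the top treatment
    by Tukey-Kramer HSD (pooled within-treatment variance)."""
    groups = {float(r): g["ldm"].to_numpy()
              for r, g in frame.groupby("n_rate", sort=True)}
    k = len(groups)
    n_total = sum(g.size for g in groups.values())
    df = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / df
    if mse == 0:  # degenerate noiseless data: any difference is real
        return {r for r in groups
                if r not in top
                and means.loc[r, "ldm"] < means["ldm"].max()}
    qcrit = _tukey_qcrit(alpha, k, df)
    lower = set()
    for r, g in groups.items():
        if r in top:
            continue
        for t in top:
            gt = groups[t]
            se = np.sqrt(mse / 2.0 * (1.0 / g.size + 1.0 / gt.size))
            qstat = (gt.mean() - g.mean()) / se
            if qstat > qcrit:
                lower.add(r)
                break
    return lower


def classify_anova(observations, alpha: float = 0.05) -> LimitationResult:
    """Partition treatments from replicate-level data by ANOVA + Tukey HSD.

    If the global one-way F-test of LDM on nitrogen rate is not
    significant at ``alpha``, every treatment is labelled non-limited and
    the date is unusable.  Otherwise each treatment is compared with the
    maximal-LDM treatment by Tukey HSD; treatments with significantly
    lower mean LDM are limited, all others (including the maximum itself
    and any exact ties) non-limited.

    Raises
    ------
    InsufficientDataError
        With fewer than 3 rate levels, or fewer than 2 replicates in any
        treatment.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    frame = _as_group_frame(observations)
    counts = frame.groupby("n_rate")["ldm"].count()
    if len(counts) < 3:
        raise InsufficientDataError(
            f"need >= 3 nitrogen-rate levels, got {len(counts)}")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise InsufficientDataError(
            f"need >= 2 replicates per treatment; rates {bad} have fewer")

    means, kw = _result_skeleton(frame, "anova_posthoc", alpha)
    groups = [g["ldm"].to_numpy() for _, g in frame.groupby("n_rate", sort=True)]
    import warnings as _warnings
    with _warnings.catch_warnings(), np.errstate(all="ignore"):
        _warnings.simplefilter("ignore")  # noiseless data: F = inf or nan
        f_stat, p_global = stats.f_oneway(*groups)
    # zero within- and between-group variance: no signal at all
    if np.isnan(p_global) and len({g.mean() for g in groups}) > 1:
        p_global = 0.0

    top = set(float(r) for r in _top_rates(means))
    labels = {float(r): NON_LIMITED for r in means.index}
    if np.isfinite(p_global) and p_global < alpha:
        for r in _tukey_lower_than_top(frame, means, top, alpha):
            labels[r] = LIMITED
    return LimitationResult(labels=labels, anova_p=float(p_global), **kw)


def classify_letters(observations) -> LimitationResult:
    """Partition treatments from published means with grouping letters.

    Treatments sharing at least one LDM significance letter with the
    maximal-LDM treatment are non-limited; all others are limited
    (standard compact-letter-display semantics, multi-letter labels such
    as 'ab' belonging to both groups).
    """
    frame = _as_group_frame(observations)
    if frame["replicate"].notna().any():
        raise ValidationError(
            "classify_letters expects mean-level records (no replicate ids)")
    letters = frame.set_index("n_rate")["sig_letter"]
    if letters.isna().any() or (letters.astype(str).str.strip() == "").any():
        raise ValidationError(
            "every observation needs a non-empty sig_letter; "
            "use classify_anova for replicate-level data")

    means, kw = _result_skeleton(frame, "letters", alpha=0.05)
    top_rates = _top_rates(means)
    top_letters = set().union(*(set(letters.loc[r]) for r in top_rates))
    labels = {}
    for r in means.index:
        shared = set(letters.loc[r]) & top_letters
        labels[float(r)] = NON_LIMITED if shared else LIMITED
    for r in top_rates:  # the maximum itself is non-limited by definition
        labels[float(r)] = NON_LIMITED
    return LimitationResult(labels=labels, **kw)


def classify_table(table: ExperimentTable, method: str = "auto",
                   alpha: float = 0.05) -> list:
    """Classify every (variety, season, year, stage) group of a table.

    ``method`` is 'letters', 'anova', or 'auto' (letters for mean-level
    groups, ANOVA for replicate-level ones).  Returns a list of
    :class:`LimitationResult` in table order.
    """
    if method not in ("auto", "letters", "anova"):
        raise ValidationError(f"unknown classification method {method!r}")
    frame = table.to_frame()
    results = []
    for _, group in frame.groupby(["variety", "season", "year", "stage"],
                                  dropna=False, sort=False):
        use = method
        if use == "auto":
            use = "anova" if group["replicate"].notna().any() else "letters"
        if use == "anova":
            results.append(classify_anova(group, alpha=alpha))
        else:
            results.append(classify_letters(group))
    return results
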