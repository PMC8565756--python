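"""Reading and writing the delimited observation format.

The canonical format is comma-separated UTF-8 text with a mandatory header
row, ``.`` as decimal separator and empty fields for missing values::

    variety,season,year,stage,n_rate,replicate,ldm,pnc,yield,ldm_se,pnc_se,sig_letter,pnc_sig_letter

``year``, ``replicate``, ``yield``, the standard errors and the letter
columns are optional; a file may omit them entirely.  The packaged fixture
(:func:`load_table2_fixture`) transcribes the published treatment-mean
table of the Jiangxi double-cropped rice nitrogen-rate trial: 2 seasons x
2 varieties x 5 stages x 4 nitrogen rates of LDM and PNC means with
standard errors and P<0.05 grouping letters.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .errors import FormatError, ValidationError
from .model import CSV_COLUMNS, MANDATORY_COLUMNS, ExperimentTable

PathLike = Union[str, Path]

_FIXTURE_NAME = "table2_means.csv"


def read_observations(path: PathLike, *, dialect: Optional[dict] = None,
                      metadata: str = "") -> ExperimentTable:
    """Read a validated :class:`~cndc.model.ExperimentTable` from CSV.

    Parameters
    ----------
    path
        CSV file with a header row naming at least the mandatory columns
        (variety, season, stage, n_rate, ldm, pnc).
    dialect
        Extra keyword arguments forwarded to :func:`pandas.read_csv`
        (e.g. ``{"sep": ";"}``).

    Raises
    ------
    FormatError
        If a mandatory column is missing from the header.
    ValidationError
        If any row violates an observation invariant; the error lists
        row-indexed diagnostics.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"sig_letter": "string",
                                     "pnc_sig_letter": "string",
                                     "variety": "string"},
                        **(dialect or {}))
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    for col in CSV_COLUMNS:
        if col not in frame.columns:
            frame[col] = None
    try:
        return ExperimentTable.from_frame(frame[CSV_COLUMNS],
                                          metadata=metadata or str(path))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}", details=exc.details) from None


def write_observations(table: ExperimentTable, path: PathLike) -> None:
    """Write a table to CSV so that reading it back reproduces the table.

    Missing values are written as empty fields; floats use shortest
    round-tripping repr, so write->read is the identity up to text
    round-trip.
    """
    frame = table.to_frame()
    # Integer-valued optional columns must not acquire a trailing '.0'.
    for col in ("year", "replicate"):
        frame[col] = frame[col].map(
            lambda v: "" if pd.isna(v) else str(int(v)))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, na_rep="")


def load_table2_fixture() -> ExperimentTable:
    """Load the packaged treatment-mean fixture (80 mean-level rows).

    Early-rice nitrogen rates are {0, 75, 150, 225} kg/ha and late-rice
    rates {0, 90, 180, 270} kg/ha.  The source table does not state a
    trial year, so ``year`` is missing on every row.
    """
    ref = resources.files("cndc").joinpath("data", _FIXTURE_NAME)
    with resources.as_file(ref) as p:
        return read_observations(p, metadata="packaged treatment-mean fixture")
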