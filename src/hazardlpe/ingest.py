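"""Reading, validation, and merging of trial and rating tables.

Input files are delimited text (comma by default, tab accepted), UTF-8, with
a header row.  Canonical schemas:

* trials:  participant_id, experiment_id, prevalence_condition,
  session_order (optional), movie_id, hazard_present, response_yes
* ratings: rater_id, movie_id, rating

Deposited exports with different column names are handled through a
``column_map`` from canonical names to the file's names.  Every reader
returns the parsed table together with a :class:`LoadReport` recording how
many rows were read, kept, and dropped (with per-row reasons).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, MergeError, SchemaError

__all__ = [
    "LoadReport",
    "read_trials",
    "read_ratings",
    "compute_median_ratings",
    "merge_trials_ratings",
    "write_merged",
]

TRIALS_COLUMNS = (
    "participant_id",
    "experiment_id",
    "prevalence_condition",
    "session_order",
    "movie_id",
    "hazard_present",
    "response_yes",
)
RATINGS_COLUMNS = ("rater_id", "movie_id", "rating")

_TRUE = {"true", "t", "1", "yes", "y", "present", "hazard"}
_FALSE = {"false", "f", "0", "no", "n", "absent", "nohazard", "no hazard"}


@dataclass
class LoadReport:
    """Record of a file load: counts plus per-row drop reasons."""

    path: str
    n_read: int = 0
    n_kept: int = 0
    dropped: list = field(default_factory=list)

    def add_drop(self, row: int, reason: str) -> None:
        self.dropped.append({"row": int(row), "reason": reason})

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def to_json(self) -> str:
        return json.dumps(
            {
                "path": self.path,
                "n_read": self.n_read,
                "n_kept": self.n_kept,
                "n_dropped": self.n_dropped,
                "dropped": self.dropped,
            },
            indent=2,
        )


def _read_delimited(path, delimiter):
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if delimiter is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                       na_values=[""], encoding="utf-8")


def _apply_column_map(raw, columns, column_map, path, required):
    column_map = dict(column_map or {})
    rename = {}
    for canonical in columns:
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in required:
            raise SchemaError(
                f"{path}: required column {canonical!r} (mapped from "
                f"{source!r}) not found; available columns: "
                f"{list(raw.columns)}"
            )
    return raw.rename(columns=rename)


def _parse_bool(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    out = pd.Series(pd.NA, index=series.index, dtype="boolean")
    out[s.isin(_TRUE)] = True
    out[s.isin(_FALSE)] = False
    out[series.isna()] = pd.NA
    return out


def read_trials(path, column_map=None, delimiter=None):
    """Read a trial-level detection table.

    Returns ``(frame, report)``.  Rows with a missing or unparseable
    prevalence condition, ground-truth label, or response are dropped and
    listed in the report.  Fully duplicated rows are kept with a warning.
    """
    raw = _read_delimited(path, delimiter)
    required = set(TRIALS_COLUMNS) - {"session_order"}
    df = _apply_column_map(raw, TRIALS_COLUMNS, column_map, path, required)
    report = LoadReport(path=str(path), n_read=len(df))

    keep = pd.Series(True, index=df.index)
    reasons = {}

    for col in ("participant_id", "experiment_id", "movie_id"):
        df[col] = df[col].astype(str).str.strip()
        bad = df[col].isin(["", "nan"])
        for i in df.index[bad & keep]:
            reasons[i] = f"missing {col}"
        keep &= ~bad

    cond = df["prevalence_condition"].astype(str).str.strip().str.lower()
    cond_ok = cond.isin(["high", "low"])
    for i in df.index[~cond_ok & keep]:
        reasons[i] = f"unparseable prevalence_condition {df.loc[i, 'prevalence_condition']!r}"
    keep &= cond_ok
    df["prevalence_condition"] = cond

    for col in ("hazard_present", "response_yes"):
        parsed = _parse_bool(df[col])
        bad = parsed.isna()
        for i in df.index[bad & keep]:
            reasons[i] = f"missing or unparseable {col}"
        keep &= ~bad
        df[col] = parsed

    if "session_order" in df.columns:
        so = df["session_order"].astype(str).str.strip().str.lower()
        df["session_order"] = so.where(so.isin(["first", "second"]), other=pd.NA)
    else:
        df["session_order"] = pd.NA

    for i, reason in sorted(reasons.items()):
        report.add_drop(i, reason)
    out = df.loc[keep, list(TRIALS_COLUMNS)].reset_index(drop=True)
    out["hazard_present"] = out["hazard_present"].astype(bool)
    out["response_yes"] = out["response_yes"].astype(bool)
    report.n_kept = len(out)

    if out.duplicated().any():
        warnings.warn(
            f"{path}: {int(out.duplicated().sum())} fully duplicated trial rows kept",
            stacklevel=2,
        )
    return out, report


def read_ratings(path, column_map=None, delimiter=None):
    """Read a per-rater per-movie hazardousness rating table.

    Returns ``(frame, report)``.  Ratings outside [0, 1] or unparseable are
    dropped and reported.
    """
    raw = _read_delimited(path, delimiter)
    df = _apply_column_map(raw, RATINGS_COLUMNS, column_map, path,
                           set(RATINGS_COLUMNS))
    report = LoadReport(path=str(path), n_read=len(df))

    keep = pd.Series(True, index=df.index)
    reasons = {}
    for col in ("rater_id", "movie_id"):
        df[col] = df[col].astype(str).str.strip()
        bad = df[col].isin(["", "nan"])
        for i in df.index[bad & keep]:
            reasons[i] = f"missing {col}"
        keep &= ~bad

    rating = pd.to_numeric(df["rating"], errors="coerce")
    bad = rating.isna()
    for i in df.index[bad & keep]:
        reasons[i] = f"unparseable rating {df.loc[i, 'rating']!r}"
    keep &= ~bad
    out_of_range = (rating < 0) | (rating > 1)
    for i in df.index[out_of_range & keep]:
        reasons[i] = f"rating {rating[i]} outside [0, 1]"
    keep &= ~out_of_range.fillna(False)
    df["rating"] = rating

    for i, reason in sorted(reasons.items()):
        report.add_drop(i, reason)
    out = df.loc[keep, list(RATINGS_COLUMNS)].reset_index(drop=True)
    report.n_kept = len(out)
    return out, report


def compute_median_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-movie median of the panel's ratings.

    For an even panel the median is the mean of the two middle order
    statistics (the ordinary sample median).  Movies whose ratings are all
    missing are reported via a warning and excluded.
    """
    if len(ratings) == 0:
        raise InputError("empty rating table")
    df = ratings.dropna(subset=["rating"])
    empty = set(ratings["movie_id"]) - set(df["movie_id"])
    if empty:
        warnings.warn(
            f"{len(empty)} movies have no usable ratings and were excluded",
            stacklevel=2,
        )
    g = df.groupby("movie_id", sort=True)["rating"]
    out = g.agg(median_rating="median", n_ratings="count").reset_index()
    return out


def merge_trials_ratings(trials: pd.DataFrame, medians: pd.DataFrame):
    """Inner-join trials with per-movie median ratings.

    Returns ``(merged, report)`` where the report records rows in/out and the
    movie ids of dropped trial rows.  Raises :class:`MergeError` when no
    movie id overlaps (likely an ID-format mismatch between the two files).
    """
    if len(trials) == 0 or len(medians) == 0:
        raise InputError("trials and medians must both be non-empty")
    cols = ["movie_id", "median_rating"]
    merged = trials.merge(medians[cols], on="movie_id", how="inner")
    if len(merged) == 0:
        raise MergeError(
            "no overlapping movie_ids between trials and ratings; check for "
            "an ID-format mismatch (case, whitespace, prefixes)"
        )
    dropped_ids = sorted(set(trials["movie_id"]) - set(medians["movie_id"]))
    report = {
        "rows_in": int(len(trials)),
        "rows_out": int(len(merged)),
        "rows_dropped": int(len(trials) - len(merged)),
        "dropped_movie_ids": dropped_ids,
    }
    return merged.reset_index(drop=True), report


def expand_aggregated_trials(
    frame: pd.DataFrame,
    n_trials_col: str = "n_trials",
    n_yes_col: str = "n_yes",
) -> pd.DataFrame:
    """Expand a per-movie aggregated table into trial-level records.

    Some exports tabulate, per participant x movie x condition, the number
    of trials and the number of "hazard present" responses instead of one
    row per trial.  This expands each such row into ``n_trials`` trial
    records (``n_yes`` of them with ``response_yes=True``); the trial-level
    schema remains the canonical analysis input.
    """
    for col in (n_trials_col, n_yes_col):
        if col not in frame.columns:
            raise SchemaError(f"aggregated table lacks column {col!r}")
    n = frame[n_trials_col].astype(int)
    k = frame[n_yes_col].astype(int)
    if (k > n).any() or (k < 0).any():
        raise InputError("need n_trials >= n_yes >= 0 in every row")
    base = frame.drop(columns=[n_trials_col, n_yes_col])
    out = base.loc[base.index.repeat(n)].reset_index(drop=True)
    out["response_yes"] = np.concatenate(
        [np.arange(ni) < ki for ni, ki in zip(n, k)]
    ) if len(frame) else np.array([], dtype=bool)
    return out


def write_merged(merged: pd.DataFrame, path) -> Path:
    """Write a merged analysis table as comma-delimited text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    merged.to_csv(path, index=False)
    return path
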