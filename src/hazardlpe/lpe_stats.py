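"""Quartile assignment, miss-rate LPE statistics, and permutation tests.

The low prevalence effect (LPE) on misses is quantified per participant as
``miss_rate_low - miss_rate_high`` (a miss is a hazard-present trial answered
"no hazard"); the reported statistic is the mean of these within-participant
differences over participants with both cells defined.  Hazard-present
movies are split into quartiles of median hazardousness (Q1 least, Q4 most
hazardous) to ask whether highly dangerous hazards escape the effect.

Two within-participant permutation schemes build null distributions:

* condition swap — each iteration exchanges a participant's two prevalence
  labels with probability 1/2, preserving the within-subject pairing; used
  for both threshold-shift and miss-rate statistics;
* quartile shuffle — each iteration permutes the quartile labels across a
  participant's hazard-present movies (movies carry their trials with them),
  preserving per-quartile movie counts; used to compare quartiles' LPEs.

p-values use the ``(count + 1) / (B + 1)`` convention and are two-sided
(``|null| >= |observed|``) by default, so no reported p is ever exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "QuartileMap",
    "PermutationResult",
    "BonferroniResult",
    "assign_quartiles",
    "attach_quartiles",
    "miss_rates",
    "lpe_miss",
    "proportional_lpe",
    "permute_condition_swap",
    "permute_quartile_shuffle",
    "bonferroni",
    "build_miss_rate_pairs",
    "mean_paired_difference",
    "build_quartile_shuffle_data",
]

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


# ---------------------------------------------------------------------------
# quartiles


@dataclass(frozen=True)
class QuartileMap:
    """Movie -> quartile assignment over hazard-present movies.

    ``cut_points`` are the 25/50/75% empirical quantiles (linear
    interpolation) of the median ratings; a movie whose median equals a cut
    point goes to the lower quartile.  Q1 is the least hazardous quartile.
    """

    mapping: pd.Series  # index movie_id, values "Q1".."Q4"
    cut_points: tuple

    def counts(self) -> pd.Series:
        return self.mapping.value_counts().reindex(QUARTILES, fill_value=0)


def assign_quartiles(medians) -> QuartileMap:
    """Split hazard-present movies into hazardousness quartiles.

    ``medians`` is a DataFrame with movie_id / median_rating columns (or a
    Series indexed by movie_id), restricted to hazard-present movies.
    """
    if isinstance(medians, pd.DataFrame):
        s = medians.set_index("movie_id")["median_rating"]
    else:
        s = pd.Series(medians)
    if len(s) < 4:
        raise InputError("need at least 4 hazard-present movies with medians")
    vals = s.to_numpy(dtype=float)
    cuts = np.quantile(vals, [0.25, 0.50, 0.75])  # linear interpolation
    idx = (vals > cuts[0]).astype(int) + (vals > cuts[1]) + (vals > cuts[2])
    labels = pd.Series(
        pd.Categorical.from_codes(idx, categories=list(QUARTILES)),
        index=s.index,
        name="quartile",
    ).astype(str)
    return QuartileMap(mapping=labels, cut_points=tuple(float(c) for c in cuts))


def attach_quartiles(merged: pd.DataFrame, qmap: QuartileMap) -> pd.DataFrame:
    """Add a ``quartile`` column: the movie's quartile for hazard-present
    rows, ``"none"`` for hazard-absent rows."""
    out = merged.copy()
    q = out["movie_id"].map(qmap.mapping)
    out["quartile"] = np.where(out["hazard_present"], q, "none")
    missing = out["hazard_present"] & pd.isna(out["quartile"])
    if missing.any():
        raise InputError(
            f"{int(missing.sum())} hazard-present rows reference movies "
            "absent from the quartile map"
        )
    return out


# ---------------------------------------------------------------------------
# miss rates and LPE statistics


def miss_rates(table: pd.DataFrame, by_quartile: bool = False) -> pd.DataFrame:
    """Per-participant miss-rate cells, overall or per hazard quartile.

    A miss is a hazard-present trial with ``response_yes == False``.  Every
    participant x condition (x quartile) cell is emitted; cells with zero
    hazard trials carry ``miss_rate = NaN`` (undefined, never 0).
    """
    hp = table[table["hazard_present"]]
    if len(hp) == 0:
        raise InputError("table contains no hazard-present trials")
    keys = ["participant_id", "experiment_id", "prevalence_condition"]
    if by_quartile:
        if "quartile" not in hp.columns:
            raise InputError("by_quartile=True requires a 'quartile' column")
        keys = keys + ["quartile"]
    g = hp.groupby(keys, sort=True, observed=True)["response_yes"]
    cells = g.agg(
        n_hazard_trials="count", n_misses=lambda s: int((~s).sum())
    ).reset_index()

    # complete the grid so empty cells appear as undefined
    participants = table[["participant_id", "experiment_id"]].drop_duplicates()
    conds = pd.DataFrame({"prevalence_condition": ["high", "low"]})
    grid = participants.merge(conds, how="cross")
    if by_quartile:
        grid = grid.merge(pd.DataFrame({"quartile": list(QUARTILES)}), how="cross")
    else:
        cells["quartile"] = "overall"
        grid["quartile"] = "overall"
    cells = grid.merge(cells, on=list(grid.columns), how="left")
    cells["n_hazard_trials"] = cells["n_hazard_trials"].fillna(0).astype(int)
    cells["n_misses"] = cells["n_misses"].fillna(0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        cells["miss_rate"] = np.where(
            cells["n_hazard_trials"] > 0,
            cells["n_misses"] / cells["n_hazard_trials"],
            np.nan,
        )
    return cells


def _paired_rates(cells: pd.DataFrame) -> pd.DataFrame:
    wide = cells.pivot_table(
        index=["participant_id", "experiment_id", "quartile"],
        columns="prevalence_condition",
        values="miss_rate",
        aggfunc="first",
        observed=True,
    ).reset_index()
    for cond in ("high", "low"):
        if cond not in wide.columns:
            wide[cond] = np.nan
    return wide


@dataclass
class MissLpeResult:
    """Mean within-participant (low - high) miss-rate difference."""

    values: dict  # quartile (or "overall") -> LPE, NaN when undefined
    n_used: dict
    excluded: dict  # quartile -> list of participant ids lacking a cell


def lpe_miss(cells: pd.DataFrame, level: str = "overall") -> MissLpeResult:
    """Miss-rate LPE: mean over participants of (miss_low - miss_high).

    ``level`` is ``"overall"`` or ``"per_quartile"``.  Participants lacking a
    defined cell in either condition are excluded pairwise and listed in the
    result's coverage report.  More positive values mean more misses under
    low prevalence (the LPE direction).
    """
    wide = _paired_rates(cells)
    groups = ["overall"] if level == "overall" else list(QUARTILES)
    values, n_used, excluded = {}, {}, {}
    for q in groups:
        sub = wide[wide["quartile"] == q]
        ok = sub["high"].notna() & sub["low"].notna()
        values[q] = float((sub.loc[ok, "low"] - sub.loc[ok, "high"]).mean()) \
            if ok.any() else np.nan
        n_used[q] = int(ok.sum())
        excluded[q] = sorted(sub.loc[~ok, "participant_id"].tolist())
    if all(n == 0 for n in n_used.values()):
        raise InputError("no participant has defined cells in both conditions")
    return MissLpeResult(values=values, n_used=n_used, excluded=excluded)


@dataclass
class ProportionalLpeResult:
    """Ratio of mean miss rates, low over high prevalence."""

    ratios: dict  # quartile -> ratio (NaN when the denominator is 0)
    mean_low: dict
    mean_high: dict
    undefined: dict  # quartile -> bool (zero denominator)


def proportional_lpe(cells: pd.DataFrame, level: str = "per_quartile") -> ProportionalLpeResult:
    """Proportional LPE: mean miss rate under low over mean under high.

    Means are over participants with both cells defined (the same pairwise
    exclusion as :func:`lpe_miss`).  A zero denominator flags the ratio
    undefined rather than producing infinity.
    """
    wide = _paired_rates(cells)
    groups = ["overall"] if level == "overall" else list(QUARTILES)
    ratios, mean_low, mean_high, undefined = {}, {}, {}, {}
    for q in groups:
        sub = wide[wide["quartile"] == q]
        ok = sub["high"].notna() & sub["low"].notna()
        lo = float(sub.loc[ok, "low"].mean()) if ok.any() else np.nan
        hi = float(sub.loc[ok, "high"].mean()) if ok.any() else np.nan
        mean_low[q], mean_high[q] = lo, hi
        if not ok.any() or not np.isfinite(hi) or hi == 0.0:
            ratios[q] = np.nan
            undefined[q] = True
        else:
            ratios[q] = lo / hi
            undefined[q] = False
    return ProportionalLpeResult(ratios=ratios, mean_low=mean_low,
                                 mean_high=mean_high, undefined=undefined)


# ---------------------------------------------------------------------------
# permutation engines


@dataclass
class PermutationResult:
    observed: float
    null_distribution: np.ndarray
    p_value: float
    B: int
    seed: int
    scheme: str
    alternative: str = "two-sided"
    n_participants: int = 0
    excluded: list = field(default_factory=list)
    n_null_invalid: int = 0

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
            "scheme": self.scheme,
            "alternative": self.alternative,
            "n_participants": self.n_participants,
            "excluded": list(self.excluded),
            "n_null_invalid": self.n_null_invalid,
        }


def _p_value(observed, null, alternative):
    null = np.asarray(null, dtype=float)
    valid = np.isfinite(null)
    nv = null[valid]
    if alternative == "two-sided":
        count = int(np.sum(np.abs(nv) >= abs(observed)))
    elif alternative == "greater":
        count = int(np.sum(nv >= observed))
    elif alternative == "less":
        count = int(np.sum(nv <= observed))
    else:
        raise InputError(f"unknown alternative {alternative!r}")
    return (count + 1) / (nv.size + 1), int(null.size - nv.size)


def permute_condition_swap(
    pairs: Mapping,
    statistic: Callable[[Mapping], float],
    B: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Within-participant condition-swap permutation test.

    ``pairs`` maps participant id to a ``(high, low)`` tuple of arbitrary
    per-condition structures; ``statistic`` maps such a mapping to a number.
    Each iteration independently exchanges each participant's two condition
    labels with probability 1/2 and recomputes the statistic; participants
    with a missing condition (``None``) are excluded with a warning.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    usable, excluded = {}, []
    for pid, (high, low) in pairs.items():
        if high is None or low is None:
            excluded.append(pid)
        else:
            usable[pid] = (high, low)
    if excluded:
        warnings.warn(
            f"{len(excluded)} participants lack a condition and were excluded",
            stacklevel=2,
        )
    if not usable:
        raise InputError("every participant lacks one of the two conditions")

    observed = float(statistic(usable))
    pids = list(usable)
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        flips = rng.random(len(pids)) < 0.5
        relabeled = {
            pid: (usable[pid][1], usable[pid][0]) if f else usable[pid]
            for pid, f in zip(pids, flips)
        }
        null[b] = statistic(relabeled)
    p, n_invalid = _p_value(observed, null, alternative)
    return PermutationResult(
        observed=observed, null_distribution=null, p_value=p, B=B,
        seed=seed, scheme="condition_swap", alternative=alternative,
        n_participants=len(pids), excluded=sorted(map(str, excluded)),
        n_null_invalid=n_invalid,
    )


# -- ready-made statistics for the condition-swap engine --------------------


def build_miss_rate_pairs(cells: pd.DataFrame, quartile: str = "overall"):
    """Per-participant (high, low) miss-rate pairs for one quartile level.

    Undefined cells become ``None`` so the engine excludes the participant.
    """
    sub = cells[cells["quartile"] == quartile]
    wide = _paired_rates(sub)
    pairs = {}
    for _, row in wide.iterrows():
        hi = None if pd.isna(row["high"]) else float(row["high"])
        lo = None if pd.isna(row["low"]) else float(row["low"])
        pairs[row["participant_id"]] = (hi, lo)
    return pairs


def mean_paired_difference(pairs: Mapping) -> float:
    """Mean over participants of (low - high); the miss-rate LPE statistic."""
    diffs = [low - high for high, low in pairs.values()]
    return float(np.mean(diffs))


# -- quartile shuffle --------------------------------------------------------


def build_quartile_shuffle_data(table_exp: pd.DataFrame):
    """Per-participant movie-level ingredients for quartile-label shuffles.

    For each participant, the hazard-present movies they saw with each
    movie's quartile label and its (trials, misses) tallies in the two
    prevalence conditions.  Returns a dict participant_id -> dict of arrays
    ``quartile`` (int codes 0..3), ``n_high``, ``miss_high``, ``n_low``,
    ``miss_low``.
    """
    hp = table_exp[table_exp["hazard_present"]]
    if "quartile" not in hp.columns:
        raise InputError("quartile column required; call attach_quartiles first")
    data = {}
    qcode = {q: i for i, q in enumerate(QUARTILES)}
    for pid, sub in hp.groupby("participant_id", sort=True):
        per_movie = sub.groupby("movie_id", sort=True).agg(
            quartile=("quartile", "first"),
            n_high=("prevalence_condition", lambda s: int((s == "high").sum())),
            n_low=("prevalence_condition", lambda s: int((s == "low").sum())),
        )
        miss = sub.assign(miss=~sub["response_yes"]).groupby(
            ["movie_id", "prevalence_condition"], sort=True
        )["miss"].sum().unstack(fill_value=0)
        per_movie["miss_high"] = miss["high"] if "high" in miss else 0
        per_movie["miss_low"] = miss["low"] if "low" in miss else 0
        per_movie = per_movie.fillna(0)
        data[pid] = {
            "quartile": np.array([qcode[q] for q in per_movie["quartile"]]),
            "n_high": per_movie["n_high"].to_numpy(dtype=float),
            "miss_high": per_movie["miss_high"].to_numpy(dtype=float),
            "n_low": per_movie["n_low"].to_numpy(dtype=float),
            "miss_low": per_movie["miss_low"].to_numpy(dtype=float),
        }
    return data


def _quartile_lpes(data, labels_by_pid) -> np.ndarray:
    """Per-quartile LPE (mean over participants of low-high miss-rate
    differences), with pairwise exclusion of undefined cells."""
    diffs = np.full((len(data), 4), np.nan)
    for i, (pid, d) in enumerate(data.items()):
        labels = labels_by_pid[pid]
        for q in range(4):
            m = labels == q
            nh, nl = d["n_high"][m].sum(), d["n_low"][m].sum()
            if nh > 0 and nl > 0:
                diffs[i, q] = (d["miss_low"][m].sum() / nl
                               - d["miss_high"][m].sum() / nh)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(diffs, axis=0)


def permute_quartile_shuffle(
    data: Mapping,
    focal_quartile: str = "Q4",
    B: int = 1000,
    seed: int = 0,
    comparison: str | None = None,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Within-participant quartile-label shuffle permutation test.

    ``data`` comes from :func:`build_quartile_shuffle_data`.  The statistic
    is the focal quartile's miss-rate LPE, or — when ``comparison`` names a
    second quartile — the difference ``LPE(focal) - LPE(comparison)``.  Each
    iteration permutes quartile labels across each participant's
    hazard-present movies (independently per participant, preserving
    per-quartile movie counts) and recomputes the statistic; the same
    pairwise exclusion of undefined cells applies inside every iteration.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    if not data:
        raise InputError("no participants with quartile-labeled hazard trials")
    qidx = {q: i for i, q in enumerate(QUARTILES)}
    if focal_quartile not in qidx or (comparison is not None and comparison not in qidx):
        raise InputError("quartile names must be Q1..Q4")
    fi = qidx[focal_quartile]
    ci = qidx[comparison] if comparison is not None else None

    def stat(labels_by_pid):
        lpes = _quartile_lpes(data, labels_by_pid)
        v = lpes[fi]
        if ci is not None:
            v = v - lpes[ci]
        return v

    base_labels = {pid: d["quartile"] for pid, d in data.items()}
    observed = float(stat(base_labels))
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        shuffled = {
            pid: labels[rng.permutation(labels.size)]
            for pid, labels in base_labels.items()
        }
        null[b] = stat(shuffled)
    p, n_invalid = _p_value(observed, null, alternative)
    scheme = "quartile_shuffle"
    return PermutationResult(
        observed=observed, null_distribution=null, p_value=p, B=B,
        seed=seed, scheme=scheme, alternative=alternative,
        n_participants=len(data), n_null_invalid=n_invalid,
    )


# ---------------------------------------------------------------------------
# multiple comparisons


@dataclass
class BonferroniResult:
    alpha: float
    m: int
    critical_alpha: float
    decisions: dict  # name -> significant after correction


def bonferroni(p_values: Mapping, alpha: float = 0.05) -> BonferroniResult:
    """Bonferroni familywise control: compare each p to alpha / m."""
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")
    if len(p_values) == 0:
        raise InputError("empty p-value collection")
    m = len(p_values)
    crit = alpha / m
    decisions = {name: bool(p <= crit) for name, p in p_values.items()}
    return BonferroniResult(alpha=alpha, m=m, critical_alpha=crit,
                            decisions=decisions)
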