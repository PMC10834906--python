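"""Synthetic road-hazard detection studies with a known signal-detection observer.

This module generates everything the analysis pipeline consumes, with ground
truth known by construction:

* a stimulus set of "movies", each carrying a latent hazardousness value in
  [0, 1] and a hazard-present/absent label (the real stimulus set has 1376
  clips, 432 of them hazard-present);
* a panel of raters who score every movie on the [0, 1] hazardousness scale
  (48 raters in the real panel), from which per-movie medians are derived;
* simulated detection experiments in which each participant completes one
  high-prevalence and one low-prevalence session and responds according to a
  logistic (criterion-shift) observer model.

The observer responds "hazard present" with probability

    p_yes = lapse/2 + (1 - lapse) * logistic(slope * median - criterion)

where ``criterion = criterion_high`` in the high-prevalence session and
``criterion_high + criterion_shift`` in the low-prevalence session.  A
positive ``criterion_shift`` is the conservative criterion shift that produces
a low prevalence effect (LPE); ``criterion_shift = 0`` is the null generator.
The emitted response is inverted with probability ``motor_error_rate``
(a motor slip, independent of the stimulus).

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import CapacityError, InputError, ParameterError

__all__ = [
    "StimulusSet",
    "ObserverParams",
    "ExperimentDesign",
    "EXPERIMENT_DESIGNS",
    "OBSERVER_PRESETS",
    "RESPONSE_CORRECTION_FACTOR",
    "generate_stimulus_set",
    "generate_ratings",
    "simulate_experiment",
    "simulate_study",
    "write_study",
]

FEEDBACK_MODES = ("full", "none", "partial", "response_correction")

#: Multiplier applied to the motor error rate when the design lets
#: participants correct their responses before feedback.
RESPONSE_CORRECTION_FACTOR = 0.25


# ---------------------------------------------------------------------------
# distribution parameter handling


def _as_distribution(params):
    """Turn a distribution description into a frozen scipy distribution.

    Accepts a frozen scipy.stats distribution, a tuple like ``("beta", 5, 2)``,
    ``("uniform", lo, hi)``, ``("point", v)``, or a mapping with a ``name``
    key.  The support must lie within [0, 1].
    """
    if hasattr(params, "rvs") and hasattr(params, "support"):
        dist = params
    else:
        if isinstance(params, Mapping):
            name = params["name"]
            args = [v for k, v in params.items() if k != "name"]
        else:
            name, *args = params
        name = str(name).lower()
        if name == "beta":
            dist = stats.beta(*args)
        elif name == "uniform":
            lo, hi = args
            dist = stats.uniform(loc=lo, scale=hi - lo)
        elif name == "point":
            (v,) = args
            dist = stats.uniform(loc=v, scale=0.0)
        else:
            raise ParameterError(f"unknown distribution name {name!r}")
    lo, hi = dist.support()
    if lo < -1e-12 or hi > 1 + 1e-12:
        raise ParameterError(
            f"distribution support [{lo}, {hi}] extends outside [0, 1]"
        )
    return dist


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class StimulusSet:
    """A set of movies with ground-truth labels and latent hazardousness.

    ``frame`` has columns ``movie_id`` (unique string), ``hazard_present``
    (bool) and ``latent_hazardousness`` (float in [0, 1]).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        if f["movie_id"].duplicated().any():
            raise ParameterError("movie_ids must be unique")
        lat = f["latent_hazardousness"].to_numpy()
        if (lat < 0).any() or (lat > 1).any():
            raise ParameterError("latent_hazardousness must lie in [0, 1]")

    @property
    def n_present(self) -> int:
        return int(self.frame["hazard_present"].sum())

    @property
    def n_absent(self) -> int:
        return int((~self.frame["hazard_present"]).sum())

    @property
    def present_ids(self) -> np.ndarray:
        return self.frame.loc[self.frame["hazard_present"], "movie_id"].to_numpy()

    @property
    def absent_ids(self) -> np.ndarray:
        return self.frame.loc[~self.frame["hazard_present"], "movie_id"].to_numpy()


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the logistic criterion-shift observer.

    slope
        Sensitivity in logit units per unit of median hazardousness rating.
        Default 8.7 (0.87 logit per 0.1 rating).
    criterion_high
        Logit criterion under high prevalence; the high-prevalence 50%
        threshold sits at ``criterion_high / slope`` on the rating scale.
    criterion_shift
        Conservative criterion increment applied in the low-prevalence
        session; >= 0.  Zero gives the null (no-LPE) observer.
    lapse_rate
        Stimulus-independent lapse probability in [0, 0.2]; lapses respond
        "yes" half the time.
    motor_error_rate
        Probability in [0, 0.2] that the intended response is inverted.
    """

    slope: float = 8.7
    criterion_high: float = 2.61
    criterion_shift: float = 2.61
    lapse_rate: float = 0.02
    motor_error_rate: float = 0.02

    def __post_init__(self):
        if self.slope <= 0:
            raise ParameterError("slope must be > 0")
        if self.criterion_shift < 0:
            raise ParameterError("criterion_shift must be >= 0")
        for name in ("lapse_rate", "motor_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 0.2:
                raise ParameterError(f"{name} must lie in [0, 0.2]")

    def criterion(self, low_prevalence: bool) -> float:
        return self.criterion_high + (self.criterion_shift if low_prevalence else 0.0)

    def p_yes(self, median_rating, low_prevalence: bool):
        """Probability of an intended "hazard present" response."""
        m = np.asarray(median_rating, dtype=float)
        base = expit(self.slope * m - self.criterion(low_prevalence))
        return self.lapse_rate / 2.0 + (1.0 - self.lapse_rate) * base

    def p_response_yes(self, median_rating, low_prevalence: bool,
                       motor_error_rate: float | None = None):
        """Probability of an emitted "yes" after possible motor inversion."""
        mer = self.motor_error_rate if motor_error_rate is None else motor_error_rate
        p = self.p_yes(median_rating, low_prevalence)
        return p * (1.0 - mer) + (1.0 - p) * mer

    def analytic_threshold(self, low_prevalence: bool) -> float:
        """Rating at which the emitted "yes" probability crosses 0.5.

        Lapses and motor errors are symmetric around 0.5, so the crossing
        point is exactly ``criterion / slope``.
        """
        return self.criterion(low_prevalence) / self.slope

    @property
    def analytic_threshold_lpe(self) -> float:
        """Low-minus-high 50% threshold difference: criterion_shift / slope."""
        return self.criterion_shift / self.slope


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of one two-session prevalence experiment."""

    experiment_id: str
    prevalence_high: float
    prevalence_low: float
    n_trials_high: int
    n_trials_low: int
    n_participants: int
    feedback_mode: str = "full"
    session_order_counterbalanced: bool = True

    def __post_init__(self):
        if not (0 < self.prevalence_low < self.prevalence_high < 1):
            raise ParameterError(
                "need 0 < prevalence_low < prevalence_high < 1, got "
                f"{self.prevalence_low} / {self.prevalence_high}"
            )
        if self.feedback_mode not in FEEDBACK_MODES:
            raise ParameterError(f"feedback_mode must be one of {FEEDBACK_MODES}")
        for name in ("n_trials_high", "n_trials_low", "n_participants"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive integer")
        for cond in ("high", "low"):
            if self.n_present(cond) < 1:
                raise ParameterError(
                    f"{cond}-prevalence session would contain no hazard trials"
                )

    def n_trials(self, condition: str) -> int:
        return self.n_trials_high if condition == "high" else self.n_trials_low

    def prevalence(self, condition: str) -> float:
        return self.prevalence_high if condition == "high" else self.prevalence_low

    def n_present(self, condition: str) -> int:
        """Hazard-present trials per session: round(prevalence * n_trials)."""
        return int(round(self.prevalence(condition) * self.n_trials(condition)))


def _paper_designs() -> dict[str, ExperimentDesign]:
    base = dict(prevalence_high=0.50, prevalence_low=0.04,
                n_trials_high=440, n_trials_low=500, n_participants=16)
    return {
        "exp1": ExperimentDesign("exp1", feedback_mode="full", **base),
        "exp2": ExperimentDesign("exp2", feedback_mode="none", **base),
        "exp3": ExperimentDesign("exp3", feedback_mode="partial", **base),
        "exp4": ExperimentDesign("exp4", feedback_mode="response_correction", **base),
        "exp5": ExperimentDesign(
            "exp5", prevalence_high=0.10, prevalence_low=0.01,
            n_trials_high=480, n_trials_low=580, n_participants=32,
            feedback_mode="full",
        ),
    }


#: The five study designs: 50%/4% prevalence with 440/500 trials and 16
#: participants under full / no / partial / response-correction feedback,
#: and a 10%/1% variant with 480/580 trials and 32 participants.
EXPERIMENT_DESIGNS: dict[str, ExperimentDesign] = _paper_designs()


def _observer_presets() -> dict[str, ObserverParams]:
    # criterion_shift = slope * intended threshold LPE for each experiment;
    # the no-feedback shift is smallest, feedback regimes largest.
    shift = {"exp1": 2.61, "exp2": 1.13, "exp3": 2.00, "exp4": 2.44, "exp5": 2.78}
    presets = {
        exp: ObserverParams(criterion_shift=s) for exp, s in shift.items()
    }
    presets["null"] = ObserverParams(criterion_shift=0.0)
    return presets


#: Per-experiment observer presets (criterion shifts mirror the effect sizes
#: the five feedback regimes produce) plus a ``"null"`` observer with no shift.
OBSERVER_PRESETS: dict[str, ObserverParams] = _observer_presets()


# ---------------------------------------------------------------------------
# generators


def generate_stimulus_set(
    n_present: int,
    n_absent: int,
    present_dist=("beta", 5.0, 2.0),
    absent_dist=("beta", 1.6, 6.0),
    seed: int = 0,
) -> StimulusSet:
    """Sample a stimulus set with latent hazardousness values in [0, 1].

    Hazard-present movies draw their latent value from ``present_dist``
    (default a broad mid-to-high Beta(5, 2)), absent movies from
    ``absent_dist`` (default a low-concentrated Beta(1.6, 6)).
    """
    if n_present < 1 or n_absent < 1:
        raise ParameterError("n_present and n_absent must be >= 1")
    dp = _as_distribution(present_dist)
    da = _as_distribution(absent_dist)
    rng = np.random.default_rng(seed)
    lat_p = np.clip(dp.rvs(size=n_present, random_state=rng), 0.0, 1.0)
    lat_a = np.clip(da.rvs(size=n_absent, random_state=rng), 0.0, 1.0)
    n = n_present + n_absent
    width = max(5, len(str(n)))
    frame = pd.DataFrame(
        {
            "movie_id": [f"m{i:0{width}d}" for i in range(n)],
            "hazard_present": np.r_[
                np.ones(n_present, dtype=bool), np.zeros(n_absent, dtype=bool)
            ],
            "latent_hazardousness": np.r_[lat_p, lat_a],
        }
    )
    return StimulusSet(frame)


def generate_ratings(
    stimuli: StimulusSet,
    n_raters: int = 48,
    rater_noise: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a rating panel: every rater scores every movie on [0, 1].

    Ratings are the movie's latent hazardousness plus additive zero-mean
    Gaussian noise with standard deviation ``rater_noise``, clamped to
    [0, 1].  With ``rater_noise = 0`` every rating equals the latent value.
    Returns a long-format frame with columns rater_id, movie_id, rating.
    """
    if n_raters < 1:
        raise ParameterError("n_raters must be >= 1")
    if len(stimuli.frame) == 0:
        raise InputError("empty stimulus set")
    if rater_noise < 0:
        raise ParameterError("rater_noise must be >= 0")
    rng = np.random.default_rng(seed)
    latent = stimuli.frame["latent_hazardousness"].to_numpy()
    n_movies = latent.size
    vals = np.broadcast_to(latent, (n_raters, n_movies)).copy()
    if rater_noise > 0:
        vals += rng.normal(0.0, rater_noise, size=vals.shape)
        np.clip(vals, 0.0, 1.0, out=vals)
    width = max(2, len(str(n_raters)))
    return pd.DataFrame(
        {
            "rater_id": np.repeat([f"r{i:0{width}d}" for i in range(n_raters)], n_movies),
            "movie_id": np.tile(stimuli.frame["movie_id"].to_numpy(), n_raters),
            "rating": vals.ravel(),
        }
    )


def _median_series(medians) -> pd.Series:
    """Coerce a per-movie median table (frame, mapping, or series) to a Series."""
    if isinstance(medians, pd.DataFrame):
        return medians.set_index("movie_id")["median_rating"]
    if isinstance(medians, pd.Series):
        return medians
    return pd.Series(dict(medians), name="median_rating")


def simulate_experiment(
    design: ExperimentDesign,
    observer: ObserverParams,
    stimuli: StimulusSet,
    medians,
    seed: int = 0,
    response_correction_factor: float = RESPONSE_CORRECTION_FACTOR,
) -> pd.DataFrame:
    """Simulate one experiment: every participant runs both prevalence sessions.

    Within each session ``round(prevalence * n_trials)`` hazard-present movies
    and the complementary number of absent movies are drawn without
    replacement from the stimulus pools; responses follow the observer model
    applied to the movie's median rating.  Session order alternates across
    participants when the design is counterbalanced.  Deterministic in
    ``seed`` (per-participant, per-session substreams are spawned from it).

    Returns a trial table with columns participant_id, experiment_id,
    prevalence_condition, session_order, movie_id, hazard_present,
    response_yes.
    """
    med = _median_series(medians)
    missing = set(stimuli.frame["movie_id"]) - set(med.index)
    if missing:
        raise InputError(f"{len(missing)} movies lack median ratings")
    for cond in ("high", "low"):
        need_p = design.n_present(cond)
        need_a = design.n_trials(cond) - need_p
        if need_p > stimuli.n_present or need_a > stimuli.n_absent:
            raise CapacityError(
                f"{cond}-prevalence session of {design.experiment_id} needs "
                f"{need_p} present / {need_a} absent movies but the pool has "
                f"{stimuli.n_present} / {stimuli.n_absent}"
            )

    mer = observer.motor_error_rate
    if design.feedback_mode == "response_correction":
        mer *= response_correction_factor

    present_ids = stimuli.present_ids
    absent_ids = stimuli.absent_ids
    med_map = med.to_dict()

    root = np.random.SeedSequence(seed)
    per_participant = root.spawn(design.n_participants)
    pw = max(2, len(str(design.n_participants)))
    chunks = []
    for i, pss in enumerate(per_participant):
        pid = f"{design.experiment_id}_p{i:0{pw}d}"
        if design.session_order_counterbalanced and i % 2 == 1:
            order = ("low", "high")
        else:
            order = ("high", "low")
        session_streams = pss.spawn(2)
        for s, (cond, sss) in enumerate(zip(order, session_streams)):
            rng = np.random.default_rng(sss)
            n_p = design.n_present(cond)
            n_a = design.n_trials(cond) - n_p
            ids_p = rng.choice(present_ids, size=n_p, replace=False)
            ids_a = rng.choice(absent_ids, size=n_a, replace=False)
            ids = np.r_[ids_p, ids_a]
            truth = np.r_[np.ones(n_p, dtype=bool), np.zeros(n_a, dtype=bool)]
            perm = rng.permutation(ids.size)
            ids, truth = ids[perm], truth[perm]
            m = np.array([med_map[x] for x in ids])
            p_resp = observer.p_response_yes(m, cond == "low", motor_error_rate=mer)
            resp = rng.random(ids.size) < p_resp
            chunks.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "experiment_id": design.experiment_id,
                        "prevalence_condition": cond,
                        "session_order": "first" if s == 0 else "second",
                        "movie_id": ids,
                        "hazard_present": truth,
                        "response_yes": resp,
                    }
                )
            )
    return pd.concat(chunks, ignore_index=True)


def simulate_study(
    designs: Sequence[ExperimentDesign] | None = None,
    observers: Mapping[str, ObserverParams] | None = None,
    stimulus_kwargs: Mapping | None = None,
    n_raters: int = 48,
    rater_noise: float = 0.1,
    seed: int = 0,
) -> dict:
    """Simulate a full multi-experiment study.

    Defaults reproduce the five-experiment design on a 1376-movie
    stimulus set (432 hazard-present) rated by 48 raters.  Returns a dict with the
    stimulus set, ratings, per-movie medians, the combined trial table, and
    the parameter record used (for the JSON sidecar).
    """
    from .ingest import compute_median_ratings  # local import avoids a cycle

    if designs is None:
        designs = list(EXPERIMENT_DESIGNS.values())
    observers = dict(observers or {})
    root = np.random.SeedSequence(seed)
    s_stim, s_rate, *s_exps = root.spawn(2 + len(designs))

    stim_kwargs = dict(n_present=432, n_absent=944)
    stim_kwargs.update(stimulus_kwargs or {})
    stimuli = generate_stimulus_set(
        seed=s_stim.generate_state(1)[0] % (2**31), **stim_kwargs
    )
    ratings = generate_ratings(
        stimuli, n_raters=n_raters, rater_noise=rater_noise,
        seed=s_rate.generate_state(1)[0] % (2**31),
    )
    medians = compute_median_ratings(ratings)

    trials = []
    used_observers = {}
    for design, s_exp in zip(designs, s_exps):
        obs = observers.get(
            design.experiment_id,
            OBSERVER_PRESETS.get(design.experiment_id, ObserverParams()),
        )
        used_observers[design.experiment_id] = obs
        trials.append(
            simulate_experiment(
                design, obs, stimuli, medians,
                seed=s_exp.generate_state(1)[0] % (2**31),
            )
        )
    trial_table = pd.concat(trials, ignore_index=True)

    params = {
        "seed": int(seed),
        "stimuli": {k: (v if not isinstance(v, tuple) else list(v))
                    for k, v in stim_kwargs.items()},
        "n_raters": int(n_raters),
        "rater_noise": float(rater_noise),
        "designs": [asdict(d) for d in designs],
        "observers": {k: asdict(v) for k, v in used_observers.items()},
        "response_correction_factor": RESPONSE_CORRECTION_FACTOR,
    }
    return {
        "stimuli": stimuli,
        "ratings": ratings,
        "medians": medians,
        "trials": trial_table,
        "params": params,
    }


def write_study(study: dict, outdir) -> dict[str, Path]:
    """Write a simulated study as trials.csv + ratings.csv + params.json.

    The delimited-text schemas are exactly those the ingest module reads.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": outdir / "trials.csv",
        "ratings": outdir / "ratings.csv",
        "params": outdir / "params.json",
    }
    study["trials"].to_csv(paths["trials"], index=False)
    study["ratings"].to_csv(paths["ratings"], index=False)
    paths["params"].write_text(json.dumps(study["params"], indent=2, sort_keys=True))
    return paths
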