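"""Psychometric modelling of "hazard present" responses.

Two routes are provided:

* :func:`fit_logistic` — an independent-observations binomial logit fit of
  yes-counts against median hazardousness rating (one psychometric curve,
  e.g. per experiment x prevalence condition);
* :func:`fit_binomial_glmm` — the full binomial generalized linear mixed
  model over all experiments: fixed effects for median rating, prevalence,
  experiment and all interactions involving median rating, with a Gaussian
  random intercept per participant, estimated by adaptive Gauss-Hermite
  quadrature (:mod:`hazardlpe._agq`).

From either route the 50% threshold — the rating at which "hazard" and "no
hazard" responses are equally likely — is ``-intercept / slope`` on the
fitted logit scale, and the threshold-shift low prevalence effect (LPE) is
the low-prevalence threshold minus the high-prevalence threshold: positive
values are a conservative (rightward) shift, negative values the
prevalence-induced-concept-change direction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit

from ._agq import BinomialRandomInterceptModel
from .errors import (
    InputError,
    RankError,
    UndefinedThresholdError,
)

__all__ = [
    "LogisticFit",
    "Threshold",
    "GlmmFit",
    "WaldResult",
    "ThresholdLpe",
    "fit_logistic",
    "threshold_from_fit",
    "fit_binomial_glmm",
    "wald_type3",
    "threshold_lpe",
    "aggregate_binomial",
    "build_threshold_permutation_data",
    "make_threshold_statistic",
]

_PREV_T = "C(prevalence_condition, Treatment('high'))"
_EXPT_T = "C(experiment_id)"
_PREV_S = "C(prevalence_condition, Sum)"
_EXPT_S = "C(experiment_id, Sum)"


# ---------------------------------------------------------------------------
# per-condition logistic psychometric curve


@dataclass
class LogisticFit:
    """A two-parameter binomial logit fit of yes-counts on rating."""

    intercept: float
    slope: float
    covariance: np.ndarray  # 2x2, order (intercept, slope)
    log_likelihood: float
    converged: bool
    n_obs: int
    message: str = ""

    def predict(self, x):
        return expit(self.intercept + self.slope * np.asarray(x, dtype=float))


def fit_logistic(x, k, n) -> LogisticFit:
    """Maximum-likelihood logistic fit of ``k`` successes out of ``n`` at ``x``.

    Raises :class:`RankError` when ``x`` is constant.  Complete separation or
    IRLS non-convergence yields ``converged=False`` with a diagnostic message
    (never a silent result).
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if x.shape != k.shape or x.shape != n.shape:
        raise InputError("x, k, n must have equal length")
    if np.any(k < 0) or np.any(n < k):
        raise InputError("need n >= k >= 0 elementwise")
    if np.unique(x).size < 2:
        raise RankError("x is constant; the slope is not identifiable")

    exog = np.column_stack([np.ones_like(x), x])
    endog = np.column_stack([k, n - k])
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    separation = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
                maxiter=200, tol=1e-10
            )
        separation = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
    except PerfectSeparationError:
        return LogisticFit(
            intercept=np.nan, slope=np.nan,
            covariance=np.full((2, 2), np.nan),
            log_likelihood=np.nan, converged=False, n_obs=x.size,
            message="complete separation: the likelihood has no maximum",
        )

    params = np.asarray(res.params, dtype=float)
    huge = np.abs(params[1]) > 1e3
    converged = bool(res.converged) and not separation and not huge
    message = ""
    if separation or huge:
        message = "possible complete separation (diverging slope)"
    elif not res.converged:
        message = "IRLS did not converge"
    return LogisticFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        covariance=np.asarray(res.cov_params(), dtype=float),
        log_likelihood=float(res.llf),
        converged=converged,
        n_obs=int(x.size),
        message=message,
    )


@dataclass
class Threshold:
    """A 50% threshold on the rating scale.

    ``value`` is the exact crossing point ``-intercept / slope`` (it may fall
    outside [0, 1], in which case ``clamped`` is set); ``value_clipped`` is
    the value clipped into [0, 1] for reporting.
    """

    value: float
    condition: str | None = None
    experiment_id: str | None = None

    @property
    def clamped(self) -> bool:
        return not (0.0 <= self.value <= 1.0)

    @property
    def value_clipped(self) -> float:
        return float(np.clip(self.value, 0.0, 1.0))


def threshold_from_fit(fit, condition=None, experiment_id=None) -> Threshold:
    """50% threshold ``-intercept / slope`` of a fitted logit curve.

    ``fit`` may be a :class:`LogisticFit` or an ``(intercept, slope)`` pair.
    Raises :class:`UndefinedThresholdError` when the slope is not positive.
    """
    if isinstance(fit, LogisticFit):
        intercept, slope = fit.intercept, fit.slope
    else:
        intercept, slope = fit
    if not np.isfinite(slope) or slope <= 0:
        raise UndefinedThresholdError(
            f"threshold undefined for non-positive slope {slope!r}"
        )
    return Threshold(
        value=float(-intercept / slope),
        condition=condition,
        experiment_id=experiment_id,
    )


# ---------------------------------------------------------------------------
# binomial GLMM with participant random intercept


def aggregate_binomial(table: pd.DataFrame, extra_keys: Sequence[str] = ()) -> pd.DataFrame:
    """Collapse a merged trial table to binomial counts.

    Groups by participant, experiment, prevalence condition, movie and its
    median rating (plus any ``extra_keys``) and returns ``k`` yes-responses
    out of ``n`` trials per group.
    """
    keys = [
        "participant_id",
        "experiment_id",
        "prevalence_condition",
        "movie_id",
        "median_rating",
        *extra_keys,
    ]
    g = table.groupby(keys, sort=True, observed=True)["response_yes"]
    out = g.agg(k="sum", n="count").reset_index()
    out["k"] = out["k"].astype(float)
    out["n"] = out["n"].astype(float)
    return out


def _fixed_effect_terms(n_prev: int, n_expt: int, coding: str):
    prev = _PREV_T if coding == "treatment" else _PREV_S
    expt = _EXPT_T if coding == "treatment" else _EXPT_S
    names, terms = ["median_rating"], ["median_rating"]
    if n_prev > 1:
        names += ["prevalence", "median_rating:prevalence"]
        terms += [prev, f"median_rating:{prev}"]
    if n_expt > 1:
        names += ["experiment", "median_rating:experiment"]
        terms += [expt, f"median_rating:{expt}"]
    if n_prev > 1 and n_expt > 1:
        names += ["median_rating:prevalence:experiment"]
        terms += [f"median_rating:{prev}:{expt}"]
    return names, terms


@dataclass
class GlmmFit:
    """Fitted binomial GLMM: fixed effects + participant random intercept."""

    params: pd.Series
    cov: pd.DataFrame
    random_intercept_sd: float
    log_likelihood: float
    n_obs: int
    n_participants: int
    converged: bool
    message: str
    n_quad: int
    term_names: list
    _design_info: object = field(repr=False, default=None)
    _frame: pd.DataFrame = field(repr=False, default=None)
    _term_slices: dict = field(repr=False, default_factory=dict)
    _cov_full: np.ndarray = field(repr=False, default=None)

    @property
    def fixed_effects(self) -> pd.Series:
        return self.params

    @property
    def standard_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())),
                         index=self.params.index)

    @property
    def random_intercept_variance(self) -> float:
        return self.random_intercept_sd ** 2

    def coefficient_table(self) -> pd.DataFrame:
        """Coefficients with SEs, both per unit rating and per 0.1 rating.

        The per-0.1 columns rescale every term involving the rating covariate
        by 1/10; terms not involving the rating are unchanged.
        """
        se = self.standard_errors
        involves_rating = self.params.index.str.contains("median_rating")
        scale = np.where(involves_rating, 0.1, 1.0)
        z = self.params / se
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "coef_per_0.1_rating": self.params * scale,
                "se_per_0.1_rating": se * scale,
                "z": z,
                "p": 2.0 * sps.norm.sf(np.abs(z)),
            }
        )

    def condition_curve(self, experiment_id: str, condition: str):
        """Population-level (random intercept at 0) logit intercept and slope
        of the psychometric curve for one experiment x prevalence cell."""
        new = pd.DataFrame(
            {
                "median_rating": [0.0, 1.0],
                "prevalence_condition": [condition] * 2,
                "experiment_id": [str(experiment_id)] * 2,
            }
        )
        (X,) = patsy.build_design_matrices([self._design_info], new)
        eta = np.asarray(X) @ self.params.to_numpy()
        return float(eta[0]), float(eta[1] - eta[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params.to_dict(),
                "se": self.standard_errors.to_dict(),
                "cov": self.cov.to_numpy().tolist(),
                "random_intercept_sd": self.random_intercept_sd,
                "log_likelihood": self.log_likelihood,
                "n_obs": self.n_obs,
                "n_participants": self.n_participants,
                "n_quad": self.n_quad,
                "converged": self.converged,
                "message": self.message,
            },
            indent=2,
            sort_keys=True,
        )


def fit_binomial_glmm(
    table: pd.DataFrame,
    n_quad: int = 10,
    fix_sigma: float | None = None,
    gtol: float = 1e-7,
) -> GlmmFit:
    """Fit the binomial GLMM of yes-responses on median hazardousness rating.

    Fixed effects: median rating, prevalence condition, experiment, and all
    interactions involving the rating (treatment coding, reference = high
    prevalence and the first experiment label; the rating enters on its
    native [0, 1] scale).  Participant enters as a Gaussian random intercept
    whose standard deviation is estimated unless ``fix_sigma`` pins it
    (``fix_sigma=0`` reduces to the independent-observations fit).

    ``n_quad`` Gauss-Hermite nodes are used for the marginal likelihood
    (1 = Laplace approximation).
    """
    required = {"participant_id", "experiment_id", "prevalence_condition",
                "median_rating", "response_yes"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"merged table lacks columns: {sorted(missing)}")
    if table["participant_id"].nunique() < 2:
        raise InputError("need at least 2 participants for a mixed model")
    n_prev = table["prevalence_condition"].nunique()
    if n_prev < 2:
        raise InputError("both prevalence conditions must be present")

    agg = aggregate_binomial(table)
    n_expt = agg["experiment_id"].nunique()
    names, terms = _fixed_effect_terms(n_prev, n_expt, "treatment")
    formula = "1 + " + " + ".join(terms)
    X = patsy.dmatrix(formula, agg, return_type="matrix")
    design_info = X.design_info
    Xa = np.asarray(X)
    colnames = list(design_info.column_names)

    participants = pd.Categorical(agg["participant_id"])
    group_idx = participants.codes
    n_participants = len(participants.categories)

    # independent-observations start values
    glm = sm.GLM(
        np.column_stack([agg["k"], agg["n"] - agg["k"]]),
        Xa,
        family=sm.families.Binomial(),
    ).fit(maxiter=200)
    beta0 = np.asarray(glm.params, dtype=float)

    model = BinomialRandomInterceptModel(
        Xa, agg["k"].to_numpy(), agg["n"].to_numpy(), group_idx,
        n_groups=n_participants, n_quad=n_quad,
    )
    res = model.fit(beta0, fix_sigma=fix_sigma, gtol=gtol)

    p = len(colnames)
    cov_beta = res["cov"][:p, :p]
    term_slices = {
        name: design_info.term_name_slices[term]
        for name, term in _friendly_term_map(design_info, names, terms).items()
    }
    return GlmmFit(
        params=pd.Series(res["beta"], index=colnames),
        cov=pd.DataFrame(cov_beta, index=colnames, columns=colnames),
        random_intercept_sd=float(res["sigma"]),
        log_likelihood=float(res["loglik"]),
        n_obs=int(len(agg)),
        n_participants=int(n_participants),
        converged=bool(res["converged"]),
        message=res["message"],
        n_quad=int(n_quad),
        term_names=names,
        _design_info=design_info,
        _frame=agg,
        _term_slices=term_slices,
        _cov_full=res["cov"],
    )


def _friendly_term_map(design_info, names, terms):
    """Map friendly term names to patsy term names, preserving order."""
    patsy_terms = [t for t in design_info.term_name_slices if t != "Intercept"]
    if len(patsy_terms) != len(terms):  # defensive; should not happen
        raise RuntimeError("unexpected design term structure")
    return dict(zip(names, patsy_terms))


@dataclass
class WaldResult:
    term: str
    statistic: float
    df: int
    p_value: float
    note: str = ""


def wald_type3(fit: GlmmFit, term: str) -> WaldResult:
    """Type III Wald chi-square test of a model term's coefficient block.

    The treatment-coded fit is re-expressed under sum-to-zero contrasts (an
    exact linear reparametrization), and the chi-square is
    ``c' V^{-1} c`` over the term's coefficient block in that coding — the
    standard Type III construction.  A singular covariance block falls back
    to the pseudo-inverse with a warning.
    """
    agg = fit._frame
    n_prev = agg["prevalence_condition"].nunique()
    n_expt = agg["experiment_id"].nunique()
    names, terms_s = _fixed_effect_terms(n_prev, n_expt, "sum")
    if term not in names:
        raise InputError(f"unknown term {term!r}; available: {names}")
    Xs = patsy.dmatrix("1 + " + " + ".join(terms_s), agg, return_type="matrix")
    info_s = Xs.design_info
    Xt = np.asarray(patsy.build_design_matrices([fit._design_info], agg)[0])
    Xs_a = np.asarray(Xs)
    # X_t A = X_s exactly (same column space); then beta_s = A^{-1} beta_t
    A, *_ = np.linalg.lstsq(Xt, Xs_a, rcond=None)
    resid = np.abs(Xt @ A - Xs_a).max()
    if resid > 1e-6:
        raise RuntimeError("sum-coding reparametrization failed")
    Ainv = np.linalg.inv(A)
    beta_s = Ainv @ fit.params.to_numpy()
    V_s = Ainv @ fit.cov.to_numpy() @ Ainv.T

    patsy_term = _friendly_term_map(info_s, names, terms_s)[term]
    sl = info_s.term_name_slices[patsy_term]
    c = beta_s[sl]
    Vb = V_s[sl, sl]
    note = ""
    try:
        chi2 = float(c @ np.linalg.solve(Vb, c))
        df = c.size
    except np.linalg.LinAlgError:
        warnings.warn(f"singular covariance block for term {term!r}; "
                      "pseudo-inverse used", stacklevel=2)
        chi2 = float(c @ np.linalg.pinv(Vb) @ c)
        df = int(np.linalg.matrix_rank(Vb))
        note = "singular covariance block; pseudo-inverse"
    return WaldResult(term=term, statistic=chi2, df=df,
                      p_value=float(sps.chi2.sf(chi2, df)), note=note)


# ---------------------------------------------------------------------------
# threshold-shift LPE


@dataclass
class ThresholdLpe:
    """Low-minus-high 50% threshold difference for one experiment."""

    experiment_id: str
    value: float | None
    threshold_high: Threshold | None
    threshold_low: Threshold | None
    mode: str
    undefined: bool = False
    message: str = ""


def _per_condition_logistic(table_exp: pd.DataFrame, condition: str) -> LogisticFit:
    sub = table_exp[table_exp["prevalence_condition"] == condition]
    agg = sub.groupby(["movie_id", "median_rating"], sort=True)["response_yes"].agg(
        k="sum", n="count"
    ).reset_index()
    return fit_logistic(agg["median_rating"], agg["k"], agg["n"])


def threshold_lpe(
    table: pd.DataFrame,
    experiment_id: str,
    mode: str = "glmm",
    glmm_fit: GlmmFit | None = None,
    n_quad: int = 10,
) -> ThresholdLpe:
    """Threshold-shift LPE (low minus high) for one experiment.

    ``mode="glmm"`` slices the full mixed model's fixed-effect linear
    predictor at the experiment x condition cell (population level, random
    intercept at 0); ``mode="logistic"`` refits an independent logistic curve
    per condition as a sensitivity analysis.  Positive values are the LPE
    direction (higher threshold under low prevalence), negative values the
    PICC direction.
    """
    table_exp = table[table["experiment_id"].astype(str) == str(experiment_id)]
    if len(table_exp) == 0:
        raise InputError(f"no rows for experiment {experiment_id!r}")
    thr = {}
    try:
        if mode == "glmm":
            fit = glmm_fit
            if fit is None:
                fit = fit_binomial_glmm(table, n_quad=n_quad)
            for cond in ("high", "low"):
                pair = fit.condition_curve(experiment_id, cond)
                thr[cond] = threshold_from_fit(pair, condition=cond,
                                               experiment_id=experiment_id)
        elif mode == "logistic":
            for cond in ("high", "low"):
                lf = _per_condition_logistic(table_exp, cond)
                thr[cond] = threshold_from_fit(lf, condition=cond,
                                               experiment_id=experiment_id)
        else:
            raise InputError(f"unknown mode {mode!r}")
    except UndefinedThresholdError as err:
        return ThresholdLpe(
            experiment_id=str(experiment_id), value=None,
            threshold_high=thr.get("high"), threshold_low=thr.get("low"),
            mode=mode, undefined=True, message=str(err),
        )
    return ThresholdLpe(
        experiment_id=str(experiment_id),
        value=thr["low"].value - thr["high"].value,
        threshold_high=thr["high"],
        threshold_low=thr["low"],
        mode=mode,
    )


# ---------------------------------------------------------------------------
# threshold statistic for condition-swap permutations


def build_threshold_permutation_data(table_exp: pd.DataFrame):
    """Precompute per-participant, per-condition yes/total counts per movie.

    Returns ``(x, pairs)`` where ``x`` is the vector of movie median ratings
    and ``pairs`` maps participant id to a ``(high, low)`` tuple of
    ``(k_vec, n_vec)`` count vectors aligned with ``x``.  This is the cheap
    representation the condition-swap permutation engine refits from.
    """
    movies = (
        table_exp[["movie_id", "median_rating"]]
        .drop_duplicates("movie_id")
        .sort_values("movie_id")
        .reset_index(drop=True)
    )
    x = movies["median_rating"].to_numpy()
    movie_pos = {m: i for i, m in enumerate(movies["movie_id"])}
    n_movies = len(movies)

    pairs = {}
    for pid, sub in table_exp.groupby("participant_id", sort=True):
        slot = {}
        for cond in ("high", "low"):
            s = sub[sub["prevalence_condition"] == cond]
            kv = np.zeros(n_movies)
            nv = np.zeros(n_movies)
            if len(s):
                pos = s["movie_id"].map(movie_pos).to_numpy()
                np.add.at(nv, pos, 1.0)
                np.add.at(kv, pos, s["response_yes"].to_numpy(dtype=float))
            slot[cond] = (kv, nv)
        pairs[pid] = (slot["high"], slot["low"])
    return x, pairs


def make_threshold_statistic(x: np.ndarray):
    """Statistic closure: pooled per-condition logistic thresholds, low - high.

    Sums the participant count vectors per condition, refits the two
    psychometric curves, and returns the threshold difference.  Returns NaN
    when either slope is non-positive or a fit fails to converge.
    """

    def statistic(pairs: Mapping) -> float:
        thr = []
        for slot in (0, 1):  # 0 = high, 1 = low
            k = np.zeros_like(x)
            n = np.zeros_like(x)
            for high, low in pairs.values():
                kv, nv = (high, low)[slot]
                k += kv
                n += nv
            mask = n > 0
            fit = fit_logistic(x[mask], k[mask], n[mask])
            if not fit.converged or fit.slope <= 0:
                return np.nan
            thr.append(-fit.intercept / fit.slope)
        return thr[1] - thr[0]

    return statistic
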