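"""End-to-end orchestration: simulate or ingest, merge, fit, LPE statistics,
permutation tests, and tidy output tables.

A :class:`PipelineConfig` (YAML on disk) drives :func:`run_pipeline`, which
writes every statistical output of the analysis into one directory:

* ``merged.csv`` — the trial x median-rating analysis table with quartiles
* ``glmm_fit.json`` / ``logistic_fits.json`` — model fits
* ``lpe_summary.csv`` — one row per experiment: threshold LPE + p, per-quartile
  miss-rate LPE + p (the headline summary shape)
* ``quartile_miss_rates.csv`` — per-quartile miss-rate means with
  bootstrapped 95% confidence intervals (figure-ready)
* ``proportional_lpe.csv`` — low/high miss-rate ratios per quartile
* ``fig2_curves.csv`` — per-movie response proportions and fitted curves
* ``permutations.json`` — every permutation result with its seed and B
* ``run_log.json`` — versions, seeds, config hash, exclusion counts

Rerunning with the same config reproduces byte-identical outputs: all
randomness flows from the config's seeds.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ConvergenceError, PipelineStageError
from . import ingest, lpe_stats, psychometric, synthetic_data

__all__ = ["PipelineConfig", "run_pipeline", "make_figure_tables"]


# ---------------------------------------------------------------------------
# configuration


def _default_model():
    return {"threshold_mode": "glmm", "n_quad": 10, "fit_glmm": True}


def _default_permutation():
    return {"iterations": 1000, "seed": 0, "sidedness": "two-sided"}


def _default_bootstrap():
    return {"resamples": 10000, "seed": 0}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``simulate`` (generator parameters) and ``inputs``
    (paths to trial and rating files) may be set.
    """

    output_dir: str
    simulate: dict | None = None
    inputs: dict | None = None
    model: dict = field(default_factory=_default_model)
    permutation: dict = field(default_factory=_default_permutation)
    bootstrap: dict = field(default_factory=_default_bootstrap)

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of 'simulate' and 'inputs' must be provided"
            )
        self.model = {**_default_model(), **(self.model or {})}
        self.permutation = {**_default_permutation(), **(self.permutation or {})}
        self.bootstrap = {**_default_bootstrap(), **(self.bootstrap or {})}
        if self.model["threshold_mode"] not in ("glmm", "logistic"):
            raise ConfigError("model.threshold_mode must be 'glmm' or 'logistic'")
        if self.model["threshold_mode"] == "glmm" and not self.model["fit_glmm"]:
            raise ConfigError("threshold_mode 'glmm' requires model.fit_glmm")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            return cls(**d)
        except TypeError as err:
            raise ConfigError(str(err)) from err

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as err:
            raise ConfigError(f"cannot read config {path}: {err}") from err
        if not isinstance(d, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_dict(d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def _stage_data(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        sim = dict(config.simulate)
        seed = int(sim.pop("seed", 0))
        exp_ids = sim.pop("experiments", None)
        designs = None
        if exp_ids is not None:
            designs = [synthetic_data.EXPERIMENT_DESIGNS[e] for e in exp_ids]
        observers = {
            k: synthetic_data.ObserverParams(**v)
            for k, v in sim.pop("observers", {}).items()
        }
        stimulus_kwargs = sim.pop("stimuli", None)
        study = synthetic_data.simulate_study(
            designs=designs, observers=observers, stimulus_kwargs=stimulus_kwargs,
            seed=seed, **sim,
        )
        synthetic_data.write_study(study, outdir / "data")
        return study["trials"], study["ratings"], {"source": "simulate", "seed": seed}
    inp = config.inputs
    trials, trep = ingest.read_trials(
        inp["trials"], column_map=inp.get("trials_column_map")
    )
    ratings, rrep = ingest.read_ratings(
        inp["ratings"], column_map=inp.get("ratings_column_map")
    )
    (outdir / "load_report_trials.json").write_text(trep.to_json())
    (outdir / "load_report_ratings.json").write_text(rrep.to_json())
    return trials, ratings, {
        "source": "ingest",
        "trials_dropped": trep.n_dropped,
        "ratings_dropped": rrep.n_dropped,
    }


def _stage_merge(trials, ratings, outdir: Path):
    medians = ingest.compute_median_ratings(ratings)
    merged, report = ingest.merge_trials_ratings(trials, medians)
    present = (
        merged.loc[merged["hazard_present"], ["movie_id", "median_rating"]]
        .drop_duplicates("movie_id")
    )
    qmap = lpe_stats.assign_quartiles(present)
    merged = lpe_stats.attach_quartiles(merged, qmap)
    ingest.write_merged(merged, outdir / "merged.csv")
    return merged, qmap, report


def _stage_fit(config: PipelineConfig, merged, outdir: Path):
    model_cfg = config.model
    glmm_fit = None
    wald = None
    if model_cfg["fit_glmm"]:
        glmm_fit = psychometric.fit_binomial_glmm(
            merged, n_quad=int(model_cfg["n_quad"])
        )
        if not glmm_fit.converged:
            raise ConvergenceError(f"GLMM did not converge: {glmm_fit.message}")
        (outdir / "glmm_fit.json").write_text(glmm_fit.to_json())
        glmm_fit.coefficient_table().to_csv(outdir / "glmm_coefficients.csv")
        if "median_rating:prevalence:experiment" in glmm_fit.term_names:
            wald = psychometric.wald_type3(
                glmm_fit, "median_rating:prevalence:experiment"
            )

    experiments = sorted(merged["experiment_id"].unique())
    thresholds = {}
    logistic_fits = {}
    for exp in experiments:
        thresholds[exp] = psychometric.threshold_lpe(
            merged, exp, mode=model_cfg["threshold_mode"], glmm_fit=glmm_fit
        )
        sub = merged[merged["experiment_id"] == exp]
        for cond in ("high", "low"):
            lf = psychometric._per_condition_logistic(sub, cond)
            logistic_fits[f"{exp}_{cond}"] = {
                "intercept": lf.intercept,
                "slope": lf.slope,
                "log_likelihood": lf.log_likelihood,
                "converged": lf.converged,
                "n_obs": lf.n_obs,
                "message": lf.message,
            }
    (outdir / "logistic_fits.json").write_text(
        json.dumps(logistic_fits, indent=2, sort_keys=True)
    )
    return glmm_fit, wald, thresholds


def _stage_lpe(merged, outdir: Path):
    cells_overall = lpe_stats.miss_rates(merged, by_quartile=False)
    cells_quartile = lpe_stats.miss_rates(merged, by_quartile=True)
    cells_quartile.to_csv(outdir / "miss_rate_cells.csv", index=False)
    out = {}
    for exp in sorted(merged["experiment_id"].unique()):
        co = cells_overall[cells_overall["experiment_id"] == exp]
        cq = cells_quartile[cells_quartile["experiment_id"] == exp]
        out[exp] = {
            "overall": lpe_stats.lpe_miss(co, level="overall"),
            "per_quartile": lpe_stats.lpe_miss(cq, level="per_quartile"),
            "proportional": lpe_stats.proportional_lpe(cq),
        }
    return cells_overall, cells_quartile, out


def _stage_permute(config: PipelineConfig, merged, outdir: Path):
    perm_cfg = config.permutation
    B = int(perm_cfg["iterations"])
    sidedness = perm_cfg["sidedness"]
    root = np.random.SeedSequence(int(perm_cfg["seed"]))
    experiments = sorted(merged["experiment_id"].unique())
    results = {}
    cells_quartile = lpe_stats.miss_rates(merged, by_quartile=True)
    for exp, ss in zip(experiments, root.spawn(len(experiments))):
        sub = merged[merged["experiment_id"] == exp]
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
        exp_res = {}

        # threshold LPE: condition swap with per-condition logistic refits
        x, pairs = psychometric.build_threshold_permutation_data(sub)
        stat = psychometric.make_threshold_statistic(x)
        exp_res["threshold"] = lpe_stats.permute_condition_swap(
            pairs, stat, B=B, seed=seeds[0], alternative=sidedness
        )

        # per-quartile miss-rate LPE: condition swap of the quartile's cells
        cq = cells_quartile[cells_quartile["experiment_id"] == exp]
        for i, q in enumerate(lpe_stats.QUARTILES, start=1):
            qpairs = lpe_stats.build_miss_rate_pairs(cq, quartile=q)
            exp_res[q] = lpe_stats.permute_condition_swap(
                qpairs, lpe_stats.mean_paired_difference,
                B=B, seed=seeds[i], alternative=sidedness,
            )

        # Q4 vs Q1: quartile-label shuffle
        qdata = lpe_stats.build_quartile_shuffle_data(sub)
        exp_res["Q4_vs_Q1"] = lpe_stats.permute_quartile_shuffle(
            qdata, focal_quartile="Q4", comparison="Q1",
            B=B, seed=seeds[5], alternative=sidedness,
        )
        results[exp] = exp_res

    serial = {
        exp: {name: r.summary() for name, r in exp_res.items()}
        for exp, exp_res in results.items()
    }
    (outdir / "permutations.json").write_text(
        json.dumps(serial, indent=2, sort_keys=True)
    )
    return results


def _stage_report(config, merged, thresholds, lpe, permutations, wald, outdir):
    experiments = sorted(merged["experiment_id"].unique())
    rows = []
    quartile_family = {}
    for exp in experiments:
        row = {
            "experiment_id": exp,
            "threshold_lpe": thresholds[exp].value,
            "threshold_p": permutations[exp]["threshold"].p_value,
        }
        for q in lpe_stats.QUARTILES:
            row[f"lpe_{q}"] = lpe[exp]["per_quartile"].values[q]
            row[f"p_{q}"] = permutations[exp][q].p_value
            quartile_family[f"{exp}_{q}"] = permutations[exp][q].p_value
        row["lpe_Q4_vs_Q1"] = permutations[exp]["Q4_vs_Q1"].observed
        row["p_Q4_vs_Q1"] = permutations[exp]["Q4_vs_Q1"].p_value
        rows.append(row)
    summary = pd.DataFrame(rows)

    bonf = lpe_stats.bonferroni(quartile_family, alpha=0.05)
    for exp in experiments:
        for q in lpe_stats.QUARTILES:
            summary.loc[summary["experiment_id"] == exp, f"sig_{q}"] = bonf.decisions[
                f"{exp}_{q}"
            ]
    summary.to_csv(outdir / "lpe_summary.csv", index=False)

    comparison_family = {
        f"{exp}_Q4_vs_Q1": permutations[exp]["Q4_vs_Q1"].p_value
        for exp in experiments
    }
    bonf_cmp = lpe_stats.bonferroni(comparison_family, alpha=0.05)

    prop_rows = []
    for exp in experiments:
        prop = lpe[exp]["proportional"]
        for q in lpe_stats.QUARTILES:
            prop_rows.append(
                {
                    "experiment_id": exp,
                    "quartile": q,
                    "proportional_lpe": prop.ratios[q],
                    "mean_miss_low": prop.mean_low[q],
                    "mean_miss_high": prop.mean_high[q],
                    "undefined": prop.undefined[q],
                }
            )
    pd.DataFrame(prop_rows).to_csv(outdir / "proportional_lpe.csv", index=False)

    bonferroni_out = {
        "quartile_family": {
            "critical_alpha": bonf.critical_alpha,
            "m": bonf.m,
            "decisions": bonf.decisions,
        },
        "quartile_comparison_family": {
            "critical_alpha": bonf_cmp.critical_alpha,
            "m": bonf_cmp.m,
            "decisions": bonf_cmp.decisions,
        },
    }
    if wald is not None:
        bonferroni_out["wald_three_way"] = {
            "statistic": wald.statistic,
            "df": wald.df,
            "p_value": wald.p_value,
        }
    (outdir / "summary_tests.json").write_text(
        json.dumps(bonferroni_out, indent=2, sort_keys=True)
    )
    return summary


# ---------------------------------------------------------------------------
# figure tables


def _bootstrap_ci(values: np.ndarray, resamples: int, rng) -> tuple:
    """Percentile bootstrap 95% CI of the mean, resampling participants."""
    values = values[np.isfinite(values)]
    if values.size == 0:
        return (np.nan, np.nan)
    if values.size == 1:
        return (float(values[0]), float(values[0]))
    idx = rng.integers(0, values.size, size=(resamples, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return (float(lo), float(hi))


def make_figure_tables(
    merged: pd.DataFrame,
    cells_quartile: pd.DataFrame,
    thresholds: dict,
    glmm_fit=None,
    resamples: int = 10000,
    seed: int = 0,
    n_curve_points: int = 101,
) -> dict:
    """Tidy tables for the two figure shapes.

    ``curves``: per experiment x condition, the per-movie proportion of
    "hazard present" responses against median rating, plus fitted-curve
    samples on a rating grid.  ``quartile_miss_rates``: per experiment x
    quartile x condition mean miss rate over participants with a
    percentile-bootstrap 95% CI (resampling participants, seeded).
    """
    experiments = sorted(merged["experiment_id"].unique())
    grid = np.linspace(0.0, 1.0, n_curve_points)

    curve_rows = []
    for exp in experiments:
        sub = merged[merged["experiment_id"] == exp]
        for cond in ("high", "low"):
            s = sub[sub["prevalence_condition"] == cond]
            per_movie = s.groupby(["movie_id", "median_rating"], sort=True)[
                "response_yes"
            ].agg(k="sum", n="count").reset_index()
            for _, r in per_movie.iterrows():
                curve_rows.append(
                    {
                        "experiment_id": exp,
                        "prevalence_condition": cond,
                        "kind": "movie",
                        "median_rating": r["median_rating"],
                        "proportion_yes": r["k"] / r["n"],
                        "n_trials": int(r["n"]),
                    }
                )
            if glmm_fit is not None:
                a, b = glmm_fit.condition_curve(exp, cond)
                fitted = 1.0 / (1.0 + np.exp(-(a + b * grid)))
            else:
                lf = psychometric._per_condition_logistic(sub, cond)
                fitted = lf.predict(grid)
            for g, f in zip(grid, fitted):
                curve_rows.append(
                    {
                        "experiment_id": exp,
                        "prevalence_condition": cond,
                        "kind": "fitted",
                        "median_rating": float(g),
                        "proportion_yes": float(f),
                        "n_trials": 0,
                    }
                )
    curves = pd.DataFrame(curve_rows)

    rng = np.random.default_rng(seed)
    q_rows = []
    for exp in experiments:
        ce = cells_quartile[cells_quartile["experiment_id"] == exp]
        for q in lpe_stats.QUARTILES:
            for cond in ("high", "low"):
                v = ce[
                    (ce["quartile"] == q) & (ce["prevalence_condition"] == cond)
                ]["miss_rate"].to_numpy(dtype=float)
                lo, hi = _bootstrap_ci(v, resamples, rng)
                q_rows.append(
                    {
                        "experiment_id": exp,
                        "quartile": q,
                        "prevalence_condition": cond,
                        "mean_miss_rate": float(np.nanmean(v)) if np.isfinite(v).any() else np.nan,
                        "ci_low": lo,
                        "ci_high": hi,
                        "n_participants": int(np.isfinite(v).sum()),
                    }
                )
    quartile_miss = pd.DataFrame(q_rows)
    return {"curves": curves, "quartile_miss_rates": quartile_miss}


# ---------------------------------------------------------------------------
# driver


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all outputs under the output dir.

    Returns a bundle dict with the in-memory results and output paths.  Any
    stage failure raises :class:`PipelineStageError` naming the stage, after
    writing a partial-results manifest.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.hash(), "stages_completed": []}
    bundle = {"outdir": outdir, "config": config}

    def _run(stage, fn, *args):
        try:
            result = fn(*args)
        except Exception as err:
            manifest["failed_stage"] = stage
            manifest["error"] = str(err)
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True)
            )
            raise PipelineStageError(stage, str(err)) from err
        manifest["stages_completed"].append(stage)
        return result

    trials, ratings, data_info = _run("data", _stage_data, config, outdir)
    merged, qmap, merge_report = _run("merge", _stage_merge, trials, ratings, outdir)
    glmm_fit, wald, thresholds = _run("fit", _stage_fit, config, merged, outdir)
    cells_overall, cells_quartile, lpe = _run("lpe", _stage_lpe, merged, outdir)
    permutations = _run("permute", _stage_permute, config, merged, outdir)
    summary = _run(
        "report", _stage_report, config, merged, thresholds, lpe, permutations,
        wald, outdir,
    )

    figures = _run(
        "figures",
        lambda: make_figure_tables(
            merged, cells_quartile, thresholds, glmm_fit=glmm_fit,
            resamples=int(config.bootstrap["resamples"]),
            seed=int(config.bootstrap["seed"]),
        ),
    )
    figures["curves"].to_csv(outdir / "fig2_curves.csv", index=False)
    figures["quartile_miss_rates"].to_csv(
        outdir / "quartile_miss_rates.csv", index=False
    )

    run_log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "data": data_info,
        "merge_report": merge_report,
        "quartile_cut_points": list(qmap.cut_points),
        "exclusions": {
            exp: {
                "overall": lpe[exp]["overall"].excluded,
                "per_quartile": lpe[exp]["per_quartile"].excluded,
            }
            for exp in lpe
        },
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    manifest["outputs"] = sorted(p.name for p in outdir.iterdir() if p.is_file())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    bundle.update(
        {
            "merged": merged,
            "quartile_map": qmap,
            "glmm_fit": glmm_fit,
            "wald_three_way": wald,
            "thresholds": thresholds,
            "cells_overall": cells_overall,
            "cells_quartile": cells_quartile,
            "lpe": lpe,
            "permutations": permutations,
            "summary": summary,
            "figures": figures,
        }
    )
    return bundle
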