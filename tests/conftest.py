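import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hazardlpe as hl
from hazardlpe import lpe_stats

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_stimuli():
    return hl.generate_stimulus_set(120, 240, seed=11)


@pytest.fixture(scope="session")
def small_ratings(small_stimuli):
    return hl.generate_ratings(small_stimuli, n_raters=8, rater_noise=0.1, seed=12)


@pytest.fixture(scope="session")
def small_medians(small_ratings):
    return hl.compute_median_ratings(small_ratings)


@pytest.fixture(scope="session")
def small_design():
    return hl.ExperimentDesign(
        "exp1", prevalence_high=0.5, prevalence_low=0.04,
        n_trials_high=100, n_trials_low=100, n_participants=8,
    )


@pytest.fixture(scope="session")
def small_merged(small_design, small_stimuli, small_medians):
    """A small exp1-like simulated study, merged and quartile-labelled."""
    trials = hl.simulate_experiment(
        small_design, hl.OBSERVER_PRESETS["exp1"], small_stimuli,
        small_medians, seed=13,
    )
    merged, _ = hl.merge_trials_ratings(trials, small_medians)
    present = merged.loc[
        merged["hazard_present"], ["movie_id", "median_rating"]
    ].drop_duplicates("movie_id")
    qmap = lpe_stats.assign_quartiles(present)
    return lpe_stats.attach_quartiles(merged, qmap)


def make_merged_frame(rows):
    """Build a merged-table frame from terse row tuples:
    (participant, prevalence, movie, median, hazard_present, response_yes)."""
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "prevalence_condition", "movie_id",
            "median_rating", "hazard_present", "response_yes",
        ],
    ).assign(experiment_id="exp1")
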