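"""LPE statistics tests: quartile assignment, miss-rate cells, the
permutation engines against exhaustive enumeration, and Bonferroni control."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import hazardlpe as hl
from hazardlpe import lpe_stats as ls
from hazardlpe.errors import InputError
from conftest import make_merged_frame


def quartile_oracle(values):
    """Rule-following oracle: 25/50/75% cuts, ties go to the lower quartile."""
    cuts = np.quantile(np.asarray(values, float), [0.25, 0.5, 0.75])
    out = []
    for v in values:
        if v <= cuts[0]:
            out.append("Q1")
        elif v <= cuts[1]:
            out.append("Q2")
        elif v <= cuts[2]:
            out.append("Q3")
        else:
            out.append("Q4")
    return out


class TestQuartiles:
    def test_eight_distinct_movies_two_per_quartile(self):
        med = pd.DataFrame({"movie_id": [f"m{i}" for i in range(8)],
                            "median_rating": np.linspace(0.1, 0.8, 8)})
        qmap = ls.assign_quartiles(med)
        assert (qmap.counts() == 2).all()

    def test_432_distinct_movies_split_108_each(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.linspace(0.01, 0.99, 432))
        med = pd.DataFrame({"movie_id": [f"m{i}" for i in range(432)],
                            "median_rating": vals})
        qmap = ls.assign_quartiles(med)
        assert (qmap.counts() == 108).all()
        # Q1 is the least hazardous quartile
        by_q = med.assign(q=qmap.mapping.loc[med.movie_id].to_numpy())
        assert by_q.groupby("q")["median_rating"].max().is_monotonic_increasing

    @given(st.lists(st.sampled_from([0.1, 0.2, 0.2, 0.3, 0.5, 0.5, 0.7, 0.9]),
                    min_size=4, max_size=24))
    def test_matches_rule_following_oracle_with_ties(self, vals):
        med = pd.DataFrame({"movie_id": [f"m{i}" for i in range(len(vals))],
                            "median_rating": vals})
        qmap = ls.assign_quartiles(med)
        assert list(qmap.mapping) == quartile_oracle(vals)

    def test_too_few_movies_rejected(self):
        med = pd.DataFrame({"movie_id": ["a", "b", "c"],
                            "median_rating": [0.1, 0.2, 0.3]})
        with pytest.raises(InputError):
            ls.assign_quartiles(med)


class TestMissRates:
    def test_basic_arithmetic(self):
        rows = [("p1", "high", f"m{i}", 0.5, True, i >= 2) for i in range(5)]
        rows += [("p1", "low", f"m{i}", 0.5, True, True) for i in range(5)]
        cells = ls.miss_rates(make_merged_frame(rows))
        high = cells[cells.prevalence_condition == "high"].iloc[0]
        assert high["n_hazard_trials"] == 5 and high["n_misses"] == 2
        assert high["miss_rate"] == pytest.approx(0.4)

    def test_perfect_observer_zero_everywhere_defined(self, small_merged):
        perfect = small_merged.assign(response_yes=small_merged.hazard_present)
        cells = ls.miss_rates(perfect, by_quartile=True)
        defined = cells[cells.n_hazard_trials > 0]
        assert (defined["miss_rate"] == 0).all()

    def test_empty_cell_is_undefined_not_zero(self):
        rows = [("p1", "high", "m1", 0.5, True, True)]
        cells = ls.miss_rates(make_merged_frame(rows))
        low = cells[cells.prevalence_condition == "low"].iloc[0]
        assert low["n_hazard_trials"] == 0 and np.isnan(low["miss_rate"])

    def test_per_quartile_counts_match_brute_force_tally(self, small_merged):
        cells = ls.miss_rates(small_merged, by_quartile=True)
        hp = small_merged[small_merged.hazard_present]
        for _, row in cells.sample(40, random_state=1).iterrows():
            sub = hp[
                (hp.participant_id == row.participant_id)
                & (hp.prevalence_condition == row.prevalence_condition)
                & (hp.quartile == row.quartile)
            ]
            assert row.n_hazard_trials == len(sub)
            assert row.n_misses == int((~sub.response_yes).sum())


class TestLpeMiss:
    def test_constant_difference(self):
        rows = []
        for p in ("p1", "p2", "p3"):
            rows += [(p, "high", f"{p}h{i}", 0.5, True, i >= 1) for i in range(10)]
            rows += [(p, "low", f"{p}l{i}", 0.5, True, i >= 4) for i in range(10)]
        cells = ls.miss_rates(make_merged_frame(rows))
        res = ls.lpe_miss(cells)
        assert res.values["overall"] == pytest.approx(0.4 - 0.1)
        assert res.n_used["overall"] == 3

    def test_identical_conditions_give_zero(self, small_merged):
        sym = pd.concat([
            small_merged[small_merged.prevalence_condition == "high"],
            small_merged[small_merged.prevalence_condition == "high"].assign(
                prevalence_condition="low"),
        ])
        res = ls.lpe_miss(ls.miss_rates(sym))
        assert res.values["overall"] == 0.0

    def test_participants_without_both_cells_excluded(self):
        rows = [("p1", "high", "m1", 0.5, True, False),
                ("p1", "low", "m2", 0.5, True, True),
                ("p2", "high", "m3", 0.5, True, True)]  # p2 lacks a low cell
        res = ls.lpe_miss(ls.miss_rates(make_merged_frame(rows)))
        assert res.n_used["overall"] == 1
        assert res.excluded["overall"] == ["p2"]

    def test_no_defined_pair_raises(self):
        rows = [("p1", "high", "m1", 0.5, True, True)]
        with pytest.raises(InputError):
            ls.lpe_miss(ls.miss_rates(make_merged_frame(rows)))

    def test_antisymmetric_under_condition_exchange(self, small_merged):
        flipped = small_merged.assign(
            prevalence_condition=small_merged.prevalence_condition.map(
                {"high": "low", "low": "high"})
        )
        a = ls.lpe_miss(ls.miss_rates(small_merged)).values["overall"]
        b = ls.lpe_miss(ls.miss_rates(flipped)).values["overall"]
        assert a == pytest.approx(-b)


class TestProportionalLpe:
    def test_arithmetic(self):
        rows = []
        for p in ("p1", "p2"):
            rows += [(p, "high", f"{p}h{i}", 0.5, True, i >= 1) for i in range(10)]
            rows += [(p, "low", f"{p}l{i}", 0.5, True, i >= 3) for i in range(10)]
        res = ls.proportional_lpe(ls.miss_rates(make_merged_frame(rows)),
                                  level="overall")
        assert res.ratios["overall"] == pytest.approx(3.0)

    def test_equal_rates_ratio_one(self, small_merged):
        sym = pd.concat([
            small_merged[small_merged.prevalence_condition == "high"],
            small_merged[small_merged.prevalence_condition == "high"].assign(
                prevalence_condition="low"),
        ])
        res = ls.proportional_lpe(ls.miss_rates(sym), level="overall")
        assert res.ratios["overall"] == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        rows = [("p1", "high", "m1", 0.5, True, True),
                ("p1", "low", "m2", 0.5, True, False)]
        res = ls.proportional_lpe(ls.miss_rates(make_merged_frame(rows)),
                                  level="overall")
        assert res.undefined["overall"] and np.isnan(res.ratios["overall"])

    def test_conservative_shift_inflates_every_quartile(
        self, small_stimuli, small_medians
    ):
        """With a positive criterion shift the low/high miss ratio exceeds 1
        in every quartile and tracks the analytic observer-model ratio."""
        obs = hl.OBSERVER_PRESETS["exp1"]
        design = hl.ExperimentDesign("exp1", 0.5, 0.2, 200, 200, 16)
        trials = hl.simulate_experiment(design, obs, small_stimuli,
                                        small_medians, seed=77)
        merged, _ = hl.merge_trials_ratings(trials, small_medians)
        present = merged.loc[
            merged.hazard_present, ["movie_id", "median_rating"]
        ].drop_duplicates("movie_id")
        merged = ls.attach_quartiles(merged, ls.assign_quartiles(present))
        cells = ls.miss_rates(merged, by_quartile=True)
        res = ls.proportional_lpe(cells)
        hp = merged[merged.hazard_present].drop_duplicates("movie_id")
        for q in ls.QUARTILES:
            assert res.ratios[q] > 1.0
            m = hp.loc[hp.quartile == q, "median_rating"].to_numpy()
            analytic = (1 - obs.p_response_yes(m, True)).mean() / (
                1 - obs.p_response_yes(m, False)).mean()
            assert res.ratios[q] == pytest.approx(analytic, rel=0.5)


def exact_swap_p(pairs, statistic):
    """Exhaustive enumeration over all 2^n condition-swap patterns."""
    pids = list(pairs)
    obs = abs(statistic(pairs))
    count = 0
    total = 0
    for pattern in itertools.product([False, True], repeat=len(pids)):
        relabeled = {
            pid: (pairs[pid][1], pairs[pid][0]) if flip else pairs[pid]
            for pid, flip in zip(pids, pattern)
        }
        count += abs(statistic(relabeled)) >= obs - 1e-12
        total += 1
    return count / total


class TestConditionSwap:
    def test_invariant_statistic_gives_p_one(self):
        pairs = {f"p{i}": (0.3, 0.3) for i in range(6)}
        res = ls.permute_condition_swap(pairs, ls.mean_paired_difference,
                                        B=200, seed=1)
        assert res.p_value == 1.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        pairs = {f"p{i}": tuple(rng.uniform(0, 1, 2)) for i in range(4)}
        exact = exact_swap_p(pairs, ls.mean_paired_difference)
        res = ls.permute_condition_swap(pairs, ls.mean_paired_difference,
                                        B=20000, seed=3)
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_missing_condition_excluded_with_warning(self):
        pairs = {"p1": (0.1, 0.5), "p2": (None, 0.4), "p3": (0.2, 0.6)}
        with pytest.warns(UserWarning, match="excluded"):
            res = ls.permute_condition_swap(pairs, ls.mean_paired_difference,
                                            B=50, seed=4)
        assert res.n_participants == 2 and res.excluded == ["p2"]
        with pytest.raises(InputError):
            ls.permute_condition_swap({"p": (None, 1.0)},
                                      ls.mean_paired_difference, B=10, seed=5)

    @given(st.integers(0, 1000))
    def test_p_never_zero_and_at_most_one(self, seed):
        rng = np.random.default_rng(seed)
        pairs = {f"p{i}": tuple(rng.normal(0, 1, 2)) for i in range(5)}
        res = ls.permute_condition_swap(pairs, ls.mean_paired_difference,
                                        B=37, seed=seed)
        assert 0 < res.p_value <= 1


class TestQuartileShuffle:
    def build_single_participant(self, responses_by_quartile):
        """One participant, movies in two quartiles, both conditions."""
        rows = []
        for k, (q_med, resp) in enumerate(responses_by_quartile):
            for cond, r in resp:
                rows.append(("p1", cond, f"m{k}", q_med, True, r))
        frame = make_merged_frame(rows)
        present = frame[["movie_id", "median_rating"]].drop_duplicates()
        # two artificial quartile levels via explicit labels
        frame["quartile"] = np.where(frame.median_rating < 0.5, "Q1", "Q4")
        return frame

    def test_single_participant_matches_enumeration(self):
        # 4 movies: 2 in Q1 (missed under low), 2 in Q4 (never missed)
        frame = self.build_single_participant([
            (0.2, [("high", True), ("low", False)]),
            (0.3, [("high", True), ("low", False)]),
            (0.8, [("high", True), ("low", True)]),
            (0.9, [("high", True), ("low", True)]),
        ])
        data = ls.build_quartile_shuffle_data(frame)
        res = ls.permute_quartile_shuffle(data, focal_quartile="Q4",
                                          comparison="Q1", B=20000, seed=6)
        # enumerate all distinct label assignments (choose 2 of 4 as Q1)
        exceed = total = 0
        for q1_idx in itertools.combinations(range(4), 2):
            labels = np.array([0 if i in q1_idx else 3 for i in range(4)])
            lpes = ls._quartile_lpes(data, {"p1": labels})
            stat = lpes[3] - lpes[0]
            exceed += abs(stat) >= abs(res.observed) - 1e-12
            total += 1
        exact = exceed / total
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_exchangeable_null_rejection_rate(self, small_stimuli, small_medians):
        """Rating-independent miss probability makes quartiles exchangeable:
        the test should reject at about its nominal 5% level."""
        rng = np.random.default_rng(7)
        design = hl.ExperimentDesign("e", 0.5, 0.1, 40, 40, 8)
        # flat observer: slope tiny => response independent of rating
        obs = hl.ObserverParams(slope=1e-6, criterion_high=0.0,
                                criterion_shift=0.5, lapse_rate=0.0,
                                motor_error_rate=0.0)
        present = small_medians.merge(
            small_stimuli.frame[["movie_id", "hazard_present"]], on="movie_id"
        )
        qmap = ls.assign_quartiles(
            present[present.hazard_present][["movie_id", "median_rating"]]
        )
        rejections = 0
        n_studies = 200
        for s in range(n_studies):
            trials = hl.simulate_experiment(design, obs, small_stimuli,
                                            small_medians, seed=5000 + s)
            merged, _ = hl.merge_trials_ratings(trials, small_medians)
            merged = ls.attach_quartiles(merged, qmap)
            data = ls.build_quartile_shuffle_data(merged)
            res = ls.permute_quartile_shuffle(data, focal_quartile="Q4",
                                              comparison="Q1", B=99,
                                              seed=6000 + s)
            rejections += res.p_value <= 0.05
        rate = rejections / n_studies
        assert 0.01 <= rate <= 0.10  # 0.05 +/- Monte-Carlo error

    def test_preserves_per_quartile_counts(self, small_merged):
        data = ls.build_quartile_shuffle_data(
            small_merged[small_merged.experiment_id == "exp1"]
        )
        res = ls.permute_quartile_shuffle(data, "Q4", B=20, seed=8)
        assert res.scheme == "quartile_shuffle"
        assert 0 < res.p_value <= 1


class TestBonferroni:
    def test_twenty_tests_critical_alpha(self):
        ps = {f"t{i}": 0.01 for i in range(20)}
        res = ls.bonferroni(ps, alpha=0.05)
        assert res.critical_alpha == pytest.approx(0.0025)
        assert not any(res.decisions.values())

    def test_single_test_uncorrected(self):
        res = ls.bonferroni({"only": 0.03}, alpha=0.05)
        assert res.critical_alpha == 0.05 and res.decisions["only"]

    @given(st.integers(1, 50), st.floats(0.001, 0.2))
    def test_division_oracle(self, m, alpha):
        ps = {f"t{i}": 0.5 for i in range(m)}
        res = ls.bonferroni(ps, alpha=alpha)
        assert res.critical_alpha == pytest.approx(alpha / m)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            ls.bonferroni({}, 0.05)
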