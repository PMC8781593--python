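import numpy as np
import pandas as pd
import pytest

from ari_diary.datamodel import DayClass, ObservationWindow
from ari_diary.episodes import (
    TRIGGER_A,
    TRIGGER_B,
    age_at_first_episode,
    classify_day,
    classify_diary,
    duration_summary,
    episodes_per_child,
    segment_episodes,
)
from conftest import covariates_for, diary_from_days, random_symptom_diary
from oracle import oracle_classify, oracle_segment


class TestClassifyDay:
    @pytest.mark.parametrize("flags, expected", [
        ({"fever": 1}, DayClass.A_DAY),
        ({"wheezing": 2}, DayClass.A_DAY),
        ({"wet_cough": 1}, DayClass.A_DAY),
        ({"dx_pneumonia": 1}, DayClass.A_DAY),
        ({"dx_otitis_media": 1}, DayClass.A_DAY),
        ({"fever": 1, "dry_cough": 1}, DayClass.A_DAY),   # A takes precedence
        ({"runny_or_blocked_nose": 1, "loss_of_appetite": 1}, DayClass.B_PAIR),
        ({"dry_cough": 1, "chills": 1}, DayClass.B_PAIR),
        ({"dry_cough": 3}, DayClass.SINGLE_B),            # severity != two symptoms
        ({"sore_throat": 1}, DayClass.SINGLE_B),
        ({}, DayClass.FREE),
        ({"entry_present": False}, DayClass.MISSING),
    ])
    def test_a_b_classification(self, flags, expected):
        assert classify_day(flags) == expected

    def test_classes_exhaustive_and_match_independent_logic(self):
        rng = np.random.default_rng(0)
        days = random_symptom_diary(rng, n_days=300, p_missing=0.0)
        diary = diary_from_days({d: f for d, f in days.items()})
        vec = classify_diary(diary)
        for i, d in enumerate(sorted(days)):
            present = {k for k, v in days[d].items() if v}
            assert DayClass(vec.iloc[i]).name.lower() == oracle_classify(present)


def segment_days(days, missing_rule="free", n_days=None):
    """Helper: run the engine over one child's compact day spec."""
    n_days = n_days or (max(days) + 1 if days else 1)
    diary = diary_from_days({d: f for d, f in days.items() if f is not None})
    window = ObservationWindow(0, n_days - 1)
    return segment_episodes(diary, ["A"], window, missing_rule)


class TestSegmentation:
    def test_a_start_with_trailing_b_days(self):
        # fever d0; runny nose d1-2; free d3-5 -> one episode, duration 3
        eps, orphans = segment_days({
            0: {"fever": 1},
            1: {"runny_or_blocked_nose": 1}, 2: {"runny_or_blocked_nose": 1},
            3: {}, 4: {}, 5: {},
        })
        assert len(eps) == 1 and len(orphans) == 0
        ep = eps.iloc[0]
        assert (ep.start_day, ep.last_symptom_day, ep.duration_days) == (0, 2, 3)
        assert ep.trigger == TRIGGER_A and not ep.censored

    def test_three_free_days_terminate_episode(self):
        eps, _ = segment_days({0: {"fever": 1}, 1: {}, 2: {}, 3: {},
                               4: {"fever": 1}, 5: {}, 6: {}, 7: {}})
        assert len(eps) == 2
        assert eps["start_day"].tolist() == [0, 4]
        assert eps["duration_days"].tolist() == [1, 1]

    def test_two_free_days_do_not_terminate(self):
        eps, _ = segment_days({0: {"fever": 1}, 1: {}, 2: {},
                               3: {"fever": 1}, 4: {}, 5: {}, 6: {}})
        assert len(eps) == 1
        ep = eps.iloc[0]
        assert (ep.start_day, ep.last_symptom_day, ep.duration_days) == (0, 3, 4)

    def test_isolated_single_b_day_is_orphan_not_episode(self):
        eps, orphans = segment_days({0: {"dry_cough": 1}, 1: {}, 2: {}, 3: {}})
        assert len(eps) == 0
        assert orphans["day_of_life"].tolist() == [0]

    def test_single_b_inside_episode_extends_it(self):
        # fever d0, free d1-2, single B d3 resets the counter
        eps, orphans = segment_days({0: {"fever": 1}, 1: {}, 2: {},
                                     3: {"dry_cough": 1}, 4: {}, 5: {}, 6: {}})
        assert len(eps) == 1 and len(orphans) == 0
        assert eps.iloc[0].last_symptom_day == 3

    def test_b_pair_trigger_recorded(self):
        eps, _ = segment_days({0: {"dry_cough": 1, "chills": 1},
                               1: {}, 2: {}, 3: {}})
        assert eps.iloc[0].trigger == TRIGGER_B

    def test_open_episode_at_window_end_is_censored(self):
        eps, _ = segment_days({0: {}, 1: {}, 2: {"fever": 1}}, n_days=3)
        ep = eps.iloc[0]
        assert ep.censored and ep.last_symptom_day == 2

    def test_missing_rule_free_vs_pause(self):
        # fever d0; missing d1-3; fever d4
        days = {0: {"fever": 1}, 1: None, 2: None, 3: None,
                4: {"fever": 1}, 5: {}, 6: {}, 7: {}}
        eps_free, _ = segment_days(days, missing_rule="free")
        eps_pause, _ = segment_days(days, missing_rule="pause")
        assert len(eps_free) == 2      # missing days tick the counter
        assert len(eps_pause) == 1     # counter paused over missing days

    @pytest.mark.parametrize("gap", [0, 1, 2, 3, 4, 6])
    def test_gap_threshold_merges_or_splits(self, gap):
        days = {0: {"fever": 1}}
        days[1 + gap] = {"fever": 1}
        for d in range(1, 1 + gap):
            days[d] = {}
        for d in range(2 + gap, 6 + gap):
            days[d] = {}
        eps, _ = segment_days(days)
        if gap >= 3:
            assert len(eps) == 2
        else:
            assert len(eps) == 1
            assert eps.iloc[0].duration_days == gap + 2

    def test_unsorted_duplicate_days_rejected(self):
        diary = diary_from_days({0: {}, 1: {}})
        dup = pd.concat([diary, diary.iloc[[1]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            segment_episodes(dup, ["A"], ObservationWindow(0, 1))


class TestOracleEquivalence:
    """The single-pass engine must agree exactly with the quadratic re-scan."""

    @pytest.mark.parametrize("missing_rule", ["free", "pause"])
    def test_random_diaries_match_bruteforce(self, missing_rule):
        rng = np.random.default_rng(42)
        n_children, n_days = 300, 60
        frames, class_lists = [], {}
        for i in range(n_children):
            cid = f"K{i:04d}"
            days = random_symptom_diary(rng, n_days=n_days, p_missing=0.1)
            frames.append(diary_from_days(
                {d: f for d, f in days.items() if f is not None}, child_id=cid))
            class_lists[cid] = [
                oracle_classify(None if days[d] is None
                                else {k for k, v in days[d].items() if v})
                for d in range(n_days)]
        diary = pd.concat(frames, ignore_index=True)
        window = ObservationWindow(0, n_days - 1)
        child_ids = sorted(class_lists)
        episodes, orphans = segment_episodes(diary, child_ids, window, missing_rule)

        for cid in child_ids:
            exp_eps, exp_orphans = oracle_segment(class_lists[cid], missing_rule)
            got = episodes.loc[episodes["child_id"] == cid]
            got_tuples = [tuple(r) for r in got[
                ["start_day", "last_symptom_day", "trigger", "censored",
                 "n_symptom_days"]].itertuples(index=False)]
            assert got_tuples == exp_eps, f"mismatch for {cid}"
            got_orphans = orphans.loc[orphans["child_id"] == cid,
                                      "day_of_life"].tolist()
            assert got_orphans == exp_orphans, f"orphan mismatch for {cid}"

    def test_every_symptomatic_day_attributed_exactly_once(self):
        rng = np.random.default_rng(7)
        days = random_symptom_diary(rng, n_days=200, p_symptom=0.2)
        present = {d: f for d, f in days.items() if f is not None}
        diary = diary_from_days(present)
        window = ObservationWindow(0, 199)
        episodes, orphans = segment_episodes(diary, ["A"], window)
        symptomatic = {d for d, f in present.items() if f}
        in_eps = set()
        for ep in episodes.itertuples():
            span = set(range(ep.start_day, ep.last_symptom_day + 1))
            assert not (span & in_eps), "episodes overlap"
            in_eps |= span
        orphan_days = set(orphans["day_of_life"])
        assert orphan_days.isdisjoint(in_eps)
        assert symptomatic <= (in_eps | orphan_days)
        assert orphan_days <= symptomatic

    def test_determinism(self):
        rng = np.random.default_rng(3)
        days = random_symptom_diary(rng, n_days=80)
        present = {d: f for d, f in days.items() if f is not None}
        diary = diary_from_days(present)
        window = ObservationWindow(0, 79)
        out1 = segment_episodes(diary, ["A"], window)
        out2 = segment_episodes(diary, ["A"], window)
        pd.testing.assert_frame_equal(out1[0], out2[0])
        pd.testing.assert_frame_equal(out1[1], out2[1])


class TestEpisodeSummaries:
    def test_counts_assigned_by_start_day(self):
        eps = pd.DataFrame({
            "child_id": ["A", "A"], "start_day": [10, 400],
            "last_symptom_day": [12, 405], "duration_days": [3, 6],
            "trigger": [TRIGGER_A] * 2, "censored": [False] * 2,
            "n_symptom_days": [3, 6]})
        counts = episodes_per_child(eps, ["A", "B"])
        assert counts.loc["A", "0-12 months"] == 1
        assert counts.loc["A", "13-24 months"] == 1
        assert counts.loc["A", "0-24 months"] == 2
        assert (counts.loc["B"] == 0).all()

    def test_stratum_counts_sum_to_total(self, small_cohort):
        _, covariates, diary, _ = small_cohort
        child_ids = sorted(covariates.index)
        episodes, _ = segment_episodes(diary, child_ids)
        counts = episodes_per_child(episodes, child_ids)
        six_month = counts[["0-6 months", "7-12 months",
                            "13-18 months", "19-24 months"]].sum(axis=1)
        yearly = counts[["0-12 months", "13-24 months"]].sum(axis=1)
        assert (six_month == counts["0-24 months"]).all()
        assert (yearly == counts["0-24 months"]).all()

    def test_age_at_first_episode_is_minimum_start(self):
        eps = pd.DataFrame({
            "child_id": ["A", "A"], "start_day": [200, 91],
            "last_symptom_day": [205, 95], "duration_days": [6, 5],
            "trigger": [TRIGGER_A] * 2, "censored": [False] * 2,
            "n_symptom_days": [6, 5]})
        first = age_at_first_episode(eps, ["A", "B"])
        assert first["A"] == 91
        assert np.isnan(first["B"])     # zero episodes -> censored

    def test_cohort_median_first_episode_matches_sort_and_pick(self, small_cohort):
        _, covariates, diary, _ = small_cohort
        child_ids = sorted(covariates.index)
        episodes, _ = segment_episodes(diary, child_ids)
        first = age_at_first_episode(episodes, child_ids).dropna()
        expected = float(np.median(sorted(
            episodes.groupby("child_id")["start_day"].min())))
        assert first.median() == expected

    @pytest.mark.parametrize("durations, expected", [
        ([3, 3, 3], {"mean": 3.0, "sd": 0.0, "median": 3.0}),
        ([2, 4], {"mean": 3.0, "median": 3.0, "q1": 2.5, "q3": 3.5}),
    ])
    def test_duration_summary_statistics(self, durations, expected):
        eps = pd.DataFrame({
            "child_id": ["A"] * len(durations),
            "start_day": range(0, 20 * len(durations), 20),
            "last_symptom_day": [0] * len(durations),
            "duration_days": durations,
            "trigger": [TRIGGER_A] * len(durations),
            "censored": [False] * len(durations),
            "n_symptom_days": durations})
        out = duration_summary(eps)
        for key, val in expected.items():
            assert out[key] == pytest.approx(val)

    def test_duration_summary_matches_numpy_oneliner(self, small_cohort):
        _, covariates, diary, _ = small_cohort
        episodes, _ = segment_episodes(diary, sorted(covariates.index))
        out = duration_summary(episodes, level="episode")
        x = episodes["duration_days"].to_numpy(float)
        assert out["mean"] == pytest.approx(x.mean())
        assert out["sd"] == pytest.approx(x.std(ddof=1))
        assert out["median"] == pytest.approx(np.median(x))
        assert out["q1"] == pytest.approx(np.quantile(x, 0.25))

    def test_child_mean_level_summarises_per_child_means(self):
        eps = pd.DataFrame({
            "child_id": ["A", "A", "B"], "start_day": [0, 20, 0],
            "last_symptom_day": [1, 21, 9], "duration_days": [2, 4, 10],
            "trigger": [TRIGGER_A] * 3, "censored": [False] * 3,
            "n_symptom_days": [2, 4, 10]})
        out = duration_summary(eps, level="child_mean")
        assert out["n"] == 2
        assert out["mean"] == pytest.approx(np.mean([3.0, 10.0]))
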