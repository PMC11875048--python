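"""Windowed statistics, block segmentation, factorial ANOVA, lick PSTH."""

import numpy as np
import pandas as pd
import pytest

import shiftsim as ss
from shiftsim import analysis as an
from shiftsim.core import EventRecord
from oracles import (
    brute_moving_accuracy,
    brute_trials_to_criterion,
    make_trial,
    random_outcome_trials,
)


class TestMovingAccuracy:
    def test_all_correct_is_constant_one_from_first_full_window(self):
        trials = [make_trial(i, correct=True) for i in range(1, 41)]
        acc = an.moving_accuracy(trials, 20)
        assert np.isnan(acc[:19]).all()
        assert (acc[19:] == 1.0).all()

    def test_short_series_is_entirely_undefined(self):
        trials = [make_trial(i, correct=True) for i in range(1, 20)]
        assert np.isnan(an.moving_accuracy(trials, 20)).all()

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            trials = random_outcome_trials(rng, n_max=200)
            w = int(rng.integers(1, 40))
            np.testing.assert_array_equal(
                an.moving_accuracy(trials, w), brute_moving_accuracy(trials, w))


class TestTrialsToCriterion:
    CRIT = ss.CriterionSpec(accuracy_threshold=0.8, accuracy_window=20)

    def test_twenty_straight_corrects_reach_at_twenty(self):
        trials = [make_trial(i, correct=True) for i in range(1, 21)]
        assert an.trials_to_criterion(trials, self.CRIT) == 20

    def test_chance_performance_never_reaches(self):
        trials = [make_trial(i, correct=bool(i % 2)) for i in range(1, 41)]
        assert an.trials_to_criterion(trials, self.CRIT) is None

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            trials = random_outcome_trials(rng, n_max=200)
            w = int(rng.integers(1, 40))
            crit = ss.CriterionSpec(accuracy_threshold=0.8, accuracy_window=w)
            assert an.trials_to_criterion(trials, crit) == \
                brute_trials_to_criterion(trials, w, 0.8)


class TestSegmentBlocks:
    def _switch(self, at, t=0):
        return EventRecord(t, "rule_switch", {"trial": at, "shift_type": "EDS"})

    def test_no_switches_is_one_block(self):
        trials = [make_trial(i, correct=True) for i in range(1, 11)]
        blocks = an.segment_blocks(trials, [])
        assert len(blocks) == 1 and len(blocks[0].trials) == 10
        assert blocks[0].ended_by is None

    def test_switches_partition_the_session(self):
        trials = [make_trial(i, correct=True) for i in range(1, 121)]
        blocks = an.segment_blocks(trials, [self._switch(40), self._switch(90)])
        assert [len(b.trials) for b in blocks] == [40, 50, 30]
        assert [b.start_trial for b in blocks] == [1, 41, 91]
        assert [b.ended_by for b in blocks] == ["EDS", "EDS", None]

    def test_switch_at_trial_zero_is_an_error(self):
        trials = [make_trial(1, correct=True)]
        with pytest.raises(ValueError, match="nonexistent"):
            an.segment_blocks(trials, [self._switch(0)])


def _labeled_trial(i, correct, congruent, modality):
    t = make_trial(i, correct=correct)
    t.congruent = congruent
    t.whisker_stim, t.odor_stim = "W1", "O1"
    t.relevant_modality = ss.Modality(modality)
    return t


def _session_with_switches(per_block=20, n_blocks=4, correct=lambda i, b: True):
    trials, events, idx = [], [], 0
    for b in range(n_blocks):
        modality = "whisker" if b % 2 == 0 else "odor"
        for j in range(per_block):
            idx += 1
            trials.append(_labeled_trial(idx, correct(j, b), congruent=(j % 2 == 0),
                                         modality=modality))
        if b < n_blocks - 1:
            events.append(EventRecord(0, "rule_switch",
                                      {"trial": idx, "shift_type": "EDS"}))
    return trials, events


class TestSwitchAligned:
    def test_all_correct_log_has_unit_cell_means(self):
        trials, events = _session_with_switches()
        blocks = an.segment_blocks(trials, events)
        summary = an.switch_aligned([blocks])
        assert (summary.cell_table["mean"] == 1.0).all()
        assert np.nanmax(summary.mean_accuracy) == 1.0
        assert summary.cell_table["n"].sum() == len(an.periswitch_table([blocks]))

    def test_no_switches_is_an_error(self):
        trials = [make_trial(i, correct=True) for i in range(1, 11)]
        blocks = an.segment_blocks(trials, [])
        with pytest.raises(ValueError):
            an.switch_aligned([blocks])

    def test_perseverative_cohort_shows_post_switch_incongruent_dip(self):
        # saturated, lapse-free, whisker-attending agents: pre-switch accuracy 1;
        # right after EDS, incongruent trials are wrong with certainty
        rule = ss.default_rule()
        agent = ss.make_saturated_agent(rule, lapse=0.0)
        post = ss.apply_shift(rule, "EDS").rule_after
        rng = np.random.default_rng(0)
        trials, events, idx = [], [], 0
        for j in range(20):  # pre-switch block, whisker rule
            idx += 1
            side = ss.Side.LEFT if rng.random() < 0.5 else ss.Side.RIGHT
            w, o, cong = ss.compose_trial(rule, side, rng)
            resp, _ = agent.choose(w, o, rng)
            t = make_trial(idx, correct=(resp is side), side=side)
            t.congruent, t.relevant_modality = cong, ss.Modality.WHISKER
            trials.append(t)
        events.append(EventRecord(0, "rule_switch", {"trial": idx, "shift_type": "EDS"}))
        for j in range(10):  # post-switch block, odor rule, no relearning
            idx += 1
            side = ss.Side.LEFT if rng.random() < 0.5 else ss.Side.RIGHT
            w, o, cong = ss.compose_trial(post, side, rng)
            resp, _ = agent.choose(w, o, rng)
            t = make_trial(idx, correct=(resp is side), side=side)
            t.congruent, t.relevant_modality = cong, ss.Modality.ODOR
            trials.append(t)
        summary = an.switch_aligned([an.segment_blocks(trials, events)])
        cells = summary.cell_table.set_index(["modality", "congruency", "timing"])
        assert cells.loc[("whisker", "congruent", "pre"), "mean"] == 1.0
        assert cells.loc[("whisker", "incongruent", "pre"), "mean"] == 1.0
        assert cells.loc[("odor", "incongruent", "post"), "mean"] == 0.0
        assert cells.loc[("odor", "congruent", "post"), "mean"] == 1.0


def _balanced_toy_table(reps=4):
    """Hand-enumerable balanced 2x2x2 dataset with known cell means."""
    rows = []
    cell_means = {
        ("whisker", "congruent", "pre"): 1.00,
        ("whisker", "congruent", "post"): 0.75,
        ("whisker", "incongruent", "pre"): 0.75,
        ("whisker", "incongruent", "post"): 0.25,
        ("odor", "congruent", "pre"): 1.00,
        ("odor", "congruent", "post"): 0.50,
        ("odor", "incongruent", "pre"): 0.75,
        ("odor", "incongruent", "post"): 0.00,
    }
    for (m, c, ti), mean in cell_means.items():
        n_correct = int(round(mean * reps))
        for k in range(reps):
            rows.append({"offset": 0, "correct": 1 if k < n_correct else 0,
                         "modality": m, "congruency": c, "timing": ti})
    return pd.DataFrame(rows)


def _hand_anova(df):
    """From-scratch balanced three-way ANOVA (pairwise interactions)."""
    y = df["correct"].to_numpy(float)
    n = len(y)
    codes = {
        "modality": np.where(df["modality"] == "whisker", 1.0, -1.0),
        "congruency": np.where(df["congruency"] == "congruent", 1.0, -1.0),
        "timing": np.where(df["timing"] == "pre", 1.0, -1.0),
    }
    ss_ = {}
    for name, x in codes.items():
        ss_[name] = n * np.mean(y * x) ** 2
    for a, b in (("modality", "congruency"), ("modality", "timing"),
                 ("congruency", "timing")):
        x = codes[a] * codes[b]
        ss_[f"{a}:{b}"] = n * np.mean(y * x) ** 2
    # residual: within-cell + the omitted three-way term
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_resid = ss_total - sum(ss_.values())
    return ss_, ss_resid


class TestPeriswitchAnova:
    def test_matches_hand_computation_on_balanced_table(self):
        df = _balanced_toy_table(reps=4)
        result = an.periswitch_anova(df).table
        ss_hand, ss_resid = _hand_anova(df)
        for effect, expected in ss_hand.items():
            got = result.loc[effect, "ss"]
            assert got == pytest.approx(expected, rel=1e-6), effect
        assert result.loc["Residual", "ss"] == pytest.approx(ss_resid, rel=1e-6)
        df_resid = result.loc["Residual", "df"]
        assert df_resid == len(df) - 7  # grand mean + 6 effect df
        # F statistics follow from the same quantities
        for effect, expected in ss_hand.items():
            f_hand = expected / (ss_resid / df_resid)
            assert result.loc[effect, "F"] == pytest.approx(f_hand, rel=1e-6)

    def test_missing_factor_level_is_named(self):
        df = _balanced_toy_table()
        df = df[df["modality"] == "whisker"]
        with pytest.raises(ValueError, match="modality"):
            an.periswitch_anova(df)

    def test_programmed_effects_are_detected_and_null_modality_is_not(self):
        rng = np.random.default_rng(1)
        rows = []
        p_cell = {("congruent", "pre"): 0.95, ("congruent", "post"): 0.70,
                  ("incongruent", "pre"): 0.85, ("incongruent", "post"): 0.45}
        for m in ("whisker", "odor"):
            for (c, ti), p in p_cell.items():
                for _ in range(120):
                    rows.append({"offset": 0, "correct": int(rng.random() < p),
                                 "modality": m, "congruency": c, "timing": ti})
        res = an.periswitch_anova(pd.DataFrame(rows))
        assert res.p("congruency") < 0.05
        assert res.p("timing") < 0.05
        assert res.p("modality") > 0.05

    def test_posthoc_bonferroni_orders_extreme_cells(self):
        df = _balanced_toy_table(reps=8)
        post = an.posthoc_bonferroni(df)
        assert len(post) == 28  # all pairs of 8 cells
        assert (post["p_bonferroni"] >= post["p_raw"] - 1e-15).all()


class TestLickPsth:
    def _events_with_licks(self, rate_hz=8.0, n_trials=20):
        events = []
        period = 1000.0 / rate_hz
        t = 0
        for i in range(n_trials):
            events.append(EventRecord(t, "trial_start", {"trial": i + 1}))
            events.append(EventRecord(t + 3000, "response_window_on", {}))
            k = 1
            while 500 + k * period < 3000 + 500:
                events.append(EventRecord(t + 500 + int(k * period), "lick_left", {}))
                k += 1
            events.append(EventRecord(t + 4000, "trial_end", {"trial": i + 1}))
            t += 10_000
        return events

    def test_steady_licking_recovers_the_rate(self):
        events = self._events_with_licks(rate_hz=8.0)
        psth = an.lick_psth(events, align_to="response_window_on",
                            bin_ms=250, window=(-2000, 0))
        assert np.mean(psth["left"]) == pytest.approx(8.0, rel=0.05)
        assert (psth["right"] == 0).all()

    def test_counts_are_conserved(self):
        events = self._events_with_licks()
        psth = an.lick_psth(events, bin_ms=100, window=(-2500, 500))
        anchors = [e.t_ms for e in events if e.kind == "response_window_on"]
        licks = [e.t_ms for e in events if e.kind == "lick_left"]
        expected = sum(1 for a in anchors for t in licks if -2500 <= t - a < 500)
        total = psth["left"].sum() * len(anchors) * 0.1
        assert total == pytest.approx(expected)

    def test_no_alignment_events_is_an_error(self):
        with pytest.raises(ValueError, match="alignment"):
            an.lick_psth([], align_to="response_window_on")


class TestSessionSummary:
    def test_empty_input_gives_empty_table(self):
        assert an.session_summary([]).empty

    def test_hand_counted_sessions(self, seds_config):
        agent = ss.make_agent(satiety_trials=80.0, lapse=0.05)
        log = ss.run_seds_session(seds_config, ss.default_rule(), agent,
                                  rng=np.random.default_rng(4))
        row = an.session_summary([log]).iloc[0]
        assert row["n_trials"] == len(log.trials)
        assert row["n_response"] == sum(1 for t in log.trials if t.responded)
        assert row["n_rewarded"] == sum(1 for t in log.trials if t.rewarded)
        assert row["total_volume_ul"] == log.total_volume_ul
        assert row["n_blocks"] == len(log.shifts) + 1

    def test_analyses_are_pure(self, seds_config, learner):
        log = ss.run_seds_session(seds_config, ss.default_rule(), learner,
                                  rng=np.random.default_rng(5))
        blocks = an.segment_blocks(log.trials, log.events)
        t1 = an.periswitch_table([blocks])
        t2 = an.periswitch_table([blocks])
        pd.testing.assert_frame_equal(t1, t2)
        a1 = an.periswitch_anova(t1).table
        a2 = an.periswitch_anova(t2).table
        pd.testing.assert_frame_equal(a1, a2)
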