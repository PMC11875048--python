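"""Agent choice model, learning dynamics, cohorts, and grid fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shiftsim as ss
from shiftsim.agent import agent_choose, fit_agent, generate_cohort
from oracles import make_trial


def _logistic(x):
    return 1.0 / (1.0 + math.exp(-x))


class TestChoice:
    def test_saturated_left_association_yields_left(self, rng):
        agent = ss.make_agent(inv_temp=60.0, lapse=0.0, p_respond=1.0,
                              satiety_trials=float("inf"))
        agent.assoc["W1"] = -1.0
        agent.attn_whisker = 1.0
        for _ in range(200):
            side, _ = agent_choose(agent, "W1", None, rng)
            assert side is ss.Side.LEFT

    def test_pure_lapse_is_a_fair_coin(self, rng):
        agent = ss.make_agent(lapse=1.0, p_respond=1.0, satiety_trials=float("inf"))
        n = 10_000
        rights = sum(agent_choose(agent, "W1", None, rng)[0] is ss.Side.RIGHT
                     for _ in range(n))
        assert abs(rights / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_lapse_mixture_matches_closed_form(self, rng):
        # lapse 0.2, inv_temp 2, evidence pinned at +1, no side bias
        agent = ss.make_agent(lapse=0.2, inv_temp=2.0, p_respond=1.0,
                              satiety_trials=float("inf"))
        agent.assoc["W1"] = 1.0
        agent.attn_whisker = 1.0
        expected = 0.2 * 0.5 + 0.8 * _logistic(2.0)
        n = 10_000
        rights = sum(agent_choose(agent, "W1", None, rng)[0] is ss.Side.RIGHT
                     for _ in range(n))
        assert abs(rights / n - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_no_stimulus_is_rejected(self, rng):
        agent = ss.make_agent()
        with pytest.raises(ValueError):
            agent_choose(agent, None, None, rng)

    def test_interlick_interval_matches_lick_rate(self, rng):
        agent = ss.make_agent(p_respond=1.0, lapse=0.0, satiety_trials=float("inf"))
        intervals = []
        for _ in range(200):
            _, licks = agent_choose(agent, "W1", None, rng)
            anticipatory = [t for t, _ in licks[:-1]]
            intervals += [b - a for a, b in zip(anticipatory, anticipatory[1:])]
        mean_ili = np.mean(intervals)
        assert abs(mean_ili - 1000 / 8.0) <= 0.1 * (1000 / 8.0)


class TestLearning:
    def test_repeated_left_rewards_drive_association_to_minus_one(self):
        agent = ss.make_agent(assoc_lr=0.2)
        values = []
        for i in range(1, 40):
            t = make_trial(i, correct=True, side=ss.Side.LEFT)
            t.whisker_stim = "W1"
            agent.update(t)
            values.append(agent.assoc["W1"])
        assert all(b <= a for a, b in zip(values, values[1:]))  # monotone toward -1
        assert values[-1] == pytest.approx(-1.0, abs=1e-3)

    def test_zero_learning_rates_leave_state_unchanged(self):
        agent = ss.make_agent(assoc_lr=0.0, attn_lr=0.0)
        agent.assoc["W1"] = 0.3
        agent.attn_whisker = 0.7
        t = make_trial(1, correct=True, side=ss.Side.RIGHT)
        t.whisker_stim, t.odor_stim = "W1", "O1"
        agent.update(t)
        assert agent.assoc["W1"] == 0.3 and agent.attn_whisker == 0.7

    def test_no_response_trials_do_not_teach(self):
        agent = ss.make_agent()
        t = make_trial(1, correct=None)
        t.whisker_stim = "W1"
        agent.update(t)
        assert "W1" not in agent.assoc

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()),
                    min_size=1, max_size=60))
    def test_strengths_and_attention_stay_bounded(self, outcomes):
        agent = ss.make_agent(assoc_lr=0.5, attn_lr=0.5)
        for i, (corr, right, compound) in enumerate(outcomes, start=1):
            side = ss.Side.RIGHT if right else ss.Side.LEFT
            t = make_trial(i, correct=corr, side=side)
            t.whisker_stim = "W1"
            t.odor_stim = "O1" if compound else None
            agent.update(t)
            assert all(-1.0 <= v <= 1.0 for v in agent.assoc.values())
            assert 0.0 <= agent.attn_whisker <= 1.0


class TestSaturatedAgentClosedForms:
    """The saturated agent has closed-form accuracy on labeled trials."""

    def _accuracies(self, lapse, n=4000, seed=0):
        rule = ss.default_rule()
        rng = np.random.default_rng(seed)
        agent = ss.make_saturated_agent(rule, lapse=lapse)
        post_eds = ss.apply_shift(rule, "EDS").rule_after
        cong = incong = 0
        for _ in range(n):
            side = ss.Side.LEFT if rng.random() < 0.5 else ss.Side.RIGHT
            w = rule.exemplar_for_side(ss.Modality.WHISKER, side)
            o = rule.exemplar_for_side(ss.Modality.ODOR, side)
            resp, _ = agent.choose(w, o, rng)
            cong += resp is side
            # post-EDS incongruent: odor now leads, whisker points the other way
            side2 = ss.Side.LEFT if rng.random() < 0.5 else ss.Side.RIGHT
            o2 = post_eds.exemplar_for_side(ss.Modality.ODOR, side2)
            w2 = post_eds.exemplar_for_side(ss.Modality.WHISKER, side2.other)
            resp2, _ = agent.choose(w2, o2, rng)
            incong += resp2 is side2
        return cong / n, incong / n

    @pytest.mark.parametrize("lapse", [0.0, 0.3])
    def test_congruent_and_perseverative_accuracy(self, lapse):
        n = 4000
        cong, incong = self._accuracies(lapse, n=n)
        se = np.sqrt(max(lapse / 2 * (1 - lapse / 2), 1e-12) / n)
        assert abs(cong - (1 - lapse / 2)) <= 3 * se + 1e-12
        assert abs(incong - lapse / 2) <= 3 * se + 1e-12


class TestCohort:
    def test_cohort_is_reproducible(self):
        a = generate_cohort(2, sessions_per_agent=1, seed=5,
                            param_ranges={"satiety_trials": (80.0, 120.0)})
        b = generate_cohort(2, sessions_per_agent=1, seed=5,
                            param_ranges={"satiety_trials": (80.0, 120.0)})
        assert [p for p, _ in a] == [p for p, _ in b]
        assert [logs for _, logs in a] == [logs for _, logs in b]

    def test_moderate_learners_switch_at_least_once(self):
        cohort = generate_cohort(
            3, sessions_per_agent=1, seed=11,
            param_ranges={
                "assoc_lr": (0.15, 0.2), "inv_temp": (4.0, 5.0),
                "lapse": (0.02, 0.05), "side_bias": (-0.1, 0.1),
                "p_respond": (0.95, 0.98), "satiety_trials": (200.0, 250.0),
            },
        )
        for _, logs in cohort:
            assert all(len(log.shifts) >= 1 for log in logs)

    def test_unknown_parameter_range_is_an_error(self):
        with pytest.raises(ValueError, match="whiskers"):
            generate_cohort(1, param_ranges={"whiskers": (0, 1)})


class TestFitAgent:
    def _simulate(self, params, n_sessions=2, seed=0):
        agent = ss.AgentState(params=params, attn_whisker=params.attn_whisker0)
        cfg = ss.default_config("SEDS")
        logs = []
        for k in range(n_sessions):
            logs.append(ss.run_seds_session(
                cfg, ss.default_rule(), agent, rng=np.random.default_rng([seed, k])))
        return logs

    def test_singleton_grid_returns_that_point(self):
        params = ss.AgentParams(lapse=0.1, satiety_trials=300.0)
        logs = self._simulate(params, n_sessions=2)
        best, ll = fit_agent(logs, {"lapse": [0.1]}, base_params=params)
        assert best == {"lapse": 0.1} and np.isfinite(ll)

    def test_insufficient_response_trials_is_an_error(self):
        params = ss.AgentParams(satiety_trials=40.0)
        logs = self._simulate(params, n_sessions=1)
        with pytest.raises(ValueError, match="insufficient"):
            fit_agent(logs, {"lapse": [0.0, 0.1]}, base_params=params)

    def test_empty_grid_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            fit_agent([], {})

    def test_recovers_lapse_and_initial_attention(self):
        # static-attention regime: with a slow association rate both
        # modalities' strengths stay expressed, so the weight is identifiable
        true = ss.AgentParams(lapse=0.10, attn_whisker0=0.8, inv_temp=3.0,
                              assoc_lr=0.04, attn_lr=0.0, p_respond=0.97,
                              satiety_trials=1100.0)
        logs = self._simulate(true, n_sessions=2, seed=1)
        n_resp = sum(1 for log in logs for t in log.trials if t.responded)
        assert n_resp >= 2000
        grid = {
            "lapse": [0.0, 0.05, 0.10, 0.15, 0.20, 0.30],
            "attn_whisker0": [0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
            "inv_temp": [1.5, 3.0, 6.0],
        }
        best, _ = fit_agent(logs, grid, base_params=true)
        assert abs(best["lapse"] - 0.10) <= 0.1
        assert abs(best["attn_whisker0"] - 0.8) <= 0.1
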