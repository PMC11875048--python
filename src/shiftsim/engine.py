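"""Discrete-event trial and session engine.

Runs single trials and whole sessions as a deterministic (given seed)
simulation on an integer-millisecond clock.  A task trial unfolds as

    trial_start -> tone (tone_ms) -> stimulus epoch (stim_ms, whisker and/or
    odor; odor reaches the nose odor_onset_latency_ms after the valve command)
    -> response window (response_window_ms) -> reward / omission -> trial_end,

with the tone and stimulus sequential, so the response window opens exactly
``tone_ms + stim_ms`` after trial start.  Licks during the stimulus epoch are
recorded (anticipatory licking) but never rewarded; only response-window licks
enter the reward rule.  Reward is delivered at the time of the qualifying lick
and the trial then proceeds straight to the ITI.

Habituation trials (HB1-HB3B) have no onset tone or discriminative stimulus:
an armed spout waits through a response window, a lick to the armed side is
rewarded (reinforced by a 500 ms tone), and HB3B inserts a brief whisker flash
between the qualifying lick and the water.

Bookkeeping events whose natural time falls after ``trial_end`` (passive odor
clearing, the habituation reinforcement-tone offset) are emitted into the
session's flat event stream during the ITI rather than into the trial's own
event list, so that no trial event follows its ``trial_end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agent import AgentState
from .core import (
    HABITUATION_STAGES,
    EventRecord,
    Modality,
    RuleState,
    SessionConfig,
    Side,
    TrialRecord,
    validate_config,
)

__all__ = [
    "TrialSpec",
    "SessionLog",
    "SatietyError",
    "apply_reward_rule",
    "run_trial",
    "run_session",
    "schedule_pulse_train",
    "REWARD_RULE_BY_STAGE",
]

# SH4 and everything before it reward any response-window lick to the correct
# side; from SH5 onward the *first* lick must be correct.
REWARD_RULE_BY_STAGE = {
    "HB1": "any_correct_lick",
    "HB2": "any_correct_lick",
    "HB3": "any_correct_lick",
    "HB3B": "any_correct_lick",
    "SH4": "any_correct_lick",
    "SH5": "first_lick_correct",
    "SD": "first_lick_correct",
    "CD": "first_lick_correct",
    "SEDS": "first_lick_correct",
}


class SatietyError(RuntimeError):
    """Raised when a trial is requested from a satiated agent."""


@dataclass
class TrialSpec:
    """What the controller asks the engine to run: stimuli and armed side."""

    trial_index: int
    stage_id: str
    rewarded_side: Side
    whisker_stim: Optional[str] = None
    odor_stim: Optional[str] = None
    congruent: Optional[bool] = None


@dataclass
class SessionLog:
    """One session: configuration, per-trial records, flat event stream."""

    config: SessionConfig
    trials: list = field(default_factory=list)
    events: list = field(default_factory=list)
    total_volume_ul: float = 0.0
    terminated_by: str = "manual"
    shifts: list = field(default_factory=list)  # ShiftEvents, SEDS sessions only

    def trials_frame(self) -> pd.DataFrame:
        """Per-trial table (events omitted), one row per trial."""
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "trial_index": t.trial_index,
                    "stage_id": t.stage_id,
                    "whisker_stim": t.whisker_stim,
                    "odor_stim": t.odor_stim,
                    "rewarded_side": t.rewarded_side.value,
                    "congruent": t.congruent,
                    "first_response": t.first_response.value if t.responded else None,
                    "correct": t.correct,
                    "rewarded": t.rewarded,
                    "reward_volume_ul": t.reward_volume_ul,
                    "iti_ms": t.iti_ms,
                    "relevant_modality": t.relevant_modality.value,
                    "block_index": t.block_index,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "trial_index",
                "stage_id",
                "whisker_stim",
                "odor_stim",
                "rewarded_side",
                "congruent",
                "first_response",
                "correct",
                "rewarded",
                "reward_volume_ul",
                "iti_ms",
                "relevant_modality",
                "block_index",
            ],
        )


def apply_reward_rule(
    stage_id: str,
    licks_in_window: Sequence,
    rewarded_side: Side,
):
    """Map response-window licks to ``(first_response, correct, rewarded)``.

    ``licks_in_window`` is a time-sorted sequence of ``(t, Side)`` restricted
    to the response window.  Under ``any_correct_lick`` (through SH4) a lick
    to the rewarded side triggers reward even after an incorrect lick; under
    ``first_lick_correct`` (SH5 onward) the first lick decides.
    """
    rule = REWARD_RULE_BY_STAGE.get(stage_id)
    if rule is None:
        raise ValueError(f"unknown stage for reward rule: {stage_id!r}")
    if not licks_in_window:
        return None, None, False
    first = licks_in_window[0][1]
    correct = first is rewarded_side
    if rule == "any_correct_lick":
        rewarded = any(side is rewarded_side for _, side in licks_in_window)
    else:
        rewarded = correct
    return first, correct, rewarded


def _qualifying_lick_time(stage_id, licks_in_window, rewarded_side):
    rule = REWARD_RULE_BY_STAGE[stage_id]
    if rule == "any_correct_lick":
        for t, side in licks_in_window:
            if side is rewarded_side:
                return t
        return None
    t, side = licks_in_window[0]
    return t if side is rewarded_side else None


def run_trial(
    spec: TrialSpec,
    rule: RuleState,
    agent: AgentState,
    config: SessionConfig,
    rng: np.random.Generator,
    t0: int = 0,
    enforce_satiety: bool = True,
) -> TrialRecord:
    """Run one trial starting at session time ``t0``; returns its record.

    Refuses to run a satiated agent (the caller must end the session).
    """
    if enforce_satiety and agent.satiated:
        raise SatietyError("agent is satiated; end the session")
    record, _deferred, _t_end = _run_trial_internal(spec, rule, agent, config, rng, t0)
    return record


def _run_trial_internal(spec, rule, agent, config, rng, t0):
    """Full trial simulation; also returns deferred events and the end time."""
    if spec.stage_id in HABITUATION_STAGES:
        return _run_habituation_trial(spec, agent, config, rng, t0)
    return _run_task_trial(spec, rule, agent, config, rng, t0)


def _run_task_trial(spec, rule, agent, config, rng, t0):
    ev = [EventRecord(t0, "trial_start", {"trial": spec.trial_index, "side": spec.rewarded_side.short})]
    deferred = []
    stim_on = t0 + config.tone_ms
    rw_on = stim_on + config.stim_ms
    ev.append(EventRecord(t0, "tone_on", {}))
    ev.append(EventRecord(stim_on, "tone_off", {}))
    if spec.whisker_stim is not None:
        ev.append(EventRecord(stim_on, "whisker_on", {"exemplar": spec.whisker_stim}))
    if spec.odor_stim is not None:
        ev.append(EventRecord(stim_on, "odor_command_on", {"exemplar": spec.odor_stim}))
        ev.append(EventRecord(stim_on + config.odor_onset_latency_ms, "odor_nose_on", {"exemplar": spec.odor_stim}))
    ev.append(EventRecord(rw_on, "response_window_on", {}))
    response, licks = agent.choose(
        spec.whisker_stim,
        spec.odor_stim,
        rng,
        stim_ms=config.stim_ms,
        response_window_ms=config.response_window_ms,
    )
    window_licks = []
    for off, side in licks:
        t = stim_on + off
        if rw_on <= t < rw_on + config.response_window_ms:
            window_licks.append((t, side))
    first, correct, rewarded = apply_reward_rule(spec.stage_id, window_licks, spec.rewarded_side)
    if rewarded:
        t_reward = _qualifying_lick_time(spec.stage_id, window_licks, spec.rewarded_side)
        ev.append(
            EventRecord(
                t_reward,
                f"reward_{spec.rewarded_side.value}",
                {"volume_ul": config.droplet_ul},
            )
        )
        t_end = t_reward
    elif first is None:
        t_end = rw_on + config.response_window_ms
        ev.append(EventRecord(t_end, "omission", {}))
    else:
        t_end = rw_on + config.response_window_ms
    # licks are logged up to trial_end (a rewarded trial proceeds straight to ITI)
    for off, side in licks:
        t = stim_on + off
        if t <= t_end:
            ev.append(EventRecord(t, f"lick_{side.value}", {}))
    if spec.whisker_stim is not None:
        ev.append(EventRecord(min(stim_on + config.stim_ms, t_end), "whisker_off", {"exemplar": spec.whisker_stim}))
    if spec.odor_stim is not None:
        deferred.append(
            EventRecord(
                stim_on + config.stim_ms + config.odor_clear_ms,
                "odor_off",
                {"exemplar": spec.odor_stim, "trial": spec.trial_index, "deferred": 1},
            )
        )
    ev.append(EventRecord(t_end, "trial_end", {"trial": spec.trial_index}))
    ev.sort(key=lambda e: e.t_ms)
    record = TrialRecord(
        trial_index=spec.trial_index,
        stage_id=spec.stage_id,
        rewarded_side=spec.rewarded_side,
        whisker_stim=spec.whisker_stim,
        odor_stim=spec.odor_stim,
        congruent=spec.congruent,
        events=ev,
        first_response=first,
        correct=correct,
        rewarded=rewarded,
        reward_volume_ul=config.droplet_ul if rewarded else 0.0,
        relevant_modality=rule.relevant_modality,
        block_index=rule.block_index,
    )
    return record, deferred, t_end


def _run_habituation_trial(spec, agent, config, rng, t0):
    """Armed-spout trial: no onset tone, no discriminative stimulus."""
    ev = [EventRecord(t0, "trial_start", {"trial": spec.trial_index, "side": spec.rewarded_side.short})]
    deferred = []
    ev.append(EventRecord(t0, "response_window_on", {}))
    response, licks = agent.choose(
        None, None, rng, stim_ms=0, response_window_ms=config.response_window_ms
    )
    window_licks = []
    for off, side in licks:
        t = t0 + off
        if 0 <= off < config.response_window_ms:
            ev.append(EventRecord(t, f"lick_{side.value}", {}))
            window_licks.append((t, side))
    first, correct, rewarded = apply_reward_rule(spec.stage_id, window_licks, spec.rewarded_side)
    if rewarded:
        t_lick = _qualifying_lick_time(spec.stage_id, window_licks, spec.rewarded_side)
        t_reward = t_lick
        if spec.stage_id == "HB3B":
            lo, hi = config.hb3b_whisker_flash_ms
            flash = int(rng.integers(lo, hi + 1))
            ev.append(EventRecord(t_lick, "whisker_on", {"flash_ms": flash}))
            t_reward = t_lick + flash
            ev.append(EventRecord(t_reward, "whisker_off", {}))
        ev.append(
            EventRecord(t_reward, f"reward_{spec.rewarded_side.value}", {"volume_ul": config.droplet_ul})
        )
        # every water delivery is reinforced by a simultaneous 500 ms tone
        ev.append(EventRecord(t_reward, "tone_on", {}))
        deferred.append(
            EventRecord(t_reward + config.tone_ms, "tone_off", {"trial": spec.trial_index, "deferred": 1})
        )
        t_end = t_reward
    else:
        t_end = t0 + config.response_window_ms
        if first is None:
            ev.append(EventRecord(t_end, "omission", {}))
    ev.append(EventRecord(t_end, "trial_end", {"trial": spec.trial_index}))
    ev.sort(key=lambda e: e.t_ms)
    record = TrialRecord(
        trial_index=spec.trial_index,
        stage_id=spec.stage_id,
        rewarded_side=spec.rewarded_side,
        events=ev,
        first_response=first,
        correct=correct,
        rewarded=rewarded,
        reward_volume_ul=config.droplet_ul if rewarded else 0.0,
        relevant_modality=Modality.WHISKER,
        block_index=0,
    )
    return record, deferred, t_end


def run_session(
    config: SessionConfig,
    rule: RuleState,
    agent: AgentState,
    scheduler,
    rng,
) -> SessionLog:
    """Iterate trials until the first satisfied termination condition.

    ``scheduler`` supplies each trial's stimuli and armed side via
    ``next_trial(trial_index, history, rule, rng) -> TrialSpec`` and may
    implement ``after_trial(record, history, rule, rng)`` returning a
    ShiftEvent when it covertly switches the rule (set-shifting sessions).

    Termination conditions, checked after every trial in order: a run of
    ``no_response_termination`` consecutive no-response trials; the configured
    consumed-volume target; the trial cap; and (habituation) the 2-minute
    no-reward timeout, recorded as ``manual``.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    agent.begin_session(rng)
    iti_lo, iti_hi = config.iti_bounds()
    trials: list = []
    flat: list = []
    deferred_all: list = []
    shifts: list = []
    volume = 0.0
    none_run = 0
    t = 0
    last_reward_t = 0
    terminated_by = "manual"
    while True:
        spec = scheduler.next_trial(len(trials) + 1, trials, rule, rng)
        record, deferred, t_end = _run_trial_internal(spec, rule, agent, config, rng, t)
        record.relevant_modality = rule.relevant_modality
        record.block_index = rule.block_index
        record.iti_ms = int(rng.integers(iti_lo, iti_hi + 1))
        agent.update(record)
        rule.trials_in_block += 1
        trials.append(record)
        flat.extend(record.events)
        deferred_all.extend(deferred)
        volume += record.reward_volume_ul
        if record.rewarded:
            last_reward_t = t_end
        none_run = 0 if record.responded else none_run + 1
        shift = None
        if hasattr(scheduler, "after_trial"):
            shift = scheduler.after_trial(record, trials, rule, rng)
        if shift is not None:
            shifts.append(shift)
            flat.append(
                EventRecord(
                    t_end,
                    "rule_switch",
                    {
                        "trial": record.trial_index,
                        "shift_type": shift.shift_type,
                        "relevant_before": shift.rule_before.relevant_modality.value,
                        "relevant_after": shift.rule_after.relevant_modality.value,
                        **_map_payload("before", shift.rule_before),
                        **_map_payload("after", shift.rule_after),
                    },
                )
            )
        if none_run >= config.no_response_termination:
            terminated_by = "no_response_run"
            break
        if config.volume_pass_ul is not None and volume >= config.volume_pass_ul:
            terminated_by = "volume_target"
            break
        if len(trials) >= config.trial_cap:
            terminated_by = "trial_cap"
            break
        if (
            config.no_reward_timeout_ms is not None
            and t_end - last_reward_t >= config.no_reward_timeout_ms
        ):
            terminated_by = "manual"
            break
        t = t_end + record.iti_ms
    flat.extend(e for e in deferred_all if e.t_ms <= t_end)
    flat.append(EventRecord(t_end, "session_end", {"terminated_by": terminated_by}))
    flat.sort(key=lambda e: e.t_ms)
    return SessionLog(
        config=config,
        trials=trials,
        events=flat,
        total_volume_ul=volume,
        terminated_by=terminated_by,
        shifts=shifts,
    )


def _map_payload(tag: str, rule: RuleState) -> dict:
    out = {}
    for prefix, m in (("w", rule.whisker_map), ("o", rule.odor_map)):
        for ex, side in m.items():
            out[f"{tag}_{prefix}_{ex}"] = side.short
    return out


def schedule_pulse_train(frequency_hz: float, duration_ms: int, pulse_width_ms: int):
    """TTL pulse train for optogenetic stimulation, as (on, off) time pairs.

    Pulses repeat at fixed period ``1000 / frequency_hz`` ms starting at t = 0
    and the train is truncated at ``duration_ms``: a pulse is emitted only if
    it fits entirely within the duration.
    """
    if frequency_hz <= 0:
        raise ValueError("frequency_hz must be positive")
    if pulse_width_ms <= 0:
        raise ValueError("pulse_width_ms must be positive")
    period = 1000.0 / frequency_hz
    if pulse_width_ms >= period:
        raise ValueError(
            f"pulse_width_ms ({pulse_width_ms}) must be shorter than the period ({period:g} ms)"
        )
    pulses = []
    k = 0
    while True:
        onset = k * period
        if onset + pulse_width_ms > duration_ms:
            break
        pulses.append((onset, onset + pulse_width_ms))
        k += 1
    return pulses
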