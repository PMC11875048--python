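"""Set-shifting session control.

Governs the set-shifting task proper: draws reward sides (with optional
lick-bias correction), composes compound whisker+odor stimuli and labels
their congruency, monitors the 80%-in-30-trial trigger, and applies the three
rule transformations —

* **IDS** (intradimensional shift): new exemplars within the relevant modality,
* **Rev** (reversal): the relevant pair's left/right mapping is swapped,
* **EDS** (extradimensional shift): the previously irrelevant modality becomes
  relevant; the latent maps are untouched, so congruency labels are invariant.

Rule switches are covert: the agent receives no cue, only the changed reward
contingency.  A "block" is the run of trials between consecutive switches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .agent import AgentState
from .core import (
    BiasCorrection,
    Modality,
    RuleState,
    SessionConfig,
    Side,
    default_pools,
)
from .engine import SessionLog, TrialSpec, run_session

__all__ = [
    "ShiftEvent",
    "SHIFT_TYPES",
    "p_left_given_history",
    "draw_reward_side",
    "compose_trial",
    "check_switch_trigger",
    "apply_shift",
    "SetShiftController",
    "run_seds_session",
]

SHIFT_TYPES = ("IDS", "Rev", "EDS")


@dataclass
class ShiftEvent:
    """One covert rule switch: the trial it followed and the rule before/after."""

    trial_index: int
    shift_type: str
    rule_before: RuleState
    rule_after: RuleState


def p_left_given_history(recent_responses: Sequence[Side], bias_cfg: BiasCorrection) -> float:
    """Probability of arming the left spout given recent response sides.

    Disabled correction: 0.5.  Enabled: the fraction of *right* responses in
    the window (0.5 when empty), clamped to ``bias_cfg.clamp`` — a side the
    animal favors is armed less often, breaking stereotyped response
    strategies.
    """
    if not bias_cfg.enabled:
        return 0.5
    window = list(recent_responses)[-bias_cfg.window :]
    if not window:
        return 0.5
    f_right = sum(1 for s in window if s is Side.RIGHT) / len(window)
    pmin, pmax = bias_cfg.clamp
    return min(max(f_right, pmin), pmax)


def draw_reward_side(
    recent_responses: Sequence[Side],
    bias_cfg: BiasCorrection,
    rng: np.random.Generator,
) -> Side:
    """Draw the trial's rewarded side, bias-corrected when enabled."""
    p_left = p_left_given_history(recent_responses, bias_cfg)
    return Side.LEFT if rng.random() < p_left else Side.RIGHT


def compose_trial(rule: RuleState, rewarded_side: Side, rng: np.random.Generator):
    """Pick the compound stimulus for a trial with the given rewarded side.

    The relevant-modality exemplar is the one whose latent map points to the
    rewarded side; the irrelevant-modality exemplar is drawn uniformly from
    its two active exemplars, so congruent and incongruent trials each occur
    with long-run frequency 1/2.
    """
    relevant = rule.relevant_modality
    rel_ex = rule.exemplar_for_side(relevant, rewarded_side)  # raises if absent
    irrelevant = relevant.other
    irr_pool = sorted(rule.map_for(irrelevant))
    irr_ex = irr_pool[int(rng.integers(0, len(irr_pool)))]
    if relevant is Modality.WHISKER:
        whisker_stim, odor_stim = rel_ex, irr_ex
    else:
        whisker_stim, odor_stim = irr_ex, rel_ex
    congruent = rule.whisker_map[whisker_stim] is rule.odor_map[odor_stim]
    return whisker_stim, odor_stim, congruent


def check_switch_trigger(block_trials: Sequence, window: int = 30, threshold: float = 0.80) -> bool:
    """True iff the current block's trailing ``window`` response trials have
    accuracy at or above ``threshold`` (attainment is inclusive: 24/30 fires).

    No-response trials are excluded, so a block needs at least ``window``
    response trials before the trigger can fire.
    """
    correct = [t.correct for t in block_trials if t.responded]
    if len(correct) < window:
        return False
    tail = correct[-window:]
    return sum(tail) / window >= threshold


def apply_shift(
    rule: RuleState,
    shift_type: str,
    pools: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
    trial_index: int = 0,
) -> ShiftEvent:
    """Apply IDS / Rev / EDS to ``rule``, returning the ShiftEvent.

    The returned ``rule_after`` has ``block_index`` incremented and
    ``trials_in_block`` reset; ``rule`` itself is not mutated.  IDS draws a
    pair of previously unused exemplars from the relevant pool (error if
    fewer than two remain) and assigns them to sides at random.
    """
    if shift_type not in SHIFT_TYPES:
        raise ValueError(f"unknown shift type: {shift_type!r}")
    before = rule.copy()
    after = rule.copy()
    if shift_type == "Rev":
        m = after.relevant_map
        for ex in m:
            m[ex] = m[ex].other
    elif shift_type == "EDS":
        after.relevant_modality = after.relevant_modality.other
    else:  # IDS
        pools = pools or default_pools()
        pool = pools[rule.relevant_modality]
        used = set(rule.relevant_map)
        fresh = [e for e in pool if e not in used]
        if len(fresh) < 2:
            raise ValueError(
                f"IDS requires >= 2 unused {rule.relevant_modality.value} exemplars; "
                f"pool exhausted ({fresh})"
            )
        if rng is None:
            rng = np.random.default_rng(0)
        a, b = fresh[0], fresh[1]
        sides = [Side.LEFT, Side.RIGHT]
        if rng.random() < 0.5:
            sides.reverse()
        new_map = {a: sides[0], b: sides[1]}
        if rule.relevant_modality is Modality.WHISKER:
            after.whisker_map = new_map
        else:
            after.odor_map = new_map
    after.block_index = before.block_index + 1
    after.trials_in_block = 0
    return ShiftEvent(trial_index=trial_index, shift_type=shift_type, rule_before=before, rule_after=after)


class SetShiftController:
    """Trial scheduler for serial set-shifting (SEDS) sessions.

    Each trial: draw the rewarded side (bias-corrected over the last
    ``bias.window`` response sides when enabled) and compose the compound
    stimulus from the current rule.  After each trial, if the block's trailing
    30-response-trial accuracy reaches 80%, the next shift in ``shift_sequence``
    is applied covertly (the default sequence alternates EDS indefinitely,
    toggling the relevant modality).  A finite sequence is cycled.
    """

    def __init__(
        self,
        bias: Optional[BiasCorrection] = None,
        shift_sequence: Optional[Sequence[str]] = None,
        pools: Optional[dict] = None,
        trigger_window: int = 30,
        trigger_threshold: float = 0.80,
    ):
        self.bias = bias or BiasCorrection()
        self.shift_sequence = list(shift_sequence) if shift_sequence else None
        for s in self.shift_sequence or []:
            if s not in SHIFT_TYPES:
                raise ValueError(f"unknown shift type in sequence: {s!r}")
        self.pools = pools or default_pools()
        self.trigger_window = trigger_window
        self.trigger_threshold = trigger_threshold
        self._shift_cursor = 0
        self._block_start = 0  # count of trials already finished when block began
        self._used: Optional[dict] = None  # exemplars consumed by past IDS shifts

    def _next_shift_type(self) -> str:
        if self.shift_sequence is None:
            return "EDS"
        s = self.shift_sequence[self._shift_cursor % len(self.shift_sequence)]
        self._shift_cursor += 1
        return s

    def next_trial(self, trial_index, history, rule: RuleState, rng) -> TrialSpec:
        recent = [t.first_response for t in history if t.responded]
        side = draw_reward_side(recent, self.bias, rng)
        whisker_stim, odor_stim, congruent = compose_trial(rule, side, rng)
        return TrialSpec(
            trial_index=trial_index,
            stage_id="SEDS",
            rewarded_side=side,
            whisker_stim=whisker_stim,
            odor_stim=odor_stim,
            congruent=congruent,
        )

    def after_trial(self, record, history, rule: RuleState, rng) -> Optional[ShiftEvent]:
        block = history[self._block_start :]
        if not check_switch_trigger(block, self.trigger_window, self.trigger_threshold):
            return None
        if self._used is None:
            self._used = {m: set(rule.map_for(m)) for m in Modality}
        # IDS must draw exemplars never used before in this session
        fresh_pools = {
            m: [e for e in self.pools[m] if e not in self._used[m] or e in rule.map_for(m)]
            for m in Modality
        }
        event = apply_shift(
            rule,
            self._next_shift_type(),
            pools=fresh_pools,
            rng=rng,
            trial_index=record.trial_index,
        )
        for m in Modality:
            self._used[m] |= set(event.rule_after.map_for(m))
        # covert switch: mutate the live rule in place
        rule.relevant_modality = event.rule_after.relevant_modality
        rule.whisker_map = dict(event.rule_after.whisker_map)
        rule.odor_map = dict(event.rule_after.odor_map)
        rule.block_index = event.rule_after.block_index
        rule.trials_in_block = 0
        self._block_start = len(history)
        return event


def run_seds_session(
    config: SessionConfig,
    initial_rule: RuleState,
    agent: AgentState,
    shift_sequence: Optional[Sequence[str]] = None,
    rng=None,
    pools: Optional[dict] = None,
) -> SessionLog:
    """Run one serial set-shifting session; ShiftEvents land in ``log.shifts``
    and as ``rule_switch`` events (with full before/after mappings) in the
    event stream."""
    controller = SetShiftController(
        bias=config.bias_correction,
        shift_sequence=shift_sequence,
        pools=pools,
    )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return run_session(config, initial_rule, agent, controller, rng)
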