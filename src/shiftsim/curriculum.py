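"""The staged training protocol and multi-session progression.

Stage order: HB1 -> HB2 -> HB3 -> HB3B -> SH4 -> SH5 -> SD -> CD ->
set_shifting (terminal).  HB1/HB2 arm the spouts in a pseudorandomized
alternating pattern; HB3/HB3B block trials in incrementally increasing block
lengths (5, 10, 15, then 20 per side, repeating); SH4/SH5 add the trial tone
and the whisker discriminandum with a blocked 20-trial left/right alternation;
SD replaces blocking with (optionally bias-corrected) randomization; CD adds
the olfactory distractor.  A stage repeats until passed.

Pass criteria: the habituation stages and SH4 pass on 500 ul consumed in a
session; SH5 on 80% accuracy within a 100-trial moving window; SD and CD on
the fourfold criterion (>100 trials; 80% accuracy in a 30-trial window; one
10-trial window with both sides simultaneously above 50%; response rate
>80%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import analysis
from .agent import AgentState
from .controller import SetShiftController
from .core import (
    CriterionSpec,
    Modality,
    RuleState,
    SessionConfig,
    Side,
    default_rule,
)
from .engine import SessionLog, TrialSpec, run_session

__all__ = [
    "StageDefinition",
    "STAGE_ORDER",
    "TERMINAL_STAGE",
    "stage_definition",
    "default_config",
    "evaluate_stage_pass",
    "next_stage",
    "CurriculumHistory",
    "run_curriculum",
]

STAGE_ORDER = ["HB1", "HB2", "HB3", "HB3B", "SH4", "SH5", "SD", "CD"]
TERMINAL_STAGE = "set_shifting"

#: HB3's "incrementally increasing block lengths of up to 20 trials",
#: realized as 5, 10, 15, 20 and then 20 repeating.
HB3_BLOCK_SCHEDULE = [5, 10, 15, 20]


@dataclass
class StageDefinition:
    """Static description of one training stage."""

    stage_id: str
    schedule: str  # alternating_armed | blocked | randomized
    stimuli_present: tuple
    reward_rule: str  # any_correct_lick | first_lick_correct
    pass_criterion: CriterionSpec
    iti_profile: str  # habituation_timeout | shaping | task
    block_length_schedule: Optional[list] = None


_SD_CRITERION = CriterionSpec(
    accuracy_threshold=0.80,
    accuracy_window=30,
    min_trials=100,
    side_balance={"threshold": 0.5, "window": 10},
    response_rate_min=0.80,
)

_STAGES = {
    "HB1": StageDefinition(
        "HB1", "alternating_armed", (), "any_correct_lick",
        CriterionSpec(volume_target_ul=500.0), "habituation_timeout",
    ),
    "HB2": StageDefinition(
        "HB2", "alternating_armed", (), "any_correct_lick",
        CriterionSpec(volume_target_ul=500.0), "habituation_timeout",
    ),
    "HB3": StageDefinition(
        "HB3", "blocked", (), "any_correct_lick",
        CriterionSpec(volume_target_ul=500.0), "habituation_timeout",
        block_length_schedule=HB3_BLOCK_SCHEDULE,
    ),
    "HB3B": StageDefinition(
        "HB3B", "blocked", (), "any_correct_lick",
        CriterionSpec(volume_target_ul=500.0), "habituation_timeout",
        block_length_schedule=HB3_BLOCK_SCHEDULE,
    ),
    "SH4": StageDefinition(
        "SH4", "blocked", (Modality.WHISKER,), "any_correct_lick",
        CriterionSpec(volume_target_ul=500.0), "shaping",
        block_length_schedule=[20],
    ),
    "SH5": StageDefinition(
        "SH5", "blocked", (Modality.WHISKER,), "first_lick_correct",
        CriterionSpec(accuracy_threshold=0.80, accuracy_window=100), "shaping",
        block_length_schedule=[20],
    ),
    "SD": StageDefinition(
        "SD", "randomized", (Modality.WHISKER,), "first_lick_correct",
        replace(_SD_CRITERION), "task",
    ),
    "CD": StageDefinition(
        "CD", "randomized", (Modality.WHISKER, Modality.ODOR), "first_lick_correct",
        replace(_SD_CRITERION), "task",
    ),
}


def stage_definition(stage_id: str) -> StageDefinition:
    try:
        return _STAGES[stage_id]
    except KeyError:
        raise ValueError(f"unknown stage: {stage_id!r}") from None


def default_config(stage_id: str, seed: int = 0) -> SessionConfig:
    """The stage's default session configuration."""
    if stage_id == "SEDS":
        cfg = SessionConfig(stage_id="SEDS", seed=seed)
        cfg.criterion = CriterionSpec(accuracy_threshold=0.80, accuracy_window=30)
        return cfg
    stage = stage_definition(stage_id)
    cfg = SessionConfig(stage_id=stage_id, seed=seed)
    cfg.criterion = replace(stage.pass_criterion)
    if stage.iti_profile == "shaping":
        cfg.iti_range_ms = [3000, 4500]
    if stage.pass_criterion.volume_target_ul is not None:
        cfg.volume_pass_ul = stage.pass_criterion.volume_target_ul
    if stage_id in ("HB1", "HB2"):
        cfg.no_reward_timeout_ms = 120_000  # session ends after 2 min without water
    return cfg


# ---------------------------------------------------------------------------
# Stage schedulers (consumed by engine.run_session)

class ArmedScheduler:
    """HB1/HB2: arm left or right pseudorandomly each trial, no stimulus."""

    def __init__(self, stage_id: str):
        self.stage_id = stage_id

    def next_trial(self, trial_index, history, rule, rng) -> TrialSpec:
        side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        return TrialSpec(trial_index=trial_index, stage_id=self.stage_id, rewarded_side=side)


class BlockedScheduler:
    """Left/right blocks of scheduled lengths, alternating starting left.

    Used by HB3/HB3B (lengths 5, 10, 15, 20 then 20 repeating) and SH4/SH5
    (fixed 20).  When a whisker discriminandum is present, the exemplar is the
    one whose latent map points to the armed side.
    """

    def __init__(self, stage_id: str, lengths: Sequence[int], with_whisker: bool):
        self.stage_id = stage_id
        self.lengths = list(lengths)
        self.with_whisker = with_whisker

    def _side_at(self, i0: int) -> Side:
        # i0 is the 0-based trial position; walk the block schedule
        total = 0
        k = 0
        while True:
            length = self.lengths[k] if k < len(self.lengths) else self.lengths[-1]
            if i0 < total + length:
                return Side.LEFT if k % 2 == 0 else Side.RIGHT
            total += length
            k += 1

    def next_trial(self, trial_index, history, rule, rng) -> TrialSpec:
        side = self._side_at(trial_index - 1)
        whisker = rule.exemplar_for_side(Modality.WHISKER, side) if self.with_whisker else None
        return TrialSpec(
            trial_index=trial_index,
            stage_id=self.stage_id,
            rewarded_side=side,
            whisker_stim=whisker,
        )


class RandomizedScheduler:
    """SD/CD: per-trial randomization of the reward side, optionally with
    lick-bias correction; CD adds a uniformly drawn odor distractor."""

    def __init__(self, stage_id: str, bias, with_odor: bool):
        from .controller import compose_trial, draw_reward_side

        self.stage_id = stage_id
        self.bias = bias
        self.with_odor = with_odor
        self._draw = draw_reward_side
        self._compose = compose_trial

    def next_trial(self, trial_index, history, rule, rng) -> TrialSpec:
        recent = [t.first_response for t in history if t.first_response is not None]
        side = self._draw(recent, self.bias, rng)
        if self.with_odor:
            whisker, odor, congruent = self._compose(rule, side, rng)
        else:
            whisker = rule.exemplar_for_side(Modality.WHISKER, side)
            odor, congruent = None, None
        return TrialSpec(
            trial_index=trial_index,
            stage_id=self.stage_id,
            rewarded_side=side,
            whisker_stim=whisker,
            odor_stim=odor,
            congruent=congruent,
        )


def make_scheduler(config: SessionConfig):
    """Build the stage-appropriate trial scheduler for a session config."""
    sid = config.stage_id
    if sid == "SEDS":
        return SetShiftController(bias=config.bias_correction)
    stage = stage_definition(sid)
    if stage.schedule == "alternating_armed":
        return ArmedScheduler(sid)
    if stage.schedule == "blocked":
        return BlockedScheduler(
            sid, stage.block_length_schedule or [20], Modality.WHISKER in stage.stimuli_present
        )
    return RandomizedScheduler(sid, config.bias_correction, Modality.ODOR in stage.stimuli_present)


def run_stage_session(config: SessionConfig, rule: RuleState, agent: AgentState, rng) -> SessionLog:
    """One session of the configured stage with its default scheduler."""
    return run_session(config, rule, agent, make_scheduler(config), rng)


# ---------------------------------------------------------------------------
# Pass evaluation

def evaluate_stage_pass(stage, log: SessionLog):
    """Evaluate a session log against its stage's pass criterion.

    Returns ``(passed, detail)`` where ``detail`` reports each criterion
    component's status and, for accuracy, the earliest trial index at which
    the window was met.  Raises on a stage/log mismatch.
    """
    if isinstance(stage, str):
        stage = stage_definition(stage)
    if log.trials and log.trials[0].stage_id != stage.stage_id:
        raise ValueError(
            f"log/stage mismatch: log is {log.trials[0].stage_id!r}, "
            f"evaluating {stage.stage_id!r}"
        )
    crit = stage.pass_criterion
    detail = {}
    trials = log.trials
    if crit.volume_target_ul is not None:
        ok = log.total_volume_ul >= crit.volume_target_ul
        detail["volume"] = {
            "passed": ok,
            "observed_ul": log.total_volume_ul,
            "required_ul": crit.volume_target_ul,
        }
        return all(d["passed"] for d in detail.values()), detail
    if crit.min_trials is not None:
        ok = len(trials) > crit.min_trials
        detail["min_trials"] = {
            "passed": ok,
            "observed": len(trials),
            "required_exclusive": crit.min_trials,
        }
    if crit.accuracy_window is not None:
        ttc = analysis.trials_to_criterion(trials, crit)
        detail["accuracy"] = {
            "passed": ttc is not None,
            "window": crit.accuracy_window,
            "threshold": crit.accuracy_threshold,
            "first_met_response_trial": ttc,
        }
    if crit.side_balance is not None:
        thr = float(crit.side_balance.get("threshold", 0.5))
        win = int(crit.side_balance.get("window", 10))
        ok, at = _side_balance_met(trials, thr, win)
        detail["side_balance"] = {
            "passed": ok,
            "window": win,
            "threshold": thr,
            "first_met_response_trial": at,
        }
    if crit.response_rate_min is not None:
        n = len(trials)
        n_resp = sum(1 for t in trials if t.first_response is not None)
        rate = n_resp / n if n else 0.0
        detail["response_rate"] = {
            "passed": rate > crit.response_rate_min,
            "observed": rate,
            "required_exclusive": crit.response_rate_min,
        }
    return all(d["passed"] for d in detail.values()), detail


def _side_balance_met(trials, threshold: float, window: int):
    """First window of `window` consecutive response trials with accuracy
    strictly above `threshold` on both left and right trials simultaneously."""
    resp = [t for t in trials if t.first_response is not None]
    for end in range(window, len(resp) + 1):
        seg = resp[end - window : end]
        left = [1 if t.correct else 0 for t in seg if t.rewarded_side is Side.LEFT]
        right = [1 if t.correct else 0 for t in seg if t.rewarded_side is Side.RIGHT]
        if not left or not right:
            continue
        if sum(left) / len(left) > threshold and sum(right) / len(right) > threshold:
            return True, end
    return False, None


def next_stage(current: str, passed: bool) -> str:
    """Protocol-order successor: advance on pass, repeat on fail."""
    if current not in STAGE_ORDER:
        raise ValueError(f"unknown stage: {current!r}")
    if not passed:
        return current
    i = STAGE_ORDER.index(current)
    return STAGE_ORDER[i + 1] if i + 1 < len(STAGE_ORDER) else TERMINAL_STAGE


@dataclass
class CurriculumHistory:
    """Ordered record of every session run during a curriculum."""

    records: list = field(default_factory=list)  # (stage_id, session_index, log, passed, detail)
    reached_terminal: bool = False
    truncated: bool = False


def run_curriculum(
    agent: AgentState,
    configs: Optional[dict] = None,
    max_sessions: int = 60,
    seed: int = 0,
    rule: Optional[RuleState] = None,
) -> CurriculumHistory:
    """Drive an agent through the whole protocol, carrying learning across
    sessions.

    ``configs`` maps stage ids to SessionConfig overrides (defaults are used
    for stages not listed).  Session ``k`` (global index) runs on the RNG
    stream ``default_rng([seed, k])``, so any single session is reproducible
    in isolation.  Stops at the terminal token or, with a truncation flag,
    when ``max_sessions`` is exhausted.
    """
    configs = configs or {}
    history = CurriculumHistory()
    stage_id = STAGE_ORDER[0]
    rule = (rule or default_rule()).copy()
    for k in range(max_sessions):
        config = configs.get(stage_id) or default_config(stage_id, seed=seed)
        if config.stage_id != stage_id:
            raise ValueError(f"config for stage {stage_id!r} has stage_id {config.stage_id!r}")
        rng = np.random.default_rng([seed, k])
        log = run_stage_session(config, rule, agent, rng)
        passed, detail = evaluate_stage_pass(stage_id, log)
        history.records.append((stage_id, k, log, passed, detail))
        stage_id = next_stage(stage_id, passed)
        if stage_id == TERMINAL_STAGE:
            history.reached_terminal = True
            return history
    history.truncated = True
    return history
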