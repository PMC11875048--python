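"""Shared domain types for the set-shifting task simulator.

The task is a head-fixed two-alternative forced choice (2AFC): on each trial a
mouse is presented with a whisker-vibration stimulus and/or an odorant, and
reports a decision by licking the left or right water spout.  Which modality is
*relevant* (predicts the rewarded side) is governed by a covert rule that can
change within a session.  This module defines the vocabulary shared by every
other module: stimuli, rules, trials, events, and session configuration, plus
the configuration validator and (de)serialization helpers.

Conventions
-----------
* Time is integer milliseconds from session start.  All scheduled intervals are
  drawn as integers, uniformly and inclusively, over configured ranges.
* Sides are the :class:`Side` enum everywhere in memory; logs print ``"L"`` /
  ``"R"``.
* Congruency is defined relative to the two latent exemplar->side maps:
  a compound trial is congruent iff both maps send their presented exemplars to
  the same side.  It does not depend on which modality is currently relevant.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

__all__ = [
    "Side",
    "Modality",
    "EVENT_KINDS",
    "EventRecord",
    "StimulusExemplar",
    "DEFAULT_WHISKER_POOL",
    "DEFAULT_ODOR_POOL",
    "default_pools",
    "RuleState",
    "default_rule",
    "is_congruent",
    "TrialRecord",
    "CriterionSpec",
    "BiasCorrection",
    "SessionConfig",
    "validate_config",
    "validate_trial",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
]


class Side(str, enum.Enum):
    """Response / reward side of the 2AFC."""

    LEFT = "left"
    RIGHT = "right"

    @property
    def short(self) -> str:
        return "L" if self is Side.LEFT else "R"

    @property
    def other(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT

    @classmethod
    def from_any(cls, value: Any) -> "Side":
        if isinstance(value, Side):
            return value
        s = str(value).strip().lower()
        if s in ("l", "left"):
            return Side.LEFT
        if s in ("r", "right"):
            return Side.RIGHT
        raise ValueError(f"not a side: {value!r}")


class Modality(str, enum.Enum):
    WHISKER = "whisker"
    ODOR = "odor"

    @property
    def other(self) -> "Modality":
        return Modality.ODOR if self is Modality.WHISKER else Modality.WHISKER


#: The canonical event vocabulary of the simulated rig.
EVENT_KINDS = frozenset(
    {
        "trial_start",
        "tone_on",
        "tone_off",
        "whisker_on",
        "whisker_off",
        "odor_command_on",
        "odor_nose_on",
        "odor_off",
        "response_window_on",
        "lick_left",
        "lick_right",
        "reward_left",
        "reward_right",
        "omission",
        "trial_end",
        "rule_switch",
        "stage_pass",
        "session_end",
        "ttl_pulse_on",
        "ttl_pulse_off",
    }
)


@dataclass
class EventRecord:
    """One timestamped event. ``payload`` holds scalars only (ids, sides, volumes)."""

    t_ms: int
    kind: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")
        self.t_ms = int(self.t_ms)


@dataclass(frozen=True)
class StimulusExemplar:
    """One identified cue (a whisker-vibration pattern or an odorant)."""

    modality: Modality
    exemplar_id: str
    descriptor: str = ""


# Whisker patterns: a pure 210 Hz vibration vs a Poisson-distributed
# quasi-square-wave pulse train in the trained pair, plus two spare patterns
# for intradimensional shifts.  Odorants: four odorants diluted 1:100 in
# mineral oil.
DEFAULT_WHISKER_POOL = [
    StimulusExemplar(Modality.WHISKER, "W1", "210 Hz"),
    StimulusExemplar(Modality.WHISKER, "W2", "Poisson pulse train"),
    StimulusExemplar(Modality.WHISKER, "W3", "70 Hz"),
    StimulusExemplar(Modality.WHISKER, "W4", "140 Hz"),
]
DEFAULT_ODOR_POOL = [
    StimulusExemplar(Modality.ODOR, "O1", "eugenol 1:100"),
    StimulusExemplar(Modality.ODOR, "O2", "benzaldehyde 1:100"),
    StimulusExemplar(Modality.ODOR, "O3", "isoamyl acetate 1:100"),
    StimulusExemplar(Modality.ODOR, "O4", "limonene 1:100"),
]


def default_pools() -> dict:
    """Exemplar pools keyed by modality (ids only)."""
    return {
        Modality.WHISKER: [e.exemplar_id for e in DEFAULT_WHISKER_POOL],
        Modality.ODOR: [e.exemplar_id for e in DEFAULT_ODOR_POOL],
    }


@dataclass
class RuleState:
    """The currently relevant modality plus latent exemplar->side maps.

    Both maps are always defined, including when one modality is merely the
    distractor; each active map assigns exactly one exemplar to each side.
    """

    relevant_modality: Modality
    whisker_map: dict  # exemplar_id -> Side
    odor_map: dict  # exemplar_id -> Side
    block_index: int = 0
    trials_in_block: int = 0

    def __post_init__(self) -> None:
        self.relevant_modality = Modality(self.relevant_modality)
        self.whisker_map = {k: Side.from_any(v) for k, v in self.whisker_map.items()}
        self.odor_map = {k: Side.from_any(v) for k, v in self.odor_map.items()}
        for name, m in (("whisker_map", self.whisker_map), ("odor_map", self.odor_map)):
            if sorted(s.value for s in m.values()) != ["left", "right"]:
                raise ValueError(f"{name} must map exactly one exemplar to each side")

    @property
    def relevant_map(self) -> dict:
        return self.whisker_map if self.relevant_modality is Modality.WHISKER else self.odor_map

    def map_for(self, modality: Modality) -> dict:
        return self.whisker_map if modality is Modality.WHISKER else self.odor_map

    def exemplar_for_side(self, modality: Modality, side: Side) -> str:
        for ex, s in self.map_for(modality).items():
            if s is side:
                return ex
        raise ValueError(f"no {modality.value} exemplar maps to {side.value}")

    def copy(self) -> "RuleState":
        return RuleState(
            self.relevant_modality,
            dict(self.whisker_map),
            dict(self.odor_map),
            self.block_index,
            self.trials_in_block,
        )


def default_rule(relevant: Modality = Modality.WHISKER) -> RuleState:
    """The trained pairing: W1/O1 -> left, W2/O2 -> right."""
    return RuleState(
        relevant_modality=relevant,
        whisker_map={"W1": Side.LEFT, "W2": Side.RIGHT},
        odor_map={"O1": Side.LEFT, "O2": Side.RIGHT},
    )


def is_congruent(rule: RuleState, whisker_stim: Optional[str], odor_stim: Optional[str]):
    """Congruency of a compound trial; ``None`` when only one modality is shown."""
    if whisker_stim is None or odor_stim is None:
        return None
    return rule.whisker_map[whisker_stim] is rule.odor_map[odor_stim]


@dataclass
class TrialRecord:
    """One trial's specification, event stream, response, and outcome flags."""

    trial_index: int
    stage_id: str
    rewarded_side: Side
    whisker_stim: Optional[str] = None
    odor_stim: Optional[str] = None
    congruent: Optional[bool] = None
    events: list = field(default_factory=list)
    first_response: Optional[Side] = None  # None encodes "no response"
    correct: Optional[bool] = None  # None on no-response
    rewarded: bool = False
    reward_volume_ul: float = 0.0
    iti_ms: int = 0
    relevant_modality: Modality = Modality.WHISKER
    block_index: int = 0

    @property
    def responded(self) -> bool:
        return self.first_response is not None


def validate_trial(trial: TrialRecord, droplet_ul: Optional[float] = None) -> list:
    """Return invariant violations for one trial (empty list when valid)."""
    v: list = []
    if trial.responded:
        if trial.correct != (trial.first_response is trial.rewarded_side):
            v.append(f"trial {trial.trial_index}: correct flag inconsistent with response")
    elif trial.correct is not None:
        v.append(f"trial {trial.trial_index}: correct must be undefined on no-response")
    if trial.rewarded:
        if trial.reward_volume_ul <= 0:
            v.append(f"trial {trial.trial_index}: rewarded but reward_volume_ul = 0")
        if droplet_ul is not None and trial.reward_volume_ul != droplet_ul:
            v.append(
                f"trial {trial.trial_index}: reward_volume_ul != configured droplet "
                f"({trial.reward_volume_ul} vs {droplet_ul})"
            )
    elif trial.reward_volume_ul != 0:
        v.append(f"trial {trial.trial_index}: unrewarded but reward_volume_ul != 0")
    ts = [e.t_ms for e in trial.events]
    if any(b < a for a, b in zip(ts, ts[1:])):
        v.append(f"trial {trial.trial_index}: events not nondecreasing in timestamp")
    kinds = [e.kind for e in trial.events]
    if kinds:
        if kinds.count("trial_start") != 1 or kinds.count("trial_end") != 1:
            v.append(f"trial {trial.trial_index}: need exactly one trial_start and trial_end")
        else:
            t0 = trial.events[kinds.index("trial_start")].t_ms
            t1 = trial.events[kinds.index("trial_end")].t_ms
            if any(t < t0 or t > t1 for t in ts):
                v.append(f"trial {trial.trial_index}: event outside [trial_start, trial_end]")
        if "response_window_on" in kinds:
            rw = trial.events[kinds.index("response_window_on")].t_ms
            for onset in ("whisker_on", "odor_command_on"):
                if onset in kinds and trial.events[kinds.index(onset)].t_ms > rw:
                    v.append(
                        f"trial {trial.trial_index}: response_window_on precedes {onset}"
                    )
    return v


@dataclass
class CriterionSpec:
    """A stage's pass criterion.

    ``accuracy_threshold`` is inclusive: "reach 80%" is read as attainment, so
    24/30 in a 30-trial window triggers.  Accuracy windows run over *response*
    trials only; no-response trials count only toward the response-rate term.
    """

    accuracy_threshold: float = 0.80
    accuracy_window: Optional[int] = None
    min_trials: Optional[int] = None  # strict: total trials must exceed this
    side_balance: Optional[dict] = None  # {"threshold": 0.5, "window": 10}
    response_rate_min: Optional[float] = None
    volume_target_ul: Optional[float] = None


@dataclass
class BiasCorrection:
    """Lick-bias correction for reward-side scheduling.

    When enabled, the probability of arming the left spout is the fraction of
    *right* responses in the recent response window, clamped to ``clamp`` —
    i.e. reward likelihood is weighted in inverse relation to the animal's
    recent choice frequency.
    """

    enabled: bool = False
    window: int = 20
    clamp: list = field(default_factory=lambda: [0.1, 0.9])


# Stage vocabulary, in protocol order (SEDS is the terminal set-shifting program).
HABITUATION_STAGES = ("HB1", "HB2", "HB3", "HB3B")
SHAPING_STAGES = ("SH4", "SH5")
TASK_STAGES = ("SD", "CD", "SEDS")
ALL_STAGES = HABITUATION_STAGES + SHAPING_STAGES + TASK_STAGES


@dataclass
class SessionConfig:
    """All timing, reward, criterion, and randomization parameters for one session.

    Defaults are the task-stage values: a 500 ms trial-onset tone, a 2,500 ms
    stimulus epoch, a 1,500 ms response window (so the response window opens
    2.5 s after stimulus onset), an 8,000-10,000 ms ITI, 4 ul droplets, and
    session termination after 10 consecutive no-response trials.
    """

    stage_id: str = "SD"
    seed: int = 0
    tone_ms: int = 500
    stim_ms: int = 2500
    response_window_ms: int = 1500
    iti_range_ms: list = field(default_factory=lambda: [8000, 10000])
    habituation_timeout_range_ms: list = field(default_factory=lambda: [500, 1500])
    droplet_ul: float = 4.0
    odor_onset_latency_ms: int = 120
    odor_clear_ms: int = 2000
    bias_correction: BiasCorrection = field(default_factory=BiasCorrection)
    no_response_termination: int = 10
    volume_pass_ul: Optional[float] = None  # session stops at this consumed volume
    no_reward_timeout_ms: Optional[int] = None  # HB1/HB2: end after 2 min without reward
    criterion: CriterionSpec = field(default_factory=CriterionSpec)
    trial_cap: int = 2000
    hb3b_whisker_flash_ms: list = field(default_factory=lambda: [150, 300])

    def iti_bounds(self) -> tuple:
        """Effective ITI range: habituation stages use the post-reward timeout."""
        if self.stage_id in HABITUATION_STAGES:
            lo, hi = self.habituation_timeout_range_ms
        else:
            lo, hi = self.iti_range_ms
        return int(lo), int(hi)


def validate_config(config: SessionConfig) -> list:
    """Check every :class:`SessionConfig` invariant; return violation strings.

    An empty list means the configuration is valid.  Violations name the field
    and the violated bound; nothing is raised.
    """
    v: list = []
    if config.stage_id not in ALL_STAGES:
        v.append(f"stage_id: unknown stage {config.stage_id!r} (expected one of {sorted(ALL_STAGES)})")
    for name in ("tone_ms", "stim_ms", "response_window_ms", "trial_cap", "no_response_termination"):
        if int(getattr(config, name)) <= 0:
            v.append(f"{name}: must be positive")
    if config.droplet_ul <= 0:
        v.append("droplet_ul: must be positive")
    if config.odor_onset_latency_ms < 0:
        v.append("odor_onset_latency_ms: must be >= 0")
    if config.odor_clear_ms < 0:
        v.append("odor_clear_ms: must be >= 0")
    for name in ("iti_range_ms", "habituation_timeout_range_ms", "hb3b_whisker_flash_ms"):
        rng = getattr(config, name)
        if len(rng) != 2:
            v.append(f"{name}: must be a [lo, hi] pair")
            continue
        lo, hi = rng
        if lo <= 0:
            v.append(f"{name}: lo must be positive")
        if lo > hi:
            v.append(f"{name}: lo ({lo}) > hi ({hi})")
    bc = config.bias_correction
    if bc.window < 1:
        v.append("bias_correction.window: must be >= 1")
    if len(bc.clamp) != 2:
        v.append("bias_correction.clamp: must be a [pmin, pmax] pair")
    else:
        pmin, pmax = bc.clamp
        if not (0 < pmin <= 0.5):
            v.append(f"bias_correction.clamp: requires 0 < pmin ({pmin}) <= 0.5")
        if not (0.5 <= pmax < 1):
            v.append(f"bias_correction.clamp: requires 0.5 <= pmax ({pmax}) < 1")
    crit = config.criterion
    if not (0 < crit.accuracy_threshold <= 1):
        v.append(f"criterion.accuracy_threshold: must be in (0, 1], got {crit.accuracy_threshold}")
    if crit.accuracy_window is not None and crit.accuracy_window < 1:
        v.append("criterion.accuracy_window: must be >= 1")
    if crit.min_trials is not None and crit.min_trials < 0:
        v.append("criterion.min_trials: must be >= 0")
    if crit.response_rate_min is not None and not (0 < crit.response_rate_min <= 1):
        v.append("criterion.response_rate_min: must be in (0, 1]")
    if crit.volume_target_ul is not None and crit.volume_target_ul <= 0:
        v.append("criterion.volume_target_ul: must be positive")
    if crit.side_balance is not None:
        sb = crit.side_balance
        if not (0 < float(sb.get("threshold", 0.5)) < 1):
            v.append("criterion.side_balance.threshold: must be in (0, 1)")
        if int(sb.get("window", 10)) < 1:
            v.append("criterion.side_balance.window: must be >= 1")
    if config.volume_pass_ul is not None and config.volume_pass_ul <= 0:
        v.append("volume_pass_ul: must be positive")
    if config.no_reward_timeout_ms is not None and config.no_reward_timeout_ms <= 0:
        v.append("no_reward_timeout_ms: must be positive")
    return v


# ---------------------------------------------------------------------------
# Serialization (YAML config documents; unknown keys are an error)

def _criterion_to_dict(c: CriterionSpec) -> dict:
    return {
        "accuracy_threshold": c.accuracy_threshold,
        "accuracy_window": c.accuracy_window,
        "min_trials": c.min_trials,
        "side_balance": dict(c.side_balance) if c.side_balance else None,
        "response_rate_min": c.response_rate_min,
        "volume_target_ul": c.volume_target_ul,
    }


def config_to_dict(config: SessionConfig) -> dict:
    return {
        "stage_id": config.stage_id,
        "seed": int(config.seed),
        "tone_ms": int(config.tone_ms),
        "stim_ms": int(config.stim_ms),
        "response_window_ms": int(config.response_window_ms),
        "iti_range_ms": [int(x) for x in config.iti_range_ms],
        "habituation_timeout_range_ms": [int(x) for x in config.habituation_timeout_range_ms],
        "droplet_ul": float(config.droplet_ul),
        "odor_onset_latency_ms": int(config.odor_onset_latency_ms),
        "odor_clear_ms": int(config.odor_clear_ms),
        "bias_correction": {
            "enabled": bool(config.bias_correction.enabled),
            "window": int(config.bias_correction.window),
            "clamp": [float(x) for x in config.bias_correction.clamp],
        },
        "no_response_termination": int(config.no_response_termination),
        "volume_pass_ul": config.volume_pass_ul,
        "no_reward_timeout_ms": config.no_reward_timeout_ms,
        "criterion": _criterion_to_dict(config.criterion),
        "trial_cap": int(config.trial_cap),
        "hb3b_whisker_flash_ms": [int(x) for x in config.hb3b_whisker_flash_ms],
    }


_CONFIG_KEYS = {f.name for f in dataclasses.fields(SessionConfig)}
_CRITERION_KEYS = {f.name for f in dataclasses.fields(CriterionSpec)}
_BIAS_KEYS = {f.name for f in dataclasses.fields(BiasCorrection)}


def config_from_dict(data: dict) -> SessionConfig:
    """Build a :class:`SessionConfig` from a mapping; unknown keys are an error."""
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "bias_correction" in kwargs and kwargs["bias_correction"] is not None:
        bd = dict(kwargs["bias_correction"])
        bad = set(bd) - _BIAS_KEYS
        if bad:
            raise ValueError(f"unknown bias_correction keys: {sorted(bad)}")
        kwargs["bias_correction"] = BiasCorrection(**bd)
    if "criterion" in kwargs and kwargs["criterion"] is not None:
        cd = dict(kwargs["criterion"])
        bad = set(cd) - _CRITERION_KEYS
        if bad:
            raise ValueError(f"unknown criterion keys: {sorted(bad)}")
        kwargs["criterion"] = CriterionSpec(**cd)
    return SessionConfig(**kwargs)


def load_config(path) -> SessionConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config document must be a mapping")
    return config_from_dict(data)


def save_config(config: SessionConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
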