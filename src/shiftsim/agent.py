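"""Simulated mouse agents.

The agent is deliberately the simplest mechanism that produces every
phenomenon the analysis module must detect: graded acquisition toward
criterion, perseverative errors confined to incongruent trials after covert
rule switches, stochastic lapses, side bias (for the bias-correction
contract), anticipatory licking at ~8 Hz, and satiety-driven session
termination.  No claim is made that fitted parameters correspond to mouse
cognition.

Choice model
------------
On each trial the agent responds with probability ``p_respond``.  A response
is a uniformly random side with probability ``lapse``; otherwise the decision
variable is an attention-weighted sum of signed exemplar->side association
strengths (``+1`` = right),

    evidence = w * assoc[whisker_stim] + (1 - w) * assoc[odor_stim],

with an absent stimulus contributing nothing (its weight renormalized away),
and ``P(right) = logistic(inv_temp * evidence + side_bias)``.

Learning
--------
After a response trial, each presented exemplar's strength moves toward the
signed rewarded side (``target = +1`` if the reward was on the right, else
``-1``) by ``assoc_lr * (target - strength)``; the animal that licks the wrong
side and receives nothing can infer the correct side, so the update uses the
trial's rewarded side.  Attention reallocates toward a modality only when
exactly one presented modality's association sign agreed with the outcome —
congruent trials carry no information about which modality is relevant and
leave attention unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np

from .core import Modality, RuleState, Side, TrialRecord

__all__ = [
    "AgentParams",
    "AgentState",
    "agent_choose",
    "agent_update",
    "make_agent",
    "make_saturated_agent",
    "DEFAULT_COHORT_RANGES",
    "generate_cohort",
    "fit_agent",
]


@dataclass
class AgentParams:
    """Tunable behavioral parameters of a simulated mouse.

    ``satiety_trials`` is the mean of a per-session normal draw (SD
    ``satiety_sd``, truncated at 1 trial) after which the response probability
    drops to zero, producing the 10-consecutive-omission session termination
    naturally.  ``lick_rate_hz`` sets the anticipatory lick rhythm during the
    stimulus epoch (default 8 Hz).
    """

    attn_whisker0: float = 0.5
    assoc_lr: float = 0.12
    attn_lr: float = 0.08
    inv_temp: float = 3.0
    lapse: float = 0.05
    side_bias: float = 0.0
    p_respond: float = 0.95
    satiety_trials: float = 450.0
    satiety_sd: float = 50.0
    lick_rate_hz: float = 8.0
    seed_offset: int = 0

    def validate(self) -> list:
        v = []
        if not (0.0 <= self.attn_whisker0 <= 1.0):
            v.append("attn_whisker0 must be in [0, 1]")
        for name in ("assoc_lr", "attn_lr"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                v.append(f"{name} must be in [0, 1]")
        if self.inv_temp < 0:
            v.append("inv_temp must be >= 0")
        if not (0.0 <= self.lapse <= 1.0):
            v.append("lapse must be in [0, 1]")
        if not (0.0 < self.p_respond <= 1.0):
            v.append("p_respond must be in (0, 1]")
        if self.lick_rate_hz <= 0:
            v.append("lick_rate_hz must be positive")
        return v


@dataclass
class AgentState:
    """A simulated mouse: parameters plus evolving learned state.

    ``assoc`` maps exemplar ids to signed strengths in [-1, +1] (+1 = right);
    ``attn_whisker`` is the whisker attention weight (the odor weight is its
    complement, so the two always sum to 1).
    """

    params: AgentParams
    attn_whisker: float = 0.5
    assoc: dict = field(default_factory=dict)
    trials_done: int = 0
    satiated: bool = False
    satiety_threshold: Optional[int] = None

    def begin_session(self, rng: np.random.Generator) -> None:
        """Reset per-session state and draw this session's satiety point."""
        self.trials_done = 0
        self.satiated = False
        if math.isfinite(self.params.satiety_trials):
            draw = rng.normal(self.params.satiety_trials, self.params.satiety_sd)
            self.satiety_threshold = max(1, int(round(draw)))
        else:
            self.satiety_threshold = None

    def strength(self, exemplar: Optional[str]) -> float:
        return self.assoc.get(exemplar, 0.0) if exemplar is not None else 0.0

    # -- decision -----------------------------------------------------------

    def evidence(self, whisker_stim: Optional[str], odor_stim: Optional[str]) -> float:
        w = self.attn_whisker
        if whisker_stim is not None and odor_stim is not None:
            return w * self.strength(whisker_stim) + (1.0 - w) * self.strength(odor_stim)
        if whisker_stim is not None:
            return self.strength(whisker_stim)
        if odor_stim is not None:
            return self.strength(odor_stim)
        return 0.0

    def p_right(self, whisker_stim, odor_stim) -> float:
        """Marginal response probability (lapse mixture), given a response."""
        p = self.params
        base = _logistic(p.inv_temp * self.evidence(whisker_stim, odor_stim) + p.side_bias)
        return p.lapse * 0.5 + (1.0 - p.lapse) * base

    def choose(
        self,
        whisker_stim: Optional[str],
        odor_stim: Optional[str],
        rng: np.random.Generator,
        stim_ms: int = 2500,
        response_window_ms: int = 1500,
    ):
        """Simulate one trial's behavior.

        Returns ``(response, licks)`` where ``response`` is a :class:`Side` or
        ``None`` (no response), and ``licks`` is a list of ``(offset_ms,
        Side)`` pairs relative to stimulus onset.  The final lick is the
        response, placed inside the response window; earlier licks are
        anticipatory, at ``lick_rate_hz`` and mostly toward the eventual
        choice.  Counts this call toward the session's satiety threshold.
        """
        p = self.params
        self.trials_done += 1
        if self.satiety_threshold is not None and self.trials_done > self.satiety_threshold:
            self.satiated = True
        if self.satiated or rng.random() > p.p_respond:
            return None, []
        if rng.random() < p.lapse:
            p_r = 0.5
        else:
            p_r = _logistic(p.inv_temp * self.evidence(whisker_stim, odor_stim) + p.side_bias)
        side = Side.RIGHT if rng.random() < p_r else Side.LEFT
        latency = int(rng.integers(100, min(501, response_window_ms)))
        licks = []
        if whisker_stim is not None or odor_stim is not None:
            period = 1000.0 / p.lick_rate_hz
            t = period + float(rng.uniform(-0.08 * period, 0.08 * period))
            while t < stim_ms:
                lick_side = side if rng.random() < 0.8 else side.other
                licks.append((min(int(round(t)), stim_ms - 1), lick_side))
                t += period + float(rng.uniform(-0.08 * period, 0.08 * period))
        licks.append((stim_ms + latency, side))
        return side, licks

    # -- learning -----------------------------------------------------------

    def update(self, trial: TrialRecord) -> None:
        """Learn from one response trial (no-op on omissions)."""
        if not trial.responded:
            return
        p = self.params
        target = 1.0 if trial.rewarded_side is Side.RIGHT else -1.0
        agree = {}
        for modality, stim in (
            (Modality.WHISKER, trial.whisker_stim),
            (Modality.ODOR, trial.odor_stim),
        ):
            if stim is None:
                continue
            s = self.assoc.get(stim, 0.0)
            agree[modality] = s != 0.0 and math.copysign(1.0, s) == target
            self.assoc[stim] = min(1.0, max(-1.0, s + p.assoc_lr * (target - s)))
        w_agree = agree.get(Modality.WHISKER, False)
        o_agree = agree.get(Modality.ODOR, False)
        if w_agree and not o_agree:
            self.attn_whisker += p.attn_lr * (1.0 - self.attn_whisker)
        elif o_agree and not w_agree:
            self.attn_whisker -= p.attn_lr * self.attn_whisker
        self.attn_whisker = min(1.0, max(0.0, self.attn_whisker))


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def agent_choose(state: AgentState, whisker_stim, odor_stim, rng, **kwargs):
    """Functional form of :meth:`AgentState.choose`."""
    if whisker_stim is None and odor_stim is None:
        raise ValueError("agent_choose requires at least one stimulus")
    return state.choose(whisker_stim, odor_stim, rng, **kwargs)


def agent_update(state: AgentState, trial: TrialRecord) -> AgentState:
    """Functional form of :meth:`AgentState.update`; mutates and returns ``state``."""
    state.update(trial)
    return state


def make_agent(**overrides) -> AgentState:
    params = AgentParams(**overrides)
    bad = params.validate()
    if bad:
        raise ValueError("; ".join(bad))
    return AgentState(params=params, attn_whisker=params.attn_whisker0)


def make_saturated_agent(
    rule: RuleState,
    lapse: float = 0.0,
    attend: Modality = Modality.WHISKER,
    learn: bool = False,
) -> AgentState:
    """An agent with both maps learned to saturation and all-or-none attention.

    Useful for closed-form checks: on congruent trials its accuracy is
    ``1 - lapse/2``; immediately after an extradimensional shift (before any
    relearning) its incongruent-trial accuracy is ``lapse/2``.
    """
    params = AgentParams(
        attn_whisker0=1.0 if attend is Modality.WHISKER else 0.0,
        assoc_lr=0.12 if learn else 0.0,
        attn_lr=0.08 if learn else 0.0,
        inv_temp=60.0,
        lapse=lapse,
        side_bias=0.0,
        p_respond=1.0,
        satiety_trials=math.inf,
    )
    assoc = {}
    for m in (rule.whisker_map, rule.odor_map):
        for ex, side in m.items():
            assoc[ex] = 1.0 if side is Side.RIGHT else -1.0
    return AgentState(params=params, attn_whisker=params.attn_whisker0, assoc=assoc)


# ---------------------------------------------------------------------------
# Cohort generation

#: Default per-parameter uniform ranges for cohort draws.  Chosen so that
#: simulated set-shifting sessions land in a realistic envelope of a few
#: hundred trials with a handful of rule switches each.
DEFAULT_COHORT_RANGES = {
    "attn_whisker0": (0.35, 0.65),
    "assoc_lr": (0.08, 0.20),
    "attn_lr": (0.05, 0.15),
    "inv_temp": (2.5, 5.0),
    "lapse": (0.02, 0.10),
    "side_bias": (-0.3, 0.3),
    "p_respond": (0.90, 0.98),
    "satiety_trials": (250.0, 650.0),
}

_PARAM_NAMES = {f.name for f in fields(AgentParams)}


def generate_cohort(
    n_agents: int,
    param_ranges: Optional[dict] = None,
    sessions_per_agent: int = 1,
    seed: int = 0,
    config=None,
    initial_rule: Optional[RuleState] = None,
    shift_sequence=None,
):
    """Draw agents from uniform parameter ranges and run set-shifting sessions.

    Returns a list of ``(AgentParams, [SessionLog, ...])``, fully reproducible
    from ``seed``.  Each agent carries its learned state across its own
    sessions; per-session RNG streams derive from ``(seed, agent, session)``.
    """
    from .controller import run_seds_session  # local import: avoid cycle
    from .curriculum import default_config

    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    ranges = dict(DEFAULT_COHORT_RANGES)
    if param_ranges:
        bad = set(param_ranges) - _PARAM_NAMES
        if bad:
            raise ValueError(f"unknown agent parameters: {sorted(bad)}")
        ranges.update(param_ranges)
    base_config = config if config is not None else default_config("SEDS")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_agents):
        draws = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        params = AgentParams(**draws, seed_offset=i)
        agent = AgentState(params=params, attn_whisker=params.attn_whisker0)
        logs = []
        for s in range(sessions_per_agent):
            rule = (initial_rule or _fresh_default_rule()).copy()
            session_rng = np.random.default_rng([seed, i, s])
            logs.append(
                run_seds_session(
                    base_config, rule, agent, shift_sequence=shift_sequence, rng=session_rng
                )
            )
        out.append((params, logs))
    return out


def _fresh_default_rule() -> RuleState:
    from .core import default_rule

    return default_rule()


# ---------------------------------------------------------------------------
# Grid-search fitting (enables parameter recovery)

def fit_agent(
    logs: Sequence,
    grid: dict,
    base_params: Optional[AgentParams] = None,
    min_response_trials: int = 500,
):
    """Maximum-likelihood grid search over ``{lapse, attn_whisker0, inv_temp}``.

    For each grid point the agent's learning is replayed deterministically
    from the logged trials (associations start at zero, attention at the
    candidate ``attn_whisker0``, learning rates from ``base_params``), and the
    Bernoulli log-likelihood of the observed left/right responses under the
    lapse-mixture choice probability is accumulated over all response trials.

    Returns ``(best, loglik)`` where ``best`` is a dict over the grid keys.
    """
    allowed = {"lapse", "attn_whisker0", "inv_temp"}
    if not grid:
        raise ValueError("empty parameter grid")
    bad = set(grid) - allowed
    if bad:
        raise ValueError(f"grid keys must be within {sorted(allowed)}, got {sorted(bad)}")
    base = base_params or AgentParams()
    trials = [t for log in logs for t in log.trials]
    n_resp = sum(1 for t in trials if t.responded)
    if n_resp < min_response_trials:
        raise ValueError(
            f"insufficient response trials for fitting: {n_resp} < {min_response_trials}"
        )
    axes = {k: list(v) for k, v in grid.items()}
    names = sorted(axes)
    best, best_ll = None, -math.inf
    for combo in _grid_points(names, axes):
        params = replace(
            base,
            lapse=combo.get("lapse", base.lapse),
            attn_whisker0=combo.get("attn_whisker0", base.attn_whisker0),
            inv_temp=combo.get("inv_temp", base.inv_temp),
        )
        ll = _replay_loglik(trials, params)
        if ll > best_ll:
            best, best_ll = combo, ll
    return best, best_ll


def _grid_points(names, axes):
    if not names:
        yield {}
        return
    head, rest = names[0], names[1:]
    for value in axes[head]:
        for tail in _grid_points(rest, axes):
            yield {head: value, **tail}


def _replay_loglik(trials, params: AgentParams) -> float:
    sim = AgentState(params=params, attn_whisker=params.attn_whisker0)
    ll = 0.0
    for t in trials:
        if t.responded:
            p_r = sim.p_right(t.whisker_stim, t.odor_stim)
            p_obs = p_r if t.first_response is Side.RIGHT else 1.0 - p_r
            ll += math.log(max(p_obs, 1e-12))
        sim.update(t)
    return ll
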