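"""Behavioral analytics over trial tables and event streams.

Implements the task's standard performance measures: moving-window accuracy,
trials to criterion, block segmentation at covert rule switches,
switch-aligned accuracy, the modality x congruency x timing factorial summary
with a three-way ANOVA (pairwise interactions), rank-sum comparison of
trials-to-criterion across modalities, lick peri-stimulus histograms, and
per-session summaries.

Conventions
-----------
* Accuracy statistics run over *response* trials only; no-response trials are
  excluded from both numerator and denominator and count only toward
  response-rate summaries.
* Switch-offset indexing: offset 0 is the first trial under the new rule; the
  pre-switch window is offsets -pre..-1, the post-switch window 0..post-1.
* All analyses are pure functions of their inputs: identical tables give
  bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import CriterionSpec

__all__ = [
    "moving_accuracy",
    "trials_to_criterion",
    "Block",
    "segment_blocks",
    "periswitch_table",
    "SwitchAlignedSummary",
    "switch_aligned",
    "AnovaTable",
    "periswitch_anova",
    "posthoc_bonferroni",
    "ranksum_trials_to_criterion",
    "lick_psth",
    "session_summary",
]


def _responded(trial) -> bool:
    return trial.first_response is not None


def moving_accuracy(trials: Sequence, window: int) -> np.ndarray:
    """Trailing-window accuracy at each trial position.

    The value at position ``i`` (0-based over *all* trials) is the fraction
    correct among the last ``window`` response trials up to and including
    ``i``; positions before the first full window are NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out = np.full(len(trials), np.nan)
    recent: list = []
    running = 0
    for i, t in enumerate(trials):
        if _responded(t):
            recent.append(1 if t.correct else 0)
            running += recent[-1]
            if len(recent) > window:
                running -= recent.pop(0)
        if len(recent) == window:
            out[i] = running / window
    return out


def trials_to_criterion(trials: Sequence, criterion: CriterionSpec):
    """Response trials from block start until the accuracy window is first met.

    Returns the 1-based count of response trials at first attainment of
    ``criterion.accuracy_threshold`` over ``criterion.accuracy_window``
    trailing response trials, or ``None`` if never reached.
    """
    window = criterion.accuracy_window
    if window is None or window < 1:
        raise ValueError("criterion.accuracy_window must be set and >= 1")
    thr = criterion.accuracy_threshold
    recent: list = []
    running = 0
    k = 0
    for t in trials:
        if not _responded(t):
            continue
        k += 1
        recent.append(1 if t.correct else 0)
        running += recent[-1]
        if len(recent) > window:
            running -= recent.pop(0)
        if len(recent) == window and running / window >= thr:
            return k
    return None


@dataclass
class Block:
    """One inter-switch segment of a session."""

    trials: list
    modality: str  # relevant modality during the block
    start_trial: int  # 1-based index of the block's first trial
    ended_by: Optional[str] = None  # shift type that ended it, None if open


def segment_blocks(trials: Sequence, events: Sequence) -> list:
    """Partition a session's trials at its ``rule_switch`` events.

    Each switch's payload names the trial it followed (the last trial of the
    old block).  Blocks are labeled with their relevant modality and the
    shift type that ended them (``None`` for the open terminal block).
    """
    n = len(trials)
    switches = []
    for e in events:
        if e.kind != "rule_switch":
            continue
        idx = int(e.payload.get("trial", -1))
        if idx < 1 or idx > n:
            raise ValueError(f"rule_switch at nonexistent trial index {idx}")
        switches.append((idx, e.payload.get("shift_type")))
    switches.sort()
    blocks = []
    start = 0
    for idx, shift_type in switches:
        seg = list(trials[start:idx])
        if seg:
            blocks.append(
                Block(
                    trials=seg,
                    modality=seg[0].relevant_modality.value,
                    start_trial=start + 1,
                    ended_by=shift_type,
                )
            )
        start = idx
    seg = list(trials[start:])
    if seg:
        blocks.append(
            Block(trials=seg, modality=seg[0].relevant_modality.value, start_trial=start + 1)
        )
    return blocks


def periswitch_table(session_blocks, pre: int = 10, post: int = 10) -> pd.DataFrame:
    """Collect response trials around every switch into a cell-labeled table.

    ``session_blocks`` is a list of block lists, one per session (a single
    session's block list is also accepted).  Each switch between consecutive
    blocks contributes the last ``pre`` trials before it and the first
    ``post`` after; rows carry ``offset`` (0 = first post-switch trial),
    ``correct`` (0/1), ``modality`` (rule in effect at the trial),
    ``congruency`` and ``timing`` factor labels.  Trials without a congruency
    label or without a response are dropped.
    """
    if session_blocks and isinstance(session_blocks[0], Block):
        session_blocks = [session_blocks]
    rows = []
    for blocks in session_blocks:
        for b_pre, b_post in zip(blocks, blocks[1:]):
            for j, t in enumerate(reversed(b_pre.trials[-pre:])):
                rows.append((-(j + 1), t, b_pre.modality))
            for j, t in enumerate(b_post.trials[:post]):
                rows.append((j, t, b_post.modality))
    records = []
    for offset, t, modality in rows:
        if not _responded(t) or t.congruent is None:
            continue
        records.append(
            {
                "offset": offset,
                "correct": 1 if t.correct else 0,
                "modality": modality,
                "congruency": "congruent" if t.congruent else "incongruent",
                "timing": "post" if offset >= 0 else "pre",
            }
        )
    return pd.DataFrame(records, columns=["offset", "correct", "modality", "congruency", "timing"])


@dataclass
class SwitchAlignedSummary:
    """Switch-aligned accuracy and the factorial cell table."""

    offsets: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    n: np.ndarray
    by_congruency: dict = field(default_factory=dict)  # label -> (mean, sd, n)
    cell_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def switch_aligned(session_blocks, pre: int = 10, post: int = 10) -> SwitchAlignedSummary:
    """Average accuracy at each trial offset around rule switches.

    Raises if the input contains no switch.  Cell means are per
    modality x congruency x timing, with SD and contributing-trial counts.
    """
    table = periswitch_table(session_blocks, pre=pre, post=post)
    if table.empty:
        raise ValueError("no rule switches (or no labeled response trials) in input")
    offsets = np.arange(-pre, post)

    def _series(df):
        mean = np.full(len(offsets), np.nan)
        sd = np.full(len(offsets), np.nan)
        n = np.zeros(len(offsets), dtype=int)
        g = df.groupby("offset")["correct"]
        agg = g.agg(["mean", "std", "count"])
        for k, off in enumerate(offsets):
            if off in agg.index:
                mean[k] = agg.loc[off, "mean"]
                sd[k] = agg.loc[off, "std"]
                n[k] = agg.loc[off, "count"]
        return mean, sd, n

    mean, sd, n = _series(table)
    by_congruency = {
        label: _series(sub) for label, sub in table.groupby("congruency")
    }
    cells = (
        table.groupby(["modality", "congruency", "timing"])["correct"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
        .sort_values(["modality", "congruency", "timing"])
        .reset_index(drop=True)
    )
    return SwitchAlignedSummary(
        offsets=offsets,
        mean_accuracy=mean,
        sd_accuracy=sd,
        n=n,
        by_congruency=by_congruency,
        cell_table=cells,
    )


@dataclass
class AnovaTable:
    """Factorial ANOVA effects (sum of squares, df, F, p) plus residuals."""

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def p(self, name: str) -> float:
        return float(self.table.loc[name, "p"])

    def F(self, name: str) -> float:
        return float(self.table.loc[name, "F"])


_EFFECTS = [
    "modality",
    "congruency",
    "timing",
    "modality:congruency",
    "modality:timing",
    "congruency:timing",
]


def periswitch_anova(table: pd.DataFrame, ss_type: int = 3) -> AnovaTable:
    """Three-way fixed-effects ANOVA (main effects + pairwise interactions)
    on per-trial correctness.

    Unbalanced cells use marginal (Type III) sums of squares with sum-to-zero
    contrasts by default (``ss_type=1`` gives sequential SS).  Every factor
    must have both of its levels represented.
    """
    for factor, levels in (
        ("modality", {"whisker", "odor"}),
        ("congruency", {"congruent", "incongruent"}),
        ("timing", {"pre", "post"}),
    ):
        present = set(table[factor].unique())
        missing = levels - present
        if missing:
            raise ValueError(f"factor {factor!r} has empty level(s): {sorted(missing)}")
    df = table.copy()
    df["correct"] = df["correct"].astype(float)
    formula = (
        "correct ~ C(modality, Sum) + C(congruency, Sum) + C(timing, Sum)"
        " + C(modality, Sum):C(congruency, Sum)"
        " + C(modality, Sum):C(timing, Sum)"
        " + C(congruency, Sum):C(timing, Sum)"
    )
    model = smf.ols(formula, data=df).fit()
    raw = sm.stats.anova_lm(model, typ=(3 if ss_type == 3 else 1))
    rename = {}
    for idx in raw.index:
        clean = (
            str(idx)
            .replace("C(modality, Sum)", "modality")
            .replace("C(congruency, Sum)", "congruency")
            .replace("C(timing, Sum)", "timing")
        )
        rename[idx] = clean
    raw = raw.rename(index=rename)
    rows = []
    for name in _EFFECTS + ["Residual"]:
        if name not in raw.index:
            continue
        r = raw.loc[name]
        rows.append(
            {
                "effect": name,
                "ss": float(r["sum_sq"]),
                "df": float(r["df"]),
                "F": float(r["F"]) if np.isfinite(r.get("F", np.nan)) else np.nan,
                "p": float(r["PR(>F)"]) if np.isfinite(r.get("PR(>F)", np.nan)) else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("effect")
    return AnovaTable(table=out)


def posthoc_bonferroni(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Welch t-tests between the eight factorial cells, Bonferroni-
    corrected across all group pairs."""
    groups = {
        key: sub["correct"].to_numpy(dtype=float)
        for key, sub in table.groupby(["modality", "congruency", "timing"])
    }
    keys = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1 :]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        if np.var(ga) == 0 and np.var(gb) == 0:
            # degenerate pair: identical constants are indistinguishable,
            # different constants are trivially separated
            stat = 0.0 if np.mean(ga) == np.mean(gb) else np.inf
            p = 1.0 if np.mean(ga) == np.mean(gb) else 0.0
        else:
            stat, p = scipy.stats.ttest_ind(ga, gb, equal_var=False)
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "group_a": "/".join(a),
                "group_b": "/".join(b),
                "mean_a": float(np.mean(groups[a])),
                "mean_b": float(np.mean(groups[b])),
                "t": float(stat),
                "p_raw": float(p),
                "p_bonferroni": float(p_adj),
                "significant": bool(p_adj < alpha),
            }
        )
    return pd.DataFrame(rows)


def ranksum_trials_to_criterion(blocks: Sequence[Block], criterion: CriterionSpec):
    """Rank-sum (Wilcoxon) comparison of trials-to-criterion between whisker-
    rule and odor-rule blocks.  Blocks that never reach criterion are dropped.
    Returns ``(statistic, p, n_whisker, n_odor)``."""
    whisker, odor = [], []
    for b in blocks:
        ttc = trials_to_criterion(b.trials, criterion)
        if ttc is None:
            continue
        (whisker if b.modality == "whisker" else odor).append(ttc)
    if not whisker or not odor:
        raise ValueError("need criterion-reaching blocks under both modality rules")
    stat, p = scipy.stats.ranksums(whisker, odor)
    return float(stat), float(p), len(whisker), len(odor)


def lick_psth(
    events: Sequence,
    align_to: str = "response_window_on",
    bin_ms: int = 100,
    window=(-3000, 1500),
):
    """Peri-event lick-rate histogram per side.

    Licks within ``window`` ms of each ``align_to`` event are binned at
    ``bin_ms`` and normalized to a rate in Hz (counts / alignments / bin
    width).  Returns a dict with ``bin_edges_ms`` and per-side rate arrays.
    """
    if bin_ms < 1:
        raise ValueError("bin_ms must be >= 1")
    lo, hi = window
    anchors = [e.t_ms for e in events if e.kind == align_to]
    if not anchors:
        raise ValueError(f"no alignment events of kind {align_to!r}")
    edges = np.arange(lo, hi + bin_ms, bin_ms)
    licks = {
        "left": np.array([e.t_ms for e in events if e.kind == "lick_left"]),
        "right": np.array([e.t_ms for e in events if e.kind == "lick_right"]),
    }
    out = {"bin_edges_ms": edges, "n_alignments": len(anchors)}
    scale = 1.0 / (len(anchors) * bin_ms / 1000.0)
    for side, ts in licks.items():
        counts = np.zeros(len(edges) - 1)
        for a in anchors:
            rel = ts - a
            sel = rel[(rel >= lo) & (rel < hi)]
            if sel.size:
                counts += np.histogram(sel, bins=edges)[0]
        out[side] = counts * scale
    return out


def session_summary(logs: Sequence) -> pd.DataFrame:
    """Per-session counts: trials, responses, rewards, volume, blocks."""
    rows = []
    for i, log in enumerate(logs):
        trials = log.trials
        n = len(trials)
        n_resp = sum(1 for t in trials if _responded(t))
        n_rew = sum(1 for t in trials if t.rewarded)
        n_switches = sum(1 for e in log.events if e.kind == "rule_switch")
        rows.append(
            {
                "session": i,
                "stage_id": log.config.stage_id,
                "n_trials": n,
                "n_response": n_resp,
                "response_rate": (n_resp / n) if n else math.nan,
                "n_rewarded": n_rew,
                "total_volume_ul": log.total_volume_ul,
                "n_switches": n_switches,
                "n_blocks": n_switches + 1 if n else 0,
                "terminated_by": log.terminated_by,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "session",
            "stage_id",
            "n_trials",
            "n_response",
            "response_rate",
            "n_rewarded",
            "total_volume_ul",
            "n_switches",
            "n_blocks",
            "terminated_by",
        ],
    )
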