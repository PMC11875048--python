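"""Independent brute-force oracles for windowed statistics.

These deliberately use naive exhaustive scans (every window of every required
length) so they share no code path with the package implementations they
check.
"""

from __future__ import annotations

import numpy as np

from shiftsim import Side, TrialRecord


def make_trial(i, correct=None, side=Side.LEFT, stage_id="SD", **kw):
    """Minimal trial record: ``correct=None`` encodes a no-response trial."""
    if correct is None:
        first = None
    else:
        first = side if correct else side.other
    return TrialRecord(
        trial_index=i,
        stage_id=stage_id,
        rewarded_side=side,
        first_response=first,
        correct=None if correct is None else bool(correct),
        rewarded=bool(correct),
        reward_volume_ul=4.0 if correct else 0.0,
        **kw,
    )


def random_outcome_trials(rng, n_max=200, stage_id="SD"):
    """A random synthetic outcome sequence: correct / incorrect / no-response."""
    n = int(rng.integers(1, n_max + 1))
    trials = []
    for i in range(1, n + 1):
        side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        u = rng.random()
        correct = None if u < 0.15 else (u < 0.15 + 0.55)
        trials.append(make_trial(i, correct=correct, side=side, stage_id=stage_id))
    return trials


def brute_moving_accuracy(trials, window):
    out = np.full(len(trials), np.nan)
    for i in range(len(trials)):
        resp = [t for t in trials[: i + 1] if t.first_response is not None]
        if len(resp) >= window:
            tail = resp[-window:]
            out[i] = sum(1 for t in tail if t.correct) / window
    return out


def brute_trials_to_criterion(trials, window, threshold):
    resp = [t for t in trials if t.first_response is not None]
    for k in range(window, len(resp) + 1):
        tail = resp[k - window : k]
        if sum(1 for t in tail if t.correct) / window >= threshold:
            return k
    return None


def brute_switch_trigger(block_trials, window=30, threshold=0.80):
    resp = [t for t in block_trials if t.first_response is not None]
    if len(resp) < window:
        return False
    tail = resp[-window:]
    return sum(1 for t in tail if t.correct) / window >= threshold


def brute_sd_pass(trials, min_trials=100, acc_window=30, acc_thr=0.80,
                  bal_window=10, bal_thr=0.50, resp_min=0.80):
    """Exhaustive scan of the fourfold simple-discrimination criterion."""
    n = len(trials)
    resp = [t for t in trials if t.first_response is not None]
    c1 = n > min_trials
    c2 = any(
        sum(1 for t in resp[k : k + acc_window] if t.correct) / acc_window >= acc_thr
        for k in range(0, len(resp) - acc_window + 1)
    )
    c3 = False
    for k in range(0, len(resp) - bal_window + 1):
        seg = resp[k : k + bal_window]
        left = [t for t in seg if t.rewarded_side is Side.LEFT]
        right = [t for t in seg if t.rewarded_side is Side.RIGHT]
        if not left or not right:
            continue
        la = sum(1 for t in left if t.correct) / len(left)
        ra = sum(1 for t in right if t.correct) / len(right)
        if la > bal_thr and ra > bal_thr:
            c3 = True
            break
    c4 = (len(resp) / n if n else 0.0) > resp_min
    return c1 and c2 and c3 and c4, (c1, c2, c3, c4)
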