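"""Bundle formats: JSON-lines event streams, per-trial CSV, manifests.

A *bundle* is a directory holding one session (or a cohort of sessions):

    manifest.json   versions, seed, the full config, and its SHA-256 digest
    events.jsonl    one EventRecord per line, keys in fixed order
    trials.csv      one TrialRecord per row (events omitted)
    summary.json    per-session counts

Cohort bundles hold a top-level ``manifest.json`` plus ``session_NNN/``
subdirectories.  Field ordering and separators are fixed, so identical runs
produce byte-identical bundles.  Timestamps are serialized as integers; sides
print as ``"L"`` / ``"R"``.  Reading validates every trial's invariants and
rejects corrupt rows with line- or row-numbered errors.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Union

from .core import (
    EventRecord,
    Modality,
    SessionConfig,
    Side,
    TrialRecord,
    config_from_dict,
    config_to_dict,
    validate_trial,
)
from .engine import SessionLog

__all__ = ["LogBundle", "config_digest", "write_bundle", "read_bundle"]

FORMAT_NAME = "shiftsim-bundle"
FORMAT_VERSION = 1

TRIAL_COLUMNS = [
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
]


@dataclass
class LogBundle:
    """Paths and manifest of one written bundle."""

    directory: Path
    manifest: dict
    events_path: Path
    trials_path: Path
    summary_path: Path


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def config_digest(config: SessionConfig) -> str:
    """SHA-256 of the canonically serialized config."""
    return hashlib.sha256(_canonical_json(config_to_dict(config)).encode()).hexdigest()


def _event_line(e: EventRecord) -> str:
    # fixed key order: t_ms, kind, then payload with sorted keys
    payload = _canonical_json(e.payload)
    return f'{{"t_ms":{int(e.t_ms)},"kind":"{e.kind}","payload":{payload}}}'


def _bool_cell(v) -> str:
    return "" if v is None else ("1" if v else "0")


def _parse_bool_cell(s: str):
    if s == "":
        return None
    return s == "1"


def _trial_row(t: TrialRecord) -> list:
    return [
        str(t.trial_index),
        t.stage_id,
        t.whisker_stim or "",
        t.odor_stim or "",
        t.rewarded_side.short,
        _bool_cell(t.congruent),
        t.first_response.short if t.first_response is not None else "none",
        _bool_cell(t.correct),
        _bool_cell(t.rewarded),
        repr(float(t.reward_volume_ul)),
        str(int(t.iti_ms)),
        t.relevant_modality.value,
        str(int(t.block_index)),
    ]


def write_bundle(log: Union[SessionLog, List[SessionLog]], directory) -> LogBundle:
    """Serialize a session (or list of sessions) to a bundle directory."""
    directory = Path(directory)
    if isinstance(log, (list, tuple)):
        directory.mkdir(parents=True, exist_ok=True)
        sub_manifests = []
        for i, session in enumerate(log):
            sub = write_bundle(session, directory / f"session_{i:03d}")
            sub_manifests.append(
                {"path": f"session_{i:03d}", "config_digest": sub.manifest["config_digest"]}
            )
        manifest = {
            "format": FORMAT_NAME,
            "version": FORMAT_VERSION,
            "kind": "cohort",
            "n_sessions": len(log),
            "sessions": sub_manifests,
        }
        mpath = directory / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return LogBundle(directory, manifest, directory, directory, mpath)

    directory.mkdir(parents=True, exist_ok=True)
    events_path = directory / "events.jsonl"
    with open(events_path, "w", encoding="utf-8", newline="\n") as fh:
        for e in log.events:
            fh.write(_event_line(e) + "\n")
    trials_path = directory / "trials.csv"
    with open(trials_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(TRIAL_COLUMNS)
        for t in log.trials:
            writer.writerow(_trial_row(t))
    n_resp = sum(1 for t in log.trials if t.first_response is not None)
    summary = {
        "n_trials": len(log.trials),
        "n_response": n_resp,
        "n_rewarded": sum(1 for t in log.trials if t.rewarded),
        "n_switches": sum(1 for e in log.events if e.kind == "rule_switch"),
        "total_volume_ul": log.total_volume_ul,
        "terminated_by": log.terminated_by,
    }
    summary_path = directory / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "kind": "session",
        "stage_id": log.config.stage_id,
        "seed": int(log.config.seed),
        "config": config_to_dict(log.config),
        "config_digest": config_digest(log.config),
        "terminated_by": log.terminated_by,
        "total_volume_ul": log.total_volume_ul,
        "n_trials": len(log.trials),
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return LogBundle(directory, manifest, events_path, trials_path, summary_path)


def _read_events(path: Path) -> list:
    events = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not line.endswith("\n"):
                raise ValueError(f"{path}:{lineno}: truncated event line")
            try:
                obj = json.loads(stripped)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed event line: {exc}") from None
            try:
                events.append(EventRecord(int(obj["t_ms"]), obj["kind"], dict(obj["payload"])))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid event: {exc}") from None
    return events


def _read_trials(path: Path) -> list:
    trials = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != TRIAL_COLUMNS:
            raise ValueError(f"{path}: unexpected trial table header: {header}")
        for rowno, row in enumerate(reader, start=2):
            if len(row) != len(TRIAL_COLUMNS):
                raise ValueError(f"{path}: row {rowno}: expected {len(TRIAL_COLUMNS)} fields")
            try:
                trials.append(
                    TrialRecord(
                        trial_index=int(row[0]),
                        stage_id=row[1],
                        whisker_stim=row[2] or None,
                        odor_stim=row[3] or None,
                        rewarded_side=Side.from_any(row[4]),
                        congruent=_parse_bool_cell(row[5]),
                        first_response=None if row[6] == "none" else Side.from_any(row[6]),
                        correct=_parse_bool_cell(row[7]),
                        rewarded=bool(_parse_bool_cell(row[8])),
                        reward_volume_ul=float(row[9]),
                        iti_ms=int(row[10]),
                        relevant_modality=Modality(row[11]),
                        block_index=int(row[12]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: row {rowno}: {exc}") from None
    return trials


def read_bundle(directory) -> Union[SessionLog, List[SessionLog]]:
    """Reconstruct a SessionLog (or cohort list) from a bundle directory.

    Validates the manifest digest against the serialized config and every
    trial's invariants; corrupt rows raise with their location.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{directory}: no manifest.json (not a bundle)")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != FORMAT_NAME:
        raise ValueError(f"{directory}: not a {FORMAT_NAME} bundle")
    if manifest.get("kind") == "cohort":
        return [read_bundle(directory / s["path"]) for s in manifest["sessions"]]
    config = config_from_dict(manifest["config"])
    if config_digest(config) != manifest["config_digest"]:
        raise ValueError(f"{directory}: manifest config digest mismatch")
    for name in ("events.jsonl", "trials.csv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"{directory}: bundle incomplete, missing {name}")
    events = _read_events(directory / "events.jsonl")
    trials = _read_trials(directory / "trials.csv")
    for rowno, t in enumerate(trials, start=2):
        problems = validate_trial(t, droplet_ul=config.droplet_ul)
        if problems:
            raise ValueError(f"{directory / 'trials.csv'}: row {rowno}: " + "; ".join(problems))
    # Re-attach each trial's events by walking the flat stream in order:
    # trials are sequential and non-overlapping, deferred bookkeeping events
    # and session-level events stay flat-only.
    by_trial: dict = {}
    current = None
    for e in events:
        if e.kind in ("rule_switch", "session_end", "stage_pass") or e.payload.get("deferred"):
            continue
        if e.kind == "trial_start":
            current = int(e.payload["trial"])
            by_trial[current] = [e]
            continue
        if current is None:
            raise ValueError(f"{directory}: event before any trial_start at t={e.t_ms}")
        by_trial[current].append(e)
        if e.kind == "trial_end":
            current = None
    for t in trials:
        t.events = by_trial.get(t.trial_index, [])
    total = sum(t.reward_volume_ul for t in trials)
    if abs(total - float(manifest["total_volume_ul"])) > 1e-9:
        raise ValueError(f"{directory}: total volume mismatch with manifest")
    return SessionLog(
        config=config,
        trials=trials,
        events=events,
        total_volume_ul=total,
        terminated_by=manifest["terminated_by"],
        shifts=_shifts_from_events(events),
    )


def _shifts_from_events(events) -> list:
    """Rebuild ShiftEvents from rule_switch payloads (full before/after maps)."""
    from .controller import ShiftEvent
    from .core import RuleState

    def _rule(payload, tag, block_index, trials_in_block):
        maps = {"w": {}, "o": {}}
        for key, val in payload.items():
            parts = key.split("_")
            if len(parts) == 3 and parts[0] == tag and parts[1] in maps:
                maps[parts[1]][parts[2]] = val
        return RuleState(
            relevant_modality=payload[f"relevant_{tag}"],
            whisker_map=maps["w"],
            odor_map=maps["o"],
            block_index=block_index,
            trials_in_block=trials_in_block,
        )

    shifts = []
    prev_switch_trial = 0
    for e in events:
        if e.kind != "rule_switch":
            continue
        idx = int(e.payload["trial"])
        i = len(shifts)
        shifts.append(
            ShiftEvent(
                trial_index=idx,
                shift_type=e.payload["shift_type"],
                rule_before=_rule(e.payload, "before", i, idx - prev_switch_trial),
                rule_after=_rule(e.payload, "after", i + 1, 0),
            )
        )
        prev_switch_trial = idx
    return shifts
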