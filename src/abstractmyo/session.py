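"""Session logging: the offline "data bucket".

A :class:`SessionBucket` holds the synchronized, timestamped streams of one
prosthesis session — the MAV control signal, the motor commands, the user's
feedback events (phone-reported intended grasps), configuration updates and
block markers — and supports feedback→command labeling and lossless export
to CSV, newline-delimited JSON and (write-only) ARFF.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .decoder import GraspMap, MotorCommandEvent
from .emg import MAVStream
from .errors import (
    FeedbackLagWarning,
    OrphanFeedbackWarning,
    SessionParseError,
)
from .timestamps import from_iso, ms_between, to_iso

__all__ = [
    "FeedbackEvent",
    "ConfigUpdate",
    "BlockMarker",
    "SessionBucket",
    "LabeledDecision",
    "label_feedback",
    "extract_labeled_decisions",
    "split_training_verification",
    "write_bucket",
    "read_bucket",
]


@dataclass
class FeedbackEvent:
    """The user reports (after the fact) which grasp they intended."""

    t: np.datetime64
    intended_grasp: str
    command_index: Optional[int] = None  # set by label_feedback; None if orphan


@dataclass
class ConfigUpdate:
    """A timestamped remote device-configuration change (flat key→value)."""

    t: np.datetime64
    changes: dict


@dataclass
class BlockMarker:
    """Start/stop of a protocol block (touchpad point-grip press)."""

    t: np.datetime64
    kind: str  # "start" | "stop"
    block: int


@dataclass
class SessionBucket:
    """All time-ordered event streams of one session."""

    mav: MAVStream = field(default_factory=MAVStream.empty)
    commands: list[MotorCommandEvent] = field(default_factory=list)
    feedback: list[FeedbackEvent] = field(default_factory=list)
    config_updates: list[ConfigUpdate] = field(default_factory=list)
    block_markers: list[BlockMarker] = field(default_factory=list)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SessionBucket)
            and self.mav == other.mav
            and self.commands == other.commands
            and self.feedback == other.feedback
            and self.config_updates == other.config_updates
            and self.block_markers == other.block_markers
        )


def label_feedback(bucket: SessionBucket, max_lag_s: float = 60.0) -> SessionBucket:
    """Attach each feedback event to its previous motor command.

    Each feedback event links to the most recent command strictly before it
    that carries no earlier label; the linked command is marked unexpected
    with the reported intended grasp.  Feedback with no linkable predecessor
    is retained but warned as orphan.  Links further back than ``max_lag_s``
    raise a QC warning but are kept (the matching window is unbounded).

    Idempotent: labels are recomputed from scratch on every call.  Mutates
    and returns ``bucket``.
    """
    for cmd in bucket.commands:
        cmd.intended_grasp = None
        cmd.unexpected = False
    taken = [False] * len(bucket.commands)
    for fb in sorted(bucket.feedback, key=lambda f: f.t):
        fb.command_index = None
        for i in range(len(bucket.commands) - 1, -1, -1):
            cmd = bucket.commands[i]
            if ms_between(fb.t, cmd.t) > 0 and not taken[i]:
                taken[i] = True
                fb.command_index = i
                cmd.intended_grasp = fb.intended_grasp
                cmd.unexpected = True
                lag_s = ms_between(fb.t, cmd.t) / 1000.0
                if lag_s > max_lag_s:
                    warnings.warn(
                        f"feedback at {to_iso(fb.t)} linked {lag_s:.1f} s back "
                        f"(> {max_lag_s:.0f} s QC lag)",
                        FeedbackLagWarning,
                    )
                break
        else:
            warnings.warn(
                f"feedback at {to_iso(fb.t)} has no unlabeled preceding command",
                OrphanFeedbackWarning,
            )
    return bucket


@dataclass(frozen=True)
class LabeledDecision:
    """One motor command reduced to its decision angle and intent labels.

    ``intended_target`` comes from feedback when present, else equals the
    executed target; ``unexpected`` means executed != intended.
    """

    v: float
    executed_target: int
    intended_target: int
    unexpected: bool


def extract_labeled_decisions(
    bucket: SessionBucket, grasp_map: GraspMap | None = None
) -> list[LabeledDecision]:
    """One :class:`LabeledDecision` per motor command (labeling applied first)."""
    gm = grasp_map or GraspMap()
    out = []
    for cmd in bucket.commands:
        if cmd.unexpected and cmd.intended_grasp is not None:
            intended = gm.target_for(cmd.intended_grasp)
        else:
            intended = cmd.target
        out.append(
            LabeledDecision(
                v=cmd.v,
                executed_target=cmd.target,
                intended_target=intended,
                unexpected=cmd.unexpected,
            )
        )
    return out


def split_training_verification(
    decisions: Sequence[LabeledDecision],
) -> tuple[list[LabeledDecision], list[LabeledDecision]]:
    """Correct commands form the training set; unexpected ones the
    verification set.  Counts are conserved."""
    training = [d for d in decisions if not d.unexpected]
    verification = [d for d in decisions if d.unexpected]
    return training, verification


# ---------------------------------------------------------------------------
# Serialization.  One events file; a `type` column selects the payload
# columns in use.  Floats use repr() so round-trips are byte-stable.

_FIELDS = [
    "t",
    "type",
    "m1",
    "m2",
    "target",
    "grasp",
    "x",
    "y",
    "r",
    "v",
    "intended_grasp",
    "unexpected",
    "link",
    "kind",
    "block",
    "changes",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _rows(bucket: SessionBucket) -> list[dict]:
    rows: list[dict] = []
    for i in range(len(bucket.mav)):
        rows.append(
            {
                "t": to_iso(bucket.mav.t[i]),
                "type": "mav",
                "m1": _fmt(float(bucket.mav.m[i, 0])),
                "m2": _fmt(float(bucket.mav.m[i, 1])),
            }
        )
    for cmd in bucket.commands:
        row = {
            "t": to_iso(cmd.t),
            "type": "command",
            "target": str(cmd.target),
            "grasp": cmd.grasp,
            "x": _fmt(cmd.x),
            "y": _fmt(cmd.y),
            "r": _fmt(cmd.r),
            "v": _fmt(cmd.v),
        }
        if cmd.intended_grasp is not None:
            row["intended_grasp"] = cmd.intended_grasp
        if cmd.unexpected:
            row["unexpected"] = "true"
        rows.append(row)
    for fb in bucket.feedback:
        row = {"t": to_iso(fb.t), "type": "feedback", "intended_grasp": fb.intended_grasp}
        if fb.command_index is not None:
            row["link"] = _fmt(fb.command_index)
        rows.append(row)
    for cu in bucket.config_updates:
        rows.append(
            {
                "t": to_iso(cu.t),
                "type": "config",
                "changes": json.dumps(cu.changes, sort_keys=True),
            }
        )
    for bm in bucket.block_markers:
        rows.append(
            {"t": to_iso(bm.t), "type": "marker", "kind": bm.kind, "block": str(bm.block)}
        )
    rows.sort(key=lambda r: (r["t"], r["type"]))
    return rows


def _bucket_from_rows(rows: list[tuple[int, dict]]) -> SessionBucket:
    mav_t, mav_m = [], []
    bucket = SessionBucket()
    for lineno, row in rows:
        kind = row.get("type")
        try:
            if kind == "mav":
                mav_t.append(from_iso(row["t"]))
                mav_m.append((float(row["m1"]), float(row["m2"])))
            elif kind == "command":
                bucket.commands.append(
                    MotorCommandEvent(
                        t=from_iso(row["t"]),
                        target=int(row["target"]),
                        grasp=row["grasp"],
                        x=float(row["x"]),
                        y=float(row["y"]),
                        r=float(row["r"]),
                        v=float(row["v"]),
                        intended_grasp=row.get("intended_grasp") or None,
                        unexpected=row.get("unexpected") == "true",
                    )
                )
            elif kind == "feedback":
                link = row.get("link")
                bucket.feedback.append(
                    FeedbackEvent(
                        t=from_iso(row["t"]),
                        intended_grasp=row["intended_grasp"],
                        command_index=int(link) if link not in (None, "") else None,
                    )
                )
            elif kind == "config":
                bucket.config_updates.append(
                    ConfigUpdate(t=from_iso(row["t"]), changes=json.loads(row["changes"]))
                )
            elif kind == "marker":
                bucket.block_markers.append(
                    BlockMarker(t=from_iso(row["t"]), kind=row["kind"], block=int(row["block"]))
                )
            else:
                raise ValueError(f"unknown event type {kind!r}")
        except (KeyError, TypeError, ValueError) as exc:
            raise SessionParseError(f"line {lineno}: malformed {kind or 'event'} record: {exc}") from exc
    if mav_t:
        bucket.mav = MAVStream(np.array(mav_t, dtype="datetime64[ms]"), np.array(mav_m))
    return bucket


def write_bucket(bucket: SessionBucket, path: str | Path, format: str | None = None) -> Path:
    """Serialize a bucket to ``csv``, ``json`` (newline-delimited) or ``arff``
    (flat command relation, write-only).  Format defaults from the suffix."""
    path = Path(path)
    format = format or {".csv": "csv", ".ndjson": "json", ".jsonl": "json", ".json": "json", ".arff": "arff"}.get(path.suffix)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS, restval="", lineterminator="\n")
            writer.writeheader()
            writer.writerows(_rows(bucket))
    elif format == "json":
        with open(path, "w") as fh:
            for row in _rows(bucket):
                fh.write(json.dumps(row, sort_keys=True) + "\n")
    elif format == "arff":
        _write_arff(bucket, path)
    else:
        raise ValueError(f"unknown session format {format!r} for {path}")
    return path


def _write_arff(bucket: SessionBucket, path: Path) -> None:
    lines = [
        "@relation motor_commands",
        "@attribute t string",
        "@attribute v numeric",
        "@attribute executed_target numeric",
        "@attribute executed_grasp {power,tripod,pinch,point,open}",
        "@attribute intended_grasp {power,tripod,pinch,point,open,unlabeled}",
        "@attribute unexpected {true,false}",
        "@data",
    ]
    for cmd in bucket.commands:
        lines.append(
            f"'{to_iso(cmd.t)}',{cmd.v!r},{cmd.target},{cmd.grasp},"
            f"{cmd.intended_grasp or 'unlabeled'},{_fmt(cmd.unexpected)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bucket(path: str | Path, format: str | None = None) -> SessionBucket:
    """Read a bucket back; raises :class:`SessionParseError` (naming the
    line) on any malformed record — no partial silent load."""
    path = Path(path)
    format = format or {".csv": "csv", ".ndjson": "json", ".jsonl": "json", ".json": "json"}.get(path.suffix)
    rows: list[tuple[int, dict]] = []
    if format == "csv":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, lineterminator="\n")
            try:
                header = next(reader)
            except StopIteration:
                raise SessionParseError("line 1: empty file, expected header")
            if header != _FIELDS:
                raise SessionParseError(f"line 1: unexpected header {header}")
            for lineno, rec in enumerate(reader, start=2):
                if len(rec) != len(_FIELDS):
                    raise SessionParseError(
                        f"line {lineno}: expected {len(_FIELDS)} fields, got {len(rec)}"
                    )
                rows.append((lineno, {k: v for k, v in zip(_FIELDS, rec) if v != ""}))
    elif format == "json":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append((lineno, json.loads(line)))
                except json.JSONDecodeError as exc:
                    raise SessionParseError(f"line {lineno}: invalid JSON: {exc}") from exc
    else:
        raise ValueError(f"cannot read session format {format!r} from {path}")
    return _bucket_from_rows(rows)
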