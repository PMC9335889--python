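"""Boundary-adaptation reports: default vs customized boundaries and
feedback/correction counts, as JSON-ready dicts and markdown."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .adaptation import AdaptationResult, adapt_boundaries, verify_boundaries
from .decoder import DecisionBoundaries, GraspMap
from .errors import SessionParseError
from .session import (
    SessionBucket,
    extract_labeled_decisions,
    label_feedback,
    split_training_verification,
)

__all__ = ["adaptation_report", "render_markdown", "write_report"]


def adaptation_report(
    bucket: SessionBucket,
    defaults: DecisionBoundaries = DecisionBoundaries(),
    priors_mode: str = "equal",
    grasp_map: GraspMap | None = None,
    user: str = "user",
) -> dict:
    """Label a bucket, adapt boundaries and verify; returns one dict holding
    a boundary row (default vs customized) and the feedback/correction counts.

    Raises :class:`SessionParseError` if the bucket carries no commands to
    learn from.
    """
    if not bucket.commands:
        raise SessionParseError(
            "bucket holds no motor commands; run a session (or decode a MAV "
            "stream) before adapting"
        )
    label_feedback(bucket)
    decisions = extract_labeled_decisions(bucket, grasp_map)
    training, verification = split_training_verification(decisions)
    boundaries, flags = adapt_boundaries(training, defaults, priors_mode)
    result: AdaptationResult = verify_boundaries(boundaries, verification)
    assert len(training) + len(verification) == len(bucket.commands)
    return {
        "user": user,
        "boundaries": {
            "default": list(defaults.as_tuple()),
            "customized": [round(b, 4) for b in boundaries.as_tuple()],
        },
        "counts": {
            "n_commands": len(bucket.commands),
            "n_training": len(training),
            "n_feedback": result.n_feedback,
            "n_corrected": result.n_corrected,
        },
        "priors_mode": priors_mode,
        "flags": flags,
    }


def render_markdown(report: dict) -> str:
    b = report["boundaries"]
    c = report["counts"]
    lines = [
        f"# Boundary adaptation report — {report['user']}",
        "",
        "## Customized decision boundaries",
        "",
        "| | boundary 1–2 | boundary 2–3 | boundary 3–4 |",
        "|---|---|---|---|",
        "| default | {:.1f}° | {:.1f}° | {:.1f}° |".format(*b["default"]),
        "| customized | {:.1f}° | {:.1f}° | {:.1f}° |".format(*b["customized"]),
        "",
        "## Feedback and corrections",
        "",
        "| no. of commands | no. of feedback | no. of corrections |",
        "|---|---|---|",
        f"| {c['n_commands']} | {c['n_feedback']} | {c['n_corrected']} |",
    ]
    if report["flags"]:
        lines += ["", "## Flags", ""] + [f"- {f}" for f in report["flags"]]
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    jpath = out_dir / "report.json"
    mpath = out_dir / "report.md"
    jpath.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    mpath.write_text(render_markdown(report))
    return jpath, mpath
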