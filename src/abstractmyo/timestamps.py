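"""Millisecond-resolution UTC timestamps.

All event streams in the package share one time representation:
``numpy.datetime64`` at millisecond resolution, interpreted as UTC.
Serialized form is ISO-8601 with a trailing ``Z`` and exactly three
fractional digits, so round-trips are byte-stable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_ms", "to_iso", "from_iso", "ms_between", "add_ms", "DEFAULT_T0"]

#: Conventional session start used when a caller supplies no clock.
DEFAULT_T0 = np.datetime64("2022-01-01T09:00:00.000", "ms")


def as_ms(t) -> np.datetime64:
    """Coerce a datetime64 (or ISO string) to millisecond resolution."""
    return np.datetime64(t, "ms")


def to_iso(t) -> str:
    """ISO-8601 UTC string with millisecond precision, e.g. 2022-01-01T09:00:00.000Z."""
    return np.datetime_as_string(as_ms(t), unit="ms") + "Z"


def from_iso(s: str) -> np.datetime64:
    try:
        return np.datetime64(s.rstrip("Z"), "ms")
    except ValueError as exc:
        raise ValueError(f"not an ISO-8601 timestamp: {s!r}") from exc


def ms_between(later, earlier) -> float:
    """Signed difference ``later - earlier`` in milliseconds."""
    return (as_ms(later) - as_ms(earlier)) / np.timedelta64(1, "ms")


def add_ms(t, ms: float) -> np.datetime64:
    return as_ms(t) + np.timedelta64(int(round(ms)), "ms")
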