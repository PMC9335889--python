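"""Two-channel surface EMG conditioning and MAV feature extraction.

The control feature throughout the package is the normalized mean-absolute
value (MAV) of two forearm muscles (flexor and extensor carpi radialis by
convention).  Raw EMG sampled at 500 Hz is band-pass filtered, notch
filtered at the mains frequency, rectified and averaged over a sliding
window, then normalized against a per-channel rest/maximum calibration so
that 0 means muscle rest and 1 means the calibrated maximum contraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal

from .errors import CalibrationError, ConfigurationError
from .timestamps import DEFAULT_T0, as_ms, from_iso, to_iso

__all__ = [
    "EMGRecord",
    "FilterSpec",
    "CalibrationParams",
    "MAVSample",
    "MAVStream",
    "apply_filters",
    "compute_mav",
    "calibrate",
    "normalize",
]

DEFAULT_CHANNELS = ("FCR", "ECR")


@dataclass
class EMGRecord:
    """Raw two-channel EMG with a uniform timebase.

    Parameters
    ----------
    samples
        Array of shape ``(2, n)`` in arbitrary ADC/voltage units.
    fs
        Sampling rate in Hz (default 500).
    t0
        UTC start timestamp, millisecond resolution.
    channel_names
        Two labels; defaults to ("FCR", "ECR").
    """

    samples: np.ndarray
    fs: float = 500.0
    t0: np.datetime64 = DEFAULT_T0
    channel_names: tuple[str, str] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != 2:
            raise ConfigurationError(
                f"EMGRecord requires exactly 2 channels, got {self.samples.shape[0]}"
            )
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        self.t0 = as_ms(self.t0)
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != 2:
            raise ConfigurationError("exactly two channel names required")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def to_csv(self, path: str | Path) -> None:
        """Write samples as CSV (t_iso8601, ch1, ch2) plus a JSON header sidecar."""
        path = Path(path)
        dt_ms = 1000.0 / self.fs
        with open(path, "w", newline="") as fh:
            fh.write("t_iso8601,%s,%s\n" % self.channel_names)
            for i in range(self.n_samples):
                t = self.t0 + np.timedelta64(int(round(i * dt_ms)), "ms")
                fh.write(
                    f"{to_iso(t)},{float(self.samples[0, i])!r},{float(self.samples[1, i])!r}\n"
                )
        sidecar = {
            "fs": self.fs,
            "channel_names": list(self.channel_names),
            "units": "arbitrary",
            "t0": to_iso(self.t0),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "EMGRecord":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        raw = np.loadtxt(
            path, delimiter=",", skiprows=1, usecols=(1, 2), dtype=float, ndmin=2
        )
        return cls(
            samples=raw.T,
            fs=float(sidecar["fs"]),
            t0=from_iso(sidecar["t0"]),
            channel_names=tuple(sidecar["channel_names"]),
        )


@dataclass(frozen=True)
class FilterSpec:
    """Pre-processing filter parameters for the raw EMG.

    Defaults: 20–230 Hz 4th-order Butterworth band-pass (fs = 500 Hz gives a
    250 Hz Nyquist, so 230 Hz leaves margin) and a 50 Hz mains notch with
    Q = 30.  Set ``notch_hz`` to None to disable the notch.
    """

    band_low_hz: float = 20.0
    band_high_hz: float = 230.0
    band_order: int = 4
    notch_hz: float | None = 50.0
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0.0 < self.band_low_hz < self.band_high_hz < nyq):
            raise ConfigurationError(
                f"band edges ({self.band_low_hz}, {self.band_high_hz}) Hz invalid "
                f"against Nyquist {nyq} Hz"
            )
        if self.notch_hz is not None and not (0.0 < self.notch_hz < nyq):
            raise ConfigurationError(f"notch at {self.notch_hz} Hz outside (0, {nyq})")


@dataclass(frozen=True)
class CalibrationParams:
    """Per-channel rest and maximum-contraction MAV levels."""

    rest_level: tuple[float, float]
    max_level: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rest_level", tuple(float(x) for x in self.rest_level))
        object.__setattr__(self, "max_level", tuple(float(x) for x in self.max_level))
        for rest, mx in zip(self.rest_level, self.max_level):
            if not (mx > rest >= 0.0):
                raise CalibrationError(
                    f"require max_level > rest_level >= 0, got rest={rest}, max={mx}"
                )


class MAVSample(NamedTuple):
    """One normalized MAV pair; drives the task-space cursor."""

    t: np.datetime64
    m1: float
    m2: float


@dataclass
class MAVStream:
    """A time-ordered stream of MAV pairs.

    ``t`` is a datetime64[ms] array, strictly increasing; ``m`` has shape
    ``(n, 2)`` with channel 1 in column 0.
    """

    t: np.ndarray
    m: np.ndarray
    channel_names: tuple[str, str] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype="datetime64[ms]")
        self.m = np.asarray(self.m, dtype=float).reshape(-1, 2)
        if self.t.shape[0] != self.m.shape[0]:
            raise ConfigurationError("timestamp and MAV arrays must align")
        if self.t.size > 1 and not np.all(np.diff(self.t) > np.timedelta64(0, "ms")):
            raise ConfigurationError("MAV timestamps must be strictly increasing")
        self.channel_names = tuple(self.channel_names)

    def __len__(self) -> int:
        return self.t.shape[0]

    def __iter__(self):
        for i in range(len(self)):
            yield MAVSample(self.t[i], float(self.m[i, 0]), float(self.m[i, 1]))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MAVStream)
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.m, other.m)
            and self.channel_names == other.channel_names
        )

    @classmethod
    def empty(cls) -> "MAVStream":
        return cls(np.empty(0, dtype="datetime64[ms]"), np.empty((0, 2)))

    @classmethod
    def concat(cls, parts: Sequence["MAVStream"]) -> "MAVStream":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(
            np.concatenate([p.t for p in parts]),
            np.concatenate([p.m for p in parts]),
            parts[0].channel_names,
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("t_iso8601,m1,m2\n")
            for i in range(len(self)):
                fh.write(
                    f"{to_iso(self.t[i])},{float(self.m[i, 0])!r},{float(self.m[i, 1])!r}\n"
                )

    @classmethod
    def read_csv(cls, path: str | Path) -> "MAVStream":
        ts, ms = [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("t_iso8601"):
                raise ConfigurationError(f"{path}: not a MAV stream CSV")
            for line in fh:
                tok = line.rstrip("\n").split(",")
                ts.append(from_iso(tok[0]))
                ms.append((float(tok[1]), float(tok[2])))
        if not ts:
            return cls.empty()
        return cls(np.array(ts, dtype="datetime64[ms]"), np.array(ms))


def _notch_sos(notch_hz: float, notch_q: float, fs: float) -> np.ndarray:
    b, a = signal.iirnotch(notch_hz, notch_q, fs=fs)
    return signal.tf2sos(b, a)


def apply_filters(
    rec: EMGRecord, spec: FilterSpec = FilterSpec(), *, causal: bool = False
) -> EMGRecord:
    """Band-pass and notch filter an EMG record, preserving shape and timebase.

    Zero-phase (forward-backward) by default, which suits offline analysis;
    ``causal=True`` applies the filters once in the forward direction for
    closed-loop realism.
    """
    spec.validate(rec.fs)
    sos_band = signal.butter(
        spec.band_order,
        [spec.band_low_hz, spec.band_high_hz],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    stages = [sos_band]
    if spec.notch_hz is not None:
        stages.append(_notch_sos(spec.notch_hz, spec.notch_q, rec.fs))
    out = rec.samples
    for sos in stages:
        out = signal.sosfilt(sos, out, axis=1) if causal else signal.sosfiltfilt(sos, out, axis=1)
    return replace(rec, samples=out)


def compute_mav(
    rec: EMGRecord, window_ms: float = 150.0, step_ms: float = 50.0
) -> MAVStream:
    """Trailing-window mean-absolute value per channel.

    Each output sample is the mean of ``|x|`` over the trailing window; its
    timestamp is the window end.  A record shorter than one window yields an
    empty stream with a warning.
    """
    if not (window_ms >= step_ms > 0):
        raise ConfigurationError("require window_ms >= step_ms > 0")
    w = max(1, int(round(window_ms * rec.fs / 1000.0)))
    s = max(1, int(round(step_ms * rec.fs / 1000.0)))
    n = rec.n_samples
    if n < w:
        warnings.warn(
            f"record of {n} samples shorter than one {w}-sample window; empty MAV stream"
        )
        return MAVStream.empty()
    rect = np.abs(rec.samples)
    windows = np.lib.stride_tricks.sliding_window_view(rect, w, axis=1)
    mav = windows[:, ::s, :].mean(axis=2)  # (2, n_windows)
    ends = np.arange(w - 1, n, s)  # index of last sample in each window
    dt_ms = 1000.0 / rec.fs
    t = rec.t0 + ((ends + 1) * dt_ms).round().astype("timedelta64[ms]")
    return MAVStream(t, mav.T, rec.channel_names)


def calibrate(
    rest: EMGRecord,
    contractions: Sequence[EMGRecord],
    *,
    window_ms: float = 150.0,
    step_ms: float = 50.0,
    max_percentile: float = 95.0,
) -> CalibrationParams:
    """Derive rest/max MAV levels from a rest recording and per-channel
    maximum-contraction recordings.

    ``rest_level`` is the per-channel median MAV of the rest recording (robust
    to transient artifacts); ``max_level`` for channel *i* is the
    ``max_percentile``-th percentile of that channel's MAV during
    ``contractions[i]`` (robust to isolated spikes).  Raises
    :class:`CalibrationError` when the contrast is absent.
    """
    recs = [rest, *contractions]
    if len(contractions) != 2:
        raise CalibrationError("one contraction recording per channel required")
    for r in recs:
        if r.duration_s < 2.0:
            raise CalibrationError(
                f"calibration recordings must be >= 2 s, got {r.duration_s:.2f} s"
            )
    rest_mav = compute_mav(rest, window_ms, step_ms).m
    rest_level = np.median(rest_mav, axis=0)
    max_level = np.empty(2)
    for ch in (0, 1):
        mav = compute_mav(contractions[ch], window_ms, step_ms).m
        max_level[ch] = np.percentile(mav[:, ch], max_percentile)
    if np.any(max_level <= rest_level):
        raise CalibrationError(
            f"no rest/contraction contrast: rest={rest_level}, max={max_level}"
        )
    return CalibrationParams(tuple(rest_level), tuple(max_level))


def normalize(
    mav_raw: MAVStream,
    params: CalibrationParams,
    gain: tuple[float, float] = (1.0, 1.0),
    m_cap: float = 1.5,
) -> MAVStream:
    """Map raw MAV onto the calibrated [0, m_cap] control scale.

    ``m = gain * max(0, raw - rest) / (max - rest)``, clipped at ``m_cap``
    (default 1.5, so overshoot beyond the calibrated maximum stays
    representable but bounded).
    """
    rest = np.asarray(params.rest_level)
    span = np.asarray(params.max_level) - rest
    m = np.asarray(gain, dtype=float) * np.maximum(0.0, mav_raw.m - rest) / span
    return MAVStream(mav_raw.t, np.clip(m, 0.0, m_cap), mav_raw.channel_names)
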