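"""Abstract myoelectric decoder: cursor, dwell target selection, grasp gating.

The two normalized MAV channels place a cursor in the first quadrant of a 2D
task space (channel 1 on x, channel 2 on y).  Four circular targets sit on an
arc; the user selects one by holding the cursor inside its disc for a dwell
period.  The polar angle *v* of the cursor at the moment of selection is the
single feature of the adaptation classifier, and three decision boundaries
partition [0°, 90°] into the four target regions.  A two-state hand machine
(OPEN / CLOSED) accepts a closing grasp only when the hand is open and the
cursor has re-armed in the rest basket near the origin, which rules out
inadvertent grasps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .emg import MAVSample, MAVStream
from .errors import ConfigurationError, ProtocolError
from .timestamps import ms_between, to_iso

__all__ = [
    "GRASPS",
    "CLOSING_TARGETS",
    "OPEN_TARGET",
    "DecisionBoundaries",
    "GraspMap",
    "TaskSpaceConfig",
    "CursorState",
    "MotorCommandEvent",
    "HandState",
    "mav_to_cursor",
    "classify_target",
    "DwellSelector",
    "GraspStateMachine",
    "AbstractDecoder",
    "TrialResult",
    "run_familiarization_trial",
    "evaluate_familiarization_stage",
]

GRASPS = ("power", "tripod", "pinch", "point", "open")
CLOSING_TARGETS = (1, 2, 3)
OPEN_TARGET = 4


@dataclass(frozen=True)
class DecisionBoundaries:
    """Three ordered angles (degrees) splitting [0°, 90°] into four regions.

    Defaults are the symmetric partition 22.5° / 45° / 67.5°; customized
    values come from the equal-density adaptation fit.
    """

    b12: float = 22.5
    b23: float = 45.0
    b34: float = 67.5

    def __post_init__(self) -> None:
        if not (0.0 < self.b12 < self.b23 < self.b34 < 90.0):
            raise ConfigurationError(
                f"boundaries must satisfy 0 < b12 < b23 < b34 < 90, got "
                f"({self.b12}, {self.b23}, {self.b34})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.b12, self.b23, self.b34)


def classify_target(v, boundaries: DecisionBoundaries = DecisionBoundaries()):
    """Map decision angle(s) to a target index 1–4.

    Half-open intervals: a boundary angle belongs to the higher-indexed
    target (v = b12 classifies as target 2).  Accepts scalars or arrays.
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 90.0):
        raise ValueError(f"decision angle outside [0, 90] degrees: {v}")
    idx = np.searchsorted(np.array(boundaries.as_tuple()), arr, side="right") + 1
    return int(idx) if np.isscalar(v) or arr.ndim == 0 else idx


@dataclass
class GraspMap:
    """Target → grasp assignment.

    Targets 1–3 carry closing grasps and target 4 opens the hand; target 2
    is the switchable tripod/pinch slot (changed remotely between protocol
    halves in the pick-and-place study).
    """

    assignment: dict = field(
        default_factory=lambda: {1: "power", 2: "tripod", 3: "point", 4: "open"}
    )

    def __post_init__(self) -> None:
        if set(self.assignment) != {1, 2, 3, 4}:
            raise ConfigurationError("grasp map must cover targets 1-4")
        if self.assignment[4] != "open":
            raise ConfigurationError("target 4 must map to 'open'")
        for t in CLOSING_TARGETS:
            if self.assignment[t] not in ("power", "tripod", "pinch", "point"):
                raise ConfigurationError(
                    f"target {t} must carry a closing grasp, got {self.assignment[t]!r}"
                )

    def grasp_for(self, target: int) -> str:
        return self.assignment[target]

    def target_for(self, grasp: str) -> int:
        if grasp == "open":
            return OPEN_TARGET
        if grasp in ("tripod", "pinch"):
            return 2  # both occupy the switchable slot
        for t, g in self.assignment.items():
            if g == grasp:
                return t
        raise KeyError(f"grasp {grasp!r} not assigned to any target")

    def with_target2(self, grasp: str) -> "GraspMap":
        if grasp not in ("tripod", "pinch"):
            raise ConfigurationError("target 2 accepts only tripod or pinch")
        new = dict(self.assignment)
        new[2] = grasp
        return GraspMap(new)


@dataclass(frozen=True)
class TaskSpaceConfig:
    """Geometry and timing of the abstract task space.

    Target centers lie on the bisectors of the default decision regions at
    radius 0.7 in normalized-MAV units; discs have radius 0.13 so adjacent
    discs do not overlap.  The rest basket is the region within
    ``basket_radius`` of the origin.  ``trial_timeout_ms`` is the 1.5 s
    familiarization limit.
    """

    target_angles: tuple[float, float, float, float] = (11.25, 33.75, 56.25, 78.75)
    target_center_radius: float = 0.7
    target_radius: float = 0.13
    basket_radius: float = 0.15
    dwell_ms: float = 500.0
    trial_timeout_ms: float = 1500.0

    def __post_init__(self) -> None:
        ang = self.target_angles
        if len(ang) != 4 or any(not (0.0 < a < 90.0) for a in ang):
            raise ConfigurationError("need four target angles inside (0, 90) degrees")
        if any(b <= a for a, b in zip(ang, ang[1:])):
            raise ConfigurationError("target angles must be strictly increasing")
        if not (0.0 < self.basket_radius < self.target_center_radius):
            raise ConfigurationError("require 0 < basket_radius < target_center_radius")
        if self.dwell_ms <= 0:
            raise ConfigurationError("dwell_ms must be positive")
        min_gap = min(
            2.0 * self.target_center_radius * math.sin(math.radians((b - a) / 2.0))
            for a, b in zip(ang, ang[1:])
        )
        if min_gap <= 2.0 * self.target_radius:
            raise ConfigurationError(
                f"target discs overlap: adjacent center distance {min_gap:.3f} "
                f"<= 2 * target_radius {2 * self.target_radius:.3f}"
            )

    def target_centers(self) -> np.ndarray:
        """(4, 2) array of disc centers."""
        ang = np.radians(self.target_angles)
        return self.target_center_radius * np.column_stack([np.cos(ang), np.sin(ang)])


@dataclass(frozen=True)
class CursorState:
    """Cursor position at one instant; ``v`` is None at the origin."""

    t: np.datetime64
    x: float
    y: float
    r: float
    v: Optional[float]


def mav_to_cursor(s: MAVSample) -> CursorState:
    """Place the cursor at (m1, m2); polar angle in degrees from the x-axis."""
    x, y = float(s.m1), float(s.m2)
    r = math.hypot(x, y)
    v = math.degrees(math.atan2(y, x)) if r > 0.0 else None
    return CursorState(t=s.t, x=x, y=y, r=r, v=v)


@dataclass
class MotorCommandEvent:
    """A grasp decision: timestamp, executed target/grasp, and the decision
    cursor whose angle ``v`` feeds the adaptation classifier.

    ``intended_grasp``/``unexpected`` are filled in by feedback labeling.
    """

    t: np.datetime64
    target: int
    grasp: str
    x: float
    y: float
    r: float
    v: float
    intended_grasp: Optional[str] = None
    unexpected: bool = False

    def __repr__(self) -> str:  # timestamps render poorly by default
        lab = f" intended={self.intended_grasp}" if self.unexpected else ""
        return (
            f"MotorCommandEvent({to_iso(self.t)} target={self.target} "
            f"grasp={self.grasp} v={self.v:.2f}deg{lab})"
        )


class DwellSelector:
    """Fires a target when the cursor stays inside its disc for the dwell
    period continuously.  Leaving the disc resets the timer; a disc fires at
    most once per continuous visit.
    """

    def __init__(self, cfg: TaskSpaceConfig):
        self.cfg = cfg
        self._centers = cfg.target_centers()
        self.reset()

    def reset(self) -> None:
        self._inside: Optional[int] = None
        self._entry_t = None
        self._fired = False

    def _disc_at(self, x: float, y: float) -> Optional[int]:
        d = np.hypot(self._centers[:, 0] - x, self._centers[:, 1] - y)
        i = int(np.argmin(d))
        return i + 1 if d[i] <= self.cfg.target_radius else None

    def update(self, c: CursorState) -> Optional[int]:
        """Advance by one cursor sample; return the fired target or None."""
        disc = self._disc_at(c.x, c.y)
        if disc != self._inside:
            self._inside = disc
            self._entry_t = c.t
            self._fired = False
            return None
        if disc is None or self._fired:
            return None
        if ms_between(c.t, self._entry_t) >= self.cfg.dwell_ms:
            self._fired = True
            return disc
        return None


@dataclass
class HandState:
    """Two-state prosthetic hand: OPEN or CLOSED(grasp); ``armed`` is set
    when the hand is open and the cursor visits the rest basket."""

    state: str = "OPEN"  # "OPEN" or the closing grasp name
    armed: bool = False

    @property
    def is_open(self) -> bool:
        return self.state == "OPEN"


class GraspStateMachine:
    """Gate dwell fires into motor commands.

    A closing command is emitted only when the hand is open *and* the cursor
    has re-armed in the basket since the last command; an open command only
    when the hand is closed.  Ineligible fires are silently discarded (and
    counted).  The executed target of an emitted command is
    ``classify_target(v, boundaries)`` at the decision point, so commands are
    always consistent with the boundaries in force.
    """

    def __init__(
        self,
        grasp_map: GraspMap | None = None,
        boundaries: DecisionBoundaries | None = None,
        cfg: TaskSpaceConfig | None = None,
    ):
        self.grasp_map = grasp_map or GraspMap()
        self.boundaries = boundaries or DecisionBoundaries()
        self.cfg = cfg or TaskSpaceConfig()
        self.hand = HandState()
        self.n_discarded = 0

    def step(
        self, c: CursorState, fired_target: Optional[int]
    ) -> Optional[MotorCommandEvent]:
        if self.hand.is_open and c.r < self.cfg.basket_radius:
            self.hand.armed = True
        if fired_target is None or c.v is None:
            return None
        target = classify_target(c.v, self.boundaries)
        grasp = self.grasp_map.grasp_for(target)
        if target in CLOSING_TARGETS:
            if not (self.hand.is_open and self.hand.armed):
                self.n_discarded += 1
                return None
            self.hand = HandState(state=grasp, armed=False)
        else:  # open command
            if self.hand.is_open:
                self.n_discarded += 1
                return None
            self.hand = HandState(state="OPEN", armed=False)
        return MotorCommandEvent(
            t=c.t, target=target, grasp=grasp, x=c.x, y=c.y, r=c.r, v=float(c.v)
        )


class AbstractDecoder:
    """Full closed-loop decoder: MAV stream in, motor commands out.

    Boundary/grasp-map updates may be scheduled with a timestamp; they take
    effect for all samples at or after that time (remote-reconfiguration
    semantics).
    """

    def __init__(
        self,
        cfg: TaskSpaceConfig | None = None,
        boundaries: DecisionBoundaries | None = None,
        grasp_map: GraspMap | None = None,
    ):
        self.cfg = cfg or TaskSpaceConfig()
        self.selector = DwellSelector(self.cfg)
        self.machine = GraspStateMachine(grasp_map, boundaries, self.cfg)
        self._pending: list[tuple[np.datetime64, dict]] = []

    @property
    def boundaries(self) -> DecisionBoundaries:
        return self.machine.boundaries

    @property
    def n_discarded(self) -> int:
        return self.machine.n_discarded

    def schedule_update(
        self,
        t,
        boundaries: DecisionBoundaries | None = None,
        target2_grasp: str | None = None,
    ) -> None:
        changes: dict = {}
        if boundaries is not None:
            changes["boundaries"] = boundaries
        if target2_grasp is not None:
            changes["target2_grasp"] = target2_grasp
        self._pending.append((np.datetime64(t, "ms"), changes))
        self._pending.sort(key=lambda p: p[0])

    def _apply_due(self, t) -> None:
        while self._pending and self._pending[0][0] <= t:
            _, changes = self._pending.pop(0)
            if "boundaries" in changes:
                self.machine.boundaries = changes["boundaries"]
            if "target2_grasp" in changes:
                self.machine.grasp_map = self.machine.grasp_map.with_target2(
                    changes["target2_grasp"]
                )

    def process(self, s: MAVSample) -> Optional[MotorCommandEvent]:
        self._apply_due(s.t)
        c = mav_to_cursor(s)
        fired = self.selector.update(c)
        return self.machine.step(c, fired)

    def decode(self, stream: MAVStream | Iterable[MAVSample]) -> list[MotorCommandEvent]:
        out = []
        for s in stream:
            cmd = self.process(s)
            if cmd is not None:
                out.append(cmd)
        return out


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one familiarization trial."""

    success: bool
    time_to_hit_s: Optional[float]


def run_familiarization_trial(
    stream: MAVStream | Sequence[MAVSample],
    prompted_target: int,
    cfg: TaskSpaceConfig | None = None,
) -> TrialResult:
    """Stage-1 familiarization semantics: success iff the prompted target's
    disc is *entered* (no dwell) within the trial timeout.

    The stream must start with the cursor in the rest basket.
    """
    cfg = cfg or TaskSpaceConfig()
    samples = list(stream)
    if not samples:
        raise ProtocolError("empty trial stream")
    first = mav_to_cursor(samples[0])
    if first.r >= cfg.basket_radius:
        raise ProtocolError(
            f"trial must start in the basket (r={first.r:.3f} >= {cfg.basket_radius})"
        )
    center = cfg.target_centers()[prompted_target - 1]
    t_start = samples[0].t
    for s in samples:
        elapsed_ms = ms_between(s.t, t_start)
        if elapsed_ms > cfg.trial_timeout_ms:
            break
        if math.hypot(s.m1 - center[0], s.m2 - center[1]) <= cfg.target_radius:
            return TrialResult(True, elapsed_ms / 1000.0)
    return TrialResult(False, None)


def evaluate_familiarization_stage(
    results: Sequence[tuple[int, TrialResult]], threshold: float = 0.7
) -> dict:
    """Per-target success rates over a stage; cleared iff every target's
    rate strictly exceeds the threshold (default 70%)."""
    rates = {}
    for target in (1, 2, 3, 4):
        trials = [r for tgt, r in results if tgt == target]
        rates[target] = (
            sum(r.success for r in trials) / len(trials) if trials else 0.0
        )
    return {"per_target_rate": rates, "cleared": all(r > threshold for r in rates.values())}
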