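"""Virtual users: synthetic aiming, trajectories, sessions and raw EMG.

The simulator replaces the human participant and the hardware so that every
stage of the pipeline is testable end-to-end.  A virtual user aims at a
target with Gaussian angular error, reaches outward from the rest basket,
dwells, and occasionally mis-aims into a neighboring decision region — the
event that produces "unexpected grasp" feedback.  Sessions follow the
pick-and-place block protocol (16 blocks in two halves, with the target-2
grasp switched from tripod to pinch remotely between the halves).  Raw EMG
is emulated as band-limited Gaussian noise amplitude-modulated by the
commanded activation envelope, plus mains interference and sensor noise.

Ground truth (intended targets, scheduled mis-aims, activation envelopes)
is returned out-of-band and never written into the exported bucket.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

from .decoder import (
    CLOSING_TARGETS,
    OPEN_TARGET,
    AbstractDecoder,
    DecisionBoundaries,
    GraspMap,
    TaskSpaceConfig,
    classify_target,
)
from .emg import EMGRecord, MAVStream
from .session import BlockMarker, ConfigUpdate, FeedbackEvent, LabeledDecision, SessionBucket
from .timestamps import DEFAULT_T0, add_ms

__all__ = [
    "RECTIFIED_GAUSSIAN_MEAN",
    "VirtualUserProfile",
    "BlockPlan",
    "SessionGroundTruth",
    "region_bounds",
    "simulate_reach",
    "simulate_session",
    "simulate_labeled_decisions",
    "synthesize_emg",
]

#: E|X| for X ~ N(0, 1): the MAV of unit-variance noise scaled by envelope a
#: is a * sqrt(2/pi).
RECTIFIED_GAUSSIAN_MEAN = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class VirtualUserProfile:
    """Behavioral parameters of a synthetic participant.

    ``aim_mean`` is one mean aiming angle per target (degrees); None uses
    the task-space target centers.  ``aim_sigma`` (5° default) is the
    trial-to-trial angular scatter; ``misaim_prob`` (0.15 default, within
    the per-participant feedback rates observed in pick-and-place sessions)
    is the chance a closing reach is directed into a neighboring decision
    region.  ``reach_speed`` is in task-space units per second and
    ``tremor_sigma`` is per-sample positional noise.
    """

    aim_mean: Optional[tuple[float, float, float, float]] = None
    aim_sigma: float = 5.0
    reach_speed: float = 1.4
    tremor_sigma: float = 0.01
    misaim_prob: float = 0.15
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.aim_sigma <= 0:
            raise ValueError("aim_sigma must be positive")
        if not 0.0 <= self.misaim_prob < 1.0:
            raise ValueError("misaim_prob must lie in [0, 1)")

    def means(self, cfg: TaskSpaceConfig) -> tuple[float, ...]:
        return self.aim_mean if self.aim_mean is not None else cfg.target_angles


@dataclass(frozen=True)
class BlockPlan:
    """Ordered grasp sequences of the pick-and-place protocol."""

    blocks: tuple[tuple[str, ...], ...]

    @classmethod
    def default(cls, n_blocks: int = 16) -> "BlockPlan":
        """First half: point, tripod, power, point (disc + can); second
        half: point, pinch, power, point (ball + can)."""
        first = ("point", "tripod", "power", "point")
        second = ("point", "pinch", "power", "point")
        half = n_blocks // 2
        return cls(tuple([first] * half + [second] * (n_blocks - half)))


@dataclass
class SessionGroundTruth:
    """Out-of-band truth for a simulated session (kept off the bucket)."""

    intended_targets: list[int] = field(default_factory=list)  # per command
    misaim_command_indices: list[int] = field(default_factory=list)
    n_planned_grasps: int = 0
    n_extra_reaches: int = 0


def region_bounds(
    target: int, boundaries: DecisionBoundaries
) -> tuple[float, float]:
    """Angular decision region [lo, hi) of a target under given boundaries."""
    edges = (0.0, *boundaries.as_tuple(), 90.0)
    return edges[target - 1], edges[target]


def _draw_aim_angle(
    profile: VirtualUserProfile,
    intended: int,
    cfg: TaskSpaceConfig,
    boundaries: DecisionBoundaries,
    rng: np.random.Generator,
    misaim: bool,
) -> float:
    mu = profile.means(cfg)[intended - 1]
    if misaim:
        neighbors = [t for t in (intended - 1, intended + 1) if 1 <= t <= 4]
        neighbor = neighbors[0] if len(neighbors) == 1 else int(rng.choice(neighbors))
        lo, hi = region_bounds(neighbor, boundaries)
        a, b = (lo - mu) / profile.aim_sigma, (hi - mu) / profile.aim_sigma
        theta = float(
            stats.truncnorm.rvs(a, b, loc=mu, scale=profile.aim_sigma, random_state=rng)
        )
    else:
        theta = float(rng.normal(mu, profile.aim_sigma))
    return float(np.clip(theta, 0.1, 89.9))


def simulate_reach(
    profile: VirtualUserProfile,
    intended_target: int,
    cfg: TaskSpaceConfig,
    rng: np.random.Generator,
    *,
    t_start=DEFAULT_T0,
    boundaries: DecisionBoundaries | None = None,
    misaim: Optional[bool] = None,
) -> tuple[MAVStream, float, bool]:
    """One basket→target→basket reach as a MAV trajectory.

    The aim angle is drawn from the intended target's aim distribution, or
    from it truncated to a neighboring decision region on a mis-aim (drawn
    with ``profile.misaim_prob`` unless forced via ``misaim``).  The
    endpoint is pulled toward the nearest disc center when the drawn ray
    misses every disc (visual homing), which never changes the decision
    region.  Returns ``(segment, drawn_angle, misaimed)``.
    """
    boundaries = boundaries or DecisionBoundaries()
    if misaim is None:
        misaim = intended_target in CLOSING_TARGETS and rng.random() < profile.misaim_prob
    theta = _draw_aim_angle(profile, intended_target, cfg, boundaries, rng, misaim)
    rad = math.radians(theta)
    direction = np.array([math.cos(rad), math.sin(rad)])
    endpoint = cfg.target_center_radius * direction
    centers = cfg.target_centers()
    d = np.hypot(centers[:, 0] - endpoint[0], centers[:, 1] - endpoint[1])
    nearest = int(np.argmin(d))
    # homing: a ray that misses every disc settles just inside the nearest
    # one; staying near the disc edge preserves near-boundary decision
    # angles (and never changes the decision region, since the pull is
    # toward the same region's center)
    inner = 0.9 * cfg.target_radius
    if d[nearest] > inner:
        endpoint = centers[nearest] + (endpoint - centers[nearest]) * inner / d[nearest]
    start = 0.3 * cfg.basket_radius * direction

    dt_s = profile.step_ms / 1000.0
    travel_steps = max(1, int(math.ceil(np.linalg.norm(endpoint - start) / (profile.reach_speed * dt_s))))
    hold_steps = int(math.ceil(2.0 * cfg.dwell_ms / profile.step_ms))
    rest_steps = int(math.ceil(400.0 / profile.step_ms))
    path = [start + (endpoint - start) * (k / travel_steps) for k in range(travel_steps + 1)]
    path += [endpoint] * hold_steps
    path += [endpoint + (start - endpoint) * (k / travel_steps) for k in range(1, travel_steps + 1)]
    path += [start] * rest_steps
    pts = np.array(path)
    pts = pts + rng.normal(0.0, profile.tremor_sigma, pts.shape)
    pts = np.clip(pts, 0.0, None)
    t = np.array(
        [add_ms(t_start, (k + 1) * profile.step_ms) for k in range(len(pts))],
        dtype="datetime64[ms]",
    )
    return MAVStream(t, pts), theta, bool(misaim)


def simulate_session(
    profile: VirtualUserProfile,
    plan: BlockPlan,
    cfg: TaskSpaceConfig | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    t0=DEFAULT_T0,
    boundaries: DecisionBoundaries | None = None,
    max_attempts: int = 6,
) -> tuple[SessionBucket, SessionGroundTruth]:
    """Run a virtual user through the block protocol via the real decoder.

    Every reach segment is fed through the dwell selector and grasp state
    machine, so the bucket's motor commands are genuine decoder output.  On
    a wrong executed grasp the user submits feedback 1–5 s later, reopens
    the hand and retries the intended target.  The tripod→pinch switch is
    issued as a timestamped remote config update before the first block
    whose sequence uses the pinch grip.
    """
    cfg = cfg or TaskSpaceConfig()
    boundaries = boundaries or DecisionBoundaries()
    rng = np.random.default_rng(rng)
    decoder = AbstractDecoder(cfg, boundaries, GraspMap())
    grasp_map = GraspMap()
    bucket = SessionBucket()
    truth = SessionGroundTruth()
    segments: list[MAVStream] = []
    t_cur = np.datetime64(t0, "ms")
    switched = False

    def do_reach(intended: int, misaim: Optional[bool]):
        nonlocal t_cur
        seg, theta, misaimed = simulate_reach(
            profile, intended, cfg, rng,
            t_start=add_ms(t_cur, 200.0),
            boundaries=decoder.boundaries, misaim=misaim,
        )
        emitted = []
        for s in seg:
            cmd = decoder.process(s)
            if cmd is not None:
                emitted.append(cmd)
        segments.append(seg)
        t_cur = seg.t[-1]
        return emitted, misaimed

    for block_no, grasps in enumerate(plan.blocks, start=1):
        if "pinch" in grasps and not switched:
            update = ConfigUpdate(t=add_ms(t_cur, 100.0), changes={"target2_grasp": "pinch"})
            bucket.config_updates.append(update)
            decoder.schedule_update(update.t, target2_grasp="pinch")
            grasp_map = grasp_map.with_target2("pinch")
            switched = True
        bucket.block_markers.append(BlockMarker(t=add_ms(t_cur, 150.0), kind="start", block=block_no))
        for grasp in grasps:
            intended = grasp_map.target_for(grasp)
            truth.n_planned_grasps += 1
            for attempt in range(max_attempts):
                force = False if attempt == max_attempts - 1 else None
                emitted, _ = do_reach(intended, force)
                if not emitted:
                    truth.n_extra_reaches += 1
                    continue
                cmd = emitted[0]
                idx = len(bucket.commands)
                bucket.commands.append(cmd)
                truth.intended_targets.append(intended)
                if cmd.target == intended:
                    break
                # wrong grasp executed: report, reopen, retry
                truth.misaim_command_indices.append(idx)
                fb_t = add_ms(cmd.t, 1000.0 + 4000.0 * rng.random())
                bucket.feedback.append(
                    FeedbackEvent(t=fb_t, intended_grasp=grasp_map.grasp_for(intended))
                )
                t_cur = max(t_cur, add_ms(fb_t, 500.0))
                _open_hand(decoder, do_reach, bucket, truth, max_attempts)
                truth.n_extra_reaches += 1
            # release the object / reopen for the next grasp
            _open_hand(decoder, do_reach, bucket, truth, max_attempts)
        bucket.block_markers.append(BlockMarker(t=add_ms(t_cur, 150.0), kind="stop", block=block_no))
    bucket.mav = MAVStream.concat(segments)
    return bucket, truth


def _open_hand(
    decoder: AbstractDecoder,
    do_reach,
    bucket: SessionBucket,
    truth: SessionGroundTruth,
    max_attempts: int,
) -> None:
    for _ in range(max_attempts):
        if decoder.machine.hand.is_open:
            return
        emitted, _ = do_reach(OPEN_TARGET, False)
        if emitted:
            bucket.commands.append(emitted[0])
            truth.intended_targets.append(OPEN_TARGET)
            return
        truth.n_extra_reaches += 1


def simulate_labeled_decisions(
    profile: VirtualUserProfile,
    n_per_target: int,
    cfg: TaskSpaceConfig | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    boundaries: DecisionBoundaries | None = None,
    targets: Sequence[int] = (1, 2, 3, 4),
) -> list[LabeledDecision]:
    """Draw decision angles directly from the aim model (no trajectories).

    The statistical path for adaptation studies: for each target the user
    aims with Gaussian error (plus optional mis-aims into a neighbor
    region); the executed target is the decision region of the drawn angle
    under the boundaries in force, and a decision is unexpected when the
    executed target differs from the intent.
    """
    cfg = cfg or TaskSpaceConfig()
    boundaries = boundaries or DecisionBoundaries()
    rng = np.random.default_rng(rng)
    out: list[LabeledDecision] = []
    for target in targets:
        for _ in range(n_per_target):
            misaim = target in CLOSING_TARGETS and rng.random() < profile.misaim_prob
            v = _draw_aim_angle(profile, target, cfg, boundaries, rng, misaim)
            executed = classify_target(v, boundaries)
            out.append(
                LabeledDecision(
                    v=v,
                    executed_target=executed,
                    intended_target=target,
                    unexpected=executed != target,
                )
            )
    return out


def synthesize_emg(
    envelopes: np.ndarray,
    fs: float = 500.0,
    rng: np.random.Generator | int | None = None,
    *,
    band: tuple[float, float] = (20.0, 230.0),
    mains_hz: float | None = 50.0,
    mains_amp: float = 0.05,
    sensor_noise_std: float = 0.02,
    t0=DEFAULT_T0,
) -> EMGRecord:
    """Amplitude-modulated band-limited noise as surrogate raw EMG.

    ``envelopes`` has shape (2, n): the commanded activation per channel in
    the same units the MAV should recover.  The carrier is unit-variance
    band-limited Gaussian noise, so the expected MAV of a constant envelope
    ``a`` is ``a * sqrt(2/pi)`` (rectified-Gaussian mean), before the mains
    and sensor-noise terms.
    """
    rng = np.random.default_rng(rng)
    env = np.atleast_2d(np.asarray(envelopes, dtype=float))
    if env.shape[0] != 2:
        raise ValueError("envelopes must have shape (2, n)")
    n = env.shape[1]
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, rng.standard_normal((2, n)), axis=1)
    carrier /= carrier.std(axis=1, keepdims=True)
    out = env * carrier
    if mains_hz is not None and mains_amp > 0.0:
        t = np.arange(n) / fs
        out = out + mains_amp * np.sin(2.0 * np.pi * mains_hz * t)
    if sensor_noise_std > 0.0:
        out = out + sensor_noise_std * rng.standard_normal((2, n))
    return EMGRecord(samples=out, fs=fs, t0=t0)
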