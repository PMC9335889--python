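"""Decision-boundary adaptation from labeled real-life decisions.

Correct grasp decisions (no "unexpected grasp" feedback) are the training
data.  For each target, the decision angle *v* of its correct commands is
modeled as a one-dimensional Gaussian — the class-conditional of a Gaussian
Naive Bayes classifier with the single feature *v*.  Each pair of adjacent
targets then defines a two-class problem whose customized boundary is the
angle where the two (prior-weighted) class densities are equal.  The
unexpected commands form the verification set: a "correction" is an
unexpected command whose angle classifies to the user's intended target
under the new boundaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decoder import DecisionBoundaries, classify_target
from .errors import AdaptationWarning
from .session import LabeledDecision

__all__ = [
    "SIGMA_FLOOR_DEG",
    "AngleClassModel",
    "AdaptationResult",
    "fit_angle_models",
    "equal_density_boundary",
    "adapt_boundaries",
    "verify_boundaries",
]

#: Lower bound on a fitted class sigma (degrees); avoids degenerate spikes
#: when a user is extremely consistent.
SIGMA_FLOOR_DEG = 0.5


@dataclass(frozen=True)
class AngleClassModel:
    """Gaussian model of one target's decision angles (degrees)."""

    target: int
    mu: float
    sigma: float
    n: int


def fit_angle_models(
    training: Sequence[LabeledDecision],
) -> dict[int, AngleClassModel]:
    """Per-target Gaussian fit (sample mean, n−1 std) over correct decisions.

    Targets with fewer than 2 training decisions are omitted; the caller
    falls back to the default boundary for any pair touching them.
    """
    models: dict[int, AngleClassModel] = {}
    for target in (1, 2, 3, 4):
        vs = np.array([d.v for d in training if d.executed_target == target])
        if vs.size < 2:
            continue
        sigma = max(float(np.std(vs, ddof=1)), SIGMA_FLOOR_DEG)
        models[target] = AngleClassModel(
            target=target, mu=float(np.mean(vs)), sigma=sigma, n=int(vs.size)
        )
    return models


def equal_density_boundary(
    mu_i: float,
    sigma_i: float,
    mu_j: float,
    sigma_j: float,
    prior_i: float = 0.5,
    prior_j: float = 0.5,
) -> float:
    """Angle where the two prior-weighted Gaussian densities are equal.

    With equal sigmas and equal priors this is the midpoint of the means;
    in general it is a root of a quadratic in *v*, and the root inside
    ``(mu_i, mu_j)`` is returned (the Bayes decision boundary of the pair).
    If no real root lies in the interval — pathological sigma ratios — the
    midpoint is returned with a warning.  The result is always clamped to
    ``(mu_i, mu_j)``.
    """
    if not mu_i < mu_j:
        raise ValueError(f"require mu_i < mu_j, got {mu_i} >= {mu_j}")
    midpoint = 0.5 * (mu_i + mu_j)
    si2, sj2 = sigma_i**2, sigma_j**2
    log_ratio = math.log(prior_i / prior_j) + math.log(sigma_j / sigma_i)
    if math.isclose(sigma_i, sigma_j, rel_tol=1e-12, abs_tol=1e-12):
        # linear case: (mu_j - mu_i) v = (mu_j^2 - mu_i^2)/2 - s^2 log_ratio... sign below
        v = midpoint + si2 * log_ratio / (mu_j - mu_i)
        return float(min(max(v, mu_i), mu_j))
    # quadratic a v^2 + b v + c = 0 from equating log densities
    a = 0.5 * (1.0 / sj2 - 1.0 / si2)
    b = mu_i / si2 - mu_j / sj2
    c = 0.5 * (mu_j**2 / sj2 - mu_i**2 / si2) + log_ratio
    disc = b * b - 4.0 * a * c
    if disc >= 0.0:
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
        inside = [r for r in roots if mu_i < r < mu_j]
        if inside:
            return float(inside[0])
    warnings.warn(
        f"no equal-density root in ({mu_i:.2f}, {mu_j:.2f}); using midpoint",
        AdaptationWarning,
    )
    return float(midpoint)


def adapt_boundaries(
    training: Sequence[LabeledDecision],
    defaults: DecisionBoundaries = DecisionBoundaries(),
    priors_mode: str = "equal",
) -> tuple[DecisionBoundaries, list[str]]:
    """Customized boundaries from the three adjacent-pair two-class fits.

    ``priors_mode``: "equal" (default — the boundary is where the class
    densities themselves are equal) or "empirical" (priors proportional to
    per-target training counts).  Any pair lacking data, any pair whose
    means are not ordered, and any resulting boundary set violating
    ``0 < b12 < b23 < b34 < 90`` falls back to the defaults for the affected
    quantity, with a flag describing why.

    Returns ``(boundaries, flags)``; an empty training set returns the
    defaults with every pair flagged.
    """
    if priors_mode not in ("equal", "empirical"):
        raise ValueError(f"unknown priors_mode {priors_mode!r}")
    models = fit_angle_models(training)
    flags: list[str] = []
    values: list[float] = []
    for lo, hi, default in (
        (1, 2, defaults.b12),
        (2, 3, defaults.b23),
        (3, 4, defaults.b34),
    ):
        if lo not in models or hi not in models:
            flags.append(f"pair {lo}-{hi}: insufficient training data, default kept")
            values.append(default)
            continue
        mi, mj = models[lo], models[hi]
        if not mi.mu < mj.mu:
            flags.append(
                f"pair {lo}-{hi}: class means not ordered "
                f"({mi.mu:.2f} >= {mj.mu:.2f}), default kept"
            )
            values.append(default)
            continue
        if priors_mode == "empirical":
            pi = mi.n / (mi.n + mj.n)
            priors = (pi, 1.0 - pi)
        else:
            priors = (0.5, 0.5)
        values.append(
            equal_density_boundary(mi.mu, mi.sigma, mj.mu, mj.sigma, *priors)
        )
    b12, b23, b34 = values
    if not (0.0 < b12 < b23 < b34 < 90.0):
        flags.append(
            f"adapted boundaries ({b12:.2f}, {b23:.2f}, {b34:.2f}) violate "
            "ordering; defaults kept"
        )
        return defaults, flags
    return DecisionBoundaries(b12, b23, b34), flags


@dataclass(frozen=True)
class AdaptationResult:
    """Verification of customized boundaries against unexpected commands."""

    boundaries: DecisionBoundaries
    n_feedback: int
    n_corrected: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_corrected <= self.n_feedback:
            raise ValueError("require 0 <= n_corrected <= n_feedback")


def verify_boundaries(
    boundaries: DecisionBoundaries, verification: Sequence[LabeledDecision]
) -> AdaptationResult:
    """Count unexpected decisions that the given boundaries would have routed
    to the user's intended target."""
    n_corrected = sum(
        1
        for d in verification
        if classify_target(d.v, boundaries) == d.intended_target
    )
    return AdaptationResult(
        boundaries=boundaries,
        n_feedback=len(verification),
        n_corrected=n_corrected,
    )
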