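"""Random-geometry primitives.

Truncated Gaussian and truncated skew-normal draws, uniform directions on
the circle / sphere / upper hemisphere, and the steric feasibility test for
the forbidden angular region around already-placed glycans.

All truncation is done by rejection (resampling out-of-bounds draws), never
by clamping: clamping would pile probability mass onto the cutoff values.
The forbidden angle is a *half*-angle: a candidate direction is rejected
when its angle to any blocked direction is strictly below ``half_angle``,
so the excluded sector (2D) or cone (3D) has full opening ``2*half_angle``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TruncatedDistanceModel",
    "TruncatedSkewNormalModel",
    "DirectionConstraint",
    "sample_truncated_gaussian",
    "sample_truncated_skew_normal",
    "sample_direction",
    "direction_allowed",
    "sample_allowed_direction",
    "SamplingBudgetError",
    "OvercrowdedError",
    "DEFAULT_MAX_ATTEMPTS",
]

DEFAULT_MAX_ATTEMPTS = 1000


class SamplingBudgetError(RuntimeError):
    """A rejection sampler exhausted its attempt budget."""


class OvercrowdedError(SamplingBudgetError):
    """No allowed direction found: too many glycans for the available solid angle."""


@dataclass(frozen=True)
class TruncatedDistanceModel:
    """Gaussian distance law truncated at ``cutoff`` standard deviations.

    Distances are magnitudes, so the support is additionally truncated at 0:
    ``[max(0, mu - cutoff*sigma), mu + cutoff*sigma]``.  Lengths in microns.
    """

    mu: float
    sigma: float
    cutoff: float

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu!r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma!r}")
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be > 0, got {self.cutoff!r}")

    @property
    def support(self) -> tuple[float, float]:
        lo = max(0.0, self.mu - self.cutoff * self.sigma)
        hi = self.mu + self.cutoff * self.sigma
        return lo, hi


@dataclass(frozen=True)
class TruncatedSkewNormalModel:
    """Skew-normal law (location, shape, scale) restricted to [lower, upper].

    The untruncated density is ``2/scale * phi(z) * Phi(shape*z)`` with
    ``z = (x - location)/scale``; positive shape skews to the right.  Used
    for the height of protein centers above the membrane plane (microns).
    """

    location: float
    shape: float
    scale: float
    lower: float
    upper: float

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale!r}")
        if not self.lower < self.upper:
            raise ValueError(
                f"lower must be < upper, got {self.lower!r} >= {self.upper!r}"
            )


@dataclass(frozen=True)
class DirectionConstraint:
    """Unit directions already occupied by glycans, plus the exclusion half-angle."""

    blocked_directions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3))
    )
    half_angle: float = 0.0

    def __post_init__(self):
        blocked = np.atleast_2d(np.asarray(self.blocked_directions, dtype=float))
        if blocked.size == 0:
            blocked = blocked.reshape(0, blocked.shape[-1] if blocked.ndim > 1 else 3)
        else:
            norms = np.linalg.norm(blocked, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("blocked directions must be unit vectors")
        object.__setattr__(self, "blocked_directions", blocked)
        if not 0 <= self.half_angle < math.pi:
            raise ValueError(f"half_angle must be in [0, pi), got {self.half_angle!r}")


def sample_truncated_gaussian(
    model: TruncatedDistanceModel,
    rng: np.random.Generator,
    size: int | None = None,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
):
    """Draw from the Gaussian restricted to the model's support, by rejection.

    Returns a scalar when ``size`` is None, else an array of ``size`` draws.
    Raises ``ValueError`` when the support is empty (upper bound <= 0) and
    :class:`SamplingBudgetError` when ``max_attempts`` rounds of resampling
    leave draws unfilled.
    """
    lo, hi = model.support
    if hi <= 0:
        raise ValueError(f"empty support: upper bound {hi!r} <= 0")
    if model.sigma == 0:
        return model.mu if size is None else np.full(size, model.mu)

    if size is None:
        for _ in range(max_attempts):
            x = model.mu + model.sigma * rng.standard_normal()
            if lo <= x <= hi:
                return x
        raise SamplingBudgetError(
            f"no in-bounds Gaussian draw in {max_attempts} attempts "
            f"(mu={model.mu}, sigma={model.sigma}, support=[{lo}, {hi}])"
        )

    out = np.empty(size)
    unfilled = np.arange(size)
    for _ in range(max_attempts):
        draws = model.mu + model.sigma * rng.standard_normal(unfilled.size)
        ok = (draws >= lo) & (draws <= hi)
        out[unfilled[ok]] = draws[ok]
        unfilled = unfilled[~ok]
        if unfilled.size == 0:
            return out
    raise SamplingBudgetError(
        f"{unfilled.size} of {size} truncated-Gaussian draws unfilled after "
        f"{max_attempts} rounds"
    )


def sample_truncated_skew_normal(
    model: TruncatedSkewNormalModel,
    rng: np.random.Generator,
    size: int | None = None,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
):
    """Draw from the skew-normal law restricted to [lower, upper], by rejection.

    Raises :class:`SamplingBudgetError` when the interval holds negligible
    probability mass and the rejection budget runs out.
    """
    scalar = size is None
    n = 1 if scalar else size
    out = np.empty(n)
    unfilled = np.arange(n)
    for _ in range(max_attempts):
        draws = stats.skewnorm.rvs(
            model.shape,
            loc=model.location,
            scale=model.scale,
            size=unfilled.size,
            random_state=rng,
        )
        ok = (draws >= model.lower) & (draws <= model.upper)
        out[unfilled[ok]] = draws[ok]
        unfilled = unfilled[~ok]
        if unfilled.size == 0:
            return float(out[0]) if scalar else out
    raise SamplingBudgetError(
        f"{unfilled.size} of {n} truncated skew-normal draws unfilled after "
        f"{max_attempts} rounds; the interval [{model.lower}, {model.upper}] "
        "may hold negligible probability mass"
    )


def sample_direction(
    dimension: int,
    rng: np.random.Generator,
    hemisphere_only: bool = False,
    size: int | None = None,
):
    """Uniform unit vector on the circle (2D), sphere (3D), or upper hemisphere.

    ``hemisphere_only`` restricts 3D draws to z >= 0 (membrane and protein
    occupy the lower half-space); it is ignored in 2D.  Returns shape
    ``(dimension,)`` for scalar draws, ``(size, dimension)`` otherwise.
    """
    if dimension not in (2, 3):
        raise ValueError(f"dimension must be 2 or 3, got {dimension!r}")
    scalar = size is None
    n = 1 if scalar else size
    if dimension == 2:
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
        vecs = np.column_stack([np.cos(theta), np.sin(theta)])
    else:
        vecs = rng.standard_normal((n, 3))
        norms = np.linalg.norm(vecs, axis=1)
        # degenerate near-zero norms are astronomically rare; redraw them
        while np.any(norms < 1e-12):
            bad = norms < 1e-12
            vecs[bad] = rng.standard_normal((int(bad.sum()), 3))
            norms = np.linalg.norm(vecs, axis=1)
        vecs /= norms[:, None]
        if hemisphere_only:
            vecs[:, 2] = np.abs(vecs[:, 2])
    return vecs[0] if scalar else vecs


def direction_allowed(candidate: np.ndarray, constraint: DirectionConstraint) -> bool:
    """True iff the candidate is at least ``half_angle`` away from every blocked
    direction (angle via arccos of the dot product)."""
    blocked = constraint.blocked_directions
    if blocked.shape[0] == 0 or constraint.half_angle == 0:
        return True
    cosines = np.clip(blocked @ np.asarray(candidate, dtype=float), -1.0, 1.0)
    angles = np.arccos(cosines)
    return bool(np.all(angles >= constraint.half_angle))


def sample_allowed_direction(
    dimension: int,
    hemisphere_only: bool,
    constraint: DirectionConstraint,
    rng: np.random.Generator,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> np.ndarray:
    """Rejection-sample a uniform direction passing :func:`direction_allowed`.

    Raises :class:`OvercrowdedError` when the budget is exhausted, which
    signals more glycans than the available solid angle can host.
    """
    for _ in range(max_attempts):
        cand = sample_direction(dimension, rng, hemisphere_only=hemisphere_only)
        if direction_allowed(cand, constraint):
            return cand
    raise OvercrowdedError(
        f"no allowed direction in {max_attempts} attempts: "
        f"{constraint.blocked_directions.shape[0]} blocked directions with "
        f"half-angle {constraint.half_angle:.3f} rad leave too little room"
    )
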