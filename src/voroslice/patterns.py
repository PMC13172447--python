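"""Synthetic seed-point generators.

Three point-process models produce the validation microstructures: a binomial
(uniform) pattern, a hardcore pattern with a guaranteed minimum pairwise
periodic distance (regular, controlled minimal cell size), and a "twinning"
pattern of collinear point triples that yields clusters of flat, parallel
cell boundaries like those of strongly twinned metallic alloys.

The canonical study conditions are 666 seeds in a 100^3 window: 666 uniform
points, 666 hardcore points at minimum distance 10, or 222 initial points
each completed to a collinear triple with companions offset 10 voxels along
a uniformly random direction.
"""

from __future__ import annotations

import numpy as np

from .tessellation import SeedPointPattern, periodic_distance

__all__ = [
    "sample_uniform",
    "sample_hardcore",
    "sample_twinning",
    "HardcoreSaturationError",
]


class HardcoreSaturationError(RuntimeError):
    """Raised when dart throwing cannot place all hardcore points."""

    def __init__(self, achieved: int, requested: int, max_attempts: int):
        self.achieved = achieved
        self.requested = requested
        super().__init__(
            f"hardcore sampling saturated after {max_attempts} attempts: "
            f"placed {achieved} of {requested} points"
        )


def sample_uniform(n: int, L: float, rng_seed: int = 0) -> SeedPointPattern:
    """``n`` points i.i.d. uniform on ``[0, L)^3``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    pts = rng.random((n, 3)) * L
    return SeedPointPattern(pts, L, {"kind": "uniform", "rng_seed": rng_seed})


def sample_hardcore(
    n: int,
    L: float,
    r_min: float,
    rng_seed: int = 0,
    max_attempts: int = 1_000_000,
) -> SeedPointPattern:
    """``n`` uniform points conditioned on pairwise periodic distance >= r_min.

    Sampling is by dart throwing: uniform proposals are rejected whenever they
    come within ``r_min`` (periodic metric) of an accepted point.  Raises
    :class:`HardcoreSaturationError` when ``max_attempts`` proposals do not
    suffice, naming the achieved count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if r_min <= 0:
        raise ValueError("r_min must be positive")
    rng = np.random.default_rng(rng_seed)
    accepted = np.empty((n, 3), dtype=float)
    count = 0
    for _ in range(max_attempts):
        if count == n:
            break
        p = rng.random(3) * L
        if count == 0 or periodic_distance(p, accepted[:count], L).min() >= r_min:
            accepted[count] = p
            count += 1
    if count < n:
        raise HardcoreSaturationError(count, n, max_attempts)
    return SeedPointPattern(
        accepted, L, {"kind": "hardcore", "r_min": r_min, "rng_seed": rng_seed}
    )


def sample_twinning(
    n_initial: int, L: float, offset: float, rng_seed: int = 0
) -> SeedPointPattern:
    """Collinear triples: each initial point plus companions at ``p +- offset*u``.

    ``n_initial`` points are uniform on ``[0, L)^3``; for each, a direction
    ``u`` uniform on the unit sphere (normalized Gaussian sampling) defines a
    random line through the point, and the two companions sit on it at
    periodic distance ``offset`` on opposite sides.  Companions leaving the
    window are wrapped periodically.  Returns ``3 * n_initial`` points,
    ordered triple by triple (initial, +companion, -companion); the triple
    structure is recorded in ``metadata["triples"]``.
    """
    if n_initial < 1:
        raise ValueError("n_initial must be >= 1")
    if offset <= 0:
        raise ValueError("offset must be positive")
    rng = np.random.default_rng(rng_seed)
    base = rng.random((n_initial, 3)) * L
    g = rng.normal(size=(n_initial, 3))
    u = g / np.linalg.norm(g, axis=1, keepdims=True)
    pts = np.concatenate([base, base + offset * u, base - offset * u], axis=0)
    order = np.arange(3 * n_initial).reshape(3, n_initial).T.ravel()
    triples = np.arange(3 * n_initial).reshape(n_initial, 3)
    return SeedPointPattern(
        pts[order],
        L,
        {
            "kind": "twinning",
            "offset": offset,
            "rng_seed": rng_seed,
            "triples": triples,
        },
    )
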