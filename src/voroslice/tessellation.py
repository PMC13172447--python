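"""Periodic Voronoi geometry.

A 3D cellular structure is parameterized by a seed-point pattern
``S = {s_1, ..., s_n}`` inside a cubic window ``W = [0, L)^3`` with periodic
boundary conditions (geometry on the 3-torus).  Cell ``i`` of the Voronoi
tessellation contains every point closer (in the periodic metric) to ``s_i``
than to any other seed.  A softmax relaxation over negative periodic
distances makes cell membership differentiable in the seed coordinates,
which is what enables gradient-based fitting of the tessellation to image
data.

All distances are in voxel units (grid spacing 1); the softmax temperature
``beta`` is therefore in inverse voxels and must be rescaled if a different
spacing is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SeedPointPattern",
    "periodic_delta",
    "periodic_distance",
    "soft_membership",
    "hard_assign",
    "rgb_embed",
    "voxelize",
]

#: default softmax temperature (inverse voxel units)
DEFAULT_BETA = 10.0


@dataclass
class SeedPointPattern:
    """Seed points of a periodic Voronoi tessellation.

    Parameters
    ----------
    points
        ``(n, 3)`` array of seed coordinates.  Stored wrapped into
        ``[0, L)``; the row index is the stable cell index used for
        tie-breaking and coloring.
    window_size
        Side length ``L`` of the cubic periodic window.
    metadata
        Free-form provenance (generator kind, rng seed, ...).
    """

    points: np.ndarray
    window_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("a seed pattern needs at least one point")
        L = float(self.window_size)
        if L <= 0:
            raise ValueError(f"window size must be positive, got {L}")
        self.points = np.mod(pts, L)
        self.window_size = L

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def wrapped(self, points: np.ndarray) -> "SeedPointPattern":
        """Return a new pattern with the given coordinates (wrapped mod L)."""
        return SeedPointPattern(points, self.window_size, dict(self.metadata))


def periodic_delta(x: np.ndarray, y: np.ndarray, L: float) -> np.ndarray:
    """Signed minimum-image difference ``x - y`` on the L-torus.

    Broadcasts over leading axes; the result lies in ``[-L/2, L/2)``
    component-wise and satisfies ``||periodic_delta|| == periodic_distance``.
    """
    if L <= 0:
        raise ValueError(f"window size must be positive, got {L}")
    d = np.mod(np.asarray(x, dtype=float) - np.asarray(y, dtype=float), L)
    return np.where(d >= L / 2, d - L, d)


def periodic_distance(x: np.ndarray, y: np.ndarray, L: float) -> np.ndarray:
    """Periodic Euclidean distance: min over the 27 translates of ``y``.

    Equals ``min_{v in {-L,0,L}^3} ||x - (y + v)||`` for inputs wrapped into
    the window; a metric on the 3-torus, never larger than the plain
    Euclidean distance between wrapped representatives.
    """
    return np.linalg.norm(periodic_delta(x, y, L), axis=-1)


def _axis_sq_table(coords: np.ndarray, seeds_1d: np.ndarray, L: float) -> np.ndarray:
    """Squared per-axis minimum-image differences, shape (len(coords), n)."""
    d = np.mod(coords[:, None] - seeds_1d[None, :], L)
    d = np.where(d >= L / 2, d - L, d)
    return d * d


def _distances(points: np.ndarray, S: SeedPointPattern) -> np.ndarray:
    """Periodic distances from query points (..., 3) to every seed: (..., n)."""
    delta = periodic_delta(points[..., None, :], S.points, S.window_size)
    return np.sqrt(np.einsum("...k,...k->...", delta, delta))


def soft_membership(
    x: np.ndarray, S: SeedPointPattern, beta: float = DEFAULT_BETA
) -> np.ndarray:
    """Relaxed cell memberships ``softmax_i(-beta * d~(x, s_i))``.

    Differentiable in every seed coordinate; rows sum to one.  Computed with
    max-logit subtraction so large ``beta * d`` never underflows all terms.
    Accepts a single point or any ``(..., 3)`` array and returns ``(..., n)``.
    """
    if beta <= 0:
        raise ValueError(f"temperature beta must be positive, got {beta}")
    logits = -beta * _distances(np.asarray(x, dtype=float), S)
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


def hard_assign(x: np.ndarray, S: SeedPointPattern) -> np.ndarray:
    """Index of the nearest seed (0-based); ties go to the smallest index.

    Equals ``argmax`` of :func:`soft_membership` for every ``beta > 0``
    because the softmax is monotone in the negative distance.
    """
    d = _distances(np.asarray(x, dtype=float), S)
    return np.argmin(d, axis=-1)


def rgb_embed(memberships: np.ndarray, colors: np.ndarray) -> np.ndarray:
    """Color embedding ``I = sum_i c_i * C_i(x)`` of membership vectors.

    ``memberships`` has shape ``(..., n)``, ``colors`` shape ``(n, 3)``;
    output shape ``(..., 3)`` stays in ``[0, 1]^3`` because memberships lie
    on the simplex.
    """
    m = np.asarray(memberships, dtype=float)
    c = np.asarray(colors, dtype=float)
    if m.shape[-1] != c.shape[0]:
        raise ValueError(
            f"membership length {m.shape[-1]} != number of colors {c.shape[0]}"
        )
    return m @ c


def random_colors(n: int, rng: np.random.Generator) -> np.ndarray:
    """One uniform random RGB color in [0,1]^3 per cell."""
    return rng.random((n, 3))


def voxelize(S: SeedPointPattern, L: int | None = None, chunk: int = 4) -> np.ndarray:
    """Discretize the tessellation on the voxel grid ``{0,...,L-1}^3``.

    Each voxel (sampled at its integer corner) receives the 0-based index of
    its nearest seed in the periodic metric; ties break to the smallest
    index.  Evaluation is chunked over ``chunk`` x-planes at a time to bound
    the working set; the result is independent of the chunk size.
    """
    if L is None:
        L = S.window_size
    if float(L) != int(L) or int(L) < 1:
        raise ValueError(f"grid side must be a positive integer, got {L!r}")
    L = int(L)
    coords = np.arange(L, dtype=float)
    # separable decomposition: d^2 = dx^2 + dy^2 + dz^2, one table per axis
    Dx = _axis_sq_table(coords, S.points[:, 0], S.window_size)
    Dy = _axis_sq_table(coords, S.points[:, 1], S.window_size)
    Dz = _axis_sq_table(coords, S.points[:, 2], S.window_size)
    labels = np.empty((L, L, L), dtype=np.int32)
    yz = Dy[:, None, :] + Dz[None, :, :]  # (L, L, n)
    for x0 in range(0, L, max(1, chunk)):
        x1 = min(L, x0 + max(1, chunk))
        block = Dx[x0:x1, None, None, :] + yz[None, :, :, :]
        labels[x0:x1] = np.argmin(block, axis=-1)
    return labels
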