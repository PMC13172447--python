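"""Axis-aligned planar sectioning of tessellations and label volumes.

A planar grid ``G_{d,k}`` collects the ``L^2`` integer grid points of
``{0,...,L-1}^3`` whose ``d``-th coordinate equals ``k`` (``d`` in {1,2,3}
for x/y/z).  Rendering the soft tessellation on such a grid produces a 2D
RGB image that is differentiable in the seed coordinates — the generated
counterpart to a measured 2D section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tessellation import (
    DEFAULT_BETA,
    SeedPointPattern,
    hard_assign,
    periodic_delta,
    rgb_embed,
    soft_membership,
)

__all__ = [
    "PlanarGrid",
    "planar_grid",
    "render_slice",
    "RenderTape",
    "render_slice_with_tape",
    "slice_label_image",
    "extract_all_slices",
]


@dataclass(frozen=True)
class PlanarGrid:
    """Planar section grid orthogonal to axis ``direction`` at position ``k``.

    ``direction`` is 1-based (1, 2, 3 = x, y, z).  Image layout: the free
    axes in increasing coordinate order, the first free axis as image rows.
    """

    direction: int
    k: int
    L: int

    def __post_init__(self):
        if self.direction not in (1, 2, 3):
            raise ValueError(f"direction must be 1, 2 or 3, got {self.direction}")
        if not (0 <= self.k <= self.L - 1):
            raise IndexError(f"position k={self.k} outside 0..{self.L - 1}")

    @property
    def free_axes(self) -> tuple[int, int]:
        """The two 0-based free axes, in increasing order (rows, cols)."""
        return tuple(a for a in (0, 1, 2) if a != self.direction - 1)

    def points(self) -> np.ndarray:
        """All ``L^2`` grid points as an ``(L, L, 3)`` array (rows, cols, xyz)."""
        r, c = self.free_axes
        rows, cols = np.meshgrid(
            np.arange(self.L, dtype=float),
            np.arange(self.L, dtype=float),
            indexing="ij",
        )
        pts = np.empty((self.L, self.L, 3), dtype=float)
        pts[..., r] = rows
        pts[..., c] = cols
        pts[..., self.direction - 1] = self.k
        return pts


def planar_grid(d: int, k: int, L: int) -> PlanarGrid:
    """Construct the grid ``G_{d,k}`` inside ``{0,...,L-1}^3``."""
    return PlanarGrid(d, k, int(L))


def render_slice(
    S: SeedPointPattern,
    colors: np.ndarray,
    beta: float,
    grid: PlanarGrid,
) -> np.ndarray:
    """Soft RGB section: pixel (a,b) = sum_i colors[i] * C_i(grid point)."""
    m = soft_membership(grid.points(), S, beta)
    return rgb_embed(m, colors)


@dataclass
class RenderTape:
    """Cached intermediates of a rendered slice for the backward pass."""

    grid: PlanarGrid
    memberships: np.ndarray  # (L, L, n)
    deltas: np.ndarray  # (L, L, n, 3) minimum-image (x - s_i)
    distances: np.ndarray  # (L, L, n)
    colors: np.ndarray  # (n, 3)
    beta: float

    def seed_gradient(self, d_image: np.ndarray) -> np.ndarray:
        """Chain ``dL/d(image)`` (L, L, 3) back to ``dL/d(seeds)`` (n, 3).

        For logits ``z_i = -beta * d~(x, s_i)`` and softmax memberships C:
        ``dL/dz_j = C_j (g_j - sum_i C_i g_i)`` with ``g_i = colors_i . dL/dI``,
        and ``dz_j/ds_j = beta * delta_j / d~_j`` where ``delta_j`` is the
        minimum-image vector ``x - s_j``.
        """
        g = np.einsum("abc,nc->abn", np.asarray(d_image, dtype=float), self.colors)
        gbar = np.einsum("abn,abn->ab", self.memberships, g)
        dz = self.memberships * (g - gbar[..., None])
        safe_d = np.maximum(self.distances, 1e-12)
        dseed = np.einsum(
            "abn,abnk->nk", dz * (self.beta / safe_d), self.deltas
        )
        return dseed


def render_slice_with_tape(
    S: SeedPointPattern,
    colors: np.ndarray,
    beta: float,
    grid: PlanarGrid,
) -> tuple[np.ndarray, RenderTape]:
    """Render a slice and keep the intermediates needed for seed gradients."""
    pts = grid.points()
    deltas = periodic_delta(pts[..., None, :], S.points, S.window_size)
    dist = np.sqrt(np.einsum("...k,...k->...", deltas, deltas))
    logits = -beta * dist
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    m = e / e.sum(axis=-1, keepdims=True)
    image = rgb_embed(m, colors)
    return image, RenderTape(grid, m, deltas, dist, np.asarray(colors, float), beta)


def slice_label_image(S: SeedPointPattern, grid: PlanarGrid) -> np.ndarray:
    """Hard section: nearest-seed label (0-based) at every grid point."""
    return hard_assign(grid.points(), S).astype(np.int32)


def extract_all_slices(volume: np.ndarray) -> list[np.ndarray]:
    """All ``3L`` axis-aligned sections of a cubic ``L^3`` label volume.

    Ordered lexicographically by (direction, position); each slice uses the
    same layout as :class:`PlanarGrid` (free axes increasing, first free axis
    as rows).  Restacking the direction-3 slices reproduces the volume.
    """
    v = np.asarray(volume)
    if v.ndim != 3 or len(set(v.shape)) != 1:
        raise ValueError(f"expected a cubic 3D volume, got shape {v.shape}")
    L = v.shape[0]
    out: list[np.ndarray] = []
    for d in (1, 2, 3):
        for k in range(L):
            out.append(np.take(v, k, axis=d - 1))
    return out
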