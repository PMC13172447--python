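"""Per-cell geometric descriptors and distribution-level comparison.

Four descriptors characterize each cell of a 2D or 3D label image: the
volume V (pixel/voxel count), the area/volume-equivalent diameter d_V, the
perimeter/surface area S_A extracted from a sub-pixel iso-contour or
iso-surface, and the elongation E (ratio of smallest to largest covariance
eigenvalue of the cell's grid points, 1 = isotropic, 0 = line-like), plus
the neighbor count gamma under 8- (2D) or 26- (3D) connectivity.

For periodic images every descriptor respects the wrap: cells crossing the
window boundary are measured as single connected bodies by unwrapping their
points to the periodic image nearest a per-cell anchor, and adjacency wraps
across faces.

Two empirical descriptor distributions are compared by the 1-D Wasserstein
distance (the area between their cumulative distribution functions), which
has the physical unit of the descriptor itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

__all__ = [
    "cell_volume",
    "equivalent_diameter",
    "surface_area",
    "elongation",
    "neighbor_count",
    "adjacency_sets",
    "wasserstein_1d",
    "descriptor_table",
    "compare_structures",
]

#: Gaussian pre-smoothing (in pixels) applied to binary masks before
#: iso-contour / iso-surface extraction; mitigates staircase bias of
#: digitized boundaries (validated against disk/sphere closed forms).
ISO_SMOOTH_SIGMA = 0.6


def _check_label(labels: np.ndarray, label: int) -> None:
    if not np.any(labels == label):
        raise KeyError(f"label {label} not present in image")


def cell_volume(image: np.ndarray, label: int) -> int:
    """Number of grid points carrying ``label`` (pixel/voxel count)."""
    img = np.asarray(image)
    _check_label(img, label)
    return int(np.count_nonzero(img == label))


def equivalent_diameter(V: float, dim: int) -> float:
    """Diameter of the disk (2D) / sphere (3D) with the same area/volume."""
    if V < 1:
        raise ValueError(f"cell volume must be >= 1, got {V}")
    if dim == 2:
        return 2.0 * (V / np.pi) ** 0.5
    if dim == 3:
        return 2.0 * (3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0)
    raise ValueError(f"dim must be 2 or 3, got {dim}")


def _roll_to_interior(mask: np.ndarray) -> tuple[np.ndarray, bool]:
    """Cyclically roll a periodic mask so the cell clears every boundary.

    For each axis an empty slab (a coordinate hyperplane free of the cell)
    is rolled to the end of the axis, making the cell contiguous there.
    Returns the rolled mask and whether all axes could be cleared (an axis
    spanned entirely by the cell cannot be).
    """
    out = mask
    ok = True
    for ax in range(mask.ndim):
        other = tuple(a for a in range(mask.ndim) if a != ax)
        occupied = out.any(axis=other)
        empty = np.flatnonzero(~occupied)
        if len(empty) == 0:
            ok = False
            continue
        out = np.roll(out, -(empty[0] + 1), axis=ax)
    return out, ok


def surface_area(image: np.ndarray, label: int, periodic: bool = False) -> float:
    """Perimeter (2D) or surface area (3D) of one cell.

    The binary mask is lightly Gaussian-smoothed and the 0.5 iso-contour
    (marching squares) / iso-surface (marching cubes) is extracted; its total
    polyline length / mesh area is returned.  Periodic cells are first rolled
    into the window interior so wrap-around interfaces are counted exactly
    once; a cell with no boundary at all (single cell filling a periodic
    window) has surface area 0.
    """
    img = np.asarray(image)
    _check_label(img, label)
    mask = img == label
    if periodic:
        if mask.all():
            return 0.0
        mask, cleared = _roll_to_interior(mask)
        if cleared:
            mask = np.pad(mask, 1)
        else:  # cell spans a full axis: fall back to cyclic padding
            mask = np.pad(mask, 1, mode="wrap")
    else:
        mask = np.pad(mask, 1)
    f = ndimage.gaussian_filter(mask.astype(float), ISO_SMOOTH_SIGMA, mode="nearest")
    if img.ndim == 2:
        contours = measure.find_contours(f, 0.5)
        return float(
            sum(np.linalg.norm(np.diff(c, axis=0), axis=1).sum() for c in contours)
        )
    if img.ndim == 3:
        if not (f > 0.5).any() or not (f < 0.5).any():
            return 0.0
        verts, faces, _, _ = measure.marching_cubes(f, level=0.5)
        return float(measure.mesh_surface_area(verts, faces))
    raise ValueError(f"expected a 2D or 3D image, got ndim={img.ndim}")


def _unwrapped_coords(
    image: np.ndarray, label: int, periodic: bool, anchor: np.ndarray | None = None
) -> np.ndarray:
    coords = np.argwhere(np.asarray(image) == label).astype(float)
    if periodic:
        if anchor is None:
            anchor = coords[0]  # first point in scan order
        sizes = np.asarray(image.shape, dtype=float)
        d = np.mod(coords - anchor + sizes / 2, sizes) - sizes / 2
        coords = anchor + d
    return coords


def elongation(
    image: np.ndarray,
    label: int,
    periodic: bool = False,
    anchor: np.ndarray | None = None,
) -> float:
    """Ratio lambda_min / lambda_max of the cell's coordinate covariance.

    Periodic cells are unwrapped to the periodic image nearest ``anchor``
    (the cell's seed if known, else its first grid point in scan order).
    Single-point cells return 1 by convention; perfectly collinear cells
    return 0.
    """
    img = np.asarray(image)
    _check_label(img, label)
    coords = _unwrapped_coords(img, label, periodic, anchor)
    if coords.shape[0] < 2:
        return 1.0
    cov = np.cov(coords.T)
    ev = np.linalg.eigvalsh(cov)
    lo, hi = max(float(ev[0]), 0.0), float(ev[-1])
    if hi <= 0.0:
        return 1.0
    return lo / hi


_OFFSETS_2D = [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)]
_OFFSETS_3D = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def adjacency_sets(image: np.ndarray, periodic: bool = False) -> dict[int, set[int]]:
    """Neighbor sets of all labels under 8-/26-connectivity.

    Two cells are neighbors when any of their grid points are adjacent under
    the full Moore neighborhood, wrapping across faces when ``periodic``.
    The relation is symmetric by construction.
    """
    img = np.asarray(image)
    offsets = _OFFSETS_2D if img.ndim == 2 else _OFFSETS_3D
    neighbors: dict[int, set[int]] = {int(l): set() for l in np.unique(img)}
    for off in offsets:
        rolled = np.roll(img, off, axis=tuple(range(img.ndim)))
        a, b = img, rolled
        if not periodic:
            sel = np.ones(img.shape, dtype=bool)
            for ax, o in enumerate(off):
                if o > 0:
                    sel[(slice(None),) * ax + (slice(0, o),)] = False
                elif o < 0:
                    sel[(slice(None),) * ax + (slice(o, None),)] = False
            a, b = a[sel], b[sel]
        diff = a != b
        pairs = np.unique(
            np.stack([a[diff].ravel(), b[diff].ravel()], axis=1), axis=0
        )
        for x, y in pairs:
            neighbors[int(x)].add(int(y))
            neighbors[int(y)].add(int(x))
    return neighbors


def neighbor_count(image: np.ndarray, label: int, periodic: bool = False) -> int:
    """Number of distinct cells adjacent to ``label`` (gamma)."""
    img = np.asarray(image)
    _check_label(img, label)
    return len(adjacency_sets(img, periodic)[int(label)])


def wasserstein_1d(x: np.ndarray, y: np.ndarray) -> float:
    """Exact 1-D Wasserstein distance: integral of |F_x - F_y|.

    Supports unequal sample sizes; for equal sizes it reduces to the mean
    absolute difference of the sorted samples.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    return float(stats.wasserstein_distance(x, y))


def descriptor_table(
    image: np.ndarray,
    periodic: bool = False,
    anchors: dict[int, np.ndarray] | None = None,
) -> pd.DataFrame:
    """All per-cell descriptors of a label image as one DataFrame.

    Columns: ``label, V, d_V, S_A, E, gamma``.  ``anchors`` optionally maps
    labels to seed coordinates used for periodic unwrapping in E.
    """
    img = np.asarray(image)
    dim = img.ndim
    if dim not in (2, 3):
        raise ValueError(f"expected a 2D or 3D image, got ndim={dim}")
    adj = adjacency_sets(img, periodic)
    rows = []
    for label in np.unique(img):
        label = int(label)
        V = int(np.count_nonzero(img == label))
        anchor = anchors.get(label) if anchors else None
        rows.append(
            {
                "label": label,
                "V": V,
                "d_V": equivalent_diameter(V, dim),
                "S_A": surface_area(img, label, periodic),
                "E": elongation(img, label, periodic, anchor),
                "gamma": len(adj[label]),
            }
        )
    return pd.DataFrame(rows)


#: descriptor columns entering the comparison table
DESCRIPTOR_COLUMNS = ("V", "d_V", "S_A", "E", "gamma")


def compare_structures(
    input_cells: pd.DataFrame, output_cells: pd.DataFrame
) -> pd.DataFrame:
    """Summary comparison of two per-cell descriptor tables.

    One row per descriptor: input/output mean and standard deviation, the
    relative mean error ``|mu_out - mu_in| / mu_in * 100`` (percent), and the
    empirical 1-D Wasserstein distance between the two samples.
    """
    if len(input_cells) == 0 or len(output_cells) == 0:
        raise ValueError("descriptor tables must be nonempty")
    rows = []
    for col in DESCRIPTOR_COLUMNS:
        if col not in input_cells or col not in output_cells:
            continue
        a = input_cells[col].to_numpy(dtype=float)
        b = output_cells[col].to_numpy(dtype=float)
        mu_in, mu_out = a.mean(), b.mean()
        rows.append(
            {
                "descriptor": col,
                "mean_in": mu_in,
                "std_in": a.std(ddof=0),
                "mean_out": mu_out,
                "std_out": b.std(ddof=0),
                "rel_mean_error_pct": abs(mu_out - mu_in) / abs(mu_in) * 100.0
                if mu_in != 0
                else np.inf,
                "wasserstein": wasserstein_1d(a, b),
            }
        )
    return pd.DataFrame(rows)
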