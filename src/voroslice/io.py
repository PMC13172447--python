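"""File formats: label images (PNG/TIFF), seed patterns (CSV + JSON sidecar).

Conventions: label 0 is a valid cell label (cellular structures have no
background phase); coordinates are 0-based and live in the half-open window
[0, L).  Every artifact the package writes can be re-read by the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .tessellation import SeedPointPattern

__all__ = [
    "read_label_image",
    "write_label_image",
    "write_rgb_image",
    "write_seed_pattern",
    "read_seed_pattern",
    "FormatError",
]


class FormatError(ValueError):
    """Unreadable or mistyped image / seed file."""


def read_label_image(path) -> np.ndarray:
    """Read a 2D (PNG/TIFF) or 3D (multi-page TIFF) integer label image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise FormatError(f"could not read label image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and path.suffix.lower() not in (
        ".tif",
        ".tiff",
    ):
        raise FormatError(
            f"{path} looks like an RGB image; label images must be single-channel "
            "integer maps (segment first, or provide a label mapping)"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(
            f"{path} has dtype {arr.dtype}; label images must be integer-typed"
        )
    if arr.min() < 0:
        raise FormatError(f"{path} contains negative labels")
    return arr


def write_label_image(path, labels: np.ndarray) -> None:
    """Write a 2D/3D label image (16-bit PNG for 2D .png, TIFF otherwise)."""
    path = Path(path)
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError("labels must be integer-typed")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".png":
        if labels.ndim != 2:
            raise FormatError("PNG supports 2D label images only")
        if labels.max() > np.iinfo(np.uint16).max:
            raise FormatError("labels exceed 16-bit PNG range; use TIFF")
        iio.imwrite(path, labels.astype(np.uint16))
    else:
        tifffile.imwrite(path, labels.astype(np.min_scalar_type(int(labels.max()))))


def write_rgb_image(path, image: np.ndarray) -> None:
    """Write an RGB image with values in [0, 1] as 8-bit PNG."""
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (img * 255).round().astype(np.uint8))


def write_seed_pattern(S: SeedPointPattern, path) -> None:
    """Write a seed pattern as CSV (index,x,y,z) plus a JSON header sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("index,x,y,z\n")
        for i, (x, y, z) in enumerate(S.points, start=1):
            fh.write(f"{i},{float(x)!r},{float(y)!r},{float(z)!r}\n")
    meta = {
        k: v for k, v in S.metadata.items() if isinstance(v, (str, int, float, bool))
    }
    header = {"L": S.window_size, "n": S.n, "metadata": meta}
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def read_seed_pattern(path) -> SeedPointPattern:
    """Read a seed pattern written by :func:`write_seed_pattern`.

    Validates that every coordinate lies in [0, L) and that the CSV row count
    matches the JSON header.
    """
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    L = float(header["L"])
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse seed CSV {path}: {exc}") from exc
    if data.shape[1] != 4:
        raise FormatError(f"{path}: expected 4 columns (index,x,y,z)")
    pts = data[:, 1:4]
    if int(header["n"]) != pts.shape[0]:
        raise FormatError(
            f"{path}: JSON header n={header['n']} but CSV has {pts.shape[0]} rows"
        )
    if np.any(pts < 0) or np.any(pts >= L):
        raise FormatError(
            f"{path}: coordinates must lie in the half-open window [0, {L})"
        )
    return SeedPointPattern(pts, L, dict(header.get("metadata", {})))
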