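"""Cell-localization I/O: coordinate tables, centroid extraction, masks.

Coordinate tables are comma-delimited with a mandatory header and
columns ``x,y[,label]``, in μm unless the caller declares pixel units.
Centroids are extracted from binary or labeled rasters one per
8-connected component, the way particle-picking plugins report cell
positions. Exclusion masks (white-pulp regions) come in as either a
raster (nonzero = excluded) or a small table of circles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from .window import SpatialWindow

__all__ = [
    "PointPattern",
    "LabelImage",
    "read_points",
    "write_points",
    "extract_centroids",
    "read_mask",
]


@dataclass(frozen=True)
class PointPattern:
    """An ordered set of 2-D cell localizations in μm.

    ``label`` names the population ("venus", "hspc", "random", ...).
    Duplicate coordinates are permitted: two cells can share a centroid
    at pixel resolution. The optional ``window`` ties the pattern to its
    analysis domain; it is required only at analysis time.
    """

    points: np.ndarray
    label: str = ""
    window: SpatialWindow | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be an (n, 2) array, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("coordinates must be finite (no NaN/inf)")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def with_window(self, window: SpatialWindow) -> "PointPattern":
        return PointPattern(self.points, self.label, window)


@dataclass(frozen=True)
class LabelImage:
    """A 2-D integer raster (0 = background) with its pixel size in μm."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("raster must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)


def read_points(
    path: str | Path,
    units: str = "um",
    pixel_size: float | None = None,
) -> PointPattern:
    """Read a coordinate table into a :class:`PointPattern` in μm.

    The file must be a delimited table with header columns ``x`` and
    ``y`` (an optional ``label`` column names the population). With
    ``units="pixel"`` coordinates are multiplied by ``pixel_size``.
    Row order is preserved.
    """
    if units not in ("um", "pixel"):
        raise ValueError(f"units must be 'um' or 'pixel', got {units!r}")
    if units == "pixel" and pixel_size is None:
        raise ValueError("pixel units require a pixel_size")
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "x" not in df.columns or "y" not in df.columns:
        raise ValueError(f"{path}: table must have header columns x and y")
    try:
        xy = df[["x", "y"]].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric coordinates") from exc
    if not np.all(np.isfinite(xy)):
        raise ValueError(f"{path}: non-finite coordinates")
    if units == "pixel":
        xy = xy * float(pixel_size)
    label = ""
    if "label" in df.columns and len(df):
        labels = df["label"].astype(str).unique()
        label = labels[0] if len(labels) == 1 else "mixed"
    return PointPattern(xy, label=label)


def write_points(pattern: PointPattern, path: str | Path) -> None:
    """Write ``x,y,label`` CSV at full float precision (round-trips exactly)."""
    df = pd.DataFrame({
        "x": pattern.points[:, 0],
        "y": pattern.points[:, 1],
        "label": [pattern.label] * len(pattern),
    })
    df.to_csv(path, index=False, float_format="%.17g")


def extract_centroids(
    image: LabelImage,
    min_area: int = 1,
    max_area: int | None = None,
) -> PointPattern:
    """One point per 8-connected foreground component, as its area centroid.

    Components with pixel area outside ``[min_area, max_area]`` are
    dropped; components touching the border are kept. A pixel at row i,
    column j has its center at ``((j+0.5)·s, (i+0.5)·s)`` μm. If the
    raster already carries labels (values > 1) they are used as-is, so
    touching regions with distinct ids stay distinct.
    """
    if max_area is None:
        max_area = np.iinfo(np.int64).max
    if not (1 <= min_area <= max_area):
        raise ValueError(f"need 1 <= min_area <= max_area, got [{min_area}, {max_area}]")
    px = image.pixels
    if px.max(initial=0) > 1:
        labeled = px.astype(np.int64)
    else:
        labeled = measure.label(px > 0, connectivity=2)
    pts = []
    for region in measure.regionprops(labeled):
        if min_area <= region.area <= max_area:
            i, j = region.centroid
            pts.append(((j + 0.5) * image.pixel_size, (i + 0.5) * image.pixel_size))
    return PointPattern(np.asarray(pts, dtype=float).reshape(-1, 2), label="centroid")


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse RGB(A) to a single channel
        arr = arr[..., 0]
    return arr


def read_mask(path: str | Path, pixel_size: float | None = None,
              extent: tuple[float, float] | None = None) -> SpatialWindow:
    """Read an exclusion mask into a :class:`SpatialWindow`.

    Raster files (TIFF/PNG; nonzero = excluded) become a window whose
    rectangle is the raster extent at ``pixel_size`` μm/px and whose
    exclusion field is the raster itself, used directly for membership
    tests. CSV files with columns ``x,y,r`` list exclusion discs;
    ``extent=(width, height)`` declares the rectangle (default
    150×150 μm, the standard analysis window).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        df.columns = [str(c).strip().lower() for c in df.columns]
        if not {"x", "y", "r"} <= set(df.columns):
            raise ValueError(f"{path}: circle file needs columns x, y, r")
        width, height = extent if extent is not None else (150.0, 150.0)
        discs = tuple(
            (float(row.x), float(row.y), float(row.r)) for row in df.itertuples()
        )
        return SpatialWindow(width=width, height=height, exclusions=discs)
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("raster masks require a positive pixel_size")
    raster = _read_raster(path)
    excluded = raster != 0
    nrow, ncol = excluded.shape
    return SpatialWindow(
        width=ncol * pixel_size,
        height=nrow * pixel_size,
        exclusion_raster=excluded,
        raster_pixel_size=pixel_size,
    )
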