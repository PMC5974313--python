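"""Analysis windows: rectangular domains with excluded regions.

A :class:`SpatialWindow` is the spatial domain on which point patterns
live — typically a rectangular field of view of a tissue section, in μm,
with the white-pulp follicles removed as exclusion regions. Exclusions
are modelled either as discs (center, radius) or, for windows built from
segmentation masks, as a boolean raster lookup field. All point-pattern
statistics in this package consume only the membership test and the
uniform sampler exposed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, box
from shapely.ops import unary_union

__all__ = ["SpatialWindow", "make_window"]

# Abort rejection sampling once the expected number of rejections per
# accepted point exceeds this (guards near-fully-excluded geometry).
_MAX_REJECTIONS_PER_POINT = 1_000_000

# Segments per quarter circle when rasterizing discs into shapely
# polygons for the area computation; error ~1e-7 relative at 64.
_QUAD_SEGS = 64


@dataclass(frozen=True)
class SpatialWindow:
    """Rectangular analysis domain with optional exclusion regions.

    Parameters
    ----------
    width, height : float
        Extent in μm; must be positive.
    exclusions : tuple of (cx, cy, r)
        Excluded discs in μm. Centers must lie inside the rectangle;
        discs may overlap each other and may extend past the rectangle.
    origin : (float, float)
        Lower-left corner in μm. Windows produced by tiling a larger
        section keep absolute coordinates via a non-zero origin.
    exclusion_raster : ndarray of bool, optional
        Alternative exclusion representation: ``True`` pixels are
        excluded. Used verbatim as a lookup field (never vectorized to
        discs). Row ``i``, column ``j`` covers the μm square
        ``[j·s, (j+1)·s) × [i·s, (i+1)·s)`` relative to the origin,
        with ``s = raster_pixel_size``.
    """

    width: float
    height: float
    exclusions: tuple[tuple[float, float, float], ...] = ()
    origin: tuple[float, float] = (0.0, 0.0)
    exclusion_raster: np.ndarray | None = field(default=None, compare=False)
    raster_pixel_size: float | None = None

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"window dimensions must be positive, got {self.width}×{self.height}"
            )
        object.__setattr__(self, "exclusions", tuple(
            (float(x), float(y), float(r)) for x, y, r in self.exclusions
        ))
        x0, y0 = self.origin
        for cx, cy, r in self.exclusions:
            if r < 0:
                raise ValueError(f"exclusion radius must be >= 0, got {r}")
            if not (x0 <= cx <= x0 + self.width and y0 <= cy <= y0 + self.height):
                raise ValueError(
                    f"exclusion center ({cx}, {cy}) lies outside the window rectangle"
                )
        if self.exclusion_raster is not None:
            if self.raster_pixel_size is None or self.raster_pixel_size <= 0:
                raise ValueError("raster exclusions require a positive raster_pixel_size")
        if self.usable_area() <= 0:
            raise ValueError("window has no usable area (fully excluded)")

    # -- geometry ---------------------------------------------------------

    @property
    def area(self) -> float:
        """Total rectangle area in μm² (exclusions not subtracted)."""
        return self.width * self.height

    def usable_area(self) -> float:
        """Area in μm² of the rectangle minus the exclusion regions."""
        x0, y0 = self.origin
        if self.exclusion_raster is not None:
            s = float(self.raster_pixel_size)
            return float((~self.exclusion_raster).sum()) * s * s
        if not self.exclusions:
            return self.area
        rect = box(x0, y0, x0 + self.width, y0 + self.height)
        discs = [
            Point(cx, cy).buffer(r, quad_segs=_QUAD_SEGS)
            for cx, cy, r in self.exclusions
            if r > 0
        ]
        if not discs:
            return self.area
        return float(rect.difference(unary_union(discs)).area)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized membership in the usable area.

        Parameters
        ----------
        xy : (n, 2) array of μm coordinates.

        Returns
        -------
        (n,) boolean array: inside the rectangle and outside every
        exclusion region. Points exactly on a disc boundary count as
        outside the disc (usable).
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x0, y0 = self.origin
        x, y = xy[:, 0], xy[:, 1]
        ok = (x >= x0) & (x <= x0 + self.width) & (y >= y0) & (y <= y0 + self.height)
        if self.exclusion_raster is not None:
            s = float(self.raster_pixel_size)
            nrow, ncol = self.exclusion_raster.shape
            j = np.clip(((x - x0) / s).astype(int), 0, ncol - 1)
            i = np.clip(((y - y0) / s).astype(int), 0, nrow - 1)
            ok &= ~self.exclusion_raster[i, j]
        for cx, cy, r in self.exclusions:
            if r > 0:
                ok &= (x - cx) ** 2 + (y - cy) ** 2 >= r * r
        return ok

    def boundary_distance_to_exclusions(self, xy: np.ndarray) -> np.ndarray:
        """Distance (μm) from each point to the nearest exclusion-disc boundary.

        Only defined for disc exclusions; used to carve annular
        perifollicular bands. Returns +inf if there are no discs.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if not self.exclusions:
            return np.full(len(xy), np.inf)
        d = np.full(len(xy), np.inf)
        for cx, cy, r in self.exclusions:
            dc = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
            d = np.minimum(d, np.abs(dc - r))
        return d

    # -- sampling ---------------------------------------------------------

    def sample_uniform(
        self,
        n: int,
        rng: np.random.Generator,
        accept: "callable | None" = None,
    ) -> np.ndarray:
        """Draw ``n`` points uniformly on the usable area by rejection.

        ``accept``, if given, further restricts the support: a callable
        mapping an (k, 2) array to a (k,) boolean mask, applied on top
        of the usable-area test. Raises ``RuntimeError`` if the
        acceptance region appears empty (rejection cap exceeded).
        """
        if n < 0:
            raise ValueError(f"point count must be >= 0, got {n}")
        if n == 0:
            return np.empty((0, 2))
        x0, y0 = self.origin
        out = np.empty((n, 2))
        got = 0
        attempts = 0
        budget = _MAX_REJECTIONS_PER_POINT * n
        batch = max(4 * n, 256)
        while got < n:
            if attempts > budget:
                raise RuntimeError(
                    "rejection sampling exceeded its budget; the sampling "
                    "region is empty or vanishingly small"
                )
            cand = np.column_stack([
                rng.uniform(x0, x0 + self.width, batch),
                rng.uniform(y0, y0 + self.height, batch),
            ])
            keep = self.contains(cand)
            if accept is not None:
                keep &= np.asarray(accept(cand), dtype=bool)
            cand = cand[keep]
            take = min(n - got, len(cand))
            out[got:got + take] = cand[:take]
            got += take
            attempts += batch
        return out


def make_window(
    width: float,
    height: float,
    follicles: list[tuple[float, float, float]] | None = None,
) -> SpatialWindow:
    """Build a window of ``width × height`` μm with follicle exclusion discs.

    Raises ``ValueError`` for non-positive dimensions, negative radii,
    follicle centers outside the rectangle, or a fully excluded window.
    """
    return SpatialWindow(width=float(width), height=float(height),
                         exclusions=tuple(follicles or ()))
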