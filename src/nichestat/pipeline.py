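"""End-to-end orchestration: simulate or load → analyze → report.

A pipeline run is fully described by a config mapping (usually loaded
from YAML): either a synthetic-scene block or paths to coordinate
tables and an exclusion mask, plus Hopkins and proximity parameters
and one global seed. Reports are JSON with sorted keys and floats at
12 significant digits, so identical configs re-run to byte-identical
numerical content; every random sub-stream derivation is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .hopkins import HopkinsConfig, csr_envelope, hopkins_resampled
from .point_io import PointPattern, read_mask, read_points
from .proximity import proximity_test
from .synthetic import SceneParams, make_scene
from .window import SpatialWindow

__all__ = ["AnalysisReport", "run_pipeline", "tile_windows", "write_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisReport:
    """Machine-readable record of one pipeline run.

    Every reported mean/SD is recomputable from the embedded
    per-window/per-replicate records.
    """

    metadata: dict
    hopkins: dict = field(default_factory=dict)
    proximity: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"metadata": self.metadata, "hopkins": self.hopkins,
                "proximity": self.proximity}


def _sig12(obj):
    """Recursively round floats to 12 significant digits for diff-able JSON."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _sig12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sig12(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_sig12(float(v)) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _sig12(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(report: AnalysisReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(_sig12(report.to_dict()), fh, sort_keys=True, indent=2)
        fh.write("\n")


def _sub_seed(root: np.random.SeedSequence, index: int, purpose: str) -> int:
    seed = int(root.spawn(index + 1)[index].generate_state(1)[0] % (2 ** 31))
    logger.info("derived sub-seed %d for %s (stream %d)", seed, purpose, index)
    return seed


def _load_inputs(config: dict) -> tuple[SpatialWindow, PointPattern, PointPattern]:
    if "scene" in config:
        params = SceneParams(**{**config["scene"],
                                "follicles": tuple(tuple(f) for f in
                                                   config["scene"].get("follicles", [[75, 75, 30]])),
                                "seed": int(config.get("seed", 0))})
        scene = make_scene(params)
        return scene.window, scene.niche_points, scene.target_points
    if "inputs" not in config:
        raise KeyError("config must contain a 'scene' or an 'inputs' section")
    inp = config["inputs"]
    if "mask" in inp:
        window = read_mask(inp["mask"], pixel_size=inp.get("pixel_size"),
                           extent=tuple(inp["window"]) if "window" in inp else None)
    else:
        w, h = inp.get("window", (150.0, 150.0))
        window = SpatialWindow(width=float(w), height=float(h))
    niche = read_points(inp["references"]).with_window(window)
    target = read_points(inp["targets"]).with_window(window)
    return window, niche, target


def run_pipeline(config: dict) -> AnalysisReport:
    """Run simulate/load → Hopkins → proximity and assemble a report.

    Deterministic given the config (which includes the seed). Stage
    errors propagate annotated with the stage name.
    """
    seed = int(config.get("seed", 0))
    root = np.random.SeedSequence(seed)

    try:
        window, niche, target = _load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"[stage: inputs] {exc}") from exc

    hop_cfg_in = dict(config.get("hopkins", {}))
    envelope_sims = int(hop_cfg_in.pop("envelope_sims", 100))
    try:
        hop_cfg = HopkinsConfig(seed=_sub_seed(root, 0, "hopkins resampling"),
                                **hop_cfg_in)
        hop = hopkins_resampled(niche, window, hop_cfg, window_id="window_0")
        lo, hi, null_means = csr_envelope(
            len(niche), window,
            HopkinsConfig(m=hop_cfg.m, reps=hop_cfg.reps, variant=hop_cfg.variant,
                          seed=_sub_seed(root, 1, "CSR envelope")),
            sims=envelope_sims,
        )
    except Exception as exc:
        raise RuntimeError(f"[stage: hopkins] {exc}") from exc

    prox_cfg = dict(config.get("proximity", {}))
    try:
        prox = proximity_test(
            target, niche, window,
            n_null=int(prox_cfg.get("n_null", 999)),
            seed=_sub_seed(root, 2, "proximity null"),
            mode=prox_cfg.get("mode", "point_nn"),
        )
    except Exception as exc:
        raise RuntimeError(f"[stage: proximity] {exc}") from exc

    hopkins_block = {
        "window_0": {
            "mean": hop.mean,
            "sd_per_rep": hop.sd,
            "m": hop.config.m,
            "reps": hop.config.reps,
            "variant": hop.config.variant,
            "n_points": len(niche),
        },
        "csr_envelope": {
            "lo": lo, "hi": hi, "sims": envelope_sims,
            "null_mean": float(np.mean(null_means)),
        },
        "classification": ("clustered" if hop.mean > hi
                           else "regular" if hop.mean < lo else "random"),
    }
    proximity_block = {
        "observed_mean_um": prox.observed_mean,
        "observed_sd_um": prox.observed_sd,
        "null_mean_um": float(np.mean(prox.null_means)),
        "null_sd_um": float(np.std(prox.null_means, ddof=1)),
        "p_value": prox.p_value,
        "n_null": prox.n_null,
        "n_targets": len(target),
        "mode": prox.mode,
    }
    metadata = {
        "config": _sig12(_jsonable(config)),
        "seed": seed,
        "nichestat_version": __version__,
    }
    return AnalysisReport(metadata=metadata, hopkins=hopkins_block,
                          proximity=proximity_block)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def tile_windows(
    section_extent: tuple[float, float],
    mask: SpatialWindow | None,
    window_size: float,
    min_points: int,
    pattern: PointPattern,
) -> list[SpatialWindow]:
    """Tile a section into non-overlapping square analysis windows.

    Grid tiles of ``window_size`` μm cover the section from its lower-left
    corner (partial tiles at the far edges are dropped). A tile is
    retained iff at least ``min_points`` pattern points fall inside it
    and on the mask's usable area. Tiles inherit the mask's exclusion
    geometry, rasterized per-tile where a disc overlaps the tile.
    """
    sw, sh = float(section_extent[0]), float(section_extent[1])
    if not window_size > 0:
        raise ValueError(f"window_size must be > 0, got {window_size}")
    if window_size > sw or window_size > sh:
        raise ValueError("window_size exceeds the section extent")
    nx, ny = int(sw // window_size), int(sh // window_size)
    pts = pattern.points
    usable = mask.contains(pts) if (mask is not None and len(pts)) else \
        np.ones(len(pts), dtype=bool)
    tiles: list[SpatialWindow] = []
    for iy in range(ny):
        for ix in range(nx):
            x0, y0 = ix * window_size, iy * window_size
            inside = (
                (pts[:, 0] >= x0) & (pts[:, 0] < x0 + window_size)
                & (pts[:, 1] >= y0) & (pts[:, 1] < y0 + window_size)
                & usable
            ) if len(pts) else np.zeros(0, dtype=bool)
            if int(inside.sum()) < min_points:
                continue
            tiles.append(_tile_window(x0, y0, window_size, mask))
    return tiles


def _tile_window(x0: float, y0: float, size: float,
                 mask: SpatialWindow | None) -> SpatialWindow:
    if mask is None or (not mask.exclusions and mask.exclusion_raster is None):
        return SpatialWindow(width=size, height=size, origin=(x0, y0))
    overlapping = []
    for cx, cy, r in mask.exclusions:
        dx = max(x0 - cx, 0.0, cx - (x0 + size))
        dy = max(y0 - cy, 0.0, cy - (y0 + size))
        if dx * dx + dy * dy <= r * r:
            overlapping.append((cx, cy, r))
    raster_src = mask.exclusion_raster is not None
    if not overlapping and not raster_src:
        return SpatialWindow(width=size, height=size, origin=(x0, y0))
    # Rasterize the exclusion field over the tile so membership matches
    # the section mask even when a disc's center lies outside the tile.
    npix = 256
    s = size / npix
    xs = x0 + (np.arange(npix) + 0.5) * s
    ys = y0 + (np.arange(npix) + 0.5) * s
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    excluded = ~mask.contains(centers)
    return SpatialWindow(
        width=size, height=size, origin=(x0, y0),
        exclusion_raster=excluded.reshape(npix, npix),
        raster_pixel_size=s,
    )
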