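"""Synthetic tissue scenes with known spatial structure.

Generates the three kinds of point field needed to exercise the spatial
statistics against ground truth:

* complete spatial randomness (CSR) — uniform on a window's usable
  area, the null model under which the Hopkins index expects 0.5;
* perifollicular clustering — a fraction ``p`` of points confined to
  an annular band hugging the follicle (white pulp) boundary, the
  pattern niche cells adopt when they accumulate around follicles;
* attraction — a target population (the HSPC analog) placed by
  Gaussian displacement from a reference population, with a
  controllable displacement scale σ.

Each population draws from its own deterministic sub-stream of the
scene seed, so adding one population never perturbs another. Streams
are derived as ``np.random.SeedSequence(seed).spawn(...)`` children in
a fixed role order (niche = 0, target = 1, null = 2, extra roles
onward), documented here once and used everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .point_io import PointPattern
from .window import SpatialWindow, make_window

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "population_rng",
    "simulate_csr",
    "simulate_perifollicular",
    "simulate_attracted",
    "simulate_equal_density_random",
    "make_scene",
    "save_scene_params",
    "load_scene_params",
]

# Fixed role → sub-stream index mapping (see module docstring).
_ROLE_STREAMS = {"niche": 0, "target": 1, "null": 2}


def population_rng(seed: int, role: str | int) -> np.random.Generator:
    """Deterministic per-population generator derived from the scene seed."""
    idx = _ROLE_STREAMS.get(role, role) if isinstance(role, str) else role
    children = np.random.SeedSequence(seed).spawn(int(idx) + 1)
    return np.random.default_rng(children[int(idx)])


def _as_rng(seed: "int | np.random.Generator") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_csr(
    n: int,
    window: SpatialWindow,
    seed: "int | np.random.Generator" = 0,
) -> PointPattern:
    """``n`` points uniform on the usable area (rejection against exclusions)."""
    if n < 0:
        raise ValueError(f"point count must be >= 0, got {n}")
    rng = _as_rng(seed)
    return PointPattern(window.sample_uniform(n, rng), label="csr", window=window)


def simulate_perifollicular(
    n: int,
    window: SpatialWindow,
    band_width: float,
    clustered_fraction: float,
    seed: "int | np.random.Generator" = 0,
) -> PointPattern:
    """Mixture of band-confined and CSR points around follicle exclusions.

    ``ceil(p·n)`` points are uniform on the annular band within
    ``band_width`` μm of the nearest follicle boundary (outside the
    follicle); the remainder are CSR on the whole usable area. With
    ``p = 0`` the draw protocol matches :func:`simulate_csr` on the
    same stream.
    """
    if not window.exclusions:
        raise ValueError("perifollicular simulation needs >= 1 follicle exclusion")
    if not 0.0 <= clustered_fraction <= 1.0:
        raise ValueError(f"clustered_fraction must be in [0, 1], got {clustered_fraction}")
    if not band_width > 0:
        raise ValueError(f"band_width must be > 0, got {band_width}")
    if n < 0:
        raise ValueError(f"point count must be >= 0, got {n}")
    rng = _as_rng(seed)
    n_band = math.ceil(clustered_fraction * n)
    n_bg = n - n_band

    def in_band(xy: np.ndarray) -> np.ndarray:
        return window.boundary_distance_to_exclusions(xy) <= band_width

    parts = []
    if n_band:
        try:
            parts.append(window.sample_uniform(n_band, rng, accept=in_band))
        except RuntimeError as exc:
            raise ValueError(
                "perifollicular band is empty (entirely excluded)"
            ) from exc
    if n_bg:
        parts.append(window.sample_uniform(n_bg, rng))
    pts = np.vstack(parts) if parts else np.empty((0, 2))
    return PointPattern(pts, label="perifollicular", window=window)


def simulate_attracted(
    reference: PointPattern,
    n: int,
    attraction_scale: float,
    background_fraction: float = 0.0,
    seed: "int | np.random.Generator" = 0,
    window: SpatialWindow | None = None,
) -> PointPattern:
    """Targets attracted to a reference population.

    ``ceil((1-b)·n)`` points each pick a reference point uniformly and
    displace it by an isotropic Gaussian offset of scale σ =
    ``attraction_scale`` μm, redrawing (reference choice and offset)
    until the point lands on the usable area; the remaining
    ``floor(b·n)`` points are CSR. With ``b = 1`` the draw protocol
    matches :func:`simulate_csr`.
    """
    if not attraction_scale > 0:
        raise ValueError(f"attraction_scale must be > 0, got {attraction_scale}")
    if not 0.0 <= background_fraction <= 1.0:
        raise ValueError(f"background_fraction must be in [0, 1], got {background_fraction}")
    if n < 0:
        raise ValueError(f"point count must be >= 0, got {n}")
    win = window if window is not None else reference.window
    if win is None:
        raise ValueError("a window is required (on the reference pattern or explicit)")
    n_attr = math.ceil((1.0 - background_fraction) * n)
    if n_attr > 0 and len(reference) == 0:
        raise ValueError("empty reference pattern with background_fraction < 1")
    rng = _as_rng(seed)

    parts = []
    if n_attr:
        ref = reference.points
        out = np.empty((n_attr, 2))
        got, attempts = 0, 0
        batch = max(4 * n_attr, 256)
        while got < n_attr:
            if attempts > 1_000_000 * n_attr:
                raise RuntimeError("attracted-point rejection budget exceeded")
            idx = rng.integers(0, len(ref), batch)
            cand = ref[idx] + rng.normal(0.0, attraction_scale, (batch, 2))
            cand = cand[win.contains(cand)]
            take = min(n_attr - got, len(cand))
            out[got:got + take] = cand[:take]
            got += take
            attempts += batch
        parts.append(out)
    n_bg = n - n_attr
    if n_bg:
        parts.append(win.sample_uniform(n_bg, rng))
    pts = np.vstack(parts) if parts else np.empty((0, 2))
    return PointPattern(pts, label="attracted", window=win)


def simulate_equal_density_random(
    template: PointPattern,
    window: SpatialWindow,
    seed: "int | np.random.Generator" = 0,
) -> PointPattern:
    """CSR pattern with exactly the template's count on the same usable area.

    This is the density-matched random null the proximity test compares
    against: the observed population is replaced by the same number of
    uniformly random points, keeping the spatial domain fixed.
    """
    pat = simulate_csr(len(template), window, seed)
    return PointPattern(pat.points, label="random", window=window)


# -- whole scenes ---------------------------------------------------------


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters of a synthetic tissue scene.

    Defaults mirror the study protocol: 150×150 μm analysis windows
    holding on the order of 10² localizations, a central follicle, a
    strong perifollicular bias for the niche population and a short
    attraction scale for the target population.
    """

    width: float = 150.0
    height: float = 150.0
    follicles: tuple[tuple[float, float, float], ...] = ((75.0, 75.0, 30.0),)
    n_niche: int = 120
    n_target: int = 50
    clustered_fraction: float = 0.8
    band_width: float = 10.0
    attraction_scale: float = 5.0
    background_fraction: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class SyntheticScene:
    """A generated scene: window, both populations, and their ground truth."""

    window: SpatialWindow
    niche_points: PointPattern
    target_points: PointPattern
    params: SceneParams


def make_scene(params: SceneParams) -> SyntheticScene:
    """Generate a scene; identical params (incl. seed) give identical output."""
    window = make_window(params.width, params.height, list(params.follicles))
    niche_rng = population_rng(params.seed, "niche")
    if params.follicles and params.clustered_fraction > 0:
        niche = simulate_perifollicular(
            params.n_niche, window, params.band_width,
            params.clustered_fraction, niche_rng,
        )
    else:
        niche = simulate_csr(params.n_niche, window, niche_rng)
    niche = PointPattern(niche.points, label="niche", window=window)
    target_rng = population_rng(params.seed, "target")
    target = simulate_attracted(
        niche, params.n_target, params.attraction_scale,
        params.background_fraction, target_rng, window=window,
    )
    target = PointPattern(target.points, label="target", window=window)
    return SyntheticScene(window, niche, target, params)


def save_scene_params(params: SceneParams, path) -> None:
    """Write scene parameters as a flat YAML key-value file."""
    data = {
        "width": params.width,
        "height": params.height,
        "follicles": [list(f) for f in params.follicles],
        "n_niche": params.n_niche,
        "n_target": params.n_target,
        "clustered_fraction": params.clustered_fraction,
        "band_width": params.band_width,
        "attraction_scale": params.attraction_scale,
        "background_fraction": params.background_fraction,
        "seed": params.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_scene_params(path) -> SceneParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["follicles"] = tuple(tuple(f) for f in data.get("follicles", []))
    return SceneParams(**data)
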