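"""Hopkins clustering-tendency statistic under a subsampled protocol.

The Hopkins statistic compares distances from random sampling origins
to the data (``u``) with nearest-neighbor distances within the data
(``w``):

    h = Σ uᵢᵏ / (Σ uᵢᵏ + Σ wᵢᵏ)

For a pattern under complete spatial randomness (CSR) the two kinds of
distance are exchangeable and h concentrates near 0.5; clustering
shortens within-data distances and pushes h above 0.5 (regular/
repulsive patterns push it below). The default variant uses unpowered
distances (k = 1); ``variant="powered"`` uses k = 2, the classical
Hopkins–Skellam form for two dimensions.

The protocol here is the subsampled one used for tissue sections:
within a window, draw m sampling origins on the usable area and a
random subset of m localizations, compute h, and repeat R times with
fresh origins and a fresh subset each repetition (defaults m = 40,
R = 1000 per 150×150 μm window). The per-window mean of the R values
is the window's Hopkins index; a Monte-Carlo envelope of that index
over CSR patterns of equal density calibrates "significantly clustered".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .point_io import PointPattern
from .synthetic import simulate_csr
from .window import SpatialWindow

__all__ = [
    "HopkinsConfig",
    "HopkinsResult",
    "hopkins_statistic",
    "hopkins_resampled",
    "csr_envelope",
    "hopkins_group_summary",
]

logger = logging.getLogger(__name__)

_VARIANT_EXPONENT = {"plain": 1, "powered": 2}


@dataclass(frozen=True)
class HopkinsConfig:
    """Protocol parameters: subset size m, repetitions R, distance variant."""

    m: int = 40
    reps: int = 1000
    variant: str = "plain"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"subset size m must be >= 1, got {self.m}")
        if self.reps < 1:
            raise ValueError(f"repetitions must be >= 1, got {self.reps}")
        if self.variant not in _VARIANT_EXPONENT:
            raise ValueError(f"variant must be one of {sorted(_VARIANT_EXPONENT)}")


@dataclass(frozen=True)
class HopkinsResult:
    """Per-repetition Hopkins values and their summary for one window."""

    per_rep: np.ndarray = field(compare=False)
    mean: float
    sd: float
    config: HopkinsConfig
    window_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_rep", np.asarray(self.per_rep, dtype=float))


def _nearest_other_distances(points: np.ndarray, tree: cKDTree) -> np.ndarray:
    """Distance from each pattern point to its nearest other pattern point.

    With duplicate coordinates the nearest other point may be coincident
    and the distance 0 — distances, not identities, are consumed.
    """
    d, _ = tree.query(points, k=2)
    return d[:, 1]


def hopkins_statistic(
    pattern: PointPattern,
    window: SpatialWindow,
    m: int,
    variant: str = "plain",
    rng: "np.random.Generator | int | None" = None,
    *,
    origins: np.ndarray | None = None,
    data_indices: np.ndarray | None = None,
) -> float:
    """One Hopkins draw: h ∈ [0, 1], > 0.5 indicating clustering.

    ``m`` sampling origins are drawn uniformly on the usable area (the
    exclusion mask is respected — origins inside excluded white pulp
    would inflate u artificially) and ``m`` data points are sampled
    without replacement from the pattern. ``origins`` / ``data_indices``
    override the random draws, which makes the computation fully
    deterministic for oracle testing. If every u and w is zero the
    statistic is undefined and 0.5 is returned.
    """
    n = len(pattern)
    if n < 2:
        raise ValueError(f"pattern must have >= 2 points, got {n}")
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= pattern count ({n}), got m={m}")
    k = _VARIANT_EXPONENT[variant]
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if origins is None:
        origins = window.sample_uniform(m, gen)
    else:
        origins = np.asarray(origins, dtype=float)
        if origins.shape != (m, 2):
            raise ValueError(f"origins must have shape ({m}, 2)")
    if data_indices is None:
        data_indices = gen.choice(n, size=m, replace=False)
    tree = cKDTree(pattern.points)
    u = tree.query(origins, k=1)[0]
    w = _nearest_other_distances(pattern.points, tree)[np.asarray(data_indices)]
    su, sw = float(np.sum(u ** k)), float(np.sum(w ** k))
    if su + sw == 0.0:
        return 0.5
    return su / (su + sw)


def hopkins_resampled(
    pattern: PointPattern,
    window: SpatialWindow,
    config: HopkinsConfig = HopkinsConfig(),
    window_id: str = "",
) -> HopkinsResult:
    """The subsampled protocol: R repetitions, fresh origins and subset each.

    If the window holds fewer than ``config.m`` localizations, m is
    reduced to the pattern count with a logged warning (tissue windows
    vary in density).

    The whole batch of R·m origins is drawn in one rejection-sampling
    pass and within-pattern nearest-neighbor distances are computed
    once, so the R repetitions share no per-repetition tree builds;
    draws are identical to R sequential repetitions of the same stream.
    """
    n = len(pattern)
    if n < 2:
        raise ValueError(f"pattern must have >= 2 points, got {n}")
    m = config.m
    if m > n:
        logger.warning(
            "window %s has %d < m=%d localizations; reducing m to %d",
            window_id or "<unnamed>", n, m, n,
        )
        m = n
    k = _VARIANT_EXPONENT[config.variant]
    rng = np.random.default_rng(config.seed)
    R = config.reps

    tree = cKDTree(pattern.points)
    w_all = _nearest_other_distances(pattern.points, tree)

    origins = window.sample_uniform(R * m, rng)
    u = tree.query(origins, k=1)[0].reshape(R, m)
    # without-replacement subset per repetition: top-m of a random ranking
    ranks = rng.random((R, n))
    idx = np.argpartition(ranks, m - 1, axis=1)[:, :m]
    w = w_all[idx]

    su = np.sum(u ** k, axis=1)
    sw = np.sum(w ** k, axis=1)
    tot = su + sw
    per_rep = np.where(tot > 0, su / np.where(tot > 0, tot, 1.0), 0.5)
    return HopkinsResult(
        per_rep=per_rep,
        mean=float(per_rep.mean()),
        sd=float(per_rep.std(ddof=1)) if R > 1 else 0.0,
        config=replace(config, m=m),
        window_id=window_id,
    )


def csr_envelope(
    n: int,
    window: SpatialWindow,
    config: HopkinsConfig = HopkinsConfig(),
    sims: int = 200,
) -> tuple[float, float, np.ndarray]:
    """Monte-Carlo envelope of the window Hopkins index under CSR.

    Simulates ``sims`` CSR patterns of ``n`` points on the window, runs
    the full resampled protocol on each, and returns the 2.5% and 97.5%
    quantiles of the null means plus the null means themselves. An
    observed window mean above ``hi`` is flagged clustered; below
    ``lo``, regular.
    """
    if sims < 20:
        raise ValueError(f"need >= 20 simulations for a 95% envelope, got {sims}")
    seeds = np.random.SeedSequence(config.seed).spawn(2 * sims)
    null_means = np.empty(sims)
    for i in range(sims):
        pat = simulate_csr(n, window, np.random.default_rng(seeds[2 * i]))
        sub_seed = int(seeds[2 * i + 1].generate_state(1)[0] % (2 ** 31))
        res = hopkins_resampled(pat, window, replace(config, seed=sub_seed))
        null_means[i] = res.mean
    lo, hi = np.quantile(null_means, [0.025, 0.975])
    return float(lo), float(hi), null_means


def hopkins_group_summary(
    results_by_group: dict[str, list],
    equal_var: bool = True,
) -> dict:
    """Per-group mean ± SD of window Hopkins means, plus a two-sample t test.

    Accepts :class:`HopkinsResult` objects or bare per-window means.
    The test (pooled Student's t by default; Welch with
    ``equal_var=False``) requires exactly two groups, each with >= 2
    windows, and returns a two-tailed p.
    """
    if len(results_by_group) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(results_by_group)}")
    summary: dict = {"groups": {}}
    samples = []
    for name, results in results_by_group.items():
        if len(results) == 0:
            raise ValueError(f"group {name!r} is empty")
        vals = np.array([
            r.mean if isinstance(r, HopkinsResult) else float(r) for r in results
        ])
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs >= 2 windows for an SD")
        summary["groups"][name] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "n_windows": int(len(vals)),
        }
        samples.append(vals)
    t, p = stats.ttest_ind(samples[0], samples[1], equal_var=equal_var)
    summary["t_statistic"] = float(t)
    summary["p_value"] = float(p)
    return summary
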