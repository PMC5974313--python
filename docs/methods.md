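# Methods

## Problem setting

The package quantifies two spatial relationships between cell
populations in 2-D tissue sections, given only their centroid
coordinates in μm: clustering tendency of a single population, and
proximity of a target population to a reference population. All
analysis happens on a *window*: a rectangle (by convention with its
origin at the lower-left corner, x rightward, y upward) minus excluded
regions — in the spleen, the white-pulp follicles, since cells
confined to the red pulp must be compared against randomness confined
to the red pulp, not to the whole rectangle.

Exclusions are either discs (center, radius) or a boolean raster used
directly as a lookup field. Real white pulp is irregular; discs
suffice for validating the statistics because nothing downstream uses
the follicle shape — only point coordinates and the membership mask.
Usable areas for disc geometry are computed with polygonal disc
approximations (64 segments per quarter-circle, relative error
~1e-7); raster geometry counts usable pixels.

## The Hopkins clustering-tendency index

For a pattern of n points, m sampling origins are drawn uniformly on
the usable area and m data points are drawn without replacement from
the pattern. With uᵢ the distance from origin i to the nearest data
point and wᵢ the distance from sampled data point i to the nearest
*other* data point (a coincident duplicate legitimately gives wᵢ = 0;
distances, not identities, are consumed),

    H = Σ uᵢᵏ / (Σ uᵢᵏ + Σ wᵢᵏ).

Orientation: under CSR origin-to-data and within-data distances are
exchangeable and H ≈ 0.5; clustering shortens the wᵢ and pushes H
*above* 0.5, regular (inhibited) patterns push it below. If every
distance is zero (all points coincident with all origins) H is
undefined and 0.5 is returned; if only the wᵢ vanish H = 1 exactly,
the maximal-clustering case.

Two variants are exposed. The default `plain` uses unpowered
distances (k = 1), matching the historical behaviour of early
clustering-tendency implementations; `powered` uses k = d = 2, the
classical Hopkins–Skellam form whose null is Beta(m, m). The
orientation and both variants are validated against an all-pairs
brute-force oracle with injected origins/subsamples, exactly.

### Subsampled protocol

A window's Hopkins index is the mean of R independent draws, each with
fresh origins *and* a fresh data subset (both are resampled; resampling
only one is a defensible alternative reading of subset-based protocols,
but resampling both is the interpretation adopted here and the one the
envelope calibrates). Defaults m = 40, R = 1000 per 150×150 μm
window, with on the order of 10²–10³ localizations per window.
Implementation note: all R·m origins are drawn in one
rejection-sampling batch and the within-pattern nearest-neighbor
distances are computed once per pattern, so one resampled run costs
~70 ms; results are identical to R sequential repetitions.

If a window holds fewer than m points, m is reduced to the pattern
count with a logged warning rather than erroring — section density
varies and discarding sparse windows is the caller's decision (the
tiling helper `tile_windows` retains only tiles with ≥ `min_points`).

Sampling origins respect the exclusion mask: origins placed inside
excluded regions would inflate the uᵢ and bias H upward.

### CSR envelope and group comparison

"Clustered" is operationalized by simulating `sims` (default 200) CSR
patterns of the observed count on the same window, running the full
resampled protocol on each, and taking the 2.5%/97.5% quantiles of the
null means. An observed mean above the upper quantile is flagged
clustered. No edge correction is applied; the small negative bias of
the plain-variant CSR mean (grand mean ≈ 0.495 rather than 0.500 at
n = 200, from boundary effects on the uᵢ) is absorbed by the
simulated envelope, which is the comparison actually used.

Group summaries report mean ± SD of per-window means and a two-sample
t test (pooled by default, Welch optional). Whether windows or animals
are the inferential unit is left to the caller: the report embeds the
per-window values so either aggregation is recomputable.

## Proximity to a reference population

Observed distances are exact point-to-point nearest-neighbor
distances (KD-tree, validated exactly against brute force). A raster
mode rasterizes the references at a chosen pixel size and reads a
Euclidean distance transform instead, for parity with image-based
workflows; its quantization error is bounded by one pixel diagonal
(pixel_size·√2) and is cross-validated against the exact mode.
Distances are 2-D (section plane); no 3-D or surface-to-surface
distances.

The null regenerates the *target* population as CSR with the observed
count on the same usable area, holding references fixed — random spots
replace the population whose placement is in question, at matched
density and under the same exclusion mask. With n_null replicates the
p-value is (1 + #{null mean ≤ observed mean}) / (n_null + 1): the +1
correction keeps p > 0, and the smallest attainable value is
1/(n_null + 1). Small p means the targets are closer to the
references than equally dense random points. The API is symmetric —
the caller chooses which population is "target" — because study
designs differ on which population is questioned; defaults here treat
the HSPC-analog as target and the niche population as reference.
Default n_null = 999; calibration suites use 199 (p granularity 1/200,
ample at α = 0.05).

## Synthetic scenes

The generator produces the three ingredients the validation suites
need, at densities typical of the motivating sections (~40–300 points
per 150×150 μm window):

- **CSR** — uniform on the usable area by rejection sampling (capped at
  10⁶ rejections per point, then an error: a cap hit means the
  acceptance region is empty or vanishingly small). Rejection keeps
  the sampler correct for arbitrary exclusion geometry where an
  inverse-CDF would need per-shape case analysis.
- **Perifollicular clustering** — a fraction p of points uniform on the
  annular band within `band_width` μm of the nearest follicle
  boundary (default band 10 μm, p = 0.8), the rest CSR. This annulus
  mixture is a stand-in intensity profile: the true radial profile of
  perifollicular accumulation in tissue is not characterized, so
  passing tests show the statistics detect band-concentrated
  clustering, not that real niches are uniform annuli.
- **Attraction** — each of ⌈(1−b)·n⌉ targets picks a reference point
  uniformly and displaces it by an isotropic Gaussian of scale σ
  (default 5 μm), redrawing until inside the usable area; ⌊b·n⌋
  background points are CSR. b = 1 and p = 0 reduce exactly to CSR on
  the same random stream, which the tests assert bitwise.

Scenes carry one global integer seed; each population draws from a
`numpy.random.SeedSequence(seed).spawn()` child in a fixed role order
(niche = 0, target = 1, null = 2), so adding a population never
perturbs another. Identical parameters reproduce identical
coordinates bitwise.

What the generator does *not* emulate: irregular follicle shapes,
anisotropic or density-gradient backgrounds, segmentation errors
(missed/merged cells), section-to-section variability, and any
mechanistic cell behaviour. Results on real sections additionally
depend on upstream segmentation quality, which is out of scope here
(inputs are assumed already binarized or tabulated).

## I/O conventions

Coordinate tables are comma-delimited with a mandatory `x,y[,label]`
header, μm units unless declared as pixels with a pixel size; writing
uses 17-significant-digit floats and reading uses round-trip float
parsing, so write∘read is the identity. Centroid extraction labels
8-connected components (already-labeled rasters are used as-is), keeps
those with pixel area in [min_area, max_area] (defaults 1, unbounded —
declared defaults, since particle-picking tools differ), keeps
border-touching components, and maps pixel (row i, col j) to
((j+0.5)·s, (i+0.5)·s) μm. The row axis maps directly to y without a
vertical flip: this keeps centroid extraction translation-equivariant
and is immaterial to every statistic in the package, all of which are
reflection-invariant.

## Numerical and design choices

- Exact KD-tree queries everywhere; the distance-transform mode is the
  only approximate path and carries its stated pixel bound.
- Monte-Carlo p-values use the +1 correction; envelopes use empirical
  quantiles without interpolation assumptions beyond numpy defaults.
- Reports are JSON with sorted keys and floats rounded to 12
  significant digits, so identical configs re-run to byte-identical
  files; every derived sub-seed is logged.
- Validation problem sizes: calibration uses 20 CSR windows (n = 200,
  m = 40, R = 1000); power and coverage use 100 seeds per condition
  and 200 seeds for type-I rates — large enough that the asserted
  rates have binomial SEs of 2–3 points, small enough to run
  comfortably on one CPU.

## Known limitations

- No edge-corrected Hopkins variant; bias near boundaries is handled
  by envelope comparison, not removed. Observed sub-0.5 means on
  sparse regular-ish patterns are expected behaviour.
- No other clustering statistics (Ripley's K, pair correlation,
  Clark–Evans); natural extensions, deliberately out of scope.
- The proximity test conditions on the observed reference pattern; it
  does not model uncertainty in reference placement.
- Raster masks are trusted as given; no smoothing or shape fitting is
  applied to them.
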