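# Methods

This note documents the model behind `gelpen`, the choices that were
genuinely open when the package was designed, and what the phantom-based
tests do and do not demonstrate.

## Imaging model and assumptions

The gel channel of a two-photon stack of a fluorescent hydrogel is assumed
dark above the gel and bright inside it, with a monotone axial transition
across the surface whose shape is approximately symmetric about the true
surface position. Under that assumption the half-maximum crossing
(per-column midpoint between I_min and I_max, first crossing from the top)
is an unbiased surface locator, and it is exactly invariant to affine
intensity rescaling — vignetting or depth-dependent gain does not move the
surface as long as it acts multiplicatively per column.

The undisturbed surface is modelled as a bivariate polynomial of total
degree 3 (10 coefficients). This is the crucial modelling assumption:
**cavities must perturb the surface only locally**, so that the
least-squares fit over all valid pixels still tracks the large-scale gel
shape rather than the cavities. The fit is *not* robust; every valid pixel
including cavity pixels enters it. Consequently the method degrades
predictably when cavities cover a large area fraction: the fitted
reference is pulled into the cavities, depths are underestimated, and the
fit can overshoot elsewhere. With the phantom we measured that ~18% cavity
coverage biases recovered depths by ~10%, while ≤8% coverage keeps the
pooled bias within ~2 µm. The phantom presets therefore place 4 cavities
per 256×256 px stack (≤ ~8% coverage), which is the regime the method is
meant for; results on gels where cells have merged their cavities into
large connected excavations should be treated with caution.

## Pipeline parameters

| parameter | default | unit | role |
|---|---|---|---|
| `mixing_matrix` | identity | – | observed = M · (gel, cell); inverted exactly per voxel, clipped at 0. Must come from a crosstalk calibration; it is not estimated from the data. |
| `outlier_radius_px` / `outlier_threshold` | 2 / 50 | px / intensity | bright median-test despeckle, circular neighbourhood, per z-slice. The threshold is on the 8-bit scale and is rescaled by max/255 for higher-range data. |
| `snr_floor` | 3 | – | column max-over-z must reach floor × robust noise (1.4826·MAD of all voxels). The MAD-of-everything noise scale assumes most voxels belong to one intensity population; half-dark/half-bright fields inflate it. |
| `erode_border_px` | 8 | px | border margin plus morphological erosion of the valid region. Chosen because the cubic reference systematically overshoots at the extreme corners of the valid domain, producing spurious 5–8 µm "cavities" exactly at mask corners; a ~10 µm margin removes them. |
| `presmooth_sigma_px` | 1 | z-slices | 1-D Gaussian on each axial profile before the half-max search. |
| `sigma_um` | 2 | µm | normalized-convolution Gaussian on the penetration map (invalid pixels neither contribute nor spread). Attenuates a Gaussian cavity of radius r by r²/(r²+σ²); must stay ≪ cavity radius. |
| `bin_um` | 1 | µm | histogram bin width for the mode that defines zero depth. |
| `h_floor_um` | 5 | µm | cavity floor, applied twice: as the h-minima dynamic and as an absolute-depth filter, so every reported cavity is ≥ 5 µm deep in both senses. |
| connectivity | 8 | – | in-plane neighbourhood for minima plateaus and flooding; fixed. |

## Numerical choices

* **Fit conditioning.** (x, y) are affinely mapped to [−1, 1] before
  building the 10-term design matrix; the solve uses `lstsq`, and rank
  deficiency (degenerate mask geometry, e.g. all valid pixels collinear)
  is an error rather than a silent pseudo-inverse.
* **Mode estimator.** The mode uses fixed-width bins *anchored at zero*
  (bin k covers ((k−½)b, (k+½)b)); ties go to the bin centre nearest 0,
  then the smaller centre. Zero-anchored bins make the estimator exact on
  data already centred at zero; data-anchored bins would inject a
  spurious half-bin offset on noiseless input. The subtracted shift is
  therefore quantised to multiples of the bin width — a ≤ 0.5 µm
  systematic per stack at the default bin.
* **Half-max interpolation.** Linear between the bracketing slices; the
  crossing sits at the logistic profile's inflection, so the interpolation
  error is O(dz³) and in practice ≪ dz.
* **Peak representative.** One peak per 8-connected surviving minima
  region, located at its deepest pixel, ties to the smallest (y, x).
  A minimum whose dynamic equals h exactly is retained (matching the
  `residue ≥ h` convention of the named transform).
* **Prominence.** Level-set flooding via union–find over valid pixels
  sorted by (value, y, x). When two basins meet at level L, the one whose
  minimum is lexicographically larger dies; a detected peak dying with
  minimum v gets prominence min(L, 0) − v. The cap at 0 (the mode plane)
  makes an isolated pit's prominence equal its depth and guarantees
  0 < prominence ≤ depth. Ties in depth are resolved deterministically:
  the peak earlier in (descending depth, then (y, x)) order counts as
  deeper. Invalid pixels are treated as +∞ — never minima, never bridges.
* **Outlier filter.** The bright median test is not idempotent on
  clusters of adjacent outliers (removing one can expose its neighbour);
  it is idempotent once isolated speckles are gone. It never increases a
  pixel.
* **Summary statistics.** Sample SD (n−1). Aggregation across replicate
  stacks is reported both pooled (all peaks together) and as per-stack
  means, labelled `pooled` / `per_stack_mean`, since the two differ when
  stacks contribute unequal peak counts.

## The phantom

`gelpen.phantom` renders, deterministically per seed:

* a surface height field s(x, y) = cubic polynomial + Σ pits, each pit a
  Gaussian depression of given depth and radius (closed-form truth for
  depth; for pits pairwise farther apart than 4·(r_i + r_j) the expected
  prominence equals the depth);
* gel channel = level · logistic((z − s)/w) (w = 2 µm) · optional radial
  vignette + Gaussian noise; cell channel = spherical blobs (in µm; the
  anisotropic voxel grid makes them ellipsoidal in voxels) inside the
  cavities + noise;
* observed channels = 2×2 crosstalk · true channels; sparse saturated
  single-voxel speckles written last into the gel channel.

Default geometry is 120×256×256 voxels at 2 × 1.24 × 1.24 µm — a
~0.3 × 0.3 mm field, 240 µm axial range. Condition presets draw pit
depths from the depth distributions characteristic of the
migration-supporting gel — (39 ± 18) and (75 ± 30) µm for periodontal ligament cells at days 7
and 14, (24 ± 9) and (18 ± 8) µm for SH-SY5Y — truncated to [5, 180] µm
(floor = detection threshold, cap keeps pits inside the stack; comparisons
use the truncation-corrected mean). Pit radii are 18 µm (PDLC, ~30 µm
cells) and 12 µm (SH-SY5Y, ~12 µm cells); one cell blob sits in each
cavity. Noise is 4% of the gel level, crosstalk 15%/8%, 40 speckles.
The five-pit recovery series {10, 25, 50, 100, 150} µm uses a 512×512
field so the pits are well separated *and* occupy a small area fraction;
on smaller fields the reference-fit pull consumes most of the recovery
tolerance.

What the phantom does **not** emulate: a realistic PSF (no axial/lateral
blur beyond the logistic edge), photobleaching, depth-dependent
scattering loss (beyond the optional vignette), irregular multi-cell
excavation shapes ("extended valleys"), and autofluorescence background.
Passing recovery tests therefore demonstrates correctness of the
geometry/statistics chain under the stated imaging model, not robustness
to every optical artifact of real two-photon data.

## Problem sizes used in tests and the acceptance script

Unit tests run on 64–128 px fields. Recovery experiments use the full
default 256 px preset geometry (20 seeds per condition in the test suite,
12 per condition in `scripts/acceptance.py`) and the 512 px five-pit
series; oracle-equivalence sweeps use 50 random 24×24 integer maps, where
exhaustive level-set flooding is feasible. These sizes give standard
errors a few times smaller than the effects being checked while keeping a
full run in the minutes range on one CPU.

## Known limitations

* Only the upper gel surface is extracted; a second (bottom) surface or
  internal voids are out of scope, as is watershed segmentation of full
  cavity volumes and any 3-D rendering.
* The crosstalk matrix must be supplied; there is no stain-vector
  estimation.
* Depth accuracy is bounded below by dz/2 interpolation noise and the
  mode quantisation (bin/2); cavity depth is attenuated by the smoothing
  factor r²/(r²+σ²), ~1–3% at the defaults for cell-scale cavities.
* The reference fit biases depths downward as cavity coverage grows (see
  above); no robust/RANSAC variant is provided by design.
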