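# Methods

## Problem and data model

A yield map is a georeferenced raster of harvested yield (Mg/ha) for one
field, one year, one crop, typically at 30 m resolution after cleaning and
interpolation of combine-monitor points. Given several years of maps for the
same field, the goal is to partition the field's pixels into three management
classes: **low-and-stable** (consistently below the field mean),
**high-and-stable** (consistently above), and **unstable** (relative
performance swings between years, usually with weather). Stable zones can be
managed with fixed prescriptions; unstable zones are where variable-rate
management and further diagnosis pay off.

All maps are normalized per map to z-scores (mean 0, sample SD 1 over valid
pixels) before classification, so different crops and years are comparable.
Nodata is carried as an explicit boolean mask everywhere; a pixel missing in
any year of a stack is excluded from classification (both classifiers need
the full year series). Sample statistics use the n−1 denominator; quantiles
interpolate linearly between order statistics (the common defaults of the
statistical environments used in this field).

## The two classifiers

**Standard-deviation algorithm.** Per pixel, compute the mean m and sample
SD s of the normalized yield across years. Unstable if s > s\*, otherwise
high-and-stable if m ≥ m\*, else low-and-stable. Defaults s\* = 0.75,
m\* = 0.2.

**Two-way-outlier algorithm.** Per year, band the map's pixels at the p-th
and (1−p)-th within-map percentiles into low / medium / high (default
p = 0.35, strict inequalities, so a fully tied map is all medium). A pixel
seen in the low band at least once *and* the high band at least once is
unstable; the rest split on the mean normalized yield at m\* (default 0.3).
Band membership depends only on value ranks, so it is invariant under any
strictly increasing transform of a year's raw yields. A consequence worth
knowing: the unstable set can only grow as years are added — a jump once
observed cannot be unobserved — so the unstable fraction rises with record
length even in a statistically stationary field.

Threshold comparisons are: unstable strictly `>`, high-stable `≥` on the
mean. The SD threshold default is 0.75 and the two-way mean threshold 0.3;
both are user-overridable (published sources state 0.8 and 0.4 respectively
in other places; we follow the calibrated/Methods values and expose the
parameters).

## Repeatability calibration and its degenerate optimum

Thresholds are calibrated to maximize **repeatability**: split a field's
years into two disjoint sets (every two-block partition with at least 3
years per side is enumerated; for 6 years that is C(6,3)/2 = 10 splits),
classify each side separately, and measure the fraction of jointly valid
pixels assigned the same class. The objective is the mean agreement over a
random sample of fields (default 30 per repetition, from fields with ≥ 6
years), each with one uniformly drawn split. A Nelder–Mead simplex
(standard 1 / 2 / 0.5 / 0.5 coefficients, convergence at objective spread
< 1e-4 or 200 iterations) maximizes the objective inside box bounds
(mean ∈ [−1, 1]; SD threshold ∈ [0.05, 3]; width ∈ [0.05, 0.49]), and the
whole search is repeated (default 600 times) to produce a distribution of
optima summarized by the componentwise median.

Plain pixelwise agreement has a known degenerate maximum: thresholds that
collapse the map to a single class (e.g. an SD threshold near 0 makes both
split-maps all-unstable) agree almost perfectly while carrying no
information. The simplex, started from the published thresholds, tends to
stall on a non-degenerate local ridge and miss this global optimum, so each
repetition additionally screens a 5×5 lattice of starts over the search box
and refines the best with a second simplex run; the reported optimum per
repetition is the best point ever evaluated, hence never worse than the
start. Because the objective is flat across a degenerate optimum, lattice
ties are broken toward the published prior. On synthetic data the calibrated
optimum therefore lands at the degenerate corner — the honest answer for
this objective, and the reason a practical calibration needs either a
complexity penalty or an information-bearing term alongside raw agreement.
Users who want mid-range thresholds should treat the published defaults as
the operating point and the calibration as a repeatability audit.

## Split-voting uncertainty

For a field with ≥ 6 years, every enumerated split yields a consensus map:
a pixel keeps its class where the two sides agree and is **uncertain** where
they disagree. Voting across all splits (exhaustive; capped at 500 seeded
random splits for very long records) assigns each pixel its modal category;
ties resolve by the fixed priority uncertain > unstable > low-and-stable >
high-and-stable, surfacing ambiguity rather than hiding it. Vote counts sum
to the number of splits per pixel, and a stack of identical year maps
produces zero uncertain pixels.

## Skewness and the mean–SD correlation

Within-map skewness is the Fisher–Pearson moment coefficient
g1 = m3 / m2^{3/2} with population moments (divide by n). Yield maps are
typically left-skewed. When per-pixel yearly values are drawn from a skewed
distribution, the per-pixel mean and SD across years are correlated with the
sign of the skew: under left skew, low-mean pixels are the ones that
occasionally crash, so they also have larger SDs. `simulate_skew_matrix`
demonstrates this by drawing a pixels × years matrix of i.i.d. skew-normal
variates (location 0, scale 1, shape α; negative α → left skew) and
reporting the Pearson correlation between row means and row sample SDs. At
5000 pixels × 10 years the sign of r tracks the sign of α essentially
always, and |r| < 0.05 when α = 0.

## Point-to-raster preprocessing

Monitor points are cleaned by (1) dropping yields outside
[0.1 × median, 3 × median] of the input set and (2) collapsing exact
coordinate duplicates to their mean yield (the mean is unbiased for monitor
re-reads). Interpolation is ordinary kriging with a spherical semivariogram,
a fixed 20 m search radius and a minimum of 12 neighbors per cell (fewer →
nodata) onto a 2 m grid, followed by block-mean aggregation to 30 m
(factor 15; an output cell is nodata when under half its block is valid —
this keeps edge cells without propagating mostly-interpolated noise).
Ordinary kriging's Lagrange constraint makes weights sum to 1, so constant
fields are reproduced exactly and predictions are translation-equivariant;
with zero nugget the predictor interpolates data points exactly. Variogram
parameters are fitted from the data by default (empirical semivariogram in
15 lags to 200 m, least squares weighted by pair counts, non-negative nugget
and partial sill), and can be supplied explicitly. Real monitor cleaning
also involves pass-delay, swath-overlap and moisture corrections; those are
out of scope here.

Raster I/O uses the ESRI ASCII grid text format, which round-trips values,
mask and grid geometry losslessly; class rasters use fixed integer codes
(0 nodata, 1 low-and-stable, 2 high-and-stable, 3 unstable, 4 uncertain) so
outputs of different runs compare bit-exactly.

## Synthetic fields

`synthfield` generates multi-year stacks with known truth. A Gaussian
white-noise surface is smoothed (Gaussian kernel, default correlation length
4 pixels) and thresholded at the quantiles of the requested zone fractions
(default 0.35 / 0.35 / 0.30 low / high / unstable), giving contiguous zones.
Year t's latent map is `base(zone) + sensitivity(zone) · w_t + ε` with
`w_t ~ N(0, weather_sd²)` (default weather_sd 1), base levels −0.8 / +0.8 /
0 in normalized units, sensitivities 0.1 (stable) vs 1.2 (unstable), and
skew-normal pixel noise (shape −4, scale 0.4, centered to mean zero) that
reproduces the left skew of real maps. Latent values are mapped onto
crop-typical Mg/ha scales with a round-robin maize/soybean/wheat rotation;
the default single-field grid is 40 × 40 pixels at 30 m, and the dataset
generator jitters sizes (30–60 pixels a side), year counts (2–12) and
per-field weather SD (±50%).

What the generator does *not* emulate: spatial weather gradients within a
field, crop-specific zone geometry, harvester artifacts, and temporal
autocorrelation of weather. Passing tests therefore demonstrate the
algorithms' internal correctness and their behavior under the stated
generative assumptions, not performance on real monitor archives.

One measured property worth stating: with these defaults the two-way
classifier recovers the planted zones at ~0.9 balanced accuracy, while the
SD algorithm flags only about half of the planted-unstable pixels. Per-map
z-scoring inflates a map's SD in extreme-weather years, which compresses the
unstable zone's temporal SD toward ~0.7, just under the 0.75 default
threshold; the SD algorithm still discriminates strongly (it flags
planted-unstable pixels at many times the rate of stable ones), but its
recall under these conditions is threshold-limited. This interaction is a
property of the method, not of the implementation.

## Problem sizes

Tests and the acceptance script run on deliberately small instances chosen
as representative: 20×20×6 stacks for oracle equivalence (50 replicates),
40×40-pixel fields for zone recovery (10 seeds), 40 synthetic fields with
25 calibration repetitions of 10 fields each, and 5000×10 matrices for the
skew simulation (20 seeds per shape). These sizes put every Monte-Carlo
estimate well inside the tolerances asserted.
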