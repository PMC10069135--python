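# Methods

This note documents the models behind `canoheight`: what the synthetic trial
generator simulates and deliberately omits, the estimators the analysis
stages use, the numerical conventions, and the design choices made where the
design was genuinely open.

## The forward model

### Trial design

A balanced factorial of g genotypes x e nitrogen treatments x r replicates
(defaults 120 x 2 x 2 = 480 plots) on a regular grid of 1 m x 1 m plots with
0.5 m alleys (pitch 1.5 m), observed at four growth stages (jointing,
heading, flowering, maturity). Plot positions are randomized by the seed, as
in a randomized field design. Plot bounding boxes are half-open
`[x0, x0+side) x [y0, y0+side)` so every point belongs to at most one plot.

### True heights

Per plot and stage, the true maximum canopy height is

    h_ijk(s) = mu_s + G_i + E_j + GE_ij + eps_ijk(s)

with G, E, GE, eps independent zero-mean Gaussians of variances
`var_G, var_E, var_GE, var_eps` (defaults 0.010, 0.002, 0.002, 0.004 m²).
G, E and GE are drawn once per trial — a tall genotype stays tall across
stages and replicates — while the residual is redrawn per plot-stage.
Effects are *not* re-centered after drawing; finite-sample deviation from a
zero mean is part of a plain random-effects model. Default stage means are
0.55 / 0.72 / 0.85 / 0.82 m, giving a realistic wheat range of roughly
0.3–1.2 m in which a minority of plots exceeds the gantry scanner's ceiling.

### Canopy surface

Each plot-stage gets a crown-bump surface: paraboloid caps of random radius
(mean 0.12 x plot side) and peak height are superposed by maximum on a 1 cm
raster until the covered area reaches `cover_fraction` (default 0.85), then
the whole field is rescaled so its maximum equals the true height *exactly*.
`unevenness` (default 0.35) controls both the droop of each cap and the
spread of peak heights; 0 yields a flat slab. This is the cheapest surface
that produces the two phenomena the analysis cares about — an open, uneven
canopy top (the driver of ruler-sampling error) and a within-canopy height
distribution for quantile metrics. It is not botany: no rows, tillers,
leaves or temporal coherence of individual plants.

### Sensor observation models

Returns are sampled per plot as Poisson(density x area), uniform in x/y.
A return either lies on the local surface or, with probability
`penetration`, uniformly between ground and surface (canopy interior);
Gaussian vertical noise is added; returns outside the sensor's normalized
detection window are discarded. Defaults:

| source | density (pts/m²) | noise sd (m) | penetration | window (m) | other |
|--------|-----------------|--------------|-------------|------------|-------|
| TLS    | 1858            | 0.003        | 0.7         | —          | |
| BLS    | 800             | 0.012        | 0.7         | —          | |
| GLS    | 1394            | 0.002        | 0.6         | [0.28, 0.82] | ground-free, pre-normalized |
| DAP    | 800             | 0.010        | 0.0         | —          | 30 % tip loss near the canopy maximum |

Densities are the published per-source survey densities scaled by
`density_scale` (default 2e-3; 1.0 restores the full ~9.3e5 pts/m² TLS
cloud) with an 800 pts/m² floor so the sparse sources keep a usable per-plot
sample. Noise values are plot-level *precision* (post-registration vertical
dispersion), not datasheet absolute range accuracy; they were fixed, before
the acceptance experiments were written, so that per-plot sensor error is
clearly below ruler error — the regime the multi-sensor comparison design
presumes (see "What passing tests show", below). DAP is surface-only with
tip loss, encoding photogrammetry's loss of thin leaf tips; the gantry
scanner emits heights already normalized and ground-filtered (lowest 0.28 m
removed), so with its 1.1 m scan range the tallest reportable canopy is
1.1 − 0.28 = 0.82 m. Sensors that keep ground returns also see the alleys,
at 25 % of canopy density (partial occlusion); those returns feed the ground
filter downstream.

### Field measurement and LAI

FM is the mean of `k_locations` (default 3) readings; each reading is the
maximum of the true surface inside a random 0.3 m window plus Gaussian
observer error (`observer_sd`, default 0.02 m — no published within-plot
value exists, so this is a package choice, config-exposed). Window maxima
can only under-read the plot maximum, so FM is slightly low-biased on uneven
canopies — deliberately so, since that is the documented failure mode of
ruler measurement. LAI is a linear proxy
`alpha * cover_fraction * height + noise` (alpha = 5, noise sd 0.3,
truncated at 0): it is only needed as a stratification covariate positively
correlated with canopy size, not as a gap-fraction model.

## Preprocessing

* **Denoising**: statistical outlier removal — drop points whose mean
  distance to k = 10 nearest neighbors exceeds the global mean by more than
  3 sd. Deterministic, replacing interactive manual cleanup.
* **Ground filtering**: the minimum z of each 0.5 m cell seeds the ground;
  points within 0.05 m of their cell's seed are ground; empty cells are
  filled by iterative 8-neighbor averaging. This is a simplified,
  reproducible stand-in for progressive-TIN densification with manual
  revision; it is adequate for near-flat trial fields and is *not* claimed
  to match any proprietary tool (whose thresholds are unpublished). The
  grid-minimum seed biases each cell to its low edge by at most
  cell_size x slope, which the tilted-plane test bounds.
* **Normalization**: `z_above_ground = z - elevation(nearest cell)`, small
  negatives clamped to 0. The sign is chosen so canopy heights are positive.
* **GLS path**: gantry clouds arrive normalized and ground-free; the 0.28 m
  threshold is re-asserted and ground filtering is skipped. A config switch
  (`prep.assume_flat_ground`) likewise skips ground estimation when the
  terrain is known flat, which the exactness tests use.

## Height metrics

Hmax and H80…H99 (1 % steps) per plot, using the linear-interpolation
percentile estimator (the rule under which the p-quantile of 0…100 over 101
points is p); the estimator is config-exposed because no universal
convention exists in point-cloud tooling. Metric selection per source
maximizes Pearson r against FM with ties broken by lower RMSE, then lower
quantile (Hmax last); statistics are rounded to 12 decimals before ranking
so ties-by-construction are not split by summation noise. The full score
table is always written for audit.

## Accuracy statistics

Pearson's product-moment r is primary. The √(1 − SSE/SST) form of the
correlation (an R of the fitted line, which equals |r| under OLS) is emitted
as a secondary `r_fit` column because both conventions appear in the
agreement literature. Bias is `mean(prediction − reference)` so that
underestimation is negative — the convention under which a range-limited
scanner shows negative bias. Group bins are half-open with the final bin
closed; subgroup "Mean" rows average the subgroup statistics unweighted
(groups have unequal n). Any comparison involving GLS keeps only plots whose
*measured* height is strictly below the 0.82 m ceiling.

## Heritability

Effects come from marginal means of the balanced table; the closed-form
components sum squared effects (σ²_G = ΣG²ᵢ/(g−1), etc.) and σ²_ε is the
within-cell replicate mean square. These effect-sum forms estimate the
variance of *genotype means*, which exceeds the generating genotypic
variance by the averaged interaction and residual shares; an EMS-corrected
mode (`h2.ems_correction`) subtracts the expected-mean-square contributions
and recovers the generating components (negative estimates are clamped at
zero and flagged). The parameter-recovery experiment therefore reports the
EMS-corrected estimate as its headline (target = the generating value) with
the effect-sum estimate alongside. H² = σ²_G/(σ²_G + σ²_GE/e + σ²_ε/(re)),
undefined (never silently 0) when a required component is undefined, e.g.
r = 1.

Grouped H² applies a variety-completeness rule: within a group, a variety
enters only when *all* e·r of its plots satisfy the group condition at a
given stage, keeping the design balanced; groups with fewer than 2 complete
varieties at every stage are undefined ("–"). Because stage means dominate
raw height variance, stages are decomposed separately and a group's H² is
the unweighted mean over stages with data — pooling stages would conflate
phenology with genotype. The 0.82 m restriction applies only to the GLS
column by default (`h2.restrict_all_sources` extends it to every source).

## Error attribution

Δ = |H_sensor − H_FM|/H_FM per plot and sensor; S_a = {Δ ≥ τ} with τ = 0.2
(the threshold is inclusive — where prose and formula conventions for
"greater than 20 %" differ, the formula's ≥ wins). Error_FM is the four-way
intersection; Error_a = S_a \ Error_FM. Signed residuals are retained in the
output for direction diagnosis, but only |Δ| drives membership. Plots
missing any of the four sensors, with non-positive FM, or above the GLS
ceiling are excluded from the universe (all four comparisons must exist for
the intersection to be meaningful) and logged. The relaxed m-of-4 variant
(default m = 3) formalizes the "more than two suspects" idea; m = 4
coincides with the strict rule. It is an interpretation, labeled as such.

## Numerical conventions

* One root seed drives everything through keyed child streams
  (SeedSequence over (seed, labels)), so runs are bit-reproducible and
  independent of iteration order.
* The central table `heights/plot_heights.csv` is written with `%.17g` and
  re-read with round-trip float parsing, so a resumed run reproduces the
  downstream CSVs byte for byte.
* Quantiles of empty clouds, correlations of constant vectors and
  percentages with zero reference mean are NaN, propagated and logged, never
  silently zero.

## What passing tests do and do not show

The generator realizes the *structure* of a multi-sensor trial: shared true
canopies observed by error-prone instruments whose error hierarchy (ruler >
photogrammetry ≈ sparse LiDAR > dense LiDAR) is imposed by the defaults
chosen above. Under that structure the pipeline reproduces the qualitative
signatures reported for real trials — cross-sensor correlations exceed
sensor-vs-FM correlations, range restriction shrinks within-subgroup
correlations, GLS saturates with negative bias above its ceiling, and
3D-sensing heritability is at least the ruler's. Passing these tests shows
the *analysis chain* is correct and that those signatures follow from the
stated error structure; it does not validate the sensor models against real
instruments, and numerical agreement with any particular field campaign's
tables is out of reach of a synthetic trial. Known further limitations: no
occlusion ray-tracing, no SLAM drift or registration error, no lodging or
senescence, LAI is a linear proxy, and quantile-choice sensitivity of
photogrammetry (which in reality stems from per-plant geometry) is not
reproduced by the crown-bump surface.

## Problem sizes used by the shipped experiments

The heritability recovery runs 50 seeds of a single-stage, TLS-only trial at
500 pts/m² with the denoiser off (this generator produces no gross outliers)
and a 2 cm raster — settings at which the recovered components are
indistinguishable from the full-resolution ones at a fraction of the cost.
The headline experiment runs the full default 480-plot, four-stage,
four-sensor trial. The saturation experiment uses one 0.9 m-mean stage of 60
genotypes observed by TLS and GLS; the injection experiment plants ±50 %
errors in 10 eligible plots of a 40-genotype trial.
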