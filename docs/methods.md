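# Methods

## The measure

Functional connectivity density (FCD) treats the gray-matter voxels of a
resting-state BOLD acquisition as nodes of a graph. Two voxels are
functionally connected when the Pearson correlation of their full
(preprocessed) time courses exceeds a threshold r0 = 0.25, counting
positive correlations only. The FCD of a voxel is its degree k in this
graph, partitioned by the anatomical (world-mm, center-to-center)
distance of each neighbour:

* **sFCD** — edges to voxels within a 12 mm-radius sphere (local
  connectivity),
* **lFCD** — edges to voxels beyond 12 mm (remote connectivity),

so `k_short + k_long` is always the unpartitioned degree (a tested
invariant). Ties at exactly 12 mm are short-range. The distance-ball
definition of the short range is used (every suprathreshold neighbour
inside the sphere counts), not the growing-connected-cluster variant
found elsewhere in the FCD literature. Per subject we emit three products
per range: raw integer counts k; Z-standardized counts (population-SD
convention over the mask) smoothed with a 6 mm-FWHM Gaussian, which feed
the voxel-wise group model; and k/k0 maps (k divided by the whole-mask
mean degree) from the raw counts, which feed ROI extraction, Cohen's d
and the clinical correlations. Zero-variance voxels have undefined
correlations; they contribute no edges, are logged, and stay in the mask
for Z-scoring.

The pairwise computation is blocked (configurable block size) so memory
stays bounded at (block x mask) correlations; counts are integer-exact
and independent of blocking, verified against an exhaustive double-loop
oracle.

## Temporal preprocessing

Fixed order, applied per subject: (1) discard the first 10 volumes
(magnetic-saturation transients; 240 -> 230 at defaults); (2) per-voxel
linear detrend, then zero-phase band-pass to 0.01–0.1 Hz; (3) nuisance
regression of the 24-parameter Friston motion model (6 rigid-body
parameters, their one-volume lags, and both squared; the lagged row at
t = 0 is zero-padded, a `repeat` option exists). The filter is a
frequency-domain mask — rectangular pass band with raised-cosine
transitions of 0.004 Hz total width centred on each edge, DC weight zero
— chosen for exactly reproducible spectral behaviour; its response is
closed-form testable (unit gain at 0.05 Hz, >90 % attenuation at
0.2 Hz). Nuisance regressors are passed through the same band-pass before
regression so the regression cannot reintroduce out-of-band variance;
degenerate (constant/collinear) regressor columns are dropped with a
logged warning. Tissue (WM/CSF) signals are accepted as optional extra
regressors and, when supplied, are filtered the same way as the data.

Head motion is summarized as Jenkinson frame-wise displacement: for each
adjacent volume pair, with the relative rigid-body transform written as
`I + [A b]`, `FD = sqrt((1/5) R^2 trace(A'A) + b'b)` with R = 80 mm, using
the full rotation matrices (small-angle closed form `FD ≈ R θ sqrt(2/5)`
is a test, not the implementation). The exclusion screen fails a subject
whose displacement relative to the first retained volume reaches 2 mm
translation or 2° rotation on any axis (strict inequality). Note the
offset-invariance of FD is exact only for rotation-free traces; with
rotations the relative transform acquires an O(θ·offset) term.

## Group inference

Voxel-wise OLS on the smoothed Z maps with design
`[intercept, group, age, gender, mean FD]` (covariates mean-centered,
gender coded F = 1). The group-contrast t is thresholded two-tailed at
voxel p < .001; suprathreshold voxels are clustered with a metric
connectivity rule — neighbours iff centers within rmm = 5 mm, which on a
3 mm grid connects face and edge but not corner neighbours — with
positive and negative clusters labeled separately.

Cluster extent is corrected by Monte-Carlo simulation in the style of
AlphaSim/3dClustSim: each of (default) 1000 iterations fills the grid
with unit Gaussian noise, smooths it to the nominal FWHM,
re-standardizes within the mask, thresholds two-tailed at the voxel p,
labels clusters with the same rmm rule and records the pooled maximum
cluster size; the extent threshold is the smallest k whose null
exceedance probability is ≤ α = 0.05.

**Smoothness input.** The conventional choice — feed the applied
smoothing FWHM (6 mm) to the null simulation — is the default. It is
mildly anticonservative here because FCD count maps carry intrinsic
spatial correlation (neighbouring voxels share most of their
correlation neighbourhoods), so the t maps are smoother than 6 mm; on
null cohorts we measured a family-wise rate of roughly 0.07–0.10. The
`smoothness="estimate"` option instead estimates the Gaussian-equivalent
FWHM from the GLM residuals (per-axis lag-1 autocorrelation,
`FWHM = 1.1774 d / sqrt(-ln r1)`, geometric mean over axes; typically
~10 mm on the synthetic maps) and restores the nominal rate — the
calibration experiments use it.

Effect sizes are Cohen's d (pooled-SD, n1+n2−2 denominator) on
per-subject cluster means of the k/k0 maps. Demographic comparisons use
the pooled-variance Student t from summary statistics and a Pearson
chi-square without continuity correction for gender. Clinical analyses
are partial correlations (Pearson on OLS residuals after removing age
and gender plus an intercept; p from t = ρ√(df/(1−ρ²)), df = n−2−k)
within patients, corrected by standard capped Benjamini–Hochberg over
the full region × metric grid.

## Seed-based iFC

Seeds default to the surviving negative lFCD clusters. Per subject: the
seed's unweighted mean time course is correlated with every mask voxel
and Fisher r-to-z transformed (|r| clamped at 1 − 1e−7 before atanh;
clamps are logged). Within-group connectivity masks come from one-sample
t tests with BH-FDR over mask voxels, keeping voxels with adjusted
p < .001 **and** positive mean z ("p < .001, FDR-corrected" is read as
adjusted-p < .001). Between-group comparison reuses the identical GLM +
extent-correction code path as the FCD analysis (enforced by a test).

## The synthetic cohort

The generator emulates a two-group case-control study: 27 patients with
chronic insomnia and 27 good-sleeper controls, 240 volumes at TR = 2 s,
3 mm isotropic voxels, gray matter modeled as the ellipsoid inscribed in
the grid. Each subject's series sums:

* **Network signals** — one unit-variance signal per synthetic network,
  built from ~40 random-phase sinusoids at rFFT-bin frequencies inside
  0.01–0.1 Hz (exactly band-limited; >99 % of power in band is a tested
  property). Five spherical ROIs (radius 2 voxels) form two networks;
  same-network ROI centers are separated by more than 12 mm so network
  edges are purely long-range. ROI voxels mix their network signal at
  amplitude 0.9 (both groups).
* **Local field** — spatially Gaussian-smoothed (9 mm FWHM), temporally
  band-limited, per-voxel standardized noise at unit gain: its
  distance-decaying correlation generates short-range edges.
* **AR(1) noise** (lag-1 ρ = 0.3, unit marginal variance, scaled by
  1/snr), a linear drift (0.02 units/volume) and a 100-unit baseline.

Planted patient effects, scaled by a per-subject severity
s ~ N(1, 0.2²) clipped to [0.4, 1.6] (controls: 0): network-0 coupling
multiplied by (1 − 0.6 s) — the long-range deficit; local gain times
(1 − 0.45 s) inside one sphere and (1 + 0.5 s) inside another — the
short-range decrease/increase. These magnitudes are free parameters of
the simulation (no empirical ground truth exists for them); they were
fixed once such that the planted contrasts are detectable at n = 27 per
group, and the defaults are the study conditions of every recovery
experiment. A known side effect: reducing a voxel's network coupling
slightly raises its relative local-signal share, producing a small
secondary short-range increase near the decoupled ROIs; recovery
metrics therefore use Dice overlap of the surviving-cluster union per
sign, which tolerates such satellites.

Motion traces are 6-parameter Gaussian random walks (steps 0.05 mm /
5e−4 rad, per-subject severity ~N(1, 0.4²)) giving mean FD near 0.1 mm;
they are recorded and regressed but do not corrupt the images (the data
are generated "aligned", matching the scope: spatial preprocessing of
real anatomy is out of scope). Clinical scores are linear in severity
plus Gaussian noise, clipped to instrument ranges (e.g. PSQI
0.9 + 12.4 s ± 1.0 on [0, 21], giving ≈13.3 ± 2.7 for patients vs
≈0.9 ± 1.0 for controls); illness duration exists for patients only.
Ages, genders (17 F / 10 M per group) and severities come from a
cohort-level stream; every subject's imaging data comes from an
independent substream keyed `[seed, subject_index]`, so cohorts are
bitwise reproducible and subjects individually regenerable.

What the simulation does **not** model: scanner artifacts, slice-timing
offsets, susceptibility distortion, anatomical variability, spatially
varying hemodynamics, motion-correlated signal changes, or negative
correlations between regions. Passing recovery tests therefore shows the
statistical machinery detects the planted covariance structure at
realistic n, T and effect sizes — not that the pipeline is robust to the
artifacts of real acquisitions.

## Problem sizes and numerical choices

Validation experiments are sized for a single CPU: planted-effect
recovery runs the study conditions (27 + 27 subjects, 240 volumes) on a
16³ grid (~1650 mask voxels); null-FWE calibration uses 200 cohorts at
12³ / 120 volumes / 10 + 10 with the extent threshold cached per 0.5 mm
smoothness bin (500 Monte-Carlo iterations); the analysis scripts use
the 16³ profile with 1000 iterations. The short-T null runs have fewer
effective temporal degrees of freedom after band-passing, which raises
chance edge counts symmetrically in both groups — the null FWE is
unaffected, which is why the reduction is legitimate there but not for
recovery, which keeps T = 240.

Other numerics: correlations are computed on double-precision
standardized series; cluster components use a KD-tree union-find
(enumeration-order invariant); the degenerate-voxel rule (zero variance
-> no edges), the two-point Z-score convention, the smoothing boundary
renormalization (smooth the zero-embedded map, divide by the smoothed
mask indicator), and `voxel_p >= 1` (everything survives, extent =
mask + 1, nothing passes) are all covered by unit tests. Determinism:
every stage draws from `numpy` Generators seeded from the run seed; two
runs with the same config and seed produce byte-identical reports.

## Known limitations

* The Monte-Carlo null assumes stationary Gaussian smoothness; with the
  "applied" default it understates cluster sizes for intrinsically
  smooth maps (see above) — use `smoothness="estimate"` when calibration
  matters more than convention.
* `run_pipeline` drives synthetic cohorts end-to-end; real datasets are
  processed per stage through the CLI (the BIDS layer is out of scope).
* The short-range definition is the 12 mm distance ball; the
  connected-cluster sFCD variant is deliberately not implemented.
* Global FCD (gFCD), negative-edge networks, and dynamic (sliding
  window) connectivity are out of scope.
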