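# Methods

This note records the models behind `sgnano`, the defaults and why they
hold, the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Imaging model and units

Coordinates are continuous nanometres with the origin at the field corner,
x right and y down. Pixels are half-open: a localization at the center of
camera pixel (i, j) has position ((i+0.5)·a, (j+0.5)·a) nm for pixel size
a (160 nm camera, 20 nm super-resolution grid by default). Times are in
seconds; the default frame interval is 0.018 s (55 Hz acquisition), with a
0.036 s (27.5 Hz) preset for the two-channel tracking + localization
variant. Diffusion coefficients are in μm²/s.

## Motion model

Tracks are a labelled three-component mixture:

- **stationary** — a fixed point;
- **confined** — Brownian motion with coefficient `D_conf` reflected per
  axis at ±`R_conf` around the start point;
- **diffusive** — free Brownian motion, per-axis step variance `2·D·Δt`.

Localization noise is added post hoc as i.i.d. Gaussian with σ = 25 nm,
matching a ~50 nm (≈2σ) spatial resolution.

The confined domain is the square `[−R, R]²` rather than a disk. The
classifier's confined model, `MSD(t) = (4R²/3)(1−e^{−t/τ})`, saturates at
`4R²/3`; per-axis reflection on an interval of half-width R has exactly
that stationary plateau (2 axes × 2·(2R)²/12), whereas reflection in a
disk of radius R plateaus at R², which would build a −13% bias into every
R_conf recovery. Reflection is implemented exactly by triangle-wave
folding of the unconstrained path (reflection principle), so no time-step
subdivision is needed. Note the single-exponential confined model is
itself an approximation to the exact reflected-diffusion MSD (a series of
exponential modes with leading time constant `4R²/π²D`); fits to exact
simulated MSDs therefore recover τ a little above `R²/3D` while R_conf
stays accurate.

## Mode classification

Per track, the time-averaged MSD (lags 1..N−1 over the first N = 40
points) is classified in two steps:

1. `D_init` = slope/4 of a free-intercept linear regression over lags in
   18–180 ms. The free intercept absorbs the localization-noise offset
   4σ² ≈ 0.0025 μm², so the slope estimates D without noise bias.
   `D_init < D_threshold = resolution²/(4·9·Δt)` → stationary. The
   threshold formula is applied to both time bases (0.00386 μm²/s at
   18 ms, 0.00193 at 36 ms).
2. Mobile tracks: Levenberg–Marquardt least squares of the confined model
   over lags in 18–396 ms, initial guesses `R² = ¾·max(MSD)`,
   `τ = window/3`, bounds R ∈ (0, 2 μm], τ ∈ (0, 10 s]. `τ < half the
   fit window (198 ms)` → confined with `D_conf = R²/(3τ)`; otherwise
   diffusive with `D_diff` = slope/4 of a free-intercept linear fit over
   the same lags. A non-converged confined fit falls back to the
   diffusive branch with its residual norm flagged.

**Operating characteristics.** At the study conditions (exactly 40-frame
tracks), the classifier recovers stationary tracks essentially perfectly
and confined tracks (R = 100 nm, D_conf = 0.05 μm²/s) at ~88–90%. Free
Brownian tracks, however, are relabelled confined in roughly a quarter of
realizations: the time-averaged MSD of a 40-point Brownian track flattens
by chance that often, and those flattened curves genuinely fit the
confined model with τ < 198 ms (the spurious fits are global least-squares
optima; inverse-variance weighting, offset terms and multi-start do not
remove them). Two consequences worth knowing:

- recovered mixture fractions are biased by roughly +6 points into
  confined and −7 points out of diffusive at a 40/25/35 truth;
- the mean `D_diff` *conditioned on the diffusive label* is inflated
  ~20–25% by selection (the tracks lost to the confined label are exactly
  the low-slope ones). The unconditioned mean of the linear-fit D over all
  free tracks is unbiased (±5% at n = 500), which is why parameter
  recovery is reported unconditioned (`modes.d_from_linear_fit`).

Tracks longer than the 40-point window are truncated to their first 40
points rather than windowed or split — the simplest reading consistent
with a fixed analysis window. The factor 9 in the `D_threshold`
denominator is part of the stated formula and is reproduced as such.

## Blinking model and segmentation

Emitters are two-state continuous-time renewal processes with exponential
on/off dwells, started dark; each on period may end in permanent
photobleaching with a configurable probability. Discretization marks a
frame "on" when the emitter was bright for ≥ 50% of the frame interval —
an unbiased duty-cycle rule (mean measured on-duration equals the mean
dwell up to the loss of sub-half-frame events, ~1%). Defaults: mean on
1.0 s, 268 expected photons per on frame, mean off 10 s (duty cycle ≈ 9%,
a typical sparse-blinking regime for localization microscopy; the off time
is a free parameter of the generator, not a measured constant).

Segmentation thresholds each trace at `median + 5·(1.4826·MAD)`. Median
and MAD are per-trace (robust to high duty cycles); a trace ending in the
on state has its last event flagged right-censored, and censored events
are excluded from duration means. Photon counts are background-subtracted
by the trace median and converted with a configurable gain (default
1 count = 1 photon; camera gain is setup-specific).

Two systematics are inherent to measuring exponential dwells from a
finite, discretized recording and are accounted for in the validation
rather than hidden: half-a-frame discretization jitter, and the −θ²/T
length-bias of gaps that must complete inside a recording of length T.

## Localization

Detection: difference-of-Gaussians band-pass (σ and 2.5σ of the PSF),
local maxima above `median + snr·MAD` of the filtered frame, minimum
separation ~2 PSF σ. Fitting: integrated symmetric 2D Gaussian (erf over
pixel edges) plus constant offset in an 11×11 window, least squares with
residuals weighted by 1/√max(counts, 1) — the Gaussian approximation to
Poisson likelihood; unweighted fitting lets the bright central pixel
dominate and collapses σ onto a single pixel in a few percent of spots.
Acceptance gates: fitted σ within [0.5, 2]× the PSF guess (rejects
overlapping doublets, which fit too wide), center within the window,
positive photons; duplicates within 1 px keep the brightest. Localization
precision uses the Thompson photon-statistics approximation and feeds only
the optional blurred rendering. Measured on synthetic movies at 268
photons/frame over 10 photons/px background: recall and precision > 95%,
median error ~18 nm.

## Tracking

Greedy mutual-nearest-neighbour linking: all candidate pairs within the
400 nm gate between consecutive frames are linked in ascending distance
order, each localization used once; no gap closing, merging or splitting.
Input is put in canonical (frame, x, y) order first, so the partition is
independent of row order; equidistant ties resolve by canonical index.
"Over 720 ms (40 points)" is read as n_points·Δt ≥ 720 ms with an
inclusive boundary (each point represents one frame of record), so a
40-point track passes and a 39-point track does not.

## Scene generation and core analysis

SG footprints are disks (0.3–2 μm² in the stressed-scene preset). Core
counts per SG are Poisson(density × area); centers are uniform within the
disk under a hard-core exclusion of one core diameter (sequential
inhibition). The exclusion reflects that two dense clusters overlapping
within a core diameter are one physical core — without it, ~19% of
Poisson-placed centers at 10/μm² sit closer than any density-based method
can resolve and the seeded "core density" stops being a meaningful
recovery target; at these packings (~6%) the exclusion almost never
discards a draw. Each core contributes Poisson(400) localizations from an
isotropic Gaussian with σ = core diameter/4 (20 nm for the default 80 nm
core) — consistent with ≥10 molecules per core, each blinking into tens
of localizations — over a uniform shell background (500/μm² default).

SG segmentation: Gaussian smoothing (1 SR pixel), binarization of occupied
pixels at Otsu's threshold (the half-height edge criterion keeps the
segmented area of a smooth-edged region unbiased; a fixed density quantile
is available as an option), 8-connected labelling, area ≥ 0.3 μm².
Cores: standard Euclidean DBSCAN (ε 25 nm; minPts 100 fixed / 40 live);
cluster diameter is the equivalent-circle diameter `2√(A_hull/π)` of the
member convex hull (the definition is a package choice; Feret or radius of
gyration would differ by O(10%)). Density is the zero-intercept
least-squares slope `Σaᵢcᵢ/Σaᵢ²` of count on area; a single SG reports
count/area with a flag. Measured end to end, DBSCAN recovers 97–98% of
seeded (resolvable) cores and the density slope lands within ~5% of the
seeded 11.7/μm²; the recovered median core diameter (~96 nm at these
defaults) matches the ~100 nm scale of real cores.

## RDF and flux

Distances from track points to their nearest core centroid are histogrammed
in 10 nm bins, divided by each annulus area (the standard RDF definition;
the normalization below removes global density), then divided by the
profile's own value in the bin containing 500 nm — so that bin is exactly
1 by construction and an empty normalization bin is an error rather than a
silent NaN. The relative RDF divides by the average profile of n_random
(default 10) uniform draws over the SG region with the observed point
count; bins with zero baseline mass are flagged undefined. Sampling note:
with 10 nm bins and ~10⁵ points, inner bins hold tens of counts, so
per-bin noise of several percent to tens of percent is expected — flatness
claims are made through per-bin consistency, a pooled mean and a joint χ²
rather than per-bin equality.

Flux classification tests the first and last track positions against the
SG regions (pixel-mask ownership, boundary pixels inside): in→out is
efflux, out→in influx; counts and ratios are crossed with the mode labels.
A track whose interior touches two SGs is flagged; its category still uses
its endpoints.

## Pipeline and reproducibility

All stage defaults equal the study parameterization; the CLI reproduces it
with zero flags. One root seed feeds every stage through named substreams
(CRC32-keyed `SeedSequence` spawns), so adding or reordering stages never
perturbs the others; identical configs and seed give bit-identical
bundles. Every table carries the SHA-256 (truncated) hash of its config as
a comment line, and `run-all` writes a JSON provenance record with
versions, seed and the hash. In the demo pipeline, molecule appearances
are staggered over the movie, emulating the sparse per-frame visibility
that blinking-limited imaging provides; linking quality degrades
gracefully (and realistically) as concurrent density rises.

## What the generator does not emulate

No drift or drift correction, no sub-frame motion blur (positions are
sampled instantaneously at frame times), no astigmatism or 3D, no
background structure (cellular autofluorescence is flat), no photophysics
beyond the two-state chain plus bleaching, and cores are static isotropic
Gaussians rather than evolving structures. Passing recovery tests
therefore demonstrates the correctness of the analysis chain under the
stated noise model, not robustness to every artifact of live-cell data.

## Problem sizes

Validation runs use 1000-track mixtures, 500-track single-mode recoveries,
30-SG scenes (~2×10⁵ localizations) and 10⁴ blinking emitters × 10⁴
frames (processed in batches); these sizes put simulation standard errors
well inside every stated tolerance while keeping a full run in the tens of
seconds on one CPU.
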