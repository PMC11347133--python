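# sgnano

Nanoscale analysis of single mRNA molecules in stress granules (SGs):
single-particle tracking, super-resolution localization microscopy, and the
statistics that connect them.

Stress granules are membraneless cytoplasmic condensates that form under
cellular stress and sequester mRNA. Imaged at the single-molecule level,
mRNAs inside SGs are a mixture of populations — most anchored, some locally
confined, some freely diffusing — and localization microscopy shows they
organize into dense ~100 nm **cores** surrounded by a dilute shell. `sgnano`
implements the full quantitative pipeline for this kind of experiment, plus
a ground-truth synthetic-data generator that emulates the imaging
conditions, so every stage is testable without microscope data.

## What it computes

**Blinking statistics** (`sgnano.blink`). Intensity traces of single
fluorophores are segmented into on/off states by thresholding at
`baseline + 5·σ`, with baseline and noise estimated robustly
(median / 1.4826·MAD). Outputs: number of on events, on/off durations, and
photons per on frame — the four numbers that decide whether a dye can
support blinking-based tracking.

**Localization** (`sgnano.locfit`). Difference-of-Gaussians detection and
Poisson-weighted least-squares fitting of an integrated 2D Gaussian in an
11×11 px window gives sub-pixel positions, photon counts and PSF widths.
Super-resolution images are localization histograms, including the
live-imaging sliding-window reconstruction (5000-frame windows advanced
every 1000 frames).

**Tracking** (`sgnano.tracking`). Frame-to-frame nearest-neighbour linking
with a hard 400 nm gate, no gap closing; tracks shorter than 40 points /
720 ms are discarded.

**Diffusion-mode classification** (`sgnano.modes`). Per track, the
time-averaged MSD over a 40-frame window

```
MSD(n·Δt) = Σ_{i=1..N−n} [(x_{i+n}−x_i)² + (y_{i+n}−y_i)²] / (N−n)
```

is classified in two steps. Tracks whose initial slope (18–180 ms) gives
`D_init = slope/4` below `D_threshold = (0.05 μm)²/(4·9·Δt) ≈ 0.004 μm²/s`
are **stationary**. Mobile tracks are fitted over 18–396 ms with the
confined-diffusion model `MSD(t) = (4R²_conf/3)(1−exp(−t/τ))`,
`τ = R²_conf/(3D_conf)`; tracks with `τ < 198 ms` are **confined**, the
rest **diffusive** with `D_diff` from the linear fit `MSD = 4Dt`. Group
comparisons use Kruskal–Wallis plus the Steel–Dwass–Critchlow–Fligner
all-pairs post hoc on joint ranks.

**Core analysis** (`sgnano.granules`). SG regions are segmented from
rendered images (≥ 0.3 μm²); cores are DBSCAN clusters (ε = 25 nm,
minPts = 100 fixed-cell / 40 live) with convex-hull equivalent-circle
diameters; the areal core density is the zero-intercept regression slope
of core count on SG area, `Σaᵢcᵢ/Σaᵢ²`.

**RDF and flux** (`sgnano.rdfflux`). The radial distribution function of
track points around their nearest core centroid (10 nm bins, annulus-area
weighted, normalized at 500 nm, optionally divided by a uniform-random
baseline) quantifies whether molecules dwell near cores. Each track is
classified in→in / in→out (efflux) / out→in (influx) / out→out from its
first and last positions, crossed with its diffusion mode.

**Synthetic data** (`sgnano.synthgen`). Seeded generators for SG scenes
with cores, three-population trajectories (stationary / reflected-confined
/ Brownian at D ≈ 0.1–0.3 μm²/s plus 25 nm localization noise), two-state
exponential blinking (mean on 1.0 s, 268 photons/frame at 55 Hz), and
movie rendering with an integrated-Gaussian PSF, Poisson shot noise and
Gaussian camera noise — all returning their ground truth.

## Worked example

The `sgnano` command runs the whole pipeline on synthetic data with the
study parameterization as defaults (55 Hz, 400 nm gate, 40-point filter,
DBSCAN 25 nm / 100, 0.3 μm² SG threshold, 10 nm RDF bins, SNR 5):

```bash
$ sgnano run-all --out demo --seed 7
{
  "config_hash": "d4f2f1c31bcb",
  "n_simulated_tracks": 40,
  "n_storm_localizations": 21154,
  "n_localizations": 1306,
  "n_tracks": 13,
  "mode_fractions": {
    "stationary": 0.3076923076923077,
    "confined": 0.23076923076923078,
    "diffusive": 0.46153846153846156
  },
  "core_density": 8.792904258928225,
  "n_cores": 45,
  "rdf_bins": 106,
  "flux_counts": {"in→in": 8, "in→out": 4, "out→in": 0, "out→out": 1}
}
```

Reading the output: 40 molecules were simulated in a stressed scene,
rendered to a movie and re-localized (1306 localizations); 13 trajectories
survived the 40-point/720 ms filter and were classified into modes (small-n
fractions; the dedicated recovery analyses below use 1000 tracks). The
fixed-channel localization map yielded 45 DBSCAN cores across 4 SGs, an
areal density of 8.8 cores/μm² at the default seeded density of 10/μm².
`demo/` contains every intermediate table (ThunderSTORM-dialect CSVs with a
config-hash header), the movie, a summary figure and a JSON provenance
record. Individual stages are available as subcommands (`simulate`,
`blink`, `localize`, `render`, `track`, `classify`, `cores`, `rdf`,
`flux`, `report`); `sgnano init-config config.yaml` writes the editable
defaults.

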