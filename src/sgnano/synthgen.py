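"""Ground-truth synthetic data for the whole pipeline.

Emulates the study's imaging conditions: circular stress-granule (SG)
regions containing high-density localization cores, three trajectory
populations (stationary / confined / freely diffusing), two-state blinking
emitters, and movies rendered with an integrated-Gaussian PSF, Poisson shot
noise and Gaussian camera noise. Every generator is seeded and returns its
ground truth so downstream stages can be scored exactly.

Units: lengths in nm, times in s, diffusion coefficients in μm²/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from ._rng import substream
from .blink import BlinkTrace
from .tracking import Track, TrackSet

NM2_PER_UM2 = 1.0e6


@dataclass(frozen=True)
class Disk:
    """A circular region (an SG footprint), nm coordinates."""

    center: tuple[float, float]
    radius: float

    @property
    def area_um2(self) -> float:
        return np.pi * self.radius**2 / NM2_PER_UM2

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.hypot(p[:, 0] - self.center[0], p[:, 1] - self.center[1]) <= self.radius

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r = self.radius * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, size=n)
        return np.column_stack(
            [self.center[0] + r * np.cos(th), self.center[1] + r * np.sin(th)]
        )


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and imaging constants of a synthetic field of view.

    ``frame_time`` defaults to 0.018 s (55 Hz acquisition); the two-channel
    tracking/localization variant runs at 27.5 Hz (0.036 s per step).
    Core localizations are drawn as isotropic Gaussians with
    σ = core_diameter / 4, so the default 80 nm core has σ = 20 nm.
    """

    field_size: tuple[float, float] = (20480.0, 20480.0)
    pixel_size: float = 160.0
    sg_regions: tuple[tuple[tuple[float, float], float], ...] = ()
    cores_per_sg_area: float = 10.0
    core_diameter: float = 80.0
    core_loc_count: float = 400.0
    shell_loc_density: float = 500.0
    frame_time: float = 0.018
    n_frames: int = 1000
    psf_sigma: float = 130.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.field_size) <= 0 or self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("lengths must be positive")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.cores_per_sg_area < 0 or self.core_loc_count < 0:
            raise ValueError("densities and counts must be non-negative")
        w, h = self.field_size
        for (cx, cy), r in self.sg_regions:
            if r <= 0:
                raise ValueError("SG radius must be positive")
            if cx - r < 0 or cy - r < 0 or cx + r > w or cy + r > h:
                raise ValueError("SG region must lie fully inside the field")

    @property
    def core_sigma(self) -> float:
        return self.core_diameter / 4.0


@dataclass(frozen=True)
class MotionParams:
    """Ground-truth motion mixture.

    ``mode_fractions`` are (stationary, confined, diffusive) probabilities;
    localization noise is added post hoc as i.i.d. Gaussian with
    ``loc_noise_sigma`` (default 25 nm, i.e. ≈ 50 nm spatial resolution).
    """

    mode_fractions: tuple[float, float, float] = (0.40, 0.25, 0.35)
    D_diff: float = 0.23
    R_conf_true: float = 100.0
    D_conf_true: float = 0.05
    loc_noise_sigma: float = 25.0
    track_length: int = 40

    def __post_init__(self) -> None:
        f = np.asarray(self.mode_fractions, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("mode_fractions must be >= 0 and sum to 1")
        if self.D_diff < 0 or self.D_conf_true < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.loc_noise_sigma < 0:
            raise ValueError("loc_noise_sigma must be >= 0")
        if self.R_conf_true <= 0:
            raise ValueError("R_conf_true must be positive")
        if self.track_length < 2:
            raise ValueError("track_length must be >= 2")


@dataclass(frozen=True)
class Photophysics:
    """Two-state blinking emitter parameters.

    Defaults follow the silicon-rhodamine tracer characterization: mean on
    time 1.0 s and 268 expected photons per on frame; the mean off time
    (10 s, duty cycle ≈ 9%) is a typical sparse-blinking regime for
    single-molecule localization.
    """

    mean_on: float = 1.0
    mean_off: float = 10.0
    photons_per_frame_on: float = 268.0
    bleach_prob_per_on_event: float = 0.0
    background_photons: float = 10.0
    camera_noise_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_on <= 0 or self.mean_off <= 0:
            raise ValueError("mean dwell times must be positive")
        if not 0.0 <= self.bleach_prob_per_on_event <= 1.0:
            raise ValueError("bleach probability must be in [0, 1]")
        if self.photons_per_frame_on < 0 or self.background_photons < 0:
            raise ValueError("photon rates must be >= 0")
        if self.camera_noise_sigma < 0:
            raise ValueError("camera_noise_sigma must be >= 0")


@dataclass
class Scene:
    """Generated SG geometry: SG disks and the core centers inside each."""

    config: SceneConfig
    sgs: list[Disk]
    core_centers: list[np.ndarray]  # one (k_i, 2) array per SG

    @property
    def all_core_centers(self) -> np.ndarray:
        if not self.core_centers or all(c.size == 0 for c in self.core_centers):
            return np.empty((0, 2))
        return np.vstack([c for c in self.core_centers if c.size])


@dataclass
class GroundTruth:
    """Everything the generators know that the analysis must recover."""

    true_tracks: TrackSet | None = None
    true_mode_labels: np.ndarray | None = None
    true_core_centroids: np.ndarray | None = None
    emitter_frames_on: np.ndarray | None = None  # (n_emitters, n_frames) bool
    true_positions: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


MODE_NAMES = ("stationary", "confined", "diffusive")


def make_scene(config: SceneConfig, seed: int | None = None) -> Scene:
    """Populate each SG disk with core centers.

    The number of cores per SG is Poisson with mean density × SG area and
    centers are uniform over the disk, subject to a hard-core exclusion of
    one core diameter: two dense clusters whose centers overlap within a
    core diameter are physically a single core, so the seeded count only
    refers to distinguishable cores. At the densities studied (~10/μm²,
    ~6% packing) the exclusion almost never discards a draw.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    sgs = [Disk(tuple(c), r) for c, r in config.sg_regions]
    core_centers = []
    for sg in sgs:
        k = rng.poisson(config.cores_per_sg_area * sg.area_um2)
        placed: list[np.ndarray] = []
        for _ in range(k):
            for _attempt in range(100):
                cand = sg.sample_uniform(1, rng)[0]
                if all(np.hypot(*(cand - p)) >= config.core_diameter for p in placed):
                    placed.append(cand)
                    break
        core_centers.append(np.array(placed) if placed else np.empty((0, 2)))
    return Scene(config, sgs, core_centers)


def sample_scene_localizations(scene: Scene, seed: int = 0) -> pd.DataFrame:
    """Draw a super-resolution localization map of a scene.

    Each core contributes Poisson(core_loc_count) points from an isotropic
    Gaussian (σ = core_diameter/4); the SG shell contributes a uniform
    background at ``shell_loc_density`` per μm². Returns a table with
    columns x, y (nm), sg_id, core_id (−1 for shell points).
    """
    cfg = scene.config
    rng = np.random.default_rng(seed)
    rows = []
    for sg_id, (sg, centers) in enumerate(zip(scene.sgs, scene.core_centers)):
        for core_id, c in enumerate(centers):
            n = rng.poisson(cfg.core_loc_count)
            pts = c + rng.normal(scale=cfg.core_sigma, size=(n, 2))
            for x, y in pts:
                rows.append((x, y, sg_id, core_id))
        n_shell = rng.poisson(cfg.shell_loc_density * sg.area_um2)
        for x, y in sg.sample_uniform(n_shell, rng):
            rows.append((x, y, sg_id, -1))
    return pd.DataFrame(rows, columns=["x", "y", "sg_id", "core_id"])


def _fold_reflect(z: np.ndarray, R: float) -> np.ndarray:
    """Map an unconstrained coordinate onto [−R, R] by reflection.

    The triangle-wave folding of a Brownian path is exactly reflected
    Brownian motion on the interval (reflection principle).
    """
    u = np.mod(z + R, 4.0 * R)
    return np.where(u <= 2.0 * R, u - R, 3.0 * R - u)


def simulate_tracks(
    scene: Scene | None,
    motion: MotionParams,
    n_tracks: int,
    seed: int = 0,
    frame_time: float | None = None,
) -> tuple[TrackSet, GroundTruth]:
    """Simulate a labelled mixture of stationary/confined/diffusive tracks.

    Stationary tracks are a fixed point plus localization noise; confined
    tracks are Brownian motion reflected per axis at ±R_conf about the
    start point (long-lag MSD plateau 4·R_conf²/3, matching the confined
    MSD model used by the classifier); diffusive tracks are free Brownian
    motion with per-axis step variance 2·D·Δt. Localization noise is added
    to all of them. Start positions are uniform over the scene's SG disks
    when a scene is given, otherwise uniform over a 10×10 μm box.
    """
    if n_tracks <= 0:
        raise ValueError("n_tracks must be positive")
    rng = np.random.default_rng(seed)
    dt = frame_time if frame_time is not None else (
        scene.config.frame_time if scene is not None else 0.018
    )
    n_pts = motion.track_length
    labels = rng.choice(3, size=n_tracks, p=np.asarray(motion.mode_fractions))

    if scene is not None and scene.sgs:
        areas = np.array([sg.area_um2 for sg in scene.sgs])
        which = rng.choice(len(scene.sgs), size=n_tracks, p=areas / areas.sum())
        starts = np.vstack(
            [scene.sgs[i].sample_uniform(1, rng)[0] for i in which]
        )
    else:
        starts = rng.uniform(0.0, 10000.0, size=(n_tracks, 2))

    # per-axis Brownian step sigma in nm: sqrt(2 D dt), D in um^2/s -> nm^2/s
    sig_diff = np.sqrt(2.0 * motion.D_diff * dt * NM2_PER_UM2)
    sig_conf = np.sqrt(2.0 * motion.D_conf_true * dt * NM2_PER_UM2)

    true_tracks, noisy_tracks = [], []
    for tid in range(n_tracks):
        lab = labels[tid]
        if lab == 0:
            path = np.tile(starts[tid], (n_pts, 1))
        elif lab == 1:
            steps = rng.normal(scale=sig_conf, size=(n_pts - 1, 2))
            free = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
            path = starts[tid] + _fold_reflect(free, motion.R_conf_true)
        else:
            steps = rng.normal(scale=sig_diff, size=(n_pts - 1, 2))
            path = starts[tid] + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        noise = (
            rng.normal(scale=motion.loc_noise_sigma, size=path.shape)
            if motion.loc_noise_sigma > 0
            else 0.0
        )
        frames = np.arange(n_pts)
        true_tracks.append(Track(tid, frames, path, dt))
        noisy_tracks.append(Track(tid, frames, path + noise, dt))

    gt = GroundTruth(
        true_tracks=TrackSet(true_tracks, dt, {"kind": "noise-free"}),
        true_mode_labels=labels,
        true_core_centroids=scene.all_core_centers if scene is not None else None,
    )
    ts = TrackSet(noisy_tracks, dt, {"kind": "simulated", "seed": seed})
    return ts, gt


def simulate_blinking(
    photo: Photophysics,
    n_emitters: int,
    n_frames: int,
    frame_time: float = 0.018,
    seed: int = 0,
    make_traces: bool = True,
) -> tuple[list[BlinkTrace], GroundTruth]:
    """Simulate two-state blinking emitters.

    Each emitter is a continuous-time alternating renewal process with
    exponential on/off dwell times, started in the dark state; each on
    period ends in permanent photobleaching with ``bleach_prob_per_on_event``.
    The schedule is discretized to frames (a frame is on if the emitter was
    bright for ≥ 50% of the frame interval). While on, per-frame photons are
    Poisson(photons_per_frame_on); traces add Poisson background and
    Gaussian camera noise.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    T = n_frames * frame_time
    frames_on = np.zeros((n_emitters, n_frames), dtype=bool)
    edges = np.arange(n_frames + 1) * frame_time
    for e in range(n_emitters):
        t = 0.0
        coverage = np.zeros(n_frames)
        while t < T:
            t += rng.exponential(photo.mean_off)
            if t >= T:
                break
            on_len = rng.exponential(photo.mean_on)
            a, b = t, min(t + on_len, T)
            # add overlap of [a, b) with each frame; only edge frames are partial
            i0, i1 = int(a // frame_time), min(int(b // frame_time), n_frames - 1)
            if i0 == i1:
                coverage[i0] += b - a
            else:
                coverage[i0] += edges[i0 + 1] - a
                coverage[i1] += b - edges[i1]
                if i1 > i0 + 1:
                    coverage[i0 + 1:i1] += frame_time
            t += on_len
            if rng.uniform() < photo.bleach_prob_per_on_event:
                break
        frames_on[e] = coverage >= 0.5 * frame_time

    traces: list[BlinkTrace] = []
    if make_traces:
        for e in range(n_emitters):
            signal = np.zeros(n_frames)
            on = frames_on[e]
            signal[on] = rng.poisson(photo.photons_per_frame_on, size=int(on.sum()))
            bg = rng.poisson(photo.background_photons, size=n_frames)
            read = (
                rng.normal(scale=photo.camera_noise_sigma, size=n_frames)
                if photo.camera_noise_sigma > 0
                else 0.0
            )
            intensities = np.clip(signal + bg + read, 0.0, None)
            traces.append(BlinkTrace(intensities, frame_time, emitter_id=e))
    gt = GroundTruth(emitter_frames_on=frames_on)
    return traces, gt


def _integrated_gaussian(shape: tuple[int, int], x: float, y: float,
                         photons: float, sigma: float, pixel_size: float) -> np.ndarray:
    """Photons of a PSF at (x, y) nm integrated over each pixel."""
    h, w = shape
    s = sigma / pixel_size
    xc, yc = x / pixel_size, y / pixel_size
    cols = np.arange(w)
    rows = np.arange(h)
    fx = 0.5 * (erf((cols + 1 - xc) / (np.sqrt(2) * s)) - erf((cols - xc) / (np.sqrt(2) * s)))
    fy = 0.5 * (erf((rows + 1 - yc) / (np.sqrt(2) * s)) - erf((rows - yc) / (np.sqrt(2) * s)))
    return photons * np.outer(fy, fx)


def render_movie(
    config: SceneConfig,
    tracks: TrackSet | None = None,
    frames_on: np.ndarray | None = None,
    photo: Photophysics | None = None,
    static_positions: np.ndarray | None = None,
    noise: bool = True,
    quantize: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a 16-bit movie of emitters with an integrated-Gaussian PSF.

    Emitters come either from ``tracks`` (moving; a track contributes to the
    frames it spans) or from ``static_positions`` (fixed (n, 2) nm positions
    present in every frame). ``frames_on`` (emitters × frames, boolean)
    optionally gates emission, e.g. a blinking schedule. With ``noise=True``
    the signal+background is Poisson-sampled and Gaussian read noise is
    added; with ``noise=False`` the expected photon image (plus background
    level) is returned. ``quantize=False`` skips the 16-bit conversion and
    returns float photon counts (useful for flux-conservation checks).
    """
    photo = photo or Photophysics()
    rng = np.random.default_rng(seed)
    w_px = int(round(config.field_size[0] / config.pixel_size))
    h_px = int(round(config.field_size[1] / config.pixel_size))
    n_frames = config.n_frames
    # per-frame emitter positions
    per_frame: list[list[tuple[float, float]]] = [[] for _ in range(n_frames)]
    if tracks is not None:
        emitters = [(t.frames, t.xy) for t in tracks]
    elif static_positions is not None:
        pos = np.atleast_2d(static_positions)
        emitters = [(np.arange(n_frames), np.tile(p, (n_frames, 1))) for p in pos]
    else:
        emitters = []
    for eid, (frs, xy) in enumerate(emitters):
        for f, (x, y) in zip(frs, xy):
            if f < 0 or f >= n_frames:
                continue
            if frames_on is not None and not frames_on[eid, f]:
                continue
            if not (0 <= x <= config.field_size[0] and 0 <= y <= config.field_size[1]):
                warnings.warn(f"emitter {eid} outside field in frame {f}; skipped")
                continue
            per_frame[f].append((x, y))

    movie = np.zeros((n_frames, h_px, w_px),
                     dtype=np.uint16 if quantize else float)
    for f in range(n_frames):
        img = np.zeros((h_px, w_px))
        for x, y in per_frame[f]:
            p = (
                rng.poisson(photo.photons_per_frame_on)
                if noise else photo.photons_per_frame_on
            )
            img += _integrated_gaussian(
                (h_px, w_px), x, y, float(p), config.psf_sigma, config.pixel_size
            )
        img += photo.background_photons
        if noise:
            img = rng.poisson(img).astype(float)
            if photo.camera_noise_sigma > 0:
                img += rng.normal(scale=photo.camera_noise_sigma, size=img.shape)
        movie[f] = np.clip(np.round(img), 0, 65535).astype(np.uint16) if quantize else img

    gt = GroundTruth(
        true_tracks=tracks,
        true_positions=(
            np.atleast_2d(static_positions) if static_positions is not None else None
        ),
        emitter_frames_on=frames_on,
    )
    return movie, gt


def scenario_stressed(seed: int = 0, n_sgs: int = 5) -> SceneConfig:
    """Preset: arsenite-stressed field with SGs of area 0.3–2 μm²."""
    rng = substream(seed, "scenario-stressed")
    w = h = 20480.0
    sgs = []
    for _ in range(n_sgs):
        area = rng.uniform(0.3, 2.0)  # um^2
        r = np.sqrt(area * NM2_PER_UM2 / np.pi)
        cx = rng.uniform(r + 200, w - r - 200)
        cy = rng.uniform(r + 200, h - r - 200)
        sgs.append(((cx, cy), r))
    return SceneConfig(field_size=(w, h), sg_regions=tuple(sgs), rng_seed=seed)
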