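"""Per-frame single-molecule detection, sub-pixel localization, and
super-resolution rendering.

Detection is a difference-of-Gaussians band-pass followed by local-maximum
picking above ``detect_snr`` times the robust image noise; each candidate is
then refined by least-squares fitting of a symmetric 2D Gaussian plus
constant offset in an 11×11 px window. Fits that do not converge, whose
width falls outside [0.5, 2]× the PSF guess, or whose center leaves the
window are dropped; localizations within 1 px of each other in the same
frame are merged keeping the brightest.

Rendering accumulates localizations into a 2D histogram at a chosen
super-resolution pixel size; the sliding-window variant reproduces the
live-reconstruction scheme of accumulating a fixed window of neighbor
frames advanced by a fixed step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.ndimage import gaussian_filter
from scipy.special import erf
from skimage.feature import peak_local_max

LOC_COLUMNS = ["frame", "x", "y", "photons", "sigma", "uncertainty"]


@dataclass
class SRImage:
    """Super-resolution rendering: a localization-count grid.

    ``data[row, col]`` covers x in [col·px, (col+1)·px) nm and likewise for
    y; in histogram mode the total intensity equals the number of
    contributing localizations.
    """

    data: np.ndarray
    pixel_size: float
    frame_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def total(self) -> float:
        return float(self.data.sum())


def _igauss2d(params: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Integrated symmetric 2D Gaussian over unit pixels plus offset.

    ``params`` = (xc, yc, photons, sigma, offset) with the center in pixel-
    edge coordinates of the fit window (pixel i spans [i, i+1)).
    """
    xc, yc, photons, sig, off = params
    s = np.sqrt(2.0) * sig
    fx = 0.5 * (erf((edges[1:] - xc) / s) - erf((edges[:-1] - xc) / s))
    fy = 0.5 * (erf((edges[1:] - yc) / s) - erf((edges[:-1] - yc) / s))
    return photons * np.outer(fy, fx) + off


def thompson_uncertainty(photons: float, sigma_nm: float, pixel_nm: float,
                         background: float) -> float:
    """Localization precision from photon statistics (Thompson-style).

    σ_loc² = (s² + a²/12)/N + 8π s⁴ b² / (a² N²), with s the PSF width,
    a the pixel size, N the photon count and b the background noise per
    pixel (all in nm / photons).
    """
    s2 = sigma_nm**2 + pixel_nm**2 / 12.0
    var = s2 / photons + 8 * np.pi * sigma_nm**4 * background**2 / (pixel_nm**2 * photons**2)
    return float(np.sqrt(var))


def localize_frame(
    frame: np.ndarray,
    psf_sigma_px: float,
    detect_snr: float = 5.0,
    pixel_size: float = 160.0,
    window: int = 11,
) -> list[tuple[float, float, float, float, float]]:
    """Localize all spots in one frame; returns (x, y, photons, sigma, unc) in nm."""
    img = frame.astype(float)
    band = gaussian_filter(img, psf_sigma_px) - gaussian_filter(img, 2.5 * psf_sigma_px)
    med = np.median(band)
    noise = 1.4826 * np.median(np.abs(band - med))
    if noise == 0:
        noise = max(np.std(band), 1e-12)
    peaks = peak_local_max(
        band, min_distance=max(int(round(2 * psf_sigma_px)), 1),
        threshold_abs=med + detect_snr * noise,
    )
    half = window // 2
    h, w = img.shape
    edges = np.arange(window + 1, dtype=float)
    out = []
    for r0, c0 in peaks:
        if r0 < half or c0 < half or r0 >= h - half or c0 >= w - half:
            continue
        sub = img[r0 - half:r0 + half + 1, c0 - half:c0 + half + 1]
        if sub.max() >= 65535:  # saturated window: photon count unusable
            continue
        off0 = float(np.median(sub))
        tot = float(np.clip(sub[half - 2:half + 3, half - 2:half + 3] - off0, 0, None).sum())
        # inverse-variance (Poisson) weights keep the bright central pixel
        # from dominating the fit and collapsing sigma
        wgt = 1.0 / np.sqrt(np.clip(sub, 1.0, None))
        p0 = np.array([half + 0.5, half + 0.5, max(tot, 10.0), psf_sigma_px, off0])
        try:
            fit = least_squares(
                lambda p: ((_igauss2d(p, edges) - sub) * wgt).ravel(), p0,
                bounds=(
                    [0, 0, 1e-3, 0.3 * psf_sigma_px, -np.inf],
                    [window, window, np.inf, 3 * psf_sigma_px, np.inf],
                ),
                max_nfev=300,
            )
        except Exception:
            continue
        if not fit.success:
            continue
        xc, yc, photons, sig, off = fit.x
        if not (0.5 * psf_sigma_px <= sig <= 2.0 * psf_sigma_px):
            continue
        if not (1.5 <= xc <= window - 1.5 and 1.5 <= yc <= window - 1.5):
            continue
        photons = float(photons)
        if photons <= 0:
            continue
        x_nm = (c0 - half + xc) * pixel_size
        y_nm = (r0 - half + yc) * pixel_size
        bg_noise = max(np.sqrt(max(off, 0.0)), 1e-6)
        unc = thompson_uncertainty(photons, sig * pixel_size, pixel_size, bg_noise)
        out.append((x_nm, y_nm, photons, sig * pixel_size, unc))
    return out


def localize_stack(
    stack: np.ndarray,
    psf_sigma_guess: float = 130.0,
    detect_snr: float = 5.0,
    pixel_size: float = 160.0,
) -> pd.DataFrame:
    """Detect and localize single molecules in every frame of a stack.

    Returns a localization table with columns frame, x, y (nm), photons,
    sigma (nm), uncertainty (nm), sorted by frame.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frames, rows, cols) array")
    psf_px = psf_sigma_guess / pixel_size
    rows = []
    for f in range(stack.shape[0]):
        locs = localize_frame(stack[f], psf_px, detect_snr, pixel_size)
        # duplicate suppression: within 1 px, keep the brightest
        locs.sort(key=lambda t: -t[2])
        kept: list[tuple[float, float, float, float, float]] = []
        for cand in locs:
            if all(np.hypot(cand[0] - k[0], cand[1] - k[1]) > pixel_size for k in kept):
                kept.append(cand)
        rows.extend((f, *c) for c in kept)
    return pd.DataFrame(rows, columns=LOC_COLUMNS)


def render_sr(
    locs: pd.DataFrame,
    pixel_size: float = 20.0,
    field_size: tuple[float, float] | None = None,
    blur_sigma: float | None = None,
) -> SRImage:
    """Render a localization table as a 2D histogram super-resolution image.

    With ``blur_sigma`` (nm) the histogram is Gaussian-smoothed; in plain
    histogram mode the image sums exactly to the number of localizations.
    """
    if len(locs) == 0:
        raise ValueError("cannot render an empty localization table")
    if field_size is None:
        field_size = (
            float(np.ceil(locs["x"].max() / pixel_size + 1) * pixel_size),
            float(np.ceil(locs["y"].max() / pixel_size + 1) * pixel_size),
        )
    nx = int(np.ceil(field_size[0] / pixel_size))
    ny = int(np.ceil(field_size[1] / pixel_size))
    hist, _, _ = np.histogram2d(
        locs["y"].to_numpy(), locs["x"].to_numpy(),
        bins=(ny, nx), range=((0, ny * pixel_size), (0, nx * pixel_size)),
    )
    if blur_sigma is not None:
        hist = gaussian_filter(hist, blur_sigma / pixel_size)
    fr = (int(locs["frame"].min()), int(locs["frame"].max()) + 1)
    return SRImage(hist, pixel_size, fr)


def render_sliding(
    locs: pd.DataFrame,
    n_frames: int,
    window: int = 5000,
    step: int = 1000,
    pixel_size: float = 20.0,
    field_size: tuple[float, float] | None = None,
) -> list[SRImage]:
    """Sliding-window live reconstruction.

    Image k accumulates the localizations of frames
    [k·step, k·step + window); the number of images is
    floor((n_frames − window)/step) + 1.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    if n_frames < window:
        raise ValueError("need at least `window` frames")
    if field_size is None:
        field_size = (
            float(np.ceil(locs["x"].max() / pixel_size + 1) * pixel_size),
            float(np.ceil(locs["y"].max() / pixel_size + 1) * pixel_size),
        )
    n_images = (n_frames - window) // step + 1
    images = []
    frames = locs["frame"].to_numpy()
    for k in range(n_images):
        lo, hi = k * step, k * step + window
        sel = locs[(frames >= lo) & (frames < hi)]
        if len(sel) == 0:
            nx = int(np.ceil(field_size[0] / pixel_size))
            ny = int(np.ceil(field_size[1] / pixel_size))
            images.append(SRImage(np.zeros((ny, nx)), pixel_size, (lo, hi)))
        else:
            img = render_sr(sel, pixel_size, field_size)
            images.append(SRImage(img.data, pixel_size, (lo, hi)))
    return images
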