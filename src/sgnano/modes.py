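"""MSD computation, diffusion-mode classification, and group statistics.

Per-track mean squared displacement over a fixed time window::

    MSD(n·Δt) = Σ_{i=1}^{N−n} [(x_{i+n}−x_i)² + (y_{i+n}−y_i)²] / (N − n)

Classification proceeds in two steps. The initial MSD slope (lags between
Δt and 180 ms, linear regression with free intercept) yields
D_init = slope/4; tracks with D_init below a resolution-derived threshold

    D_threshold = resolution² / (4 × 9 × Δt)

(≈ 0.004 μm²/s for 50 nm resolution at 18 ms) are stationary. Mobile
tracks are fitted with the confined-diffusion model

    MSD(t) = (4 R_conf²/3) · (1 − exp(−t/τ)),   τ = R_conf²/(3 D_conf)

over lags up to 396 ms; tracks with τ below half of the fitting interval
(198 ms) are confined, the rest are diffusive with D_diff from the slope of
a linear fit (MSD = 4 D t) over the same lags.

Group comparisons use the Kruskal–Wallis omnibus test followed by the
Steel–Dwass–Critchlow–Fligner (DSCF) all-pairs post hoc, with pairwise
joint-rank statistics referred to the studentized range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .tracking import Track, TrackSet

MODE_NAMES = ("stationary", "confined", "diffusive")


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track; lags in s, msd in μm²."""

    lags: np.ndarray
    msd: np.ndarray
    n_window: int
    frame_time: float


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and fit windows of the mode classifier.

    ``d_threshold`` and ``tau_threshold`` are derived, not free: the former
    from the spatial resolution and frame time, the latter as half of the
    upper edge of the confined-fit window. ``for_frame_time`` rebuilds the
    windows for a different time base (e.g. the 27.5 Hz two-channel
    variant) from the same rules.
    """

    frame_time: float = 0.018
    n_window: int = 40
    spatial_resolution: float = 0.05  # um
    initial_slope_window: tuple[float, float] = (0.018, 0.180)
    fit_window: tuple[float, float] = (0.018, 0.396)

    @property
    def d_threshold(self) -> float:
        """Stationary/mobile split in μm²/s: resolution²/(4·9·Δt)."""
        return self.spatial_resolution**2 / (4.0 * 9.0 * self.frame_time)

    @property
    def tau_threshold(self) -> float:
        """Confined/diffusive split in s: half of the fit-window upper edge."""
        return self.fit_window[1] / 2.0

    @classmethod
    def for_frame_time(cls, frame_time: float, n_window: int = 40) -> "ClassifierConfig":
        return cls(
            frame_time=frame_time,
            n_window=n_window,
            initial_slope_window=(frame_time, 0.180),
            fit_window=(frame_time, 0.396),
        )

    @classmethod
    def spt_storm(cls) -> "ClassifierConfig":
        """Two-channel tracking/localization variant: 27.5 Hz, 20-point tracks."""
        return cls.for_frame_time(0.036, n_window=20)


@dataclass
class ModeFit:
    """Classification result of one track.

    Only the fields relevant to the label are populated: confined tracks
    carry (r_conf, tau, d_conf), diffusive tracks carry d_diff; d_init is
    always available.
    """

    label: str
    d_init: float
    r_conf: float | None = None  # um
    tau: float | None = None  # s
    d_conf: float | None = None  # um^2/s
    d_diff: float | None = None  # um^2/s
    fit_quality: float | None = None
    track_id: int | None = None
    fit_converged: bool = True


def compute_msd(track: Track, n_window: int = 40) -> MSDCurve:
    """Time-averaged MSD of the first ``n_window`` points of a track.

    Raises if the track is shorter than the window (filter tracks first);
    longer tracks are truncated. Output in μm².
    """
    if track.n_points < n_window:
        raise ValueError(
            f"track has {track.n_points} points, needs >= {n_window}; filter first"
        )
    xy_um = track.xy[:n_window] / 1000.0
    N = n_window
    msd = np.empty(N - 1)
    for n in range(1, N):
        d = xy_um[n:] - xy_um[:-n]
        msd[n - 1] = np.mean(np.sum(d * d, axis=1))
    lags = np.arange(1, N) * track.frame_time
    return MSDCurve(lags, msd, N, track.frame_time)


def _confined_model(t: np.ndarray, r_conf: float, tau: float) -> np.ndarray:
    return (4.0 * r_conf**2 / 3.0) * (1.0 - np.exp(-t / tau))


def _window_mask(lags: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    eps = 1e-9
    return (lags >= window[0] - eps) & (lags <= window[1] + eps)


def classify_track(msd: MSDCurve, cfg: ClassifierConfig | None = None,
                   track_id: int | None = None) -> ModeFit:
    """Classify one MSD curve as stationary, confined or diffusive."""
    cfg = cfg or ClassifierConfig()
    m_init = _window_mask(msd.lags, cfg.initial_slope_window)
    m_fit = _window_mask(msd.lags, cfg.fit_window)
    if m_init.sum() < 2 or m_fit.sum() < 3:
        raise ValueError("MSD curve does not cover the classifier fit windows")

    slope_init = np.polyfit(msd.lags[m_init], msd.msd[m_init], 1)[0]
    d_init = slope_init / 4.0
    if d_init < cfg.d_threshold:
        return ModeFit("stationary", d_init, track_id=track_id)

    t, y = msd.lags[m_fit], msd.msd[m_fit]
    r0 = np.sqrt(max(0.75 * float(np.max(y)), 1e-8))
    tau0 = cfg.fit_window[1] / 3.0
    converged = True
    try:
        fit = least_squares(
            lambda p: _confined_model(t, *p) - y,
            x0=[min(r0, 2.0), tau0],
            bounds=([1e-6, 1e-6], [2.0, 10.0]),
            max_nfev=400,
        )
        converged = bool(fit.success)
        r_conf, tau = fit.x
        resid = float(np.linalg.norm(fit.fun))
    except Exception:
        converged = False
        r_conf, tau, resid = np.nan, np.inf, np.nan

    if converged and tau < cfg.tau_threshold:
        d_conf = r_conf**2 / (3.0 * tau)
        return ModeFit(
            "confined", d_init, r_conf=float(r_conf), tau=float(tau),
            d_conf=float(d_conf), fit_quality=resid, track_id=track_id,
        )
    slope = np.polyfit(t, y, 1)[0]
    return ModeFit(
        "diffusive", d_init, d_diff=float(slope / 4.0), fit_quality=resid,
        track_id=track_id, fit_converged=converged,
    )


def d_from_linear_fit(msd: MSDCurve, cfg: ClassifierConfig | None = None) -> float:
    """Free-diffusion coefficient from the linear MSD fit (MSD = 4Dt).

    Slope of a free-intercept linear regression over the classifier's fit
    window, divided by 4. Defined for any track, independent of its mode
    label.
    """
    cfg = cfg or ClassifierConfig()
    m = _window_mask(msd.lags, cfg.fit_window)
    return float(np.polyfit(msd.lags[m], msd.msd[m], 1)[0] / 4.0)


def classify_tracks(ts: TrackSet, cfg: ClassifierConfig | None = None) -> list[ModeFit]:
    """Compute MSD and classify every track of a set."""
    cfg = cfg or ClassifierConfig.for_frame_time(ts.frame_time)
    return [
        classify_track(compute_msd(t, cfg.n_window), cfg, track_id=t.track_id)
        for t in ts
    ]


@dataclass
class ModesSummary:
    """Per-group mode fractions and parameter distributions."""

    fractions: pd.DataFrame  # rows: group, cols: MODE_NAMES (sum to 1)
    counts: pd.DataFrame
    params: pd.DataFrame  # long table: group, label, parameter, value

    def summary(self) -> str:
        lines = ["Diffusion-mode summary", "=" * 22, "", "Fractions:"]
        lines.append(self.fractions.round(4).to_string())
        lines.append("")
        lines.append("Counts:")
        lines.append(self.counts.to_string())
        if len(self.params):
            lines.append("")
            stats_tbl = (
                self.params.groupby(["group", "parameter"])["value"]
                .agg(["mean", "sem", "count"])
            )
            lines.append("Parameters (mean ± s.e.m.):")
            lines.append(stats_tbl.round(4).to_string())
        return "\n".join(lines)


def aggregate_modes(
    fits: list[ModeFit],
    groups: list | None = None,
    cells: list | None = None,
) -> ModesSummary:
    """Aggregate per-track fits into per-group fractions and distributions.

    With ``cells`` given, fractions are computed per cell first and then
    averaged over the cells of each group (mean-of-cells convention);
    otherwise they are pooled over tracks.
    """
    n = len(fits)
    if n == 0:
        raise ValueError("no fits to aggregate")
    groups = list(groups) if groups is not None else ["all"] * n
    df = pd.DataFrame(
        {
            "group": groups,
            "label": [f.label for f in fits],
            "cell": list(cells) if cells is not None else [0] * n,
        }
    )
    counts = (
        df.groupby(["group", "label"]).size().unstack(fill_value=0)
        .reindex(columns=list(MODE_NAMES), fill_value=0)
    )
    per_cell = (
        df.groupby(["group", "cell", "label"]).size().unstack(fill_value=0)
        .reindex(columns=list(MODE_NAMES), fill_value=0)
    )
    per_cell_frac = per_cell.div(per_cell.sum(axis=1), axis=0)
    fractions = per_cell_frac.groupby(level="group").mean()

    rows = []
    for f, g in zip(fits, groups):
        for name in ("d_init", "r_conf", "tau", "d_conf", "d_diff"):
            v = getattr(f, name)
            if v is not None and np.isfinite(v):
                rows.append((g, f.label, name, float(v)))
    params = pd.DataFrame(rows, columns=["group", "label", "parameter", "value"])
    return ModesSummary(fractions, counts, params)


@dataclass
class DSCFResult:
    """Kruskal–Wallis omnibus plus DSCF all-pairs post hoc."""

    h_statistic: float
    p_omnibus: float
    pairwise_p: pd.DataFrame
    pairwise_q: pd.DataFrame

    def summary(self) -> str:
        return (
            f"Kruskal-Wallis H = {self.h_statistic:.4f}, p = {self.p_omnibus:.4g}\n"
            f"DSCF pairwise p-values:\n{self.pairwise_p.round(4).to_string()}"
        )


def dscf_pair_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected joint-rank statistic W for one group pair.

    W = (R_a − n_a(N+1)/2) / sqrt(V) with V the tie-corrected rank-sum
    variance; the studentized-range statistic is q = √2·|W|.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    N = na + nb
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = float(ranks[:na].sum())
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1)) if N > 1 else 0.0
    var = na * nb / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 0.0
    return (r_a - na * (N + 1) / 2.0) / np.sqrt(var)


def kruskal_dscf(groups: list[np.ndarray], labels: list | None = None) -> DSCFResult:
    """Kruskal–Wallis H (tie-corrected) with DSCF all-pairs post hoc.

    Pairwise p-values come from referring q = √2·|W| to the studentized
    range distribution with k groups and infinite degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    labels = list(labels) if labels is not None else list(range(len(arrays)))
    k = len(arrays)

    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)

    q = pd.DataFrame(np.nan, index=labels, columns=labels)
    pmat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, j in combinations(range(k), 2):
        w = dscf_pair_statistic(arrays[i], arrays[j])
        qij = np.sqrt(2.0) * abs(w)
        pij = float(stats.studentized_range.sf(qij, k, 1e7)) if qij > 0 else 1.0
        q.iloc[i, j] = q.iloc[j, i] = qij
        pmat.iloc[i, j] = pmat.iloc[j, i] = min(max(pij, 0.0), 1.0)
    return DSCFResult(float(h), float(p), pmat, q)
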