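"""Track-to-core radial distribution and SG influx/efflux accounting.

The radial distribution function (RDF) here is the annulus-area-weighted
histogram of distances from track points to their *nearest* core centroid,
in 10 nm bins, normalized by its own value in the bin containing 500 nm.
Dividing an observed profile by the profile of uniformly distributed random
points over the same SG region gives the relative RDF, which equals 1 for
a spatially unstructured point pattern.

Flux accounting classifies each track by whether its first and last frames
fall inside or outside the SG regions: out→in is influx, in→out efflux;
the summary crosses these categories with the diffusion-mode labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .modes import ModeFit
from .tracking import TrackSet

FLUX_CATEGORIES = ("in→in", "in→out", "out→in", "out→out")


@dataclass
class RDFProfile:
    """Binned radial distribution; ``kind`` is 'raw' or 'relative'.

    A raw profile is normalized so the bin containing ``norm_radius`` has
    g = 1 exactly; bins flagged in ``undefined`` had no baseline mass (only
    possible for relative profiles).
    """

    bin_edges: np.ndarray  # nm, width 10 by default
    g: np.ndarray
    norm_radius: float
    kind: str
    n_points: int
    undefined: np.ndarray | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def nearest_core_distances(points: np.ndarray, core_centroids: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest core centroid (nm)."""
    pts = np.atleast_2d(np.asarray(points, float))
    cents = np.atleast_2d(np.asarray(core_centroids, float))
    if len(cents) == 0:
        raise ValueError("need at least one core centroid")
    if len(pts) == 0:
        raise ValueError("need at least one point")
    d, _ = cKDTree(cents).query(pts)
    return d


def rdf_to_cores(
    points: np.ndarray,
    core_centroids: np.ndarray,
    bin_width: float = 10.0,
    norm_radius: float = 500.0,
    r_max: float | None = None,
) -> RDFProfile:
    """Raw RDF of point-to-nearest-core distances.

    The distance histogram (``bin_width`` nm bins) is divided by the area
    of each annulus and then by its own value in the bin containing
    ``norm_radius``. Raises if that bin is empty (no points that far out —
    widen the field or lower the normalization radius).
    """
    d = nearest_core_distances(points, core_centroids)
    if r_max is None:
        r_max = max(norm_radius + bin_width, float(np.ceil(d.max() / bin_width)) * bin_width)
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    hist, _ = np.histogram(d, bins=edges)
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g = hist / annulus
    norm_bin = int(norm_radius // bin_width)
    if norm_bin >= g.size or g[norm_bin] == 0:
        raise ValueError(
            f"no mass in the normalization bin at {norm_radius} nm; widen the range"
        )
    g = g / g[norm_bin]
    return RDFProfile(edges, g, norm_radius, "raw", n_points=len(d))


def relative_rdf(
    observed: RDFProfile,
    region,
    core_centroids: np.ndarray,
    n_random: int = 10,
    seed: int = 0,
) -> RDFProfile:
    """Observed RDF relative to a uniform-random baseline over the region.

    ``region`` must expose ``sample_uniform(n, rng)`` returning (n, 2) nm
    points (an ``SGRegion`` mask or a synthetic disk). Each of ``n_random``
    replicates draws as many points as the observed profile used; the
    replicate-averaged raw profile divides the observed one bin by bin.
    Bins with zero baseline mass are flagged undefined (NaN).
    """
    if observed.kind != "raw":
        raise ValueError("relative_rdf expects a raw observed profile")
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(observed.g)
    counts = np.zeros_like(observed.g)
    r_max = float(observed.bin_edges[-1])
    bw = float(observed.bin_edges[1] - observed.bin_edges[0])
    for _ in range(n_random):
        pts = region.sample_uniform(observed.n_points, rng)
        prof = rdf_to_cores(pts, core_centroids, bw, observed.norm_radius, r_max=r_max)
        acc += prof.g
        counts += 1
    baseline = acc / counts
    undefined = baseline == 0
    rel = np.full_like(observed.g, np.nan)
    rel[~undefined] = observed.g[~undefined] / baseline[~undefined]
    return RDFProfile(
        observed.bin_edges, rel, observed.norm_radius, "relative",
        n_points=observed.n_points, undefined=undefined,
    )


@dataclass
class FluxRecord:
    """Influx/efflux classification of one track."""

    track_id: int
    start_in_sg: bool
    end_in_sg: bool
    mode: str
    straddles_sgs: bool = False

    @property
    def category(self) -> str:
        return {
            (True, True): "in→in",
            (True, False): "in→out",
            (False, True): "out→in",
            (False, False): "out→out",
        }[(self.start_in_sg, self.end_in_sg)]


def classify_flux(
    ts: TrackSet,
    fits: list[ModeFit],
    sg_regions: list,
) -> tuple[list[FluxRecord], pd.DataFrame]:
    """Classify tracks into in/out flux categories crossed with modes.

    ``sg_regions`` is a list of objects with a ``contains(points)`` method
    (SGRegion masks or synthetic disks). A track is "in" at its first/last
    frame if any region contains that point. A track whose interior points
    visit more than one region is flagged (its category still uses the
    first/last points). Returns the per-track records and a category ×
    mode summary with counts and ratios.
    """
    if len(fits) != len(ts):
        raise ValueError("need exactly one mode fit per track")

    def region_hits(points: np.ndarray) -> np.ndarray:
        hits = np.full(len(points), -1)
        for i, reg in enumerate(sg_regions):
            inside = reg.contains(points)
            hits[(hits == -1) & inside] = i
        return hits

    records = []
    for track, fit in zip(ts, fits):
        hits = region_hits(track.xy)
        visited = set(hits[hits >= 0])
        records.append(
            FluxRecord(
                track_id=track.track_id,
                start_in_sg=bool(hits[0] >= 0),
                end_in_sg=bool(hits[-1] >= 0),
                mode=fit.label,
                straddles_sgs=len(visited) > 1,
            )
        )

    df = pd.DataFrame(
        {"category": [r.category for r in records], "mode": [r.mode for r in records]}
    )
    counts = (
        df.groupby(["category", "mode"]).size().unstack(fill_value=0)
        .reindex(index=list(FLUX_CATEGORIES), fill_value=0)
    )
    counts["total"] = counts.sum(axis=1)
    counts["ratio"] = counts["total"] / max(len(records), 1)
    return records, counts
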