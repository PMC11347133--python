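"""Independent reference implementations used as oracles by the tests.

These deliberately avoid the package's own code paths: plain quadratic
loops, exhaustive enumeration, and closed forms.
"""

from itertools import combinations

import numpy as np
import pandas as pd

from sgnano.modes import dscf_pair_statistic
from sgnano.tracking import Track, TrackSet


def naive_msd(xy_um, n_window, dt):
    """Double-loop evaluation of the time-averaged MSD."""
    xy = np.asarray(xy_um, float)[:n_window]
    N = n_window
    out = []
    for n in range(1, N):
        acc = 0.0
        for i in range(N - n):
            acc += (xy[i + n, 0] - xy[i, 0]) ** 2 + (xy[i + n, 1] - xy[i, 1]) ** 2
        out.append(acc / (N - n))
    return np.array(out)


def brute_force_link(locs: pd.DataFrame, max_disp: float) -> TrackSet:
    """Reference linking: greedy ascending-distance assignment between
    consecutive frames, written as plain quadratic loops."""
    df = locs.sort_values(["frame", "x", "y"]).reset_index(drop=True)
    tracks = []
    open_by_row = {}
    frames = sorted(df["frame"].unique())
    for k, f in enumerate(frames):
        rows = df.index[df["frame"] == f].tolist()
        if k > 0 and f == frames[k - 1] + 1 and open_by_row:
            pairs = []
            for ar in open_by_row:
                for br in rows:
                    d = np.hypot(df.x[br] - df.x[ar], df.y[br] - df.y[ar])
                    if d <= max_disp:
                        pairs.append((d, ar, br))
            used_a, used_b = set(), set()
            new_open = {}
            for d, ar, br in sorted(pairs):
                if ar in used_a or br in used_b:
                    continue
                used_a.add(ar)
                used_b.add(br)
                tr = open_by_row[ar]
                tr.append(br)
                new_open[br] = tr
            for br in rows:
                if br not in used_b:
                    new_open[br] = [br]
                    tracks.append(new_open[br])
            open_by_row = new_open
        else:
            open_by_row = {}
            for br in rows:
                open_by_row[br] = [br]
                tracks.append(open_by_row[br])
    out = []
    for tid, idx in enumerate(tracks):
        out.append(Track(tid, df.loc[idx, "frame"].to_numpy(),
                         df.loc[idx, ["x", "y"]].to_numpy(), 0.018))
    return TrackSet(out, 0.018)


def track_partition(ts: TrackSet):
    """Canonical representation of a track partition for comparisons."""
    return sorted(
        tuple(zip(t.frames.tolist(), map(tuple, np.round(t.xy, 6))))
        for t in ts
    )


def naive_dbscan(points, eps, min_pts):
    """Reference O(n^2) DBSCAN; labels array with -1 = noise.

    Border points join the first cluster that reaches them, as in the
    classic region-growing formulation.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    neighbors = [np.flatnonzero(d2[i] <= eps**2) for i in range(n)]
    is_core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -2)
    cluster = -1
    for i in range(n):
        if labels[i] != -2 or not is_core[i]:
            continue
        cluster += 1
        labels[i] = cluster
        queue = list(neighbors[i])
        while queue:
            j = queue.pop(0)
            if labels[j] == -2:
                labels[j] = cluster
                if is_core[j]:
                    queue.extend(neighbors[j])
    labels[labels == -2] = -1
    return labels, is_core


def canonical_dbscan_partition(labels, is_core):
    """Partition of core points plus the noise set (border ties ignored)."""
    core_clusters = {}
    for i in np.flatnonzero(np.asarray(is_core)):
        core_clusters.setdefault(labels[i], set()).add(int(i))
    noise = frozenset(np.flatnonzero(np.asarray(labels) == -1).tolist())
    return set(map(frozenset, core_clusters.values())), noise


def permutation_mid_p(a, b):
    """Exhaustive-permutation mid-p of the pairwise joint-rank statistic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    obs = np.sqrt(2) * abs(dscf_pair_statistic(a, b))
    pool = np.concatenate([a, b])
    qs = []
    for idx in combinations(range(pool.size), a.size):
        mask = np.zeros(pool.size, bool)
        mask[list(idx)] = True
        qs.append(np.sqrt(2) * abs(dscf_pair_statistic(pool[mask], pool[~mask])))
    qs = np.array(qs)
    return 0.5 * (np.mean(qs >= obs - 1e-9) + np.mean(qs > obs + 1e-9))
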