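"""Soft c-means clustering of chromatin-accessibility time courses.

Per-window DHS activity (representative -10*log10 p scores) is averaged
over replicates per (species, time), log2-transformed with a +1 offset, and
row-standardized.  Fuzzy c-means with Euclidean distance then groups the
standardized trajectories; the fuzzifier m is set from the data dimensions
by the Schwämmle–Jensen estimator, and the number of clusters is chosen
where the minimum pairwise centroid distance (Dmin) stops dropping
appreciably.  Windows are assigned trajectory labels (opening, closing,
transient) from the shape of their best cluster's centroid, provided their
membership reaches a minimum (default 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "FuzzyClustering",
    "standardize_profiles",
    "estimate_fuzzifier",
    "fuzzy_cmeans",
    "choose_cluster_number",
    "trajectory_classes",
]


@dataclass
class ProfileMatrix:
    """Row-standardized log2 activity trajectories (windows x time points)."""

    ids: list[str]
    times: list[str]
    values: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.times)):
            raise ValueError("profile matrix shape mismatch")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def d(self) -> int:
        return len(self.times)


@dataclass
class FuzzyClustering:
    c: int
    m: float
    centroids: np.ndarray  # c x T, ordered by value at the final time point
    memberships: np.ndarray  # N x c, rows sum to 1
    objective: float
    n_iter: int
    converged: bool


def standardize_profiles(
    scores: pd.DataFrame,
    replicate_map: dict[str, tuple[str, str]],
    species: str,
    times: list[str],
    offset: float = 1.0,
) -> ProfileMatrix:
    """Mean over replicates per time, log2(x + offset), then row z-score.

    ``scores`` is windows x samples (columns keyed like the replicate map);
    only columns of the requested species are used.  Constant rows carry no
    trajectory information and are dropped (count reported on the result).
    """
    if len(times) < 2:
        raise ValueError("at least 2 time points required")
    cols_by_time: dict[str, list[str]] = {t: [] for t in times}
    for col in scores.columns:
        sp, t = replicate_map[col]
        if sp == species and t in cols_by_time:
            cols_by_time[t].append(col)
    for t, cols in cols_by_time.items():
        if not cols:
            raise ValueError(f"no replicate columns for time point {t!r}")

    means = np.column_stack(
        [scores[cols_by_time[t]].mean(axis=1).to_numpy() for t in times]
    )
    logged = np.log2(means + offset)
    mu = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 1e-12
    if not keep.any():
        raise ValueError("all trajectories are constant; nothing to cluster")
    z = (logged[keep] - mu[keep]) / sd[keep]
    return ProfileMatrix(
        ids=[i for i, k in zip(scores.index, keep) if k],
        times=list(times),
        values=z,
        n_dropped=int((~keep).sum()),
    )


def estimate_fuzzifier(pm: ProfileMatrix) -> float:
    """Data-driven fuzzifier m from the matrix dimensions.

    m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)
    with N rows and D columns (Schwämmle & Jensen's estimator, the formula
    behind the widely used ``mestimate``).
    """
    n, d = pm.n, pm.d
    if n < 2 or d < 2:
        raise ValueError("fuzzifier estimation needs N >= 2 rows and D >= 2 columns")
    return float(
        1.0
        + (1418.0 / n + 22.05) * d**-2.0
        + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    )


def _order_centroids(
    centroids: np.ndarray, memberships: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical ordering: ascending centroid value at the final time."""
    order = np.argsort(centroids[:, -1], kind="mergesort")
    return centroids[order], memberships[:, order]


def fuzzy_cmeans(
    pm: ProfileMatrix,
    c: int,
    m: float,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FuzzyClustering:
    """Standard fuzzy c-means (Euclidean) with random membership init.

    Alternates membership updates u_ik ∝ d_ik^(-2/(m-1)) (row-normalized)
    and weighted centroid updates until the largest centroid shift is below
    ``tol``.  The objective sum_ik u_ik^m d_ik^2 is non-increasing.
    Deterministic given the seed; centroids are returned in canonical order
    (ascending final-time value) so labels are reproducible.
    """
    x = pm.values
    n = x.shape[0]
    if not 2 <= c < n:
        raise ValueError(f"need 2 <= c < N rows, got c={c}, N={n}")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)

    centroids = np.zeros((c, x.shape[1]))
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        um = u**m
        centroids_new = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centroids_new[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        shift = np.abs(centroids_new - centroids).max() if n_iter > 1 else np.inf
        centroids = centroids_new
        if shift < tol:
            converged = True
            break

    um = u**m
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    objective = float((um * d2).sum())
    centroids, u = _order_centroids(centroids, u)
    return FuzzyClustering(
        c=c, m=m, centroids=centroids, memberships=u,
        objective=objective, n_iter=n_iter, converged=converged,
    )


def choose_cluster_number(
    pm: ProfileMatrix,
    c_range: tuple[int, int],
    m: float,
    seed: int = 0,
    drop_fraction: float = 0.1,
) -> tuple[int, dict[int, float]]:
    """Select c from the minimum-centroid-distance (Dmin) curve.

    Dmin(c) is the smallest pairwise centroid distance after clustering at
    c.  While c is at or below the number of genuinely distinct trajectory
    shapes, centroids stay far apart; once a real cluster is forced to
    split, two centroids land close together and Dmin collapses.  The
    chosen c is therefore the largest value before Dmin first falls below
    ``drop_fraction`` x Dmin at the low end of the range (the smallest
    number of clusters compatible with a large centroid separation).
    """
    lo, hi = c_range
    if lo > hi or lo < 2 or hi >= pm.n:
        raise ValueError(f"invalid cluster range {c_range} for N={pm.n}")
    rng = np.random.default_rng(seed)
    dmin: dict[int, float] = {}
    for c in range(lo, hi + 1):
        fc = fuzzy_cmeans(pm, c, m, seed=int(rng.integers(0, 2**31 - 1)))
        dists = [
            float(np.linalg.norm(fc.centroids[i] - fc.centroids[j]))
            for i in range(c)
            for j in range(i + 1, c)
        ]
        dmin[c] = min(dists)
    ref = dmin[lo]
    chosen = hi
    for c in range(lo + 1, hi + 1):
        if dmin[c] < drop_fraction * ref:
            chosen = c - 1
            break
    return chosen, dmin


def _classify_centroid(
    centroid: np.ndarray, t0_index: int, min_change: float = 0.5,
    monotone_tol: float = 0.1,
) -> str:
    """Label one centroid trajectory from t0 onward (standardized units)."""
    traj = centroid[t0_index:]
    if traj.size < 2:
        return "other"
    delta = traj[-1] - traj[0]
    diffs = np.diff(traj)
    i_max, i_min = int(np.argmax(traj)), int(np.argmin(traj))
    if delta >= min_change and np.all(diffs >= -monotone_tol):
        return "opening"
    if delta <= -min_change and np.all(diffs <= monotone_tol):
        return "closing"
    interior = range(1, traj.size - 1)
    if i_max in interior and traj[i_max] - max(traj[0], traj[-1]) >= min_change:
        return "transient_up"
    if i_min in interior and min(traj[0], traj[-1]) - traj[i_min] >= min_change:
        return "transient_down"
    return "other"


def trajectory_classes(
    fc: FuzzyClustering,
    pm: ProfileMatrix,
    membership_min: float = 0.6,
    t0_time: str = "T0",
) -> pd.Series:
    """Per-window trajectory label from the best cluster's centroid shape.

    A window inherits its highest-membership cluster's label when that
    membership is at least ``membership_min``; otherwise it is ``other``.
    Opening/closing require a >= 0.5 SD monotone change from T0 (the serum
    replacement point) to the final time; transient classes require an
    interior extreme.
    """
    t0_index = pm.times.index(t0_time) if t0_time in pm.times else 0
    cluster_labels = [
        _classify_centroid(fc.centroids[k], t0_index) for k in range(fc.c)
    ]
    best = fc.memberships.argmax(axis=1)
    best_val = fc.memberships.max(axis=1)
    labels = [
        cluster_labels[k] if v >= membership_min else "other"
        for k, v in zip(best, best_val)
    ]
    return pd.Series(labels, index=pm.ids, name="trajectory")
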