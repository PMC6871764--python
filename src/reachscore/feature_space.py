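"""Discovery analytics in the scorer's most informative feature space.

Frames are represented by the ~200 encoder features with the highest global
relevance, projected to a low-dimensional basis (PCA, or PLS against the
group contrast), and partitioned by k-means into subclusters (k = 40 by
default; conclusions are robust for k between 20 and 60).  Each subcluster is
characterized by:

* a **selectivity index** ``(Ns - Nc) / (Ns + Nc)`` over its stroke/control
  frame counts, +1 meaning purely stroke frames, -1 purely control;
* a **movement category**, assigned from the 8 frames nearest the cluster
  center when at least 4 agree (otherwise "not clear");
* **day-wise occupation probabilities** ``p_j(day)`` (frame counts normalized
  per day) and the recovery/compensation ratios ``M1 = (p1+eps)/(p0+eps)``,
  ``M6 = (p6+eps)/(p0+eps)`` with eps = 1e-4 — movements lost to stroke have
  M1 << 1, compensatory novel movements M1 >> 1.

Trajectory-level variability is quantified by the similarity of per-trial
paths through the embedding: the maximum of the normalized cross-correlogram
of concatenated component traces (1 for identical trajectories, robust to a
shifted movement onset), or a dynamic-time-warping distance (0 for identical,
robust to velocity changes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from . import grammar
from .relevance import FeatureImportance

__all__ = [
    "ProjectionModel", "ClusterModel", "RecoveryProfile",
    "select_top_features", "fit_projection", "apply_projection",
    "cluster_frames", "selectivity_index", "assign_categories",
    "day_probabilities", "recovery_ratios", "trajectory_similarity",
    "trajectory_xcorr_max", "trajectory_dtw", "fit_ellipse",
]

RECOVERY_EPSILON = 1e-4


def select_top_features(importance: FeatureImportance | np.ndarray,
                        k: int = 200) -> np.ndarray:
    """Indices of the ``k`` largest importance values, ties to lower index."""
    imp = importance.importance if isinstance(importance, FeatureImportance) \
        else np.asarray(importance, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > imp.size:
        raise ValueError(f"k={k} exceeds feature count {imp.size}")
    # stable sort on (-importance, index) implements the tie rule
    order = np.lexsort((np.arange(imp.size), -imp))
    return np.sort(order[:k])


@dataclass
class ProjectionModel:
    """Embedding basis over the selected informative features."""

    selected_features: np.ndarray
    method: str                      # "pca" | "pls"
    components: np.ndarray           # n_components x n_selected loadings
    center: np.ndarray               # mean over the fitted frames
    explained: np.ndarray            # variance proportion per component

    def __post_init__(self):
        self.selected_features = np.asarray(self.selected_features, dtype=int)


def fit_projection(frames: np.ndarray, selected_features: np.ndarray,
                   method: str = "pca", n_components: int = 7,
                   group_labels: np.ndarray | None = None) -> ProjectionModel:
    """Fit a PCA (or group-contrast PLS) basis on the selected features.

    ``frames`` is (N, F); the fit uses only ``selected_features`` columns,
    centered on their pooled mean.  PCA components are ordered by decreasing
    explained variance; PLS components by covariance with the binary group
    contrast (which PLS requires via ``group_labels``).
    """
    sel = np.asarray(selected_features, dtype=int)
    x = np.asarray(frames, dtype=np.float64)[:, sel]
    if x.shape[0] < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} frames, got {x.shape[0]}")
    center = x.mean(axis=0)
    if method == "pca":
        pca = PCA(n_components=n_components, svd_solver="randomized",
                  random_state=0)
        pca.fit(x)
        comps, explained = pca.components_, pca.explained_variance_ratio_
    elif method == "pls":
        if group_labels is None:
            raise ValueError("pls requires group_labels")
        y = np.asarray(group_labels, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("pls requires two groups")
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(x - center, y - y.mean())
        # x_rotations_ give the projection directions for transform()
        comps = pls.x_rotations_.T
        scores = (x - center) @ comps.T
        explained = scores.var(axis=0) / (x - center).var(axis=0).sum()
    else:
        raise ValueError(f"unknown projection method {method!r}")
    if np.linalg.matrix_rank(x - center) < n_components:
        import warnings
        warnings.warn("input is rank-deficient; trailing components are degenerate")
    return ProjectionModel(selected_features=sel, method=method,
                           components=np.asarray(comps),
                           center=center, explained=np.asarray(explained))


def apply_projection(model: ProjectionModel, frames: np.ndarray) -> np.ndarray:
    """Affine center-then-project map of (N, F) frames to (N, d) scores."""
    x = np.asarray(frames, dtype=np.float64)
    if x.ndim == 1:
        x = x[None]
    x = x[:, model.selected_features] if x.shape[1] != model.center.size else x
    return (x - model.center) @ model.components.T


@dataclass
class ClusterModel:
    """k-means subclusters of embedded frames with per-cluster statistics."""

    k: int
    centers: np.ndarray                    # k x d
    assignments: np.ndarray                # frame -> cluster id
    inertia: float
    stats: pd.DataFrame = field(default=None, repr=False)  # per-cluster table

    def frames_of(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == j)

    def assign(self, embedding: np.ndarray) -> np.ndarray:
        """Assign new embedded frames to their nearest cluster center.

        Lets clusters fitted on the pooled pre/post-stroke days be tracked
        across all recovery days.
        """
        x = np.asarray(embedding, dtype=np.float64)
        d2 = ((x[:, None, :] - self.centers[None]) ** 2).sum(-1)
        return d2.argmin(axis=1)


def cluster_frames(embedding: np.ndarray, k: int = 40, seed: int = 0,
                   group_labels: np.ndarray | None = None,
                   n_restarts: int = 10) -> ClusterModel:
    """Seeded multi-restart k-means over the embedded frames.

    ``group_labels`` (0 control / 1 stroke per frame) populate the
    per-cluster counts and selectivity index.  Same data and seed give
    identical centers.
    """
    x = np.asarray(embedding, dtype=np.float64)
    if x.shape[0] < k:
        raise ValueError(f"{x.shape[0]} frames < k={k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assignments = km.fit_predict(x)
    rows = []
    for j in range(k):
        members = assignments == j
        row = {"cluster": j, "n_frames": int(members.sum())}
        if group_labels is not None:
            g = np.asarray(group_labels)[members]
            ns, nc = int((g == 1).sum()), int((g == 0).sum())
            row.update(n_stroke=ns, n_control=nc,
                       selectivity=selectivity_index(ns, nc))
        rows.append(row)
    return ClusterModel(k=k, centers=km.cluster_centers_,
                        assignments=assignments, inertia=float(km.inertia_),
                        stats=pd.DataFrame(rows).set_index("cluster"))


def selectivity_index(n_stroke: int, n_control: int) -> float:
    """Cluster selectivity ``(Ns - Nc) / (Ns + Nc)``, bounded in [-1, 1].

    +1: only stroke frames; 0: equal counts; -1: only control frames.
    """
    total = n_stroke + n_control
    if total <= 0:
        raise ValueError("selectivity index undefined for an empty cluster")
    return (n_stroke - n_control) / total


def assign_categories(model: ClusterModel, embedding: np.ndarray,
                      frame_labels: np.ndarray, n_probe: int = 8,
                      quorum: int = 4) -> pd.Series:
    """Assign a movement category per cluster from its nearest probe frames.

    For each cluster the ``n_probe`` member frames closest (Euclidean, in
    embedding space) to its center are examined; the modal category is
    assigned when it reaches ``quorum`` frames, with ties — two categories
    both at quorum — and failed quorums labeled "not clear".  Clusters
    smaller than ``n_probe`` use all their members.
    """
    x = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(frame_labels)
    out = {}
    for j in range(model.k):
        members = model.frames_of(j)
        if members.size == 0:
            out[j] = grammar.NOT_CLEAR
            continue
        d = np.linalg.norm(x[members] - model.centers[j], axis=1)
        probe = members[np.argsort(d, kind="stable")[:n_probe]]
        vals, counts = np.unique(labels[probe], return_counts=True)
        top = counts.max()
        if top >= quorum and (counts == top).sum() == 1:
            out[j] = str(vals[counts.argmax()])
        else:
            out[j] = grammar.NOT_CLEAR
    return pd.Series(out, name="category")


def day_probabilities(model: ClusterModel, frame_days: np.ndarray,
                      assignments: np.ndarray | None = None) -> pd.DataFrame:
    """Per-day cluster occupation probabilities.

    ``p_j(day) = n_frames(cluster j, day) / n_frames(day)``; each day's
    probabilities sum to 1 over clusters.  Days with zero frames are excluded
    with a warning.  ``assignments`` defaults to the frames the model was
    fitted on; pass ``model.assign(...)`` output to track clusters over
    frames from additional days.
    """
    days = np.asarray(frame_days)
    assign = model.assignments if assignments is None else np.asarray(assignments)
    if len(days) != len(assign):
        raise ValueError("frame_days and assignments must be aligned")
    out = {}
    for d in sorted(set(days.tolist())):
        mask = days == d
        n_day = int(mask.sum())
        if n_day == 0:
            import warnings
            warnings.warn(f"day {d} has no frames; excluded")
            continue
        counts = np.bincount(assign[mask], minlength=model.k)
        out[d] = counts / n_day
    return pd.DataFrame(out, index=pd.RangeIndex(model.k, name="cluster"))


@dataclass
class RecoveryProfile:
    """Day-probability ratios per cluster: recovery vs. compensation."""

    p0: np.ndarray   # pre-stroke day probability per cluster
    p1: np.ndarray   # day 1 post-stroke
    p6: np.ndarray   # pooled days 6-15
    m1: np.ndarray
    m6: np.ndarray
    epsilon: float = RECOVERY_EPSILON


def recovery_ratios(p0, p1, p6, epsilon: float = RECOVERY_EPSILON) -> RecoveryProfile:
    """Stabilized day-probability ratios ``M = (p + eps) / (p0 + eps)``.

    ``M1 >> 1`` marks a novel (compensatory) movement that appears after
    stroke; ``M1 << 1`` a movement lost to stroke; M6 measures the same
    against the pooled late-recovery days.
    """
    p0 = np.atleast_1d(np.asarray(p0, dtype=float))
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p6 = np.atleast_1d(np.asarray(p6, dtype=float))
    m1 = (p1 + epsilon) / (p0 + epsilon)
    m6 = (p6 + epsilon) / (p0 + epsilon)
    return RecoveryProfile(p0=p0, p1=p1, p6=p6, m1=m1, m6=m6, epsilon=epsilon)


# -- trajectory similarity ---------------------------------------------------

def _concat_components(traj: np.ndarray, n_components: int) -> np.ndarray:
    t = np.asarray(traj, dtype=np.float64)
    if t.ndim != 2:
        raise ValueError("trajectory must be T x d")
    if n_components > t.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds available {t.shape[1]}")
    return t[:, :n_components].T.reshape(-1)  # component-wise concatenation


def trajectory_xcorr_max(a: np.ndarray, b: np.ndarray,
                         n_components: int = 7) -> tuple[float, int]:
    """Maximum of the circular normalized cross-correlogram of two trials.

    Component traces are concatenated into one vector per trial, zero-meaned
    and unit-normed; the correlogram is evaluated at every circular lag via
    FFT.  Identical trajectories give exactly 1 (at lag 0); a circularly
    shifted copy gives 1 at the shift lag, which is what makes the measure
    robust to a different movement onset.  Returns (max value, argmax lag).
    """
    va = _concat_components(a, n_components)
    vb = _concat_components(b, n_components)
    if va.size != vb.size:
        raise ValueError("trajectories must have equal frame counts")
    va = va - va.mean()
    vb = vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0, 0
    corr = np.fft.irfft(np.fft.rfft(va) * np.conj(np.fft.rfft(vb)), n=va.size)
    corr /= na * nb
    lag = int(np.argmax(corr))
    return float(corr[lag]), lag


def trajectory_dtw(a: np.ndarray, b: np.ndarray, n_components: int = 7) -> float:
    """Dynamic-time-warping distance between two embedded trajectories.

    Classic O(T^2) dynamic program over frame-wise Euclidean distances in the
    first ``n_components`` embedding dimensions; 0 for identical trajectories
    and robust to local changes in movement velocity.
    """
    xa = np.asarray(a, dtype=np.float64)[:, :n_components]
    xb = np.asarray(b, dtype=np.float64)[:, :n_components]
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("component counts differ")
    n, m = xa.shape[0], xb.shape[0]
    # pairwise distances
    d = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1))
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        # cumulative DP row by row
        for j in range(1, m + 1):
            acc[i, j] = d[i - 1, j - 1] + min(acc[i - 1, j], acc[i, j - 1],
                                              acc[i - 1, j - 1])
    return float(acc[n, m])


def trajectory_similarity(a: np.ndarray, b: np.ndarray,
                          n_components: int = 7,
                          method: str = "xcorr_max") -> float:
    """Similarity (``xcorr_max``; higher = more similar, identity -> 1) or
    distance (``dtw``; lower = more similar, identity -> 0) of two trials."""
    if method == "xcorr_max":
        return trajectory_xcorr_max(a, b, n_components)[0]
    if method == "dtw":
        return trajectory_dtw(a, b, n_components)
    raise ValueError(f"unknown method {method!r}")


def compare_session_reproducibility(pre_sims: np.ndarray,
                                    post_sims: np.ndarray) -> dict:
    """Test whether pre-stroke trajectory similarities exceed post-stroke.

    One-sided tests of the pre > post alternative on pairwise xcorr_max
    samples (Welch t and Mann-Whitney U).
    """
    t_stat, t_p = stats.ttest_ind(pre_sims, post_sims, equal_var=False,
                                  alternative="greater")
    u_stat, u_p = stats.mannwhitneyu(pre_sims, post_sims, alternative="greater")
    return {"t": float(t_stat), "p_t": float(t_p),
            "u": float(u_stat), "p_u": float(u_p),
            "mean_pre": float(np.mean(pre_sims)),
            "mean_post": float(np.mean(post_sims))}


def fit_ellipse(points: np.ndarray) -> dict:
    """Direct least-squares ellipse fit (visualization only).

    Fits the conic ``ax^2 + bxy + cy^2 + dx + ey + f = 0`` constrained to an
    ellipse (4ac - b^2 = 1) by the Fitzgibbon generalized-eigenvalue method
    and returns center, semi-axes and orientation.  Needs >= 5 non-collinear
    points.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need >= 5 two-dimensional points")
    x, y = pts[:, 0], pts[:, 1]
    if np.linalg.matrix_rank(np.c_[x - x.mean(), y - y.mean()]) < 2:
        raise ValueError("degenerate (collinear) points")
    d1 = np.c_[x * x, x * y, y * y]
    d2 = np.c_[x, y, np.ones_like(x)]
    s1, s2, s3 = d1.T @ d1, d1.T @ d2, d2.T @ d2
    c1 = np.array([[0.0, 0.0, 2.0], [0.0, -1.0, 0.0], [2.0, 0.0, 0.0]])
    try:
        m = np.linalg.inv(c1) @ (s1 - s2 @ np.linalg.solve(s3, s2.T))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate point configuration: {exc}") from exc
    evals, evecs = np.linalg.eig(m)
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.flatnonzero((cond > 0) & np.isfinite(evals))
    if ok.size == 0:
        raise ValueError("no elliptical solution for these points")
    a1 = np.real(evecs[:, ok[np.argmax(np.real(evals[ok]))]])
    a2 = -np.linalg.solve(s3, s2.T) @ a1
    a, b, c, d, e, f = *a1, *a2
    # center and axes from the conic coefficients
    den = b * b - 4 * a * c
    cx = (2 * c * d - b * e) / den
    cy = (2 * a * e - b * d) / den
    num = 2 * (a * e * e + c * d * d + f * b * b - b * d * e - 4 * a * c * f)
    s = np.sqrt((a - c) ** 2 + b * b)
    ax1 = -np.sqrt(num * ((a + c) + s)) / den
    ax2 = -np.sqrt(num * ((a + c) - s)) / den
    theta = 0.5 * np.arctan2(-b, c - a)
    axes = np.sort([ax1, ax2])[::-1]
    return {"center": (float(cx), float(cy)),
            "axes": (float(axes[0]), float(axes[1])),
            "angle": float(theta)}
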