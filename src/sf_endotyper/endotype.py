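"""Cluster-detection engine: PCA reduction, multi-start k-means scan, the
ratio-of-distortions f(K) statistic, the 0.85 decision rule, majority-vote
cluster number, elbow diagnostics and a 2-D embedding."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "ReducedSpace",
    "ClusterScan",
    "ClusterDecision",
    "pca_reduce",
    "kmeans_scan",
    "f_of_k",
    "decide_clustering",
    "decide_from_scan",
    "majority_vote_k",
    "elbow_curve",
    "embed_2d",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.85


@dataclass
class ReducedSpace:
    """PCA scores retaining the minimal number of components reaching the
    variance target."""

    scores: np.ndarray  # samples x n_dims
    variance_fraction: np.ndarray  # per retained component, non-increasing
    n_dims: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.variance_fraction) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")


@dataclass
class ClusterScan:
    k_values: np.ndarray
    distortions: np.ndarray  # S_K, best of n_init starts
    labels: dict[int, np.ndarray]
    n_dims: int
    n_init: int
    seed: int | None
    weights: np.ndarray | None = None  # a_K, filled by f_of_k
    f_values: np.ndarray | None = None
    clustered: bool | None = None
    chosen_k: int | None = None
    votes: dict[str, int] = field(default_factory=dict)


@dataclass
class ClusterDecision:
    clustered: bool
    argmin_k: int
    min_f: float
    threshold: float


def _as_array(matrix) -> np.ndarray:
    if hasattr(matrix, "values") and hasattr(matrix, "ledger"):
        return matrix.values.astype(float)
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float)
    return np.asarray(matrix, dtype=float)


def pca_reduce(matrix, variance_target: float = 0.80) -> ReducedSpace:
    """Unscaled PCA (centering only): retain the smallest number of leading
    components whose cumulative variance fraction reaches the target.

    Component signs are fixed so each component's largest-magnitude loading
    is positive.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must lie in (0, 1]")
    x = _as_array(matrix)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(x)
    frac = pca.explained_variance_ratio_
    # numerical rank cut: drop null components
    nonnull = frac > 1e-12
    scores, frac = scores[:, nonnull], frac[nonnull]
    comps = pca.components_[nonnull]
    flip = np.sign(comps[np.arange(comps.shape[0]), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip[None, :]
    cum = np.cumsum(frac)
    n_dims = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_dims = min(n_dims, scores.shape[1])
    return ReducedSpace(scores[:, :n_dims], frac[:n_dims], n_dims)


def _total_ss(x: np.ndarray) -> float:
    return float(((x - x.mean(axis=0)[None, :]) ** 2).sum())


def _split_largest(x: np.ndarray, labels: np.ndarray, k_prev: int) -> np.ndarray:
    """Initial centers for K = k_prev + 1: previous centroids plus the point
    farthest from its own centroid. Lloyd from this start cannot exceed the
    previous distortion, guaranteeing a monotone scan."""
    centers = np.vstack([x[labels == c].mean(axis=0) for c in range(k_prev)])
    d = ((x - centers[labels]) ** 2).sum(axis=1)
    return np.vstack([centers, x[np.argmax(d)]])


def kmeans_scan(
    space: ReducedSpace, k_max: int, n_init: int = 10, seed: int | None = None
) -> ClusterScan:
    """Best-of-``n_init`` random-start Lloyd k-means for K = 1..k_max.

    S_K is the minimal total within-cluster sum of squared distances over
    the starts; a deterministic split-based fallback enforces the
    non-increasing S_K invariant when random starts fail to find it.
    """
    x = np.asarray(space.scores, dtype=float)
    n = x.shape[0]
    if k_max >= n:
        raise ValueError(f"k_max must be < number of samples ({n})")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(k_max + 1)
    k_values = np.arange(1, k_max + 1)
    distortions = np.empty(k_max)
    labels: dict[int, np.ndarray] = {}
    distortions[0] = _total_ss(x)
    labels[1] = np.zeros(n, dtype=int)
    for k in range(2, k_max + 1):
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=n_init,
            max_iter=300,
            algorithm="lloyd",
            random_state=int(child_seeds[k] % (2**32 - 1)),
        ).fit(x)
        best_inertia, best_labels = km.inertia_, km.labels_
        if best_inertia > distortions[k - 2]:
            init = _split_largest(x, labels[k - 1], k - 1)
            km2 = KMeans(
                n_clusters=k, init=init, n_init=1, max_iter=300, algorithm="lloyd"
            ).fit(x)
            if km2.inertia_ < best_inertia:
                best_inertia, best_labels = km2.inertia_, km2.labels_
        distortions[k - 1] = best_inertia
        labels[k] = best_labels
    if np.any(np.diff(distortions) > 1e-8 * max(distortions[0], 1.0)):
        raise RuntimeError("distortions are not non-increasing in K")
    return ClusterScan(k_values, distortions, labels, space.n_dims, n_init, seed)


def f_of_k(scan: ClusterScan, n_dims: int | None = None) -> np.ndarray:
    """Ratio-of-distortions statistic.

    f(1) = 1; for K >= 2, f(K) = S_K / (a_K * S_{K-1}) when S_{K-1} != 0,
    else 1, with a_2 = 1 - 3/(4 d) and a_K = a_{K-1} + (1 - a_{K-1})/6.
    """
    d = scan.n_dims if n_dims is None else n_dims
    if d < 1:
        raise ValueError("dimension count must be >= 1")
    k_max = len(scan.distortions)
    a = np.ones(k_max)
    f = np.ones(k_max)
    for k in range(2, k_max + 1):
        a[k - 1] = 1 - 3.0 / (4.0 * d) if k == 2 else a[k - 2] + (1 - a[k - 2]) / 6.0
        s_prev = scan.distortions[k - 2]
        f[k - 1] = scan.distortions[k - 1] / (a[k - 1] * s_prev) if s_prev != 0 else 1.0
    scan.weights = a
    scan.f_values = f
    return f


def decide_clustering(
    f_values: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> ClusterDecision:
    """Clustered iff min over K >= 2 of f(K) falls below the threshold."""
    f = np.asarray(f_values, dtype=float)
    if len(f) < 2:
        raise ValueError("need f values for K >= 2")
    tail = f[1:]
    argmin = int(np.argmin(tail)) + 2
    min_f = float(tail.min())
    return ClusterDecision(min_f < threshold, argmin, min_f, threshold)


def decide_from_scan(
    scan: ClusterScan, threshold: float = DEFAULT_THRESHOLD
) -> ClusterDecision:
    if scan.f_values is None:
        f_of_k(scan)
    decision = decide_clustering(scan.f_values, threshold)
    scan.clustered = decision.clustered
    return decision


DEFAULT_VOTE_INDICES = (
    "silhouette",
    "calinski_harabasz",
    "davies_bouldin",
    "gap",
    "f_argmin",
)


def _gap_optimal_k(
    x: np.ndarray, scan: ClusterScan, n_ref: int = 10, seed: int | None = None
) -> int:
    """Gap statistic vote: uniform reference over the bounding box; optimal
    K is the smallest K with gap(K) >= gap(K+1) - s(K+1)."""
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    ks = [int(k) for k in scan.k_values if k >= 2]
    log_wk = np.log(np.maximum(scan.distortions[1:], 1e-300))
    ref = np.empty((n_ref, len(ks)))
    for b in range(n_ref):
        xr = rng.uniform(lo, hi, size=x.shape)
        for i, k in enumerate(ks):
            km = KMeans(
                n_clusters=k,
                init="random",
                n_init=3,
                algorithm="lloyd",
                random_state=int(rng.integers(2**31)),
            ).fit(xr)
            ref[b, i] = np.log(max(km.inertia_, 1e-300))
    gap = ref.mean(axis=0) - log_wk
    s = ref.std(axis=0, ddof=0) * np.sqrt(1 + 1.0 / n_ref)
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            return ks[i]
    return ks[int(np.argmax(gap))]


def majority_vote_k(
    space: ReducedSpace,
    scan: ClusterScan,
    indices=DEFAULT_VOTE_INDICES,
    seed: int | None = None,
) -> int:
    """Modal optimal K across clustering-quality indices; ties broken by
    the smallest K."""
    if scan.clustered is False:
        raise ValueError("majority_vote_k requires a positive clustering decision")
    if len(indices) < 3:
        raise ValueError("need at least 3 voting indices")
    x = np.asarray(space.scores, dtype=float)
    ks = [int(k) for k in scan.k_values if k >= 2]
    votes: dict[str, int] = {}
    per_k_scores: dict[str, dict[int, float]] = {}
    for name in indices:
        if name == "f_argmin":
            if scan.f_values is None:
                f_of_k(scan)
            votes[name] = int(decide_clustering(scan.f_values).argmin_k)
            continue
        if name == "gap":
            votes[name] = _gap_optimal_k(x, scan, seed=seed)
            continue
        scores: dict[int, float] = {}
        for k in ks:
            lab = scan.labels[k]
            if len(np.unique(lab)) < 2:
                continue
            if name == "silhouette":
                scores[k] = silhouette_score(x, lab)
            elif name == "calinski_harabasz":
                scores[k] = calinski_harabasz_score(x, lab)
            elif name == "davies_bouldin":
                scores[k] = -davies_bouldin_score(x, lab)  # lower is better
            else:
                raise ValueError(f"unknown index {name!r}")
        per_k_scores[name] = scores
        votes[name] = min(k for k, v in scores.items() if v == max(scores.values()))
    chosen = _modal_vote(list(votes.values()))
    scan.votes = votes
    scan.chosen_k = chosen
    return chosen


def _modal_vote(votes: list[int]) -> int:
    """Modal K; ties broken by the smallest K."""
    counts = pd.Series(votes).value_counts()
    top = counts[counts == counts.max()].index
    return int(min(top))


def elbow_curve(scan: ClusterScan, plot_path=None) -> pd.DataFrame:
    """Distortion table (K, S_K), sorted by K; optional plot file."""
    table = pd.DataFrame({"K": scan.k_values, "S_K": scan.distortions})
    table = table.sort_values("K").reset_index(drop=True)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(table["K"], table["S_K"], marker="o")
        ax.set_xlabel("K")
        ax.set_ylabel("distortion $S_K$")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=100)
        plt.close(fig)
    return table


def embed_2d(space: ReducedSpace, seed: int = 0) -> np.ndarray:
    """Deterministic 2-D embedding of the reduced space for visualization."""
    x = np.asarray(space.scores, dtype=float)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 samples to embed")
    import umap  # deferred: slow import (numba compilation)

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(15, x.shape[0] - 1),
        random_state=seed,
        n_jobs=1,
    )
    coords = reducer.fit_transform(x)
    if not np.isfinite(coords).all():
        raise RuntimeError("embedding produced non-finite coordinates")
    return np.asarray(coords, dtype=float)
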