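"""From-scratch clustering (k-means, DBSCAN) and internal validation scores.

k-means uses k-means++ seeding, Lloyd iterations with within-run inertia
monotonicity asserted, empty-cluster repair by reseeding at the farthest
point, and best-of-``n_init`` restarts.  Model selection sweeps k over a
range, scoring each clustering by mean silhouette and Calinski–Harabasz
over seeds; the selected k is the silhouette argmax (smaller k on ties).
All distances are Euclidean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Per-row cluster labels plus fit diagnostics (−1 = DBSCAN noise)."""

    labels: np.ndarray
    k: int
    algorithm: str
    centroids: np.ndarray | None = None   # k-means only
    inertia: float | None = None
    seed: int | None = None


@dataclass
class ClusterQuality:
    """Silhouette / Calinski–Harabasz score table over a k sweep."""

    k_values: list[int]
    silhouette_mean: list[float]
    calinski_harabasz_mean: list[float]
    per_seed: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    selected_k: int = 0

    def to_dict(self) -> dict:
        return {
            "k_values": list(self.k_values),
            "silhouette_mean": [float(s) for s in self.silhouette_mean],
            "calinski_harabasz_mean": [float(s) for s in self.calinski_harabasz_mean],
            "selected_k": self.selected_k,
        }


def _pairwise_sq(X: np.ndarray) -> np.ndarray:
    # difference-based form: slower than the expanded inner-product form but
    # numerically exact, which the validation scores need
    return ((X[:, None, :] - X[None, :, :])**2).sum(axis=2)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = ((X - centroids[0])**2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = X[rng.integers(n)]
            continue
        centroids[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centroids[j])**2).sum(axis=1))
    return centroids


def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # nearest centroid; np.argmin returns the lowest index on ties
    d2 = ((X[:, None, :] - centroids[None, :, :])**2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    return labels, d2


def kmeans(matrix: np.ndarray, k: int, seed: int = 0, n_init: int = 10,
           tol: float = 1e-6, max_iter: int = 300) -> ClusterAssignment:
    """Lloyd's k-means with k-means++ seeding, best of ``n_init`` restarts.

    Raises if the within-run inertia ever increases (it cannot, up to
    floating slack — treated as an internal error).
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows n={n}")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None

    for _ in range(n_init):
        centroids = _kmeanspp_init(X, k, rng)
        prev_inertia = np.inf
        labels, d2 = _assign(X, centroids)
        for _ in range(max_iter):
            # repair empty clusters: reseed at the farthest point
            nearest = d2[np.arange(n), labels]
            for j in range(k):
                if not np.any(labels == j):
                    far = int(np.argmax(nearest))
                    centroids[j] = X[far]
                    labels[far] = j
                    nearest[far] = 0.0
            new_centroids = np.stack([X[labels == j].mean(axis=0) for j in range(k)])
            shift = float(np.sqrt(((new_centroids - centroids)**2).sum(axis=1)).max())
            centroids = new_centroids
            labels, d2 = _assign(X, centroids)
            inertia = float(d2[np.arange(n), labels].sum())
            if inertia > prev_inertia + 1e-9 * max(1.0, prev_inertia):
                raise AssertionError(
                    f"k-means inertia increased: {prev_inertia} -> {inertia}")
            prev_inertia = inertia
            if shift <= tol:
                break
        if best is None or prev_inertia < best[0]:
            best = (prev_inertia, labels.copy(), centroids.copy())

    inertia, labels, centroids = best
    return ClusterAssignment(labels=labels, k=k, algorithm="kmeans",
                             centroids=centroids, inertia=inertia, seed=seed)


def dbscan(matrix: np.ndarray, eps: float = 0.5, min_samples: int = 5
           ) -> ClusterAssignment:
    """Density-based clustering with core/border/noise labeling.

    A point is core if its eps-neighborhood (including itself) holds at
    least ``min_samples`` points.  Cluster ids follow discovery order from
    row 0; noise points get label −1.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    D2 = _pairwise_sq(X)
    neighbors = [np.where(D2[i] <= eps**2)[0] for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cluster
        frontier = [i]
        while frontier:
            p = frontier.pop(0)
            for q in neighbors[p]:
                if labels[q] == -1:
                    labels[q] = cluster
                    if core[q]:
                        frontier.append(q)
        cluster += 1
    return ClusterAssignment(labels=labels, k=cluster, algorithm="dbscan")


def _validate_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    keep = labels >= 0
    uniq = np.unique(labels[keep])
    if uniq.size < 2:
        raise ValueError("need at least 2 non-noise clusters")
    return keep


def silhouette(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient; DBSCAN noise (−1) is excluded.

    Per point: ``(b − a) / max(a, b)`` with ``a`` the mean distance to its
    own cluster's other members and ``b`` the smallest mean distance to
    another cluster.  Points in singleton clusters contribute 0.
    """
    keep = _validate_labels(labels)
    X = np.asarray(matrix, dtype=float)[keep]
    lab = np.asarray(labels)[keep]
    D = np.sqrt(_pairwise_sq(X))
    uniq = np.unique(lab)
    scores = np.zeros(len(lab))
    for i in range(len(lab)):
        own = lab == lab[i]
        n_own = int(own.sum())
        if n_own == 1:
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, lab == c].mean() for c in uniq if c != lab[i])
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def calinski_harabasz(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Between/within dispersion ratio scaled by degrees of freedom.

    Returns ``inf`` (logged) when the within-group sum of squares is zero.
    """
    keep = _validate_labels(labels)
    X = np.asarray(matrix, dtype=float)[keep]
    lab = np.asarray(labels)[keep]
    n = len(lab)
    uniq = np.unique(lab)
    k = uniq.size
    overall = X.mean(axis=0)
    bgss = wgss = 0.0
    for c in uniq:
        Xc = X[lab == c]
        mu = Xc.mean(axis=0)
        bgss += len(Xc) * float(((mu - overall)**2).sum())
        wgss += float(((Xc - mu)**2).sum())
    if wgss == 0:
        logger.warning("calinski_harabasz: zero within-group SS, returning inf")
        return float("inf")
    return (bgss / (k - 1)) / (wgss / (n - k))


def select_k(matrix: np.ndarray, k_range: range | list[int] = range(2, 13),
             seeds: list[int] = (0,), clusterer: str = "kmeans",
             n_init: int = 10, eps: float = 0.5, min_samples: int = 5
             ) -> ClusterQuality:
    """Sweep k, score each clustering, and pick the silhouette argmax.

    Scores are averaged over ``seeds``; ties in the mean silhouette resolve
    to the smaller k.  The full score table is returned so the fluctuation
    pattern across k can be inspected alongside the automatic choice.
    (DBSCAN fixes its own cluster count, so the sweep applies to k-means.)
    """
    X = np.asarray(matrix, dtype=float)
    k_values = list(k_range)
    if not k_values or k_values[0] < 2 or k_values[-1] > X.shape[0] - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    if clusterer != "kmeans":
        raise ValueError("the k sweep applies to k-means only")
    sil_mean, ch_mean, per_seed = [], [], {}
    for k in k_values:
        ss, cc = [], []
        for s in seeds:
            fit = kmeans(X, k, seed=s, n_init=n_init)
            ss.append(silhouette(X, fit.labels))
            cc.append(calinski_harabasz(X, fit.labels))
        per_seed[k] = list(zip(ss, cc))
        sil_mean.append(float(np.mean(ss)))
        ch_mean.append(float(np.mean(cc)))
    best = int(np.argmax(sil_mean))  # argmax returns first (smallest k) on ties
    return ClusterQuality(k_values=k_values, silhouette_mean=sil_mean,
                          calinski_harabasz_mean=ch_mean, per_seed=per_seed,
                          selected_k=k_values[best])
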