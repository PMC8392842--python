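"""Dimensionality reduction: PCA and exact (quadratic-time) t-SNE.

t-SNE follows the original formulation: per-row Gaussian bandwidths found by
bisection so each conditional distribution hits the target perplexity,
symmetrized input affinities, Student-t (1 df) low-dimensional kernel, and
gradient descent with early exaggeration, momentum switching and adaptive
per-parameter gains.  Cohorts here are a few hundred rows, so the O(n^2)
exact gradient is the right tool; no Barnes–Hut approximation is provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class EmbeddingConfig:
    """Hyperparameters for dimensionality reduction.

    Defaults are the canonical t-SNE settings: perplexity 30, learning rate
    200, 1000 iterations, early exaggeration x12 for the first 250
    iterations, momentum 0.5 switching to 0.8 at iteration 250.
    """

    method: str = "tsne"            # {"none", "pca", "tsne"}
    out_dims: int = 2
    perplexity: float = 30.0
    tsne_iters: int = 1000
    learning_rate: float = 200.0
    early_exaggeration: float = 12.0
    exaggeration_iters: int = 250
    momentum_switch_iter: int = 250
    initial_momentum: float = 0.5
    final_momentum: float = 0.8
    pca_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("none", "pca", "tsne"):
            raise ValueError(f"unknown reduction method {self.method!r}")
        if self.perplexity <= 0 or self.learning_rate <= 0:
            raise ValueError("perplexity and learning_rate must be positive")


@dataclass
class Embedding:
    """Result of a dimensionality reduction."""

    coords: np.ndarray
    method: str
    kl_trace: np.ndarray | None = None                 # t-SNE only
    explained_variance_ratio: np.ndarray | None = None  # PCA only
    sigmas: np.ndarray | None = None                    # t-SNE bandwidths
    config: EmbeddingConfig | None = field(default=None, repr=False)


def pca_reduce(matrix: np.ndarray, n_components: int) -> Embedding:
    """Project centered data onto its top principal axes.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making the output deterministic.
    """
    X = np.asarray(matrix, dtype=float)
    n, d = X.shape
    if n_components > min(n - 1, d):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, d)={min(n - 1, d)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    coords = Xc @ Vt[:n_components].T
    return Embedding(coords=coords, method="pca",
                     explained_variance_ratio=evr[:n_components])


def _entropy_and_prow(d2_row: np.ndarray, beta: float) -> tuple[float, np.ndarray]:
    """Shannon entropy (nats) and conditional distribution at precision beta."""
    p = np.exp(-d2_row * beta)
    sum_p = p.sum()
    if sum_p <= 0:
        return 0.0, np.zeros_like(p)
    # H = log(sum_p) + beta * sum(d2 * p) / sum_p
    h = np.log(sum_p) + beta * float((d2_row * p).sum()) / sum_p
    return h, p / sum_p


def perplexity_bisection(d2_row: np.ndarray, perplexity: float,
                         tol: float = 1e-4, max_iter: int = 200
                         ) -> tuple[float, np.ndarray]:
    """Find the Gaussian precision matching a target perplexity by bisection.

    ``d2_row`` holds squared distances from one point to all others (self
    excluded).  Returns ``(beta, p_row)`` with ``beta = 1/(2 sigma^2)`` such
    that the conditional distribution's log-perplexity (= entropy in nats)
    is within ``tol`` of ``log(perplexity)``.
    """
    target = np.log(perplexity)
    beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
    h, p = _entropy_and_prow(d2_row, beta)
    for _ in range(max_iter):
        if abs(h - target) <= tol:
            break
        if h > target:          # too flat -> increase precision
            beta_lo = beta
            beta = beta * 2.0 if np.isinf(beta_hi) else (beta + beta_hi) / 2.0
        else:
            beta_hi = beta
            beta = beta / 2.0 if beta_lo == 0.0 else (beta + beta_lo) / 2.0
        h, p = _entropy_and_prow(d2_row, beta)
    return beta, p


def _joint_probabilities(X: np.ndarray, perplexity: float) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    sq = (X**2).sum(axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    P = np.zeros((n, n))
    sigmas = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        beta, p_row = perplexity_bisection(D2[i, mask], perplexity)
        P[i, mask] = p_row
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta))
    P = (P + P.T) / (2.0 * n)
    return np.maximum(P, _EPS), sigmas


def tsne_reduce(matrix: np.ndarray, config: EmbeddingConfig | None = None) -> Embedding:
    """Exact t-SNE embedding of ``matrix`` into ``config.out_dims`` dimensions.

    The per-iteration KL divergence (on the un-exaggerated affinities) is
    recorded in ``kl_trace``.  Reproducible under ``config.seed``.
    """
    cfg = config or EmbeddingConfig()
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("t-SNE needs at least 4 rows")
    if np.ptp(X, axis=0).max() == 0:
        raise ValueError("all rows identical: no distance structure to embed")
    perplexity = cfg.perplexity
    limit = (n - 1) / 3.0
    if perplexity >= limit:
        perplexity = max(1.0, limit - 1e-9)
        warnings.warn(
            f"perplexity {cfg.perplexity} too large for n={n}; shrunk to "
            f"{perplexity:.2f}", stacklevel=2)

    P, sigmas = _joint_probabilities(X, perplexity)
    rng = np.random.default_rng(cfg.seed)
    Y = rng.normal(0.0, 1e-4, size=(n, cfg.out_dims))
    dY = np.zeros_like(Y)
    gains = np.ones_like(Y)
    kl_trace = np.empty(cfg.tsne_iters)

    for it in range(cfg.tsne_iters):
        sq = (Y**2).sum(axis=1)
        num = 1.0 / (1.0 + np.maximum(sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T), 0.0))
        np.fill_diagonal(num, 0.0)
        Q = np.maximum(num / num.sum(), _EPS)

        P_eff = P * cfg.early_exaggeration if it < cfg.exaggeration_iters else P
        W = (P_eff - Q) * num
        grad = 4.0 * ((np.diag(W.sum(axis=1)) - W) @ Y)

        momentum = (cfg.initial_momentum if it < cfg.momentum_switch_iter
                    else cfg.final_momentum)
        inc = np.sign(grad) != np.sign(dY)
        gains = np.where(inc, gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        dY = momentum * dY - cfg.learning_rate * gains * grad
        Y = Y + dY
        Y = Y - Y.mean(axis=0)

        kl_trace[it] = float((P * np.log(P / Q)).sum())

    return Embedding(coords=Y, method="tsne", kl_trace=kl_trace,
                     sigmas=sigmas, config=cfg)


def reduce_matrix(matrix: np.ndarray, config: EmbeddingConfig) -> Embedding:
    """Dispatch on ``config.method`` (``none`` returns the input as-is)."""
    if config.method == "none":
        return Embedding(coords=np.asarray(matrix, dtype=float), method="none")
    if config.method == "pca":
        return pca_reduce(matrix, config.pca_components)
    return tsne_reduce(matrix, config)
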