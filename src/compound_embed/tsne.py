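"""Exact t-SNE engine with a per-iteration hook.

This is a standard exact (O(n^2)) t-SNE: Gaussian input affinities
calibrated to a target perplexity by per-point bisection, Student-t
low-dimensional kernel, gradient descent with momentum and per-parameter
gains, and an early-exaggeration phase.  It exists as its own module
because the alignment force must be interleaved with individual gradient
steps, which batch ``fit`` APIs do not expose.  All state lives in
:class:`TsneOptimizer`; a caller may mutate ``Y`` between steps.

Everything is plain deterministic numpy: given the same initialization
the trajectory is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

_EPS = 1e-12


def squared_distances(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(X, float), "sqeuclidean"))


def joint_probabilities(X: np.ndarray, perplexity: float,
                        tol: float = 1e-5, max_iter: int = 64) -> np.ndarray:
    """Symmetrized joint affinities P with row entropy == log(perplexity).

    Per-point Gaussian precisions are found by bisection on the Shannon
    entropy of the conditional distribution (self excluded), then the
    conditionals are symmetrized and normalized to sum to 1.
    """
    n = X.shape[0]
    if not (0 < perplexity < n):
        raise ValueError(f"perplexity must lie in (0, n); got {perplexity} "
                         f"for n={n}")
    D = squared_distances(X)
    np.fill_diagonal(D, np.inf)
    Dfin = np.where(np.isfinite(D), D, 0.0)
    target = np.log(perplexity)
    beta = np.ones(n)
    beta_lo = np.full(n, -np.inf)
    beta_hi = np.full(n, np.inf)
    P = np.empty_like(D)
    for _ in range(max_iter):
        P = np.exp(-D * beta[:, None])
        sumP = np.maximum(P.sum(axis=1), _EPS)
        # H = entropy of the conditional distribution, in nats
        H = np.log(sumP) + beta * np.einsum("ij,ij->i", Dfin, P) / sumP
        diff = H - target
        if np.all(np.abs(diff) < tol):
            break
        too_high = diff > 0  # entropy too high -> narrow kernel
        beta_lo = np.where(too_high, beta, beta_lo)
        beta_hi = np.where(~too_high, beta, beta_hi)
        beta = np.where(
            too_high,
            np.where(np.isinf(beta_hi), beta * 2, (beta + beta_hi) / 2),
            np.where(np.isinf(beta_lo), beta / 2, (beta + beta_lo) / 2),
        )
    P /= np.maximum(P.sum(axis=1, keepdims=True), _EPS)
    P = (P + P.T) / (2.0 * n)
    return np.maximum(P, _EPS)


def kl_divergence(P: np.ndarray, Y: np.ndarray) -> float:
    """The t-SNE loss KL(P || Q) at embedding Y."""
    num = 1.0 / (1.0 + squared_distances(Y))
    np.fill_diagonal(num, 0.0)
    Q = np.maximum(num / num.sum(), _EPS)
    return float(np.sum(P * np.log(P / Q)))


class TsneOptimizer:
    """Gradient-descent state for one embedding.

    Parameters follow the conventional implementation: momentum 0.5
    during early exaggeration and 0.8 afterwards, per-parameter gains in
    [0.01, inf), learning rate ``n / exaggeration`` when ``"auto"``.
    """

    def __init__(self, P: np.ndarray, Y0: np.ndarray,
                 learning_rate: float | str = "auto",
                 exaggeration: float = 12.0):
        self.P = P
        self.Y = np.array(Y0, dtype=float, copy=True)
        n = self.Y.shape[0]
        # n / exaggeration keeps the early phase in the regime where the
        # initialization's global arrangement survives optimization; a
        # larger rate visibly scrambles cluster positions.
        if learning_rate == "auto":
            learning_rate = n / max(exaggeration, 1.0)
        self.learning_rate = float(learning_rate)
        self.velocity = np.zeros_like(self.Y)
        self.gains = np.ones_like(self.Y)

    def gradient(self, exaggeration: float = 1.0) -> np.ndarray:
        Y = self.Y
        num = 1.0 / (1.0 + squared_distances(Y))
        np.fill_diagonal(num, 0.0)
        Q = np.maximum(num / num.sum(), _EPS)
        W = (self.P * exaggeration - Q) * num
        return 4.0 * (W.sum(axis=1)[:, None] * Y - W @ Y)

    def step(self, exaggeration: float = 1.0, momentum: float = 0.8) -> None:
        grad = self.gradient(exaggeration)
        inc = np.sign(grad) != np.sign(self.velocity)
        self.gains = np.where(inc, self.gains + 0.2, self.gains * 0.8)
        np.clip(self.gains, 0.01, None, out=self.gains)
        self.velocity = momentum * self.velocity \
            - self.learning_rate * self.gains * grad
        self.Y += self.velocity
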