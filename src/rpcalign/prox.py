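"""Proximal operators and norms for the weighted-nuclear / L2,1 decomposition.

The low-rank update is a weighted singular-value thresholding with weights
``w_i = b*sqrt(n) / (sigma_i + eps)`` (larger singular values are shrunk
less, preserving the dominant shared structure of the image stack).  The
sparse-error update is the L2,1 proximal map, which shrinks whole columns
(entire images) toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import sqrt

import numpy as np

__all__ = [
    "WeightScheme",
    "weighted_svt",
    "svt",
    "l21_shrink",
    "soft_threshold",
    "weighted_nuclear_norm",
    "l21_norm",
]


@dataclass(frozen=True)
class WeightScheme:
    """Constants of the singular-value weight family.

    Attributes
    ----------
    b : float
        Positive weight numerator constant.
    C : float or None
        Constant of the closed-form threshold; when None it is resolved to
        ``b * sqrt(n)`` for the matrix at hand (n = number of columns).
    epsilon : float
        Small positive guard against division by zero (<= 1e-8).
    literal : bool
        Use the literal weight reading ``w_i = b / (n*sigma_i + eps)``
        instead of the default ``b*sqrt(n) / (sigma_i + eps)``.
    """

    b: float = 1.0
    C: float | None = None
    epsilon: float = 1e-16
    literal: bool = False

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("weight constant b must be positive")
        if self.C is not None and self.C <= 0:
            raise ValueError("closed-form constant C must be positive")
        if not (0 < self.epsilon <= 1e-8):
            raise ValueError("epsilon must lie in (0, 1e-8]")

    def resolved_C(self, n: int) -> float:
        return self.C if self.C is not None else self.b * sqrt(n)

    def resolve(self, n: int) -> "WeightScheme":
        """Scheme with C pinned for a matrix with ``n`` columns."""
        return self if self.C is not None else replace(self, C=self.b * sqrt(n))

    def weights(self, sigmas: np.ndarray, n: int) -> np.ndarray:
        s = np.asarray(sigmas, float)
        if self.literal:
            return self.b / (n * s + self.epsilon)
        return self.b * sqrt(n) / (s + self.epsilon)


def shrink_singular_values(sigmas: np.ndarray, C: float, epsilon: float) -> np.ndarray:
    """Closed-form stationary shrinkage of singular values.

    For each input sigma: c1 = sigma - eps, c2 = (sigma + eps)^2 - 4C;
    output 0 when c2 < 0, else (c1 + sqrt(c2)) / 2 (clamped at 0).  This is
    the stationary point of soft-thresholding with the adaptive threshold
    C / (sigma + eps).
    """
    s = np.asarray(sigmas, float)
    c1 = s - epsilon
    c2 = (s + epsilon) ** 2 - 4.0 * C
    out = np.where(c2 >= 0, 0.5 * (c1 + np.sqrt(np.maximum(c2, 0.0))), 0.0)
    return np.maximum(out, 0.0)


def weighted_svt(K: np.ndarray, scheme: WeightScheme) -> np.ndarray:
    """Weighted singular-value thresholding (the weighted-nuclear-norm prox).

    Computes the SVD of K, applies :func:`shrink_singular_values` to the
    spectrum, and reassembles with the singular vectors unchanged.  Every
    output singular value lies in [0, sigma_i(K)], so this is a spectral
    shrinkage and never increases rank.
    """
    K = np.asarray(K, float)
    if not np.all(np.isfinite(K)):
        raise ValueError("weighted_svt input must be finite")
    C = scheme.resolved_C(K.shape[1])
    if C <= 0:
        raise ValueError("closed-form constant C must be positive")
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    s_hat = shrink_singular_values(s, C, scheme.epsilon)
    return (U * s_hat) @ Vt


def svt(K: np.ndarray, tau: float) -> np.ndarray:
    """Classical singular-value soft-thresholding (nuclear-norm prox)."""
    K = np.asarray(K, float)
    if not np.all(np.isfinite(K)):
        raise ValueError("svt input must be finite")
    if tau < 0:
        raise ValueError("threshold must be nonnegative")
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    return (U * np.maximum(s - tau, 0.0)) @ Vt


def l21_shrink(U: np.ndarray, kappa: float) -> np.ndarray:
    """Column-wise L2,1 shrinkage: the prox of ``kappa * sum_j ||E_j||_2``.

    Column j becomes ``(1 - kappa/||U_j||) * U_j`` when ``||U_j|| >= kappa``
    and the zero column otherwise.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    U = np.asarray(U, float)
    if not np.all(np.isfinite(U)):
        raise ValueError("l21_shrink input must be finite")
    norms = np.linalg.norm(U, axis=0)
    scale = np.zeros_like(norms)
    nz = norms >= kappa
    scale[nz] = (norms[nz] - kappa) / norms[nz]
    return U * scale


def soft_threshold(X: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise soft-thresholding (L1 prox), used by the convex baseline."""
    X = np.asarray(X, float)
    return np.sign(X) * np.maximum(np.abs(X) - tau, 0.0)


def weighted_nuclear_norm(L: np.ndarray, scheme: WeightScheme) -> float:
    """``sum_i w_i * sigma_i(L)`` with the scheme's singular-value weights."""
    L = np.asarray(L, float)
    if not np.all(np.isfinite(L)):
        raise ValueError("weighted_nuclear_norm input must be finite")
    s = np.linalg.svd(L, compute_uv=False)
    w = scheme.weights(s, L.shape[1])
    return float(np.sum(w * s))


def l21_norm(E: np.ndarray) -> float:
    """Sum of column Euclidean norms."""
    E = np.asarray(E, float)
    if not np.all(np.isfinite(E)):
        raise ValueError("l21_norm input must be finite")
    return float(np.linalg.norm(E, axis=0).sum())
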