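"""Closed-form Mahalanobis metric learning (CFML), regularized.

Given labeled feature vectors, let ``M_S`` and ``M_D`` be the mean outer
products of feature differences over all same-label (similar) and
different-label (dissimilar) unordered pairs.  CFML seeks a projection
``L`` (d x D) minimizing ``tr(L (M_S - M_D) L^T)`` subject to the
regularized constraint ``L (M_S + lambda I) L^T = I``: same-class pairs
become close and different-class pairs far under the squared Mahalanobis
distance ``d(x_i, x_j) = ||L (x_i - x_j)||^2``.

The solution is closed-form: rows of ``L`` are the eigenvectors of the
generalized symmetric eigenproblem ``M_D v = mu (M_S + lambda I) v`` with
the ``d`` largest eigenvalues, scaled so ``v^T (M_S + lambda I) v = 1``.
The ridge ``lambda`` handles the small-sample large-feature regime where
``M_S`` is (near-)singular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "PairScatter",
    "MetricModel",
    "compute_scatters",
    "fit_cfml",
    "mahalanobis_distance",
    "pairwise_distances",
]


@dataclass
class PairScatter:
    """Mean pairwise-difference scatter over similar and dissimilar pairs."""

    m_similar: np.ndarray  # (D, D)
    m_dissimilar: np.ndarray  # (D, D)
    n_similar: int
    n_dissimilar: int


@dataclass
class MetricModel:
    """Learned projection defining the squared Mahalanobis distance."""

    projection: np.ndarray  # L, (d, D)
    lam: float
    eigenvalues: np.ndarray | None = None  # generalized eigenvalues of the kept rows

    @property
    def dim_out(self) -> int:
        return self.projection.shape[0]

    @property
    def dim_in(self) -> int:
        return self.projection.shape[1]


def compute_scatters(features: np.ndarray, labels: np.ndarray) -> PairScatter:
    """Exact mean outer products over all unordered label pairs.

    Uses the Gram identity ``sum_{i<j} (x_i - x_j)(x_i - x_j)^T =
    n X^T X - s s^T`` (``s`` the column sum) per label group and overall,
    which matches the explicit pair loop in exact arithmetic.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(features)
    if n != len(labels):
        raise ValueError("one label per feature row required")

    def unordered_sum(x: np.ndarray) -> np.ndarray:
        s = x.sum(axis=0)
        return len(x) * (x.T @ x) - np.outer(s, s)

    total = unordered_sum(features)
    sim = np.zeros_like(total)
    n_sim = 0
    for lab in np.unique(labels):
        grp = features[labels == lab]
        if len(grp) >= 2:
            sim += unordered_sum(grp)
            n_sim += len(grp) * (len(grp) - 1) // 2
    n_all = n * (n - 1) // 2
    n_dis = n_all - n_sim
    if n_sim == 0:
        raise ValueError("no similar pairs: every class has a single sample")
    if n_dis == 0:
        raise ValueError("no dissimilar pairs: all samples share one label")
    m_s = sim / n_sim
    m_d = (total - sim) / n_dis
    return PairScatter(
        m_similar=(m_s + m_s.T) / 2.0,
        m_dissimilar=(m_d + m_d.T) / 2.0,
        n_similar=n_sim,
        n_dissimilar=n_dis,
    )


def fit_cfml(scatter: PairScatter, lam: float = 1e-6, dim_out: int = 2) -> MetricModel:
    """Solve the regularized CFML eigenproblem for the projection ``L``.

    Deterministic: eigenvalues sorted descending (stable index tie-break)
    and each eigenvector's sign fixed by making its largest-magnitude
    entry positive.  If ``dim_out`` exceeds the available eigenvectors it
    is reduced with a warning.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    m_s = np.asarray(scatter.m_similar, dtype=np.float64)
    m_d = np.asarray(scatter.m_dissimilar, dtype=np.float64)
    dim = m_s.shape[0]
    if not (1 <= dim_out <= dim):
        if dim_out > dim:
            warnings.warn(f"requested {dim_out} projection rows, only {dim} available")
            dim_out = dim
        else:
            raise ValueError("projection dimension must be at least 1")
    b = m_s + lam * np.eye(dim)
    eigvals, eigvecs = linalg.eigh(m_d, b)  # ascending; v^T B v = 1
    order = np.argsort(-eigvals, kind="stable")[:dim_out]
    vecs = eigvecs[:, order]
    # re-enforce the constraint scaling explicitly (guards against solver
    # normalization drift) and fix signs for reproducibility
    scale = np.sqrt(np.einsum("ij,jk,ki->i", vecs.T, b, vecs))
    vecs = vecs / scale
    flip = np.abs(vecs).argmax(axis=0)
    signs = np.sign(vecs[flip, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    return MetricModel(
        projection=vecs.T, lam=float(lam), eigenvalues=eigvals[order]
    )


def mahalanobis_distance(model: MetricModel, x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Squared Mahalanobis distance ``||L (x_i - x_j)||^2``."""
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    if x_i.shape != (model.dim_in,) or x_j.shape != (model.dim_in,):
        raise ValueError(f"expected vectors of dimension {model.dim_in}")
    z = model.projection @ (x_i - x_j)
    return float(z @ z)


def pairwise_distances(model: MetricModel, query: np.ndarray, dataset: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distances from one query to every dataset row."""
    diff = np.asarray(dataset, dtype=np.float64) - np.asarray(query, dtype=np.float64)
    proj = diff @ model.projection.T
    return np.einsum("ij,ij->i", proj, proj)
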