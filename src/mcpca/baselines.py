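"""Linear PCA and polynomial-kernel KPCA baselines with explained-variance
accounting comparable to the Ky Fan objective of the core optimizer."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import DosageMatrix
from .errors import DataError

__all__ = ["EmbeddingResult", "pca", "kpca"]


@dataclass
class EmbeddingResult:
    """Scores and spectrum of a baseline embedding."""

    method: str
    scores: np.ndarray
    eigenvalues: np.ndarray
    explained_fraction: float
    q: int
    kernel_params: dict = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)
    seed: int | None = None
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_sweeps: int = 0


def _as_array(X):
    if isinstance(X, DosageMatrix):
        return np.asarray(X.values, dtype=float), list(X.sample_ids)
    return np.asarray(X, dtype=float), []


def pca(X, q: int, standardize: bool = True) -> EmbeddingResult:
    """PCA via the correlation (standardize=True) or covariance matrix.

    explained_fraction = sum of the top-q eigenvalues over the sum of all
    eigenvalues; scores are the projections of the centered (and scaled)
    data onto the top-q eigenvectors.  Constant columns are dropped with a
    warning when standardizing; q beyond the rank is truncated.
    """
    X, sample_ids = _as_array(X)
    n, p = X.shape
    if n < 2:
        raise DataError("need at least 2 samples")
    Z = X - X.mean(axis=0)
    if standardize:
        sd = Z.std(axis=0)  # divisor n, matching the core convention
        keep = sd > 0
        if not np.all(keep):
            warnings.warn(f"dropping {int((~keep).sum())} constant column(s)")
            Z = Z[:, keep]
            sd = sd[keep]
        if Z.shape[1] == 0:
            raise DataError("all columns constant")
        Z = Z / sd
    p_eff = Z.shape[1]
    rank = min(n - 1, p_eff)
    if q < 1:
        raise DataError("q must be >= 1")
    if q > rank:
        warnings.warn(f"q={q} exceeds rank {rank}; truncating")
        q = rank
    # spectrum of Z^T Z / n via SVD (cheaper of the two dimensions)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    lam = np.zeros(p_eff)
    lam[: s.size] = s**2 / n
    total = lam.sum()
    scores = Z @ Vt[:q].T
    for r in range(q):  # deterministic sign: largest |loading| positive
        i = int(np.argmax(np.abs(Vt[r])))
        if Vt[r, i] < 0:
            scores[:, r] *= -1
    return EmbeddingResult(
        method="pca",
        scores=scores,
        eigenvalues=lam,
        explained_fraction=float(lam[:q].sum() / total),
        q=q,
        kernel_params={"standardize": standardize},
        sample_ids=sample_ids,
    )


def kpca(
    X,
    q: int,
    degree: int = 2,
    scale: float | None = None,
    offset: float = 1.0,
    standardize: bool = True,
) -> EmbeddingResult:
    """Polynomial-kernel PCA: G(i, k) = (scale * <x_i, x_k> + offset)^degree,
    double-centered and eigen-decomposed.

    ``standardize`` (default) centers and unit-scales each column first, the
    kernel counterpart of correlation-based PCA; ``scale`` defaults to 1/p.
    explained_fraction = sum of the top-q eigenvalues over the trace of the
    centered Gram; scores are the eigenvectors scaled by sqrt(eigenvalue).
    Small negative eigenvalues (numerical) are clipped to zero; larger ones
    trigger a warning.
    """
    X, sample_ids = _as_array(X)
    n, p = X.shape
    if n < 2:
        raise DataError("need at least 2 samples")
    if not 1 <= q <= n:
        raise DataError(f"q must be in [1, {n}], got {q}")
    if standardize:
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0)
        keep = sd > 0
        if not np.all(keep):
            warnings.warn(f"dropping {int((~keep).sum())} constant column(s)")
            Xc = Xc[:, keep]
            sd = sd[keep]
        X = Xc / sd
        p = X.shape[1]
    if scale is None:
        scale = 1.0 / p
    G = (scale * (X @ X.T) + offset) ** degree
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    Gc = H @ G @ H
    Gc = (Gc + Gc.T) / 2
    lam, V = np.linalg.eigh(Gc)
    lam, V = lam[::-1], V[:, ::-1]
    if lam.min() < -1e-8 * max(1.0, lam.max()):
        warnings.warn("centered Gram has negative eigenvalues; clipping to 0")
    lam = np.maximum(lam, 0.0)
    total = lam.sum()
    if total <= 0:
        raise DataError("centered Gram is identically zero")
    scores = V[:, :q] * np.sqrt(lam[:q])
    for r in range(q):
        i = int(np.argmax(np.abs(scores[:, r])))
        if scores[i, r] < 0:
            scores[:, r] *= -1
    return EmbeddingResult(
        method="kpca",
        scores=scores,
        eigenvalues=lam,
        explained_fraction=float(lam[:q].sum() / total),
        q=q,
        kernel_params={"degree": degree, "scale": scale, "offset": offset,
                       "standardize": standardize},
        sample_ids=sample_ids,
    )
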