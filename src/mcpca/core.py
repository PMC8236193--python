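"""Block-coordinate maximization of the Ky Fan q-norm of the transformed
covariance matrix over per-feature standardized transformations.

Each discrete feature j carries a table phi_j mapping its categories to real
values, standardized to sample mean 0 and sample second moment 1 (divisor n).
The optimizer alternates between (a) taking the projector W = U U^T onto the
top-q eigenspace of the current transformed covariance K and (b) updating
each phi_j in turn to the standardized conditional mean of the surrogate
g_j(i) = sum_{j' != j} W(j, j') phi_{j'}(x_i^{j'}), which maximizes the
U-fixed surrogate trace(U^T K U).  The objective — the sum of the top q
eigenvalues of K — is non-decreasing across sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import DiscreteMatrix
from .errors import DataError, DegenerateTransformError

__all__ = [
    "TransformTable",
    "MCPCAResult",
    "standardize_transform",
    "transformed_covariance",
    "kyfan",
    "fit_mcpca",
    "explained_fraction",
]

_VAR_EPS = 1e-12


def standardize_transform(phi, counts) -> np.ndarray:
    """Standardize a per-category table to weighted mean 0, variance 1.

    Weights are the empirical category frequencies counts/n (divisor n).
    Raises :class:`DegenerateTransformError` when the table is constant on
    the observed categories.
    """
    phi = np.asarray(phi, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if phi.shape != counts.shape:
        raise DataError("phi and counts must have the same length")
    if np.count_nonzero(counts) < 2:
        raise DataError("need at least 2 categories with nonzero count")
    w = counts / counts.sum()
    mu = float(w @ phi)
    var = float(w @ (phi - mu) ** 2)
    if var < _VAR_EPS:
        raise DegenerateTransformError(
            "transform is constant on the observed categories"
        )
    return (phi - mu) / np.sqrt(var)


@dataclass
class TransformTable:
    """Per-feature category -> value tables, standardized w.r.t. the
    empirical category frequencies."""

    tables: list[np.ndarray]
    counts: list[np.ndarray]

    @classmethod
    def identity(cls, D: DiscreteMatrix) -> "TransformTable":
        """Standardized raw labels: phi_j(c) = standardize(c)."""
        tables, counts = [], []
        for j in range(D.n_features):
            cnt = np.bincount(D.labels[:, j], minlength=D.n_categories[j]).astype(float)
            tables.append(standardize_transform(np.arange(D.n_categories[j], dtype=float), cnt))
            counts.append(cnt)
        return cls(tables, counts)

    @classmethod
    def random(cls, D: DiscreteMatrix, rng: np.random.Generator) -> "TransformTable":
        tables, counts = [], []
        for j in range(D.n_features):
            m = int(D.n_categories[j])
            cnt = np.bincount(D.labels[:, j], minlength=m).astype(float)
            while True:
                raw = rng.normal(size=m)
                try:
                    tables.append(standardize_transform(raw, cnt))
                    break
                except DegenerateTransformError:  # pragma: no cover
                    continue
            counts.append(cnt)
        return cls(tables, counts)

    def apply(self, D: DiscreteMatrix) -> np.ndarray:
        """Transformed value matrix Phi (n x p): Phi[i, j] = phi_j(D[i, j])."""
        n, p = D.labels.shape
        Phi = np.empty((n, p), dtype=float)
        for j in range(p):
            Phi[:, j] = self.tables[j][D.labels[:, j]]
        return Phi

    def is_standardized(self, atol: float = 1e-8) -> bool:
        for phi, cnt in zip(self.tables, self.counts):
            w = cnt / cnt.sum()
            if abs(w @ phi) > atol or abs(w @ phi**2 - 1.0) > atol:
                return False
        return True


@dataclass
class MCPCAResult:
    """Outcome of a fit: transforms, transformed covariance and spectrum,
    objective trajectory and the q-dimensional sample scores (MCPCs)."""

    transforms: TransformTable
    K: np.ndarray
    eigenvalues: np.ndarray
    q: int
    objective_trace: list[float]
    scores: np.ndarray
    explained_fraction: float
    converged: bool
    n_sweeps: int
    seed: int | None = None
    sample_ids: list[str] = field(default_factory=list)
    method: str = "mcpca"

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def transformed_covariance(D: DiscreteMatrix, T: TransformTable) -> np.ndarray:
    """K(j, j') = (1/n) sum_i phi_j(x_i^j) phi_{j'}(x_i^{j'}).

    Requires standardized transforms (then K is symmetric with unit
    diagonal).
    """
    if not T.is_standardized():
        raise DataError("transform table is not standardized")
    Phi = T.apply(D)
    n = Phi.shape[0]
    return (Phi.T @ Phi) / n


def kyfan(K: np.ndarray, q: int) -> float:
    """Sum of the q largest eigenvalues of a symmetric matrix."""
    K = np.asarray(K, dtype=float)
    p = K.shape[0]
    if K.shape != (p, p) or not np.allclose(K, K.T, atol=1e-8):
        raise DataError("K must be a symmetric matrix")
    if not 1 <= q <= p:
        raise DataError(f"q must be in [1, {p}], got {q}")
    lam = np.linalg.eigvalsh(K)  # ascending
    return float(lam[p - q :].sum())


def _spectrum_and_basis(Phi: np.ndarray, q: int):
    """Eigenvalues (descending, zero-padded to p) and the top-q orthonormal
    eigenvectors of K = Phi^T Phi / n, computed in the cheaper of the primal
    (p x p) or dual (n x n Gram) form."""
    n, p = Phi.shape
    if p <= n:
        lam, V = np.linalg.eigh(Phi.T @ Phi / n)
        lam, V = lam[::-1], V[:, ::-1]
        return np.maximum(lam, 0.0), V[:, :q]
    lam_d, Vd = np.linalg.eigh(Phi @ Phi.T / n)
    lam_d, Vd = lam_d[::-1], Vd[:, ::-1]
    lam = np.zeros(p)
    lam[:n] = np.maximum(lam_d, 0.0)
    U = np.empty((p, q))
    for r in range(q):
        lr = lam[r]
        if lr > 1e-12:
            U[:, r] = (Phi.T @ Vd[:, r]) / np.sqrt(n * lr)
        else:  # eigenvector in the null space: any orthonormal completion
            U[:, r] = 0.0
    return lam, U


def _fix_signs(U: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic sign convention: per component, the largest-magnitude
    loading is positive."""
    for r in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, r])))
        if U[i, r] < 0:
            U[:, r] *= -1
            scores[:, r] *= -1


def fit_mcpca(
    D: DiscreteMatrix,
    q: int,
    tol: float = 1e-6,
    max_sweeps: int = 100,
    init: str = "identity",
    seed: int | None = 0,
) -> MCPCAResult:
    """Fit the transform tables by block coordinate ascent.

    Sweeps stop when the objective improves by less than ``tol`` or after
    ``max_sweeps`` (then ``converged`` is False).  The recorded trajectory
    starts with the objective of the initial (identity or random) transforms,
    so with identity init its first entry equals the Ky Fan value of the raw
    label correlation matrix (the PCA objective).
    """
    n, p = D.labels.shape
    if n < 2:
        raise DataError("need at least 2 samples")
    if not 1 <= q <= p:
        raise DataError(f"q must be in [1, {p}], got {q}")
    if np.any(D.degenerate):
        bad = np.flatnonzero(D.degenerate)
        raise DataError(
            f"degenerate (single-category) features present: {bad.tolist()}; "
            "drop them first (DiscreteMatrix.drop_degenerate)"
        )
    rng = np.random.default_rng(seed)
    if init == "identity":
        T = TransformTable.identity(D)
    elif init == "random":
        T = TransformTable.random(D, rng)
    else:
        raise DataError(f"init must be 'identity' or 'random', got {init!r}")

    labels = D.labels
    m_list = [int(m) for m in D.n_categories]
    Phi = T.apply(D)
    lam, U = _spectrum_and_basis(Phi, q)
    trace: list[float] = [float(lam[:q].sum())]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        W = U @ U.T
        wdiag = np.diag(W).copy()
        for j in range(p):
            g = Phi @ W[:, j] - wdiag[j] * Phi[:, j]
            cnt = T.counts[j]
            sums = np.bincount(labels[:, j], weights=g, minlength=m_list[j])
            with np.errstate(invalid="ignore", divide="ignore"):
                phi_new = sums / cnt
            try:
                phi_new = standardize_transform(phi_new, cnt)
            except DegenerateTransformError:
                continue  # keep the previous transform
            T.tables[j] = phi_new
            Phi[:, j] = phi_new[labels[:, j]]
        lam, U = _spectrum_and_basis(Phi, q)
        obj = float(lam[:q].sum())
        trace.append(obj)
        if obj - trace[-2] < tol:
            converged = True
            break

    scores = Phi @ U
    _fix_signs(U, scores)
    K = (Phi.T @ Phi) / n
    return MCPCAResult(
        transforms=T,
        K=K,
        eigenvalues=lam,
        q=q,
        objective_trace=trace,
        scores=scores,
        explained_fraction=trace[-1] / p,
        converged=converged,
        n_sweeps=sweeps,
        seed=seed,
        sample_ids=list(D.sample_ids),
        method="mcpca",
    )


def explained_fraction(result: MCPCAResult) -> float:
    """Objective / trace(K) = objective / p."""
    return result.objective / result.K.shape[0]
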