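"""Core data containers shared across the package.

All containers are thin wrappers around numpy arrays with validation of the
structural invariants they promise (shapes, value ranges, normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import DataError

__all__ = [
    "Marker",
    "GenotypeLikelihoodSet",
    "DosageMatrix",
    "DiscreteMatrix",
    "ReadCounts",
]

#: tolerance for "triplet sums to one" checks
POSTERIOR_ATOL = 1e-6


class Marker(NamedTuple):
    """A biallelic site: identifier plus major/minor allele codes."""

    id: str
    allele_major: str
    allele_minor: str


def _default_markers(p: int) -> list[Marker]:
    return [Marker(f"site{j}", "0", "1") for j in range(p)]


def _default_samples(n: int) -> list[str]:
    return [f"sample{i}" for i in range(n)]


@dataclass
class GenotypeLikelihoodSet:
    """Per-individual, per-site genotype likelihoods or posteriors.

    ``values`` has shape (n, p, 3): probabilities/likelihoods of carrying
    0, 1 or 2 copies of the minor allele.  When ``is_posterior`` is true
    every triplet sums to one (within ``POSTERIOR_ATOL``).
    """

    values: np.ndarray
    markers: list[Marker] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    is_posterior: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise DataError(
                f"likelihood array must be (n, p, 3), got {self.values.shape}"
            )
        n, p, _ = self.values.shape
        if not self.markers:
            self.markers = _default_markers(p)
        if not self.sample_ids:
            self.sample_ids = _default_samples(n)
        if len(self.markers) != p:
            raise DataError(f"{len(self.markers)} markers for {p} sites")
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} samples")
        if np.any(self.values < 0):
            raise DataError("negative genotype likelihood")
        if self.is_posterior:
            sums = self.values.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=POSTERIOR_ATOL):
                bad = np.unravel_index(np.argmax(np.abs(sums - 1.0)), sums.shape)
                raise DataError(
                    f"posterior triplet does not sum to 1 at sample {bad[0]}, "
                    f"site {bad[1]} (sum={sums[bad]:.8f})"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]


@dataclass
class ReadCounts:
    """Per-individual, per-site sequencing depths and minor-allele read
    counts (0 <= minor <= depth)."""

    depths: np.ndarray
    minor_counts: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        self.minor_counts = np.asarray(self.minor_counts, dtype=np.int64)
        if self.depths.shape != self.minor_counts.shape:
            raise DataError("depths and minor_counts must share a shape")
        if np.any(self.depths < 0):
            raise DataError("negative read depth")
        if np.any(self.minor_counts < 0) or np.any(self.minor_counts > self.depths):
            raise DataError("minor counts must satisfy 0 <= minor <= depth")


#: allowed provenance tags for a DosageMatrix
DOSAGE_PROVENANCE = ("true_genotype", "observed_genotype", "posterior_dosage")


@dataclass
class DosageMatrix:
    """n x p matrix of genotype dosages in [0, 2].

    ``provenance`` records how the values were obtained; hard genotype
    matrices (``true_genotype``) must contain only {0, 1, 2}.
    """

    values: np.ndarray
    markers: list[Marker] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    provenance: str = "posterior_dosage"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError(f"dosage matrix must be 2-D, got shape {self.values.shape}")
        n, p = self.values.shape
        if not self.markers:
            self.markers = _default_markers(p)
        if not self.sample_ids:
            self.sample_ids = _default_samples(n)
        if len(self.markers) != p or len(self.sample_ids) != n:
            raise DataError("marker/sample metadata does not match matrix shape")
        if self.provenance not in DOSAGE_PROVENANCE:
            raise DataError(f"unknown provenance {self.provenance!r}")
        if np.any(self.values < -1e-9) or np.any(self.values > 2 + 1e-9):
            raise DataError("dosage values outside [0, 2]")
        if self.provenance == "true_genotype" and not np.all(
            np.isin(self.values, (0.0, 1.0, 2.0))
        ):
            raise DataError("true_genotype matrix must contain only {0,1,2}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]


@dataclass
class DiscreteMatrix:
    """n x p integer category labels, the input to the MCPCA optimizer.

    Per feature j the labels are 0..n_categories[j]-1 with no gaps.
    Features with a single category are flagged degenerate; the optimizer
    requires the caller to drop them first.
    """

    labels: np.ndarray
    n_categories: np.ndarray
    method: str = "raw"
    bin_info: list | None = None
    markers: list[Marker] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DataError("label matrix must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise DataError("labels must be integers")
            self.labels = as_int
        n, p = self.labels.shape
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        if self.n_categories.shape != (p,):
            raise DataError("n_categories must have one entry per feature")
        if not self.markers:
            self.markers = _default_markers(p)
        if not self.sample_ids:
            self.sample_ids = _default_samples(n)
        for j in range(p):
            m = self.n_categories[j]
            col = self.labels[:, j]
            if m < 1:
                raise DataError(f"feature {j}: n_categories must be >= 1")
            if col.min() < 0 or col.max() >= m:
                raise DataError(f"feature {j}: labels outside 0..{m - 1}")
            if len(np.unique(col)) != m:
                raise DataError(f"feature {j}: gaps in label range 0..{m - 1}")

    @classmethod
    def from_labels(
        cls,
        matrix: np.ndarray,
        method: str = "raw",
        markers: Sequence[Marker] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "DiscreteMatrix":
        """Build from an integer-valued matrix, compacting each column.

        Arbitrary (even non-contiguous) integer codes per column are mapped
        to 0..m_j-1 preserving order.
        """
        matrix = np.asarray(matrix)
        n, p = matrix.shape
        labels = np.empty((n, p), dtype=np.int64)
        m = np.empty(p, dtype=np.int64)
        for j in range(p):
            uniq, inv = np.unique(matrix[:, j], return_inverse=True)
            labels[:, j] = inv
            m[j] = len(uniq)
        return cls(
            labels=labels,
            n_categories=m,
            method=method,
            markers=list(markers) if markers else [],
            sample_ids=list(sample_ids) if sample_ids else [],
        )

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_features(self) -> int:
        return self.labels.shape[1]

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of single-category features."""
        return self.n_categories <= 1

    def drop_degenerate(self) -> "DiscreteMatrix":
        """Return a copy with single-category features removed."""
        keep = ~self.degenerate
        return DiscreteMatrix(
            labels=self.labels[:, keep],
            n_categories=self.n_categories[keep],
            method=self.method,
            bin_info=[b for b, k in zip(self.bin_info, keep) if k]
            if self.bin_info is not None
            else None,
            markers=[mk for mk, k in zip(self.markers, keep) if k],
            sample_ids=self.sample_ids,
        )
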