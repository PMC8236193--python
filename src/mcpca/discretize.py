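"""Per-SNP discretization of continuous dosage values.

Three binning schemes — equal width ("intv"), equal frequency ("freq") and
1-D optimal within-cluster-SS partitioning ("jenks") — with the number of
bins chosen per SNP by the Freedman-Diaconis rule.  All schemes are monotone
in the input values and label bins in increasing value order.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .datatypes import DiscreteMatrix, DosageMatrix
from .errors import DataError

__all__ = [
    "fd_bin_count",
    "equal_width",
    "equal_frequency",
    "jenks",
    "jenks_breaks",
    "discretize_matrix",
    "METHODS",
]

METHODS = ("intv", "freq", "jenks")

#: default bounds for automatic bin counts
M_MIN_DEFAULT = 2
M_MAX_DEFAULT = 20


def fd_bin_count(x, m_min: int = M_MIN_DEFAULT, m_max: int = M_MAX_DEFAULT) -> int:
    """Freedman-Diaconis bin count: width h = 2*IQR(x)*n^(-1/3),
    m = ceil(range/h), clamped to [m_min, m_max].

    Degenerate inputs (zero IQR or zero range) return ``m_min``.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise DataError("fd_bin_count needs at least 2 values")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    rng = float(x.max() - x.min())
    if iqr <= 0 or rng <= 0:
        return int(m_min)
    h = 2.0 * iqr * n ** (-1.0 / 3.0)
    m = math.ceil(rng / h)
    return int(min(max(m, m_min), m_max))


def _compact(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map raw bin indices to 0..k-1 preserving order; also return the
    original index of each kept bin."""
    used, labels = np.unique(raw, return_inverse=True)
    return labels.astype(np.int64), used


def equal_width(x, m: int) -> np.ndarray:
    """Labels from m equal-length bins over [min(x), max(x)].

    Half-open convention [a, b): a value on an interior edge belongs to the
    bin on its right; the last bin is closed.  Empty bins are compacted.
    """
    x = np.asarray(x, dtype=float).ravel()
    if m < 1:
        raise DataError("m must be >= 1")
    lo, hi = float(x.min()), float(x.max())
    if m == 1 or hi <= lo:
        return np.zeros(x.size, dtype=np.int64)
    width = (hi - lo) / m
    raw = np.clip(np.floor((x - lo) / width).astype(np.int64), 0, m - 1)
    labels, _ = _compact(raw)
    return labels


def equal_frequency(x, m: int) -> np.ndarray:
    """Labels from bins cut at the k/m rank quantiles, k = 1..m-1.

    Duplicated values are never split across bins: each distinct value is
    assigned by the bin containing the midpoint of its run of ranks, so
    with ties the bin sizes may be unequal; with all-distinct values the
    sizes differ by at most one.  When the number of distinct values is at
    most m every distinct value gets its own bin.
    """
    x = np.asarray(x, dtype=float).ravel()
    if m < 1:
        raise DataError("m must be >= 1")
    n = x.size
    u, inv, w = np.unique(x, return_inverse=True, return_counts=True)
    if m == 1 or u.size == 1:
        return np.zeros(n, dtype=np.int64)
    if u.size <= m:
        return inv.astype(np.int64)
    mid_rank = np.cumsum(w) - w / 2.0  # midpoint rank of each value's run
    raw = np.minimum((mid_rank * m / n).astype(np.int64), m - 1)
    labels, _ = _compact(raw)
    return labels[inv]


def _weighted_prefix(u: np.ndarray, w: np.ndarray):
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cs = np.concatenate([[0.0], np.cumsum(w * u)])
    cs2 = np.concatenate([[0.0], np.cumsum(w * u * u)])
    return cw, cs, cs2


def jenks_breaks(x, m: int) -> list[np.ndarray]:
    """Optimal 1-D partition of x into m contiguous-in-sorted-order clusters
    minimizing total within-cluster sum of squares (Fisher's exact dynamic
    program on the unique values, weighted by multiplicity).

    Returns the list of clusters as arrays of unique values (ascending).
    """
    x = np.asarray(x, dtype=float).ravel()
    u, w = np.unique(x, return_counts=True)
    k = u.size
    if m > k:
        raise DataError(f"m={m} exceeds number of distinct values ({k})")
    if m < 1:
        raise DataError("m must be >= 1")
    w = w.astype(float)
    cw, cs, cs2 = _weighted_prefix(u, w)

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-SS of unique values i..j-1 (i may be a vector)
        W = cw[j] - cw[i]
        S = cs[j] - cs[i]
        S2 = cs2[j] - cs2[i]
        return S2 - S * S / W

    INF = np.inf
    D = np.full((m + 1, k + 1), INF)
    D[0, 0] = 0.0
    back = np.zeros((m + 1, k + 1), dtype=np.int64)
    for c in range(1, m + 1):
        # first j with a feasible partition is c; must leave >= m-c values
        for j in range(c, k - (m - c) + 1):
            i = np.arange(c - 1, j)
            cand = D[c - 1, i] + seg_cost(i, j)
            best = int(np.argmin(cand))
            D[c, j] = cand[best]
            back[c, j] = i[best]
    # recover break positions
    bounds = [k]
    j = k
    for c in range(m, 0, -1):
        j = int(back[c, j])
        bounds.append(j)
    bounds.reverse()
    return [u[bounds[c] : bounds[c + 1]] for c in range(m)]


def jenks(x, m: int) -> np.ndarray:
    """Labels from the exact Jenks/Fisher partition, ordered by cluster mean
    (equivalently by value, since clusters are contiguous).

    If m exceeds the number of distinct values it is reduced with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    k = np.unique(x).size
    if m > k:
        warnings.warn(f"jenks: reducing m from {m} to {k} distinct values")
        m = k
    clusters = jenks_breaks(x, m)
    # upper boundary of each cluster -> searchsorted assignment
    uppers = np.array([c[-1] for c in clusters])
    labels = np.searchsorted(uppers, x, side="left")
    return np.clip(labels, 0, m - 1).astype(np.int64)


_DISPATCH = {"intv": equal_width, "freq": equal_frequency, "jenks": jenks}


def discretize_matrix(
    X,
    method: str = "jenks",
    m: int | str = "auto",
    m_min: int = M_MIN_DEFAULT,
    m_max: int = M_MAX_DEFAULT,
) -> DiscreteMatrix:
    """Discretize each column of a dosage matrix independently.

    ``m="auto"`` chooses the per-SNP bin count by the Freedman-Diaconis
    rule (clamped to [m_min, m_max]).  Constant columns get a single
    category and are flagged degenerate.
    """
    if method not in _DISPATCH:
        raise DataError(f"method must be one of {METHODS}, got {method!r}")
    if isinstance(X, DosageMatrix):
        values, markers, sample_ids = X.values, X.markers, X.sample_ids
    else:
        values = np.asarray(X, dtype=float)
        markers, sample_ids = [], []
    if not np.all(np.isfinite(values)):
        raise DataError("dosage matrix contains non-finite values")
    n, p = values.shape
    labels = np.empty((n, p), dtype=np.int64)
    m_j = np.empty(p, dtype=np.int64)
    bin_info: list[dict] = []
    fn = _DISPATCH[method]
    for j in range(p):
        col = values[:, j]
        n_distinct = np.unique(col).size
        if n_distinct == 1:
            labels[:, j] = 0
            m_j[j] = 1
            bin_info.append({"degenerate": True})
            continue
        mj = fd_bin_count(col, m_min, m_max) if m == "auto" else int(m)
        if method == "jenks":
            mj = min(mj, n_distinct)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lab = fn(col, mj)
        else:
            lab = fn(col, mj)
        labels[:, j] = lab
        m_j[j] = lab.max() + 1
        bin_info.append({"requested_bins": mj, "categories": int(m_j[j])})
    return DiscreteMatrix(
        labels=labels,
        n_categories=m_j,
        method=method,
        bin_info=bin_info,
        markers=list(markers),
        sample_ids=list(sample_ids),
    )
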