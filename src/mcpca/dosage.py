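"""Genotype likelihoods/posteriors -> dosage values, plus site filters."""

from __future__ import annotations

import numpy as np

from .datatypes import POSTERIOR_ATOL, DosageMatrix, GenotypeLikelihoodSet
from .errors import DataError

__all__ = [
    "posteriors_from_likelihoods",
    "dosage_from_posteriors",
    "maf_filter",
    "estimate_allele_frequency",
]


def estimate_allele_frequency(gl: GenotypeLikelihoodSet) -> np.ndarray:
    """Per-site minor-allele frequency estimated from uniformly normalized
    likelihood means (mean dosage / 2), clipped into (0, 1)."""
    tot = gl.values.sum(axis=2)
    if np.any(tot <= 0):
        i, j = np.unravel_index(np.argmin(tot), tot.shape)
        raise DataError(
            f"all-zero likelihood triplet at sample {gl.sample_ids[i]!r}, "
            f"site {gl.markers[j].id!r}"
        )
    norm = gl.values / tot[:, :, None]
    af = (norm[:, :, 1] + 2.0 * norm[:, :, 2]).mean(axis=0) / 2.0
    return np.clip(af, 1e-6, 1.0 - 1e-6)


def posteriors_from_likelihoods(
    gl: GenotypeLikelihoodSet,
    prior: str = "hwe",
    af: np.ndarray | float | None = None,
) -> GenotypeLikelihoodSet:
    """Turn genotype likelihoods into posteriors.

    prior="uniform": posterior(g) proportional to L(g).
    prior="hwe":     prior triplet ((1-af)^2, 2 af (1-af), af^2) with af the
    per-site minor-allele frequency (supplied, or estimated from the data by
    :func:`estimate_allele_frequency`).
    """
    if prior not in ("uniform", "hwe"):
        raise DataError(f"prior must be 'uniform' or 'hwe', got {prior!r}")
    tot = gl.values.sum(axis=2)
    if np.any(tot <= 0):
        i, j = np.unravel_index(np.argmin(tot), tot.shape)
        raise DataError(
            f"all-zero likelihood triplet at sample {gl.sample_ids[i]!r}, "
            f"site {gl.markers[j].id!r}"
        )
    if prior == "uniform":
        weighted = gl.values
    else:
        if af is None:
            af = estimate_allele_frequency(gl)
        af = np.asarray(af, dtype=float)
        if af.ndim == 0:
            af = np.full(gl.n_sites, float(af))
        if np.any(af <= 0) or np.any(af >= 1):
            raise DataError("hwe prior requires allele frequencies in (0, 1)")
        prior_trip = np.stack(
            [(1 - af) ** 2, 2 * af * (1 - af), af**2], axis=-1
        )  # (p, 3)
        weighted = gl.values * prior_trip[None, :, :]
    sums = weighted.sum(axis=2)
    if np.any(sums <= 0):
        i, j = np.unravel_index(np.argmin(sums), sums.shape)
        raise DataError(
            f"posterior normalizer vanished at sample {gl.sample_ids[i]!r}, "
            f"site {gl.markers[j].id!r}"
        )
    post = weighted / sums[:, :, None]
    return GenotypeLikelihoodSet(
        values=post,
        markers=list(gl.markers),
        sample_ids=list(gl.sample_ids),
        is_posterior=True,
    )


def dosage_from_posteriors(post: GenotypeLikelihoodSet) -> DosageMatrix:
    """Posterior mean genotype under additive coding:
    DS = Pr(1|Data) + 2 Pr(2|Data)."""
    sums = post.values.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=max(POSTERIOR_ATOL, 1e-6)):
        raise DataError("input triplets are not normalized posteriors")
    ds = post.values[:, :, 1] + 2.0 * post.values[:, :, 2]
    return DosageMatrix(
        values=np.clip(ds, 0.0, 2.0),
        markers=list(post.markers),
        sample_ids=list(post.sample_ids),
        provenance="posterior_dosage",
    )


def maf_filter(X, threshold: float = 0.05):
    """Remove sites whose folded allele frequency is below ``threshold``.

    The frequency is computed from dosages as mean(value)/2 and folded to
    min(f, 1-f).  Accepts a :class:`DosageMatrix` (returns one) or a plain
    array (returns an array).  Also returns the kept-site index.
    """
    if not 0.0 <= threshold <= 0.5:
        raise DataError(f"threshold must be in [0, 0.5], got {threshold}")
    values = X.values if isinstance(X, DosageMatrix) else np.asarray(X, dtype=float)
    f = values.mean(axis=0) / 2.0
    folded = np.minimum(f, 1.0 - f)
    keep = np.flatnonzero(folded >= threshold) if threshold > 0 else np.arange(
        values.shape[1]
    )
    if keep.size == 0:
        raise DataError(
            f"MAF filter at {threshold} removed every site; lower the threshold"
        )
    if isinstance(X, DosageMatrix):
        out = DosageMatrix(
            values=values[:, keep],
            markers=[X.markers[j] for j in keep],
            sample_ids=list(X.sample_ids),
            provenance=X.provenance,
        )
    else:
        out = values[:, keep]
    return out, keep
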