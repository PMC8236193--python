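"""Readers and writers for the genotype formats the pipeline touches.

Supported inputs: Beagle genotype-likelihood text (the ANGSD ``-doGlf 2``
dialect), VCF with GP/PL/DS FORMAT fields, and plain numeric dosage/genotype
TSV.  Outputs: score TSV plus a JSON run report, Beagle-GL and dosage TSV.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .datatypes import POSTERIOR_ATOL, DosageMatrix, GenotypeLikelihoodSet, Marker
from .errors import DataError, FormatError

if TYPE_CHECKING:  # pragma: no cover
    from .core import MCPCAResult

logger = logging.getLogger(__name__)

__all__ = [
    "phred_to_error",
    "error_to_phred",
    "read_beagle_gl",
    "write_beagle_gl",
    "read_vcf_genotype_probs",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "write_scores",
    "read_scores",
]


def phred_to_error(q):
    """Convert a Phred quality score into an error probability 10**(-Q/10).

    Accepts scalars or arrays; Q must be nonnegative.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise DataError("Phred quality scores must be nonnegative")
    out = np.power(10.0, -q / 10.0)
    return float(out) if out.ndim == 0 else out


def error_to_phred(eps):
    """Inverse of :func:`phred_to_error`: Q = -10*log10(eps), eps in (0, 1]."""
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0) or np.any(eps > 1):
        raise DataError("error probability must be in (0, 1]")
    out = -10.0 * np.log10(eps)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Beagle genotype-likelihood text format
# ---------------------------------------------------------------------------


def read_beagle_gl(path) -> GenotypeLikelihoodSet:
    """Read a Beagle-GL text file (header ``marker allele1 allele2`` then
    three columns per individual).

    ``is_posterior`` is inferred: true iff every triplet sums to one.
    """
    path = Path(path)
    markers: list[Marker] = []
    rows: list[list[float]] = []
    sample_ids: list[str] = []
    n_ind = None
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty file")
        head = header.split()
        if head[0].lower() != "marker":
            raise FormatError(
                f"{path}: expected header starting with 'marker', got {head[0]!r}"
            )
        if (len(head) - 3) % 3 != 0:
            raise FormatError(
                f"{path}: header has {len(head)} columns, not 3 + 3k"
            )
        # ANGSD repeats each individual name three times in the header
        n_ind = (len(head) - 3) // 3
        sample_ids = [head[3 + 3 * i] for i in range(n_ind)]
        if len(set(sample_ids)) != n_ind:
            sample_ids = [f"sample{i}" for i in range(n_ind)]
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if (len(fields) - 3) % 3 != 0 or len(fields) != 3 + 3 * n_ind:
                raise FormatError(
                    f"{path}:{lineno}: expected {3 + 3 * n_ind} columns, "
                    f"got {len(fields)}"
                )
            markers.append(Marker(fields[0], fields[1], fields[2]))
            try:
                vals = [float(v) for v in fields[3:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
            if any(v < 0 for v in vals):
                raise FormatError(f"{path}:{lineno}: negative likelihood")
            rows.append(vals)
    if not markers:
        raise FormatError(f"{path}: no marker records")
    values = np.array(rows, dtype=float).reshape(len(markers), n_ind, 3)
    values = np.transpose(values, (1, 0, 2))  # -> (n, p, 3)
    sums = values.sum(axis=2)
    is_posterior = bool(np.allclose(sums, 1.0, atol=POSTERIOR_ATOL))
    return GenotypeLikelihoodSet(
        values=values,
        markers=markers,
        sample_ids=sample_ids,
        is_posterior=is_posterior,
    )


def write_beagle_gl(gl: GenotypeLikelihoodSet, path) -> None:
    """Write a GenotypeLikelihoodSet in Beagle-GL text format."""
    path = Path(path)
    n, p, _ = gl.values.shape
    with open(path, "w") as fh:
        cols = ["marker", "allele1", "allele2"]
        for sid in gl.sample_ids:
            cols.extend([sid] * 3)
        fh.write("\t".join(cols) + "\n")
        for j in range(p):
            mk = gl.markers[j]
            fields = [mk.id, mk.allele_major, mk.allele_minor]
            fields.extend(f"{v:.10g}" for v in gl.values[:, j, :].ravel())
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_genotype_probs(path, field: str = "GP"):
    """Read genotype probabilities (GP), Phred-scaled likelihoods (PL) or
    dosages (DS) from a VCF.

    Returns a :class:`GenotypeLikelihoodSet` for GP/PL, a
    :class:`DosageMatrix` for DS.  Multiallelic records are skipped with a
    warning; missing calls become uniform triplets (GP/PL) or dosage 1.0
    (DS), with a logged count.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    field = field.upper()
    if field not in ("GP", "PL", "DS"):
        raise DataError(f"field must be one of GP, PL, DS; got {field!r}")
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    markers: list[Marker] = []
    site_values: list[np.ndarray] = []
    n_missing = 0
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        try:
            raw = var.format(field)
        except KeyError:
            raw = None
        if raw is None:
            continue
        raw = np.asarray(raw, dtype=float)
        if field == "DS":
            vals = raw.reshape(n)
            miss = ~np.isfinite(vals) | (vals < 0) | (vals > 2)
            n_missing += int(miss.sum())
            vals = np.where(miss, 1.0, vals)
        else:
            if raw.shape[1] < 3:
                raise FormatError(
                    f"{field} at {var.CHROM}:{var.POS} has {raw.shape[1]} values"
                )
            trip = raw[:, :3]
            miss = ~np.all(np.isfinite(trip), axis=1) | np.any(trip < 0, axis=1)
            if field == "PL":
                with np.errstate(invalid="ignore"):
                    trip = np.power(10.0, -trip / 10.0)
            tot = trip.sum(axis=1)
            miss |= ~np.isfinite(tot) | (tot <= 0)
            n_missing += int(miss.sum())
            trip = np.where(miss[:, None], 1.0 / 3.0, trip / np.where(tot > 0, tot, 1.0)[:, None])
            vals = trip
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        markers.append(Marker(mid, var.REF, var.ALT[0]))
        site_values.append(vals)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic record(s)")
    if not markers:
        raise DataError(f"no biallelic records with field {field} in {path}")
    if n_missing:
        logger.info("filled %d missing %s call(s) with maximal uncertainty",
                    n_missing, field)
    if field == "DS":
        values = np.stack(site_values, axis=1)  # (n, p)
        return DosageMatrix(values=values, markers=markers,
                            sample_ids=sample_ids, provenance="posterior_dosage")
    values = np.stack(site_values, axis=1)  # (n, p, 3)
    return GenotypeLikelihoodSet(
        values=values, markers=markers, sample_ids=sample_ids,
        is_posterior=True,
    )


# ---------------------------------------------------------------------------
# dosage / genotype TSV
# ---------------------------------------------------------------------------


def write_dosage_tsv(X: DosageMatrix, path) -> None:
    """Write a dosage/genotype matrix as TSV: samples in rows, one header
    row of marker ids, first column ``sample_id``."""
    df = pd.DataFrame(
        X.values, index=pd.Index(X.sample_ids, name="sample_id"),
        columns=[m.id for m in X.markers],
    )
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_dosage_tsv(path, provenance: str = "posterior_dosage") -> DosageMatrix:
    """Read a matrix written by :func:`write_dosage_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    values = df.to_numpy(dtype=float)
    if provenance == "true_genotype" and not np.all(np.isin(values, (0.0, 1.0, 2.0))):
        provenance = "observed_genotype" if np.all(np.isin(values, (0.0, 1.0, 2.0))) else "posterior_dosage"
    markers = [Marker(str(c), "0", "1") for c in df.columns]
    return DosageMatrix(values=values, markers=markers,
                        sample_ids=[str(s) for s in df.index],
                        provenance=provenance)


# ---------------------------------------------------------------------------
# scores + report
# ---------------------------------------------------------------------------


def write_scores(result, path, config: dict | None = None) -> None:
    """Write embedding scores as TSV plus a companion JSON report.

    ``result`` is an :class:`~mcpca.core.MCPCAResult` or a baseline
    :class:`~mcpca.baselines.EmbeddingResult`.  The report lands next to the
    TSV with suffix ``.report.json`` and echoes eigenvalues, the objective
    trajectory (empty for baselines), q, the explained-variance fraction,
    the seed and the caller-supplied config.
    """
    path = Path(path)
    scores = np.asarray(result.scores, dtype=float)
    sample_ids = getattr(result, "sample_ids", None) or [
        f"sample{i}" for i in range(scores.shape[0])
    ]
    q = scores.shape[1]
    df = pd.DataFrame(
        scores, index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"MCPC{r + 1}" for r in range(q)],
    )
    df.to_csv(path, sep="\t", float_format="%.17g")
    report = {
        "method": getattr(result, "method", "mcpca"),
        "q": int(getattr(result, "q", q)),
        "eigenvalues": [float(v) for v in np.asarray(result.eigenvalues).ravel()],
        "objective_trace": [float(v) for v in getattr(result, "objective_trace", [])],
        "explained_fraction": float(result.explained_fraction),
        "converged": bool(getattr(result, "converged", True)),
        "n_sweeps": int(getattr(result, "n_sweeps", 0)),
        "seed": getattr(result, "seed", None),
        "config": config or {},
    }
    with open(report_path(path), "w") as fh:
        json.dump(report, fh, indent=2)


def report_path(scores_path) -> Path:
    return Path(str(scores_path) + ".report.json")


def read_scores(path) -> tuple[list[str], np.ndarray]:
    """Read a score TSV back: (sample_ids, n x q array)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(s) for s in df.index], df.to_numpy(dtype=float)
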