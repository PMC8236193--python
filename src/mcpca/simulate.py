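"""Synthetic low-coverage sequencing data.

Generates the three genotype regimes used throughout the evaluation —
perfectly known genotypes, genotypes observed with quality-driven errors,
and posterior-mean dosages computed from simulated reads — plus a
two-group nonlinear classification scenario and a parser for ms-style
coalescent output so externally simulated haplotypes can be used instead
of the built-in Balding-Nichols generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .datatypes import DosageMatrix, GenotypeLikelihoodSet, Marker, ReadCounts  # noqa: F401
from .dosage import dosage_from_posteriors, maf_filter, posteriors_from_likelihoods
from .errors import DataError, FormatError
from .io_formats import phred_to_error

__all__ = [
    "SimConfig",
    "parse_ms_output",
    "diploid_genotypes",
    "sim_admixed_genotypes",
    "sim_depths",
    "sim_quality",
    "perturb_genotypes",
    "sim_reads",
    "likelihoods_from_reads",
    "sim_two_group_nonlinear",
    "sim_low_coverage_dataset",
]


@dataclass
class SimConfig:
    """Parameters of the low-coverage genotype simulation.

    ``fst`` controls population differentiation in the Balding-Nichols
    substitute generator; ``admixture`` optionally gives each population's
    ancestry proportions (rows sum to 1), defaulting to no admixture.
    Depths come from a Gamma with shape ``depth_shape`` and scale
    ``mean_depth / depth_shape``; Phred qualities from the synthetic
    linear-in-depth model of :func:`sim_quality`.
    """

    n_per_pop: int = 50
    n_pops: int = 3
    p_sites: int = 2000
    fst: float = 0.29
    admixture: list | None = None
    mean_depth: float = 5.0
    depth_shape: float = 6.3
    quality_slope: float = 3.0
    quality_sd_base: float = 1.0
    quality_sd_slope: float = 1.2
    quality_max: float = 40.0
    read_error: float = 0.01
    maf_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise DataError("mean_depth must be > 0")
        if self.depth_shape <= 0:
            raise DataError("depth_shape must be > 0")
        if not 0 <= self.maf_threshold <= 0.5:
            raise DataError("maf_threshold must be in [0, 0.5]")
        if not 0 < self.fst < 1:
            raise DataError("fst must be in (0, 1)")
        if not 0 < self.read_error < 0.5:
            raise DataError("read_error must be in (0, 0.5)")
        if self.n_per_pop < 1 or self.n_pops < 1 or self.p_sites < 1:
            raise DataError("n_per_pop, n_pops and p_sites must be >= 1")
        if self.admixture is not None:
            A = np.asarray(self.admixture, dtype=float)
            if A.shape != (self.n_pops, self.n_pops):
                raise DataError("admixture must be an (n_pops x n_pops) matrix")
            if np.any(A < 0) or not np.allclose(A.sum(axis=1), 1.0):
                raise DataError("admixture rows must be probabilities summing to 1")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# ms output
# ---------------------------------------------------------------------------


def parse_ms_output(text: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Parse ms-style coalescent output into per-replicate
    (positions, haplotype matrix) pairs.

    Replicates are separated by ``//``; each block carries ``segsites:``,
    ``positions:`` and one 0/1 string per haplotype.  A zero-segsites block
    yields empty arrays.
    """
    lines = text.splitlines()
    reps: list[tuple[np.ndarray, np.ndarray]] = []
    i = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise FormatError(f"line {i + 1}: expected 'segsites:' after '//'")
        segsites = int(lines[i].split()[1])
        i += 1
        positions = np.empty(0)
        if segsites > 0:
            if i >= len(lines) or not lines[i].startswith("positions:"):
                raise FormatError(f"line {i + 1}: expected 'positions:'")
            positions = np.array([float(v) for v in lines[i].split()[1:]])
            if positions.size != segsites:
                raise FormatError(
                    f"line {i + 1}: {positions.size} positions for "
                    f"{segsites} segsites"
                )
            i += 1
        haps = []
        while i < len(lines):
            s = lines[i].strip()
            if not s or s == "//":
                break
            if not set(s) <= {"0", "1"}:
                break
            if len(s) != segsites:
                raise FormatError(
                    f"line {i + 1}: haplotype length {len(s)} != "
                    f"segsites {segsites}"
                )
            haps.append([int(c) for c in s])
            i += 1
        hap_mat = (
            np.array(haps, dtype=np.int64)
            if haps
            else np.empty((0, segsites), dtype=np.int64)
        )
        reps.append((positions, hap_mat))
    if not reps:
        raise FormatError("no '//' replicate blocks found")
    return reps


def diploid_genotypes(haplotypes: np.ndarray) -> np.ndarray:
    """Pair haplotypes in input order into diploid genotypes G = h1 + h2."""
    h = np.asarray(haplotypes)
    if h.shape[0] % 2 != 0:
        raise DataError(f"odd number of haplotypes ({h.shape[0]})")
    return h[0::2] + h[1::2]


# ---------------------------------------------------------------------------
# genotype generation
# ---------------------------------------------------------------------------


def sim_admixed_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Multi-population (optionally admixed) genotypes from the
    Balding-Nichols model, MAF-filtered.

    Ancestral frequencies are Uniform(0.05, 0.95); population frequencies
    Beta(f(1-F)/F, (1-f)(1-F)/F) with F = cfg.fst; each individual's allele
    frequency mixes the population frequencies by its ancestry proportions;
    genotypes are Binomial(2, freq).  Returns (DosageMatrix with
    provenance='true_genotype', population labels, kept-site index).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    K, p = cfg.n_pops, cfg.p_sites
    n = cfg.n_per_pop * K
    F = cfg.fst
    f_anc = rng.uniform(0.05, 0.95, size=p)
    a = f_anc * (1 - F) / F
    b = (1 - f_anc) * (1 - F) / F
    f_pop = rng.beta(a, b, size=(K, p))  # (K, p)
    A = (
        np.asarray(cfg.admixture, dtype=float)
        if cfg.admixture is not None
        else np.eye(K)
    )
    pop_labels = np.repeat(np.arange(K), cfg.n_per_pop)
    f_ind = A[pop_labels] @ f_pop  # (n, p)
    G = rng.binomial(2, f_ind).astype(np.int64)
    X = DosageMatrix(
        values=G.astype(float),
        markers=[Marker(f"snp{j}", "0", "1") for j in range(p)],
        sample_ids=[f"pop{pop_labels[i]}_ind{i}" for i in range(n)],
        provenance="true_genotype",
    )
    X, kept = maf_filter(X, cfg.maf_threshold)
    return X, pop_labels, kept


# ---------------------------------------------------------------------------
# depths, qualities, errors, reads
# ---------------------------------------------------------------------------


def sim_depths(
    n: int,
    p: int,
    mean_depth: float,
    shape: float = 6.3,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-site read depths: round(Gamma(shape, mean_depth/shape))."""
    if mean_depth <= 0:
        raise DataError("mean_depth must be > 0")
    rng = rng if rng is not None else np.random.default_rng()
    d = rng.gamma(shape, mean_depth / shape, size=(n, p))
    return np.rint(d).astype(np.int64)


def sim_quality(
    depths: np.ndarray,
    model: str = "synthetic",
    rng: np.random.Generator | None = None,
    slope: float = 3.0,
    sd_base: float = 1.0,
    sd_slope: float = 1.2,
    q_max: float = 40.0,
    table: dict | None = None,
) -> np.ndarray:
    """Phred quality scores for each depth.

    synthetic (default): Q = clamp(slope*d + Normal(0, sd_base + sd_slope*d),
    0, q_max), so mean quality grows with depth.  table: ``table`` maps a
    read depth to a pool of observed quality scores (emulating matching
    against an external quality catalogue); the pool of the nearest
    available depth is used, with a warning, when a depth is absent.
    """
    depths = np.asarray(depths)
    rng = rng if rng is not None else np.random.default_rng()
    if model == "synthetic":
        sd = sd_base + sd_slope * depths
        q = slope * depths + rng.normal(0.0, 1.0, size=depths.shape) * sd
        return np.clip(q, 0.0, q_max)
    if model == "table":
        if not table:
            raise DataError("table mode requires a non-empty depth->pool table")
        avail = np.array(sorted(table.keys()))
        q = np.empty(depths.shape, dtype=float)
        missing = set()
        flat_d = depths.ravel()
        flat_q = q.ravel()
        for idx, d in enumerate(flat_d):
            d = int(d)
            if d in table and len(table[d]) > 0:
                pool = np.asarray(table[d], dtype=float)
            else:
                near = int(avail[np.argmin(np.abs(avail - d))])
                missing.add(d)
                pool = np.asarray(table[near], dtype=float)
            flat_q[idx] = pool[rng.integers(len(pool))]
        if missing:
            warnings.warn(
                f"no quality pool for depth(s) {sorted(missing)}; "
                "used nearest available depth"
            )
        return q
    raise DataError(f"model must be 'synthetic' or 'table', got {model!r}")


def perturb_genotypes(
    G: np.ndarray,
    Q: np.ndarray,
    seed: int | np.random.Generator | None = None,
    mode: str = "uniform",
):
    """Observed genotypes: with probability eps = 10^(-Q/10) the genotype is
    replaced.

    mode='uniform' replaces it by one of the two other genotypes with equal
    probability; mode='allele' flips a single allele (0 <-> 1 <-> 2, with 1
    moving either way).  Returns (perturbed matrix, boolean error mask).
    """
    G = np.asarray(G)
    Q = np.asarray(Q, dtype=float)
    if G.shape != Q.shape:
        raise DataError(f"shape mismatch: genotypes {G.shape}, qualities {Q.shape}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    eps = phred_to_error(Q)
    mask = rng.random(G.shape) < eps
    u = rng.random(G.shape)
    out = G.copy()
    if mode == "uniform":
        # the two alternatives to g, ordered: (g+1)%3 and (g+2)%3
        shift = np.where(u < 0.5, 1, 2)
        out[mask] = (G[mask] + shift[mask]) % 3
    elif mode == "allele":
        step = np.where(u < 0.5, -1, 1)
        step = np.where(G == 0, 1, np.where(G == 2, -1, step))
        out[mask] = G[mask] + step[mask]
    else:
        raise DataError(f"mode must be 'uniform' or 'allele', got {mode!r}")
    return out, mask


def sim_reads(
    G: np.ndarray,
    depths: np.ndarray,
    eps,
    rng: np.random.Generator | None = None,
) -> ReadCounts:
    """Minor-allele read counts given true genotypes, depths and per-read
    error probability: a ~ Binomial(d, (g/2)(1-eps) + (1-g/2) eps)."""
    G = np.asarray(G)
    depths = np.asarray(depths)
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0) or np.any(eps >= 1):
        raise DataError("per-read error probability must be in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    pi = (G / 2.0) * (1 - eps) + (1 - G / 2.0) * eps
    minor = rng.binomial(depths, pi)
    return ReadCounts(depths=depths, minor_counts=minor)


def likelihoods_from_reads(reads: ReadCounts, eps) -> GenotypeLikelihoodSet:
    """Biallelic genotype likelihoods from read counts.

    For genotype g the per-read minor-allele probability is
    pi_g = (g/2)(1-eps) + (1-g/2) eps, so L(g) = pi_g^a (1-pi_g)^(d-a) for a
    minor reads out of d.  Zero-depth sites get a flat (1, 1, 1) triplet.
    """
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0) or np.any(eps >= 1):
        raise DataError("per-read error probability must be in (0, 1)")
    d = np.asarray(reads.depths, dtype=float)
    a = np.asarray(reads.minor_counts, dtype=float)
    if eps.ndim == 0:
        eps = np.broadcast_to(eps, d.shape)
    L = np.empty(d.shape + (3,), dtype=float)
    for g in (0, 1, 2):
        pi = (g / 2.0) * (1 - eps) + (1 - g / 2.0) * eps
        L[..., g] = pi**a * (1 - pi) ** (d - a)
    L[d == 0] = 1.0
    return GenotypeLikelihoodSet(values=L, is_posterior=False)


# ---------------------------------------------------------------------------
# nonlinear two-group scenario
# ---------------------------------------------------------------------------


def sim_two_group_nonlinear(
    n1: int = 200,
    n2: int = 100,
    p: int = 1000,
    seed: int | None = 0,
    r1: float = 1.0,
    r2: float = 2.5,
    sigma: float = 0.15,
):
    """Two groups separated by a nonlinear (radial) boundary in (x1, x2).

    Group 1 sits on a circle of radius r1, group 2 on radius r2, both with
    angular-uniform placement and radial noise sigma; features 3..p are
    i.i.d. standard normal.  Returns (n x p feature matrix, 0/1 labels).
    """
    if n1 < 1 or n2 < 1 or p < 2:
        raise DataError("need n1, n2 >= 1 and p >= 2")
    rng = np.random.default_rng(seed)
    n = n1 + n2
    labels = np.concatenate([np.zeros(n1, dtype=np.int64), np.ones(n2, dtype=np.int64)])
    radii = np.where(labels == 0, r1, r2) + rng.normal(0.0, sigma, size=n)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    X = np.empty((n, p))
    X[:, 0] = radii * np.cos(theta)
    X[:, 1] = radii * np.sin(theta)
    if p > 2:
        X[:, 2:] = rng.normal(size=(n, p - 2))
    perm = rng.permutation(n)
    return X[perm], labels[perm]


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def sim_low_coverage_dataset(cfg: SimConfig) -> dict:
    """Run the whole simulation pipeline under one seed.

    Returns a dict with the true genotypes ('true', DosageMatrix), observed
    genotypes ('observed'), per-site depths and qualities, genotype
    likelihoods ('gl'), posterior dosages ('dosage'), population labels and
    the realized error mask.
    """
    rng = np.random.default_rng(cfg.seed)
    true, pop_labels, kept = sim_admixed_genotypes(cfg, rng)
    G = true.values.astype(np.int64)
    n, p = G.shape
    depths = sim_depths(n, p, cfg.mean_depth, cfg.depth_shape, rng)
    Q = sim_quality(
        depths,
        rng=rng,
        slope=cfg.quality_slope,
        sd_base=cfg.quality_sd_base,
        sd_slope=cfg.quality_sd_slope,
        q_max=cfg.quality_max,
    )
    G_obs, err_mask = perturb_genotypes(G, Q, rng)
    observed = DosageMatrix(
        values=G_obs.astype(float),
        markers=list(true.markers),
        sample_ids=list(true.sample_ids),
        provenance="observed_genotype",
    )
    # base-calling error per read is roughly depth-independent; the
    # depth-driven genotype-call qualities Q above only govern the
    # observed-genotype perturbation
    eps_read = cfg.read_error
    reads = sim_reads(G, depths, eps_read, rng)
    gl = likelihoods_from_reads(reads, eps_read)
    gl = GenotypeLikelihoodSet(
        values=gl.values,
        markers=list(true.markers),
        sample_ids=list(true.sample_ids),
        is_posterior=False,
    )
    post = posteriors_from_likelihoods(gl, prior="hwe")
    ds = dosage_from_posteriors(post)
    return {
        "true": true,
        "observed": observed,
        "depths": depths,
        "qualities": Q,
        "reads": reads,
        "gl": gl,
        "dosage": ds,
        "pop_labels": pop_labels,
        "error_mask": err_mask,
        "kept_sites": kept,
        "config": cfg,
    }
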