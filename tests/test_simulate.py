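import numpy as np
import pytest

from mcpca import (
    ReadCounts,
    SimConfig,
    likelihoods_from_reads,
    parse_ms_output,
    perturb_genotypes,
    sim_admixed_genotypes,
    sim_depths,
    sim_low_coverage_dataset,
    sim_quality,
    sim_two_group_nonlinear,
)
from mcpca.dosage import dosage_from_posteriors, posteriors_from_likelihoods
from mcpca.errors import DataError, FormatError
from mcpca.simulate import diploid_genotypes, sim_reads

MS_BLOCK = """\
ms 2 1 -t 5
1234 5678 91011

//
segsites: 2
positions: 0.1 0.9
01
11
"""


class TestMsParser:
    def test_minimal_block(self):
        reps = parse_ms_output(MS_BLOCK)
        assert len(reps) == 1
        pos, haps = reps[0]
        assert np.allclose(pos, [0.1, 0.9])
        assert haps.tolist() == [[0, 1], [1, 1]]
        assert diploid_genotypes(haps).tolist() == [[1, 2]]

    def test_zero_segsites(self):
        reps = parse_ms_output("//\nsegsites: 0\n")
        pos, haps = reps[0]
        assert pos.size == 0 and haps.shape[1] == 0

    def test_two_replicates(self):
        text = MS_BLOCK + "\n//\nsegsites: 1\npositions: 0.5\n0\n1\n"
        assert len(parse_ms_output(text)) == 2

    def test_length_mismatch(self):
        bad = "//\nsegsites: 3\npositions: 0.1 0.5 0.9\n01\n"
        with pytest.raises(FormatError, match="length"):
            parse_ms_output(bad)

    def test_no_blocks(self):
        with pytest.raises(FormatError):
            parse_ms_output("ms 2 1\n")

    def test_odd_haplotypes_rejected(self):
        with pytest.raises(DataError):
            diploid_genotypes(np.zeros((3, 2), dtype=int))


class TestAdmixedGenotypes:
    def test_seed_reproducible(self):
        cfg = SimConfig(n_per_pop=10, p_sites=100, seed=3)
        X1, l1, k1 = sim_admixed_genotypes(cfg)
        X2, l2, k2 = sim_admixed_genotypes(cfg)
        assert np.array_equal(X1.values, X2.values)
        assert np.array_equal(k1, k2)

    def test_low_fst_populations_nearly_identical(self):
        cfg = SimConfig(n_per_pop=300, n_pops=2, p_sites=200, fst=1e-4, seed=0)
        X, labels, _ = sim_admixed_genotypes(cfg)
        means = np.array(
            [X.values[labels == k].mean(axis=0) for k in range(2)]
        )
        assert np.corrcoef(means)[0, 1] > 0.99

    def test_maf_postcondition(self):
        cfg = SimConfig(n_per_pop=30, p_sites=300, maf_threshold=0.05, seed=1)
        X, _, _ = sim_admixed_genotypes(cfg)
        f = X.values.mean(axis=0) / 2
        assert np.min(np.minimum(f, 1 - f)) >= 0.05

    def test_admixture_matrix_validated(self):
        with pytest.raises(DataError, match="admixture"):
            SimConfig(n_pops=3, admixture=[[1.0, 0.5], [0.0, 1.0]])

    def test_genotypes_are_hard_calls(self):
        cfg = SimConfig(n_per_pop=5, p_sites=50, seed=2)
        X, _, _ = sim_admixed_genotypes(cfg)
        assert X.provenance == "true_genotype"
        assert set(np.unique(X.values)) <= {0.0, 1.0, 2.0}


class TestDepths:
    def test_mean_matches(self, rng):
        d = sim_depths(250, 400, mean_depth=5.0, rng=rng)
        se = np.sqrt(25 / 6.3 / d.size)
        assert abs(d.mean() - 5.0) < 3 * se + 0.05  # rounding bias < 0.05

    def test_variance_matches_gamma(self, rng):
        # continuous Gamma(6.3, 5/6.3) variance = 25/6.3 = 3.968; rounding
        # to integers adds ~1/12, sampling noise ~0.02 at 1e5 draws
        d = sim_depths(250, 400, mean_depth=5.0, rng=rng)
        assert abs(d.var() - (25 / 6.3 + 1 / 12)) < 0.15

    def test_nonnegative_integers(self, rng):
        d = sim_depths(50, 50, mean_depth=0.5, rng=rng)
        assert d.min() >= 0 and np.issubdtype(d.dtype, np.integer)

    def test_bad_mean_depth(self):
        with pytest.raises(DataError):
            sim_depths(5, 5, mean_depth=0.0)


class TestQuality:
    def test_depth_zero_low_clamp(self, rng):
        q = sim_quality(np.zeros((100, 100), dtype=int), rng=rng)
        assert q.min() >= 0 and q.mean() < 1.0

    def test_mean_quality_monotone_in_depth(self, rng):
        q1 = sim_quality(np.full(10_000, 1), rng=rng)
        q10 = sim_quality(np.full(10_000, 10), rng=rng)
        assert q10.mean() > q1.mean()

    def test_table_mode_singleton_pools(self, rng):
        table = {1: [7.0], 2: [13.0]}
        depths = np.array([[1, 2], [2, 1]])
        q = sim_quality(depths, model="table", table=table, rng=rng)
        assert q.tolist() == [[7.0, 13.0], [13.0, 7.0]]

    def test_table_mode_nearest_depth_warns(self, rng):
        with pytest.warns(UserWarning, match="nearest"):
            q = sim_quality(
                np.array([[5]]), model="table", table={1: [9.0]}, rng=rng
            )
        assert q[0, 0] == 9.0

    def test_bad_model(self, rng):
        with pytest.raises(DataError):
            sim_quality(np.ones((2, 2)), model="lookup", rng=rng)


class TestPerturb:
    def test_high_quality_no_errors(self):
        G = np.random.default_rng(0).integers(0, 3, size=(100, 1000))
        out, mask = perturb_genotypes(G, np.full(G.shape, 60.0), seed=1)
        assert mask.mean() <= 1e-4
        assert np.array_equal(out[~mask], G[~mask])

    def test_zero_quality_all_errors(self):
        G = np.zeros((50, 50), dtype=int)
        out, mask = perturb_genotypes(G, np.zeros(G.shape), seed=2)
        assert mask.all()
        assert np.all(out != G)  # replacement is always a different genotype

    def test_realized_rate_matches_eps(self):
        G = np.ones((200, 200), dtype=int)
        Q = np.full(G.shape, 10.0)  # eps = 0.1
        _, mask = perturb_genotypes(G, Q, seed=3)
        se = np.sqrt(0.1 * 0.9 / G.size)
        assert abs(mask.mean() - 0.1) < 3 * se

    def test_allele_mode_stays_in_range(self):
        G = np.random.default_rng(1).integers(0, 3, size=(50, 50))
        out, _ = perturb_genotypes(G, np.zeros(G.shape), seed=4, mode="allele")
        assert out.min() >= 0 and out.max() <= 2
        assert np.all(np.abs(out - G) <= 1)

    def test_shape_mismatch(self):
        with pytest.raises(DataError):
            perturb_genotypes(np.zeros((2, 2)), np.zeros((3, 3)))


class TestReadLikelihoods:
    def test_single_minor_read_dosage(self):
        # d=1, a=1, eps ~ 0: L = (0, 1/2, 1); uniform-prior posteriors
        # (0, 1/3, 2/3); DS = 1/3 + 4/3 = 5/3
        reads = ReadCounts(depths=[[1]], minor_counts=[[1]])
        gl = likelihoods_from_reads(reads, eps=1e-12)
        post = posteriors_from_likelihoods(gl, prior="uniform")
        ds = dosage_from_posteriors(post)
        assert ds.values[0, 0] == pytest.approx(5 / 3, abs=1e-9)

    def test_zero_depth_gives_prior_mean(self):
        reads = ReadCounts(depths=[[0]], minor_counts=[[0]])
        gl = likelihoods_from_reads(reads, eps=0.01)
        assert np.allclose(gl.values[0, 0], [1, 1, 1])
        post = posteriors_from_likelihoods(gl, prior="hwe", af=0.3)
        ds = dosage_from_posteriors(post)
        assert ds.values[0, 0] == pytest.approx(0.6)  # 2 * af

    def test_eps_half_flat(self):
        reads = ReadCounts(depths=[[4]], minor_counts=[[1]])
        gl = likelihoods_from_reads(reads, eps=0.5)
        trip = gl.values[0, 0]
        assert np.allclose(trip, trip[0])

    def test_eps_out_of_range(self):
        reads = ReadCounts(depths=[[1]], minor_counts=[[0]])
        with pytest.raises(DataError):
            likelihoods_from_reads(reads, eps=0.0)

    def test_sim_reads_bounds(self, rng):
        G = rng.integers(0, 3, size=(20, 30))
        d = sim_depths(20, 30, 5.0, rng=rng)
        reads = sim_reads(G, d, eps=0.01, rng=rng)
        assert np.all(reads.minor_counts <= reads.depths)


class TestTwoGroupNonlinear:
    def test_radius_separates_groups(self):
        X, labels = sim_two_group_nonlinear(200, 100, 10, seed=0)
        r = np.hypot(X[:, 0], X[:, 1])
        pred = (r > 1.75).astype(int)  # midpoint of the two radii
        assert (pred == labels).mean() >= 0.99

    def test_noise_features_uncorrelated_with_labels(self):
        X, labels = sim_two_group_nonlinear(200, 100, 50, seed=1)
        cors = [
            abs(np.corrcoef(X[:, k], labels)[0, 1]) for k in range(2, 50)
        ]
        assert np.mean(cors) < 3 / np.sqrt(300)

    def test_reproducible(self):
        X1, l1 = sim_two_group_nonlinear(20, 10, 5, seed=9)
        X2, l2 = sim_two_group_nonlinear(20, 10, 5, seed=9)
        assert np.array_equal(X1, X2) and np.array_equal(l1, l2)

    def test_bad_args(self):
        with pytest.raises(DataError):
            sim_two_group_nonlinear(0, 10, 5)


class TestPipeline:
    def test_dataset_components_consistent(self):
        cfg = SimConfig(n_per_pop=10, p_sites=200, mean_depth=5, seed=5)
        d = sim_low_coverage_dataset(cfg)
        n, p = d["true"].values.shape
        assert d["observed"].values.shape == (n, p)
        assert d["dosage"].values.shape == (n, p)
        assert d["depths"].shape == (n, p)
        assert d["gl"].n_sites == p
        # error mask matches where observed differs from true
        diff = d["observed"].values != d["true"].values
        assert np.array_equal(diff, d["error_mask"] & diff)

    def test_dosage_approaches_truth_at_high_depth(self):
        cfg = SimConfig(
            n_per_pop=10, p_sites=150, mean_depth=100, seed=6,
            quality_slope=30.0, quality_sd_base=0.0, quality_sd_slope=0.0,
            quality_max=40.0,
        )
        d = sim_low_coverage_dataset(cfg)
        assert np.abs(d["dosage"].values - d["true"].values).max() < 0.01

    def test_regime_monotone_in_depth_quick(self):
        errs, devs = [], []
        for depth in (1, 5, 10):
            cfg = SimConfig(n_per_pop=15, p_sites=400, mean_depth=depth, seed=8)
            d = sim_low_coverage_dataset(cfg)
            errs.append(d["error_mask"].mean())
            devs.append(np.abs(d["dosage"].values - d["true"].values).mean())
        assert errs[0] > errs[1] > errs[2]
        assert devs[0] > devs[1] > devs[2]

    def test_dosage_mode_concentration_sharpens_with_depth(self):
        spread = []
        for depth in (1, 5, 10):
            cfg = SimConfig(n_per_pop=15, p_sites=400, mean_depth=depth, seed=9)
            d = sim_low_coverage_dataset(cfg)
            ds = d["dosage"].values
            spread.append(((ds - np.rint(ds)) ** 2).mean())
        assert spread[0] > spread[1] > spread[2]
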