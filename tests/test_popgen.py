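"""Windowed kinship, diversity, Fst and LD against brute-force oracles."""

import numpy as np
import pytest

import sdrmap as sm
from sdrmap.containers import MISSING, GenotypeMatrix

import oracles


def random_fixture(seed, n_samples=12, n_sites=100, missing_rate=0.05, span=900_000):
    """Random dosage matrix with missing data inside one 1-Mb window."""
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(span, size=n_sites, replace=False)) + 1
    p = rng.uniform(0.05, 0.95, size=n_sites)
    geno = (rng.random((n_samples, n_sites)) < p).astype(np.int8) + (
        rng.random((n_samples, n_sites)) < p
    ).astype(np.int8)
    geno[rng.random(geno.shape) < missing_rate] = MISSING
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples, positions, geno)


class TestKinship:
    def test_identical_vectors_give_half(self):
        """Duplicated sample with het sites: phi = 0.5 exactly."""
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(1, 60), dtype=np.int8)
        gm = GenotypeMatrix(
            ["a", "b"], np.arange(60) * 10_000, np.vstack([geno, geno])
        )
        out = sm.kinship(gm, ("a", "b"))
        assert (out["phi"] == 0.5).all()

    def test_self_pair_allowed(self):
        gm = GenotypeMatrix(["a"], np.array([100, 200]), np.array([[1, 0]], dtype=np.int8))
        out = sm.kinship(gm, ("a", "a"))
        assert out.loc[0, "phi"] == 0.5

    def test_component_formula_directly(self):
        """i all-het vs j opposite-homozygote pattern: phi = -2m/n."""
        n, m = 8, 3
        # m sites with (0,2) opposite homozygotes, n sites het in i only
        gi_full = np.concatenate([np.zeros(m, dtype=np.int8), np.ones(n, dtype=np.int8)])
        gj_full = np.concatenate([np.full(m, 2, dtype=np.int8), np.zeros(n, dtype=np.int8)])
        gm = GenotypeMatrix(
            ["i", "j"], np.arange(m + n) * 1000, np.vstack([gi_full, gj_full])
        )
        out = sm.kinship(gm, ("i", "j"))
        assert out.loc[0, "N_AA_aa"] == m and out.loc[0, "N_Aa_i"] == n
        assert out.loc[0, "phi"] == pytest.approx(-2 * m / n)

    def test_unrelated_hwe_samples_center_on_zero(self):
        """Two independent HWE genomes at 10,000 sites: phi within 3 sigma of 0."""
        rng = np.random.default_rng(1)
        n_sites = 10_000
        p = rng.uniform(0.2, 0.8, size=n_sites)
        draw = lambda: ((rng.random(n_sites) < p).astype(np.int8) + (rng.random(n_sites) < p).astype(np.int8))
        gm = GenotypeMatrix(
            ["a", "b"], np.arange(n_sites) * 10, np.vstack([draw(), draw()])
        )
        out = sm.kinship(gm, ("a", "b"), window_bp=10 * n_sites)
        # Monte-Carlo spread of phi for unrelated pairs at this site count
        phis = []
        for s in range(30):
            r2 = np.random.default_rng(100 + s)
            g1 = (r2.random(n_sites) < p).astype(np.int8) + (r2.random(n_sites) < p).astype(np.int8)
            g2 = (r2.random(n_sites) < p).astype(np.int8) + (r2.random(n_sites) < p).astype(np.int8)
            phis.append(oracles.king_phi(g1, g2))
        assert abs(out.loc[0, "phi"]) < 3 * np.std(phis) + abs(np.mean(phis))

    def test_symmetry_and_permutation_invariance(self):
        gm = random_fixture(2)
        a = sm.kinship(gm, ("s0", "s1"))["phi"]
        b = sm.kinship(gm, ("s1", "s0"))["phi"]
        assert np.allclose(a, b, equal_nan=True)

    def test_zero_denominator_window_missing(self):
        gm = GenotypeMatrix(
            ["a", "b"], np.array([100, 200]), np.array([[0, 2], [0, 2]], dtype=np.int8)
        )
        assert np.isnan(sm.kinship(gm, ("a", "b")).loc[0, "phi"])

    @pytest.mark.parametrize("eps_pair", [(0.0, 0.005), (0.005, 0.02)])
    def test_degradation_monotone_in_error(self, eps_pair):
        """Errors on one copy of an identical pair pull phi below 0.5, monotonically."""
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, size=5000, dtype=np.int8)
        phis = {}
        for eps in eps_pair:
            noisy = base.copy()
            err = rng.random(base.shape) < eps
            noisy[err] = (noisy[err] + rng.integers(1, 3, size=int(err.sum()))) % 3
            gm = GenotypeMatrix(
                ["a", "b"], np.arange(5000) * 100, np.vstack([base, noisy])
            )
            phis[eps] = sm.kinship(gm, ("a", "b"), window_bp=500_000).loc[0, "phi"]
        lo, hi = eps_pair
        assert phis[hi] < phis[lo] <= 0.5


class TestDiversity:
    def test_two_haplotype_closed_form(self):
        """One diploid (2 haplotypes) differing at k het sites: pi = k / window."""
        k = 7
        gm = GenotypeMatrix(
            ["a"], np.arange(k) * 1000, np.full((1, k), 1, dtype=np.int8)
        )
        out = sm.nucleotide_diversity(gm, window_bp=1_000_000)
        assert out.loc[0, "pi"] == pytest.approx(k / 1e6)

    def test_monomorphic_window_zero(self):
        gm = GenotypeMatrix(
            ["a", "b"], np.array([10, 20]), np.zeros((2, 2), dtype=np.int8)
        )
        assert sm.nucleotide_diversity(gm).loc[0, "pi"] == 0.0

    def test_hwe_expectation(self):
        """Window pi approximates the mean per-site 2pq (with the n/(n-1) factor)."""
        rng = np.random.default_rng(4)
        n_ind, n_sites, W = 20, 400, 1_000_000
        p = rng.uniform(0.1, 0.9, size=n_sites)
        geno = (rng.random((n_ind, n_sites)) < p).astype(np.int8) + (
            rng.random((n_ind, n_sites)) < p
        ).astype(np.int8)
        positions = np.sort(rng.choice(W - 1, n_sites, replace=False)) + 1
        gm = GenotypeMatrix([f"s{i}" for i in range(n_ind)], positions, geno)
        out = sm.nucleotide_diversity(gm, window_bp=W)
        expected = np.sum(2 * p * (1 - p)) / W
        sd = np.sqrt(np.sum((2 * p * (1 - p)) ** 2 / (2 * n_ind))) / W
        assert abs(out.loc[0, "pi"] - expected) < 3 * sd


class TestFst:
    def _pop(self, rng, n, p):
        return (rng.random((n, len(p))) < p).astype(np.int8) + (
            rng.random((n, len(p))) < p
        ).astype(np.int8)

    def test_fixed_difference_is_one(self):
        g = np.vstack([np.zeros((4, 5), dtype=np.int8), np.full((4, 5), 2, dtype=np.int8)])
        gm = GenotypeMatrix([f"s{i}" for i in range(8)], np.arange(5) * 100, g)
        groups = {f"s{i}": ("a" if i < 4 else "b") for i in range(8)}
        assert sm.fst_weir_cockerham(gm, groups).loc[0, "fst"] == pytest.approx(1.0)

    def test_identical_groups_center_on_zero(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.2, 0.8, 500)
        vals = []
        for s in range(8):
            r = np.random.default_rng(50 + s)
            g = np.vstack([self._pop(r, 10, p), self._pop(r, 10, p)])
            gm = GenotypeMatrix([f"s{i}" for i in range(20)], np.arange(500) * 100, g)
            groups = {f"s{i}": ("a" if i < 10 else "b") for i in range(20)}
            vals.append(sm.fst_weir_cockerham(gm, groups).loc[0, "fst"])
        assert abs(np.mean(vals)) < 3 * np.std(vals) / np.sqrt(len(vals)) + 0.01

    def test_small_group_rejected(self):
        gm = random_fixture(6, n_samples=3)
        groups = {"s0": "a", "s1": "a", "s2": "b"}
        with pytest.raises(ValueError, match="fewer than 2"):
            sm.fst_weir_cockerham(gm, groups)

    def test_sdr_fst_exceeds_par_fst_in_xy_population(self, chrom):
        """Shared male Y haplotype inflates male-female Fst inside the SDR."""
        pop, sexes = sm.simulate_population(chrom, seed=7)
        out = sm.fst_weir_cockerham(pop, sexes)
        in_sdr = out["window_end"] <= chrom.sdr_end_bp
        assert out.loc[in_sdr, "fst"].mean() > out.loc[~in_sdr, "fst"].mean()


class TestLD:
    def test_identical_dosage_vectors_give_one(self):
        rng = np.random.default_rng(8)
        col = rng.integers(0, 3, size=10, dtype=np.int8)
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(10)],
            np.array([100, 5_100]),
            np.column_stack([col, col]),
        )
        out = sm.ld_median_r2(gm, min_pairs=1)
        assert out.loc[0, "median_r2"] == pytest.approx(1.0)

    def test_pairs_outside_distance_range_excluded(self):
        rng = np.random.default_rng(9)
        col = rng.integers(0, 3, size=10, dtype=np.int8)
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(10)],
            np.array([100, 50_100]),  # 50 kb apart
            np.column_stack([col, col]),
        )
        out = sm.ld_median_r2(gm, min_pairs=1)
        assert out.loc[0, "n_pairs"] == 0 and np.isnan(out.loc[0, "median_r2"])

    def test_min_pairs_threshold(self):
        gm = random_fixture(10, n_sites=6, missing_rate=0.0, span=20_000)
        out = sm.ld_median_r2(gm, min_pairs=1000)
        assert out["median_r2"].isna().all()

    def test_independent_sites_have_low_median_r2(self):
        """Unlinked HWE sites: median r2 near the 1/n sampling floor."""
        rng = np.random.default_rng(11)
        n = 100
        p = rng.uniform(0.3, 0.7, size=50)
        geno = (rng.random((n, 50)) < p).astype(np.int8) + (rng.random((n, 50)) < p).astype(np.int8)
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(n)], np.arange(50) * 2_000 + 1_000, geno
        )
        out = sm.ld_median_r2(gm)
        assert out.loc[0, "median_r2"] < 5 / n


class TestOracleEquivalence:
    """Vectorised statistics match naive loop implementations to 1e-10."""

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_pi(self, seed):
        gm = random_fixture(seed)
        got = sm.nucleotide_diversity(gm).loc[0, "pi"]
        want = oracles.pi_pairwise(gm.genotypes, 1_000_000)
        assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("seed", [24, 25, 26])
    def test_fst(self, seed):
        gm = random_fixture(seed)
        half = gm.n_samples // 2
        groups = {s: ("a" if i < half else "b") for i, s in enumerate(gm.samples)}
        got = sm.fst_weir_cockerham(gm, groups).loc[0, "fst"]
        idx = list(range(half)), list(range(half, gm.n_samples))
        want = oracles.fst_wc84(gm.genotypes[idx[0]], gm.genotypes[idx[1]])
        assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("seed", [27, 28])
    def test_median_r2(self, seed):
        gm = random_fixture(seed, n_sites=60, span=120_000)
        got = sm.ld_median_r2(gm, min_pairs=1)
        want, n_pairs = oracles.median_r2(gm.genotypes, gm.positions, 1_000, 10_000)
        assert got.loc[0, "n_pairs"] == n_pairs
        assert got.loc[0, "median_r2"] == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("seed", [29, 30])
    def test_kinship(self, seed):
        gm = random_fixture(seed)
        got = sm.kinship(gm, ("s0", "s1")).loc[0, "phi"]
        want = oracles.king_phi(gm.row("s0"), gm.row("s1"))
        assert got == pytest.approx(want, abs=1e-10)

    def test_site_permutation_leaves_window_stats_unchanged(self):
        """Statistics depend on site content, not input column order."""
        gm = random_fixture(31)
        perm = np.random.default_rng(0).permutation(gm.n_sites)
        order = np.argsort(gm.positions[perm])
        gm2 = GenotypeMatrix(
            gm.samples, gm.positions[perm][order], gm.genotypes[:, perm][:, order]
        )
        assert sm.nucleotide_diversity(gm).equals(sm.nucleotide_diversity(gm2))
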