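"""SNP filtering, Patterson's D, block jackknife, and Weir-Cockerham F_ST."""

import numpy as np
import pytest
from conftest import brute_force_jackknife_se

import craterlakes as cl
from craterlakes.popgen import _jackknife, _wc_theta


def toy_genotypes(matrix, pops, locus_ids=None, outgroup=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    n, m = matrix.shape
    return cl.GenotypeDataset(
        genotypes=matrix,
        samples=[f"s{i}" for i in range(n)],
        pops=np.array(pops, dtype=object),
        locus_ids=np.array(
            locus_ids if locus_ids is not None else [f"l{j}" for j in range(m)],
            dtype=object,
        ),
        outgroup=outgroup,
    )


class TestFilterSnps:
    def test_one_snp_per_locus(self):
        geno = toy_genotypes(
            np.tile([0, 1, 2], (5, 1)).T.repeat(2, axis=0).reshape(3, -1).T[:6, :5].T
            if False
            else np.ones((6, 5), dtype=np.int8),
            ["A"] * 6,
            locus_ids=["l1", "l1", "l1", "l2", "l2"],
        )
        out = cl.filter_snps(geno, min_per_pop=6)
        assert out.n_snps == 2
        assert list(out.locus_ids) == ["l1", "l2"]
        assert out.filter_counts["dropped_duplicate_locus"] == 3

    def test_call_threshold_per_population(self):
        g = np.ones((6, 2), dtype=np.int8)
        g[0, 1] = -1  # only 5 called in A at SNP 2
        geno = toy_genotypes(g, ["A"] * 6)
        out = cl.filter_snps(geno, min_per_pop=6)
        assert out.n_snps == 1

    def test_outgroup_lower_threshold(self):
        g = np.ones((9, 1), dtype=np.int8)
        g[6:8, 0] = -1  # outgroup has 1 of 3 called
        geno = toy_genotypes(g, ["A"] * 6 + ["out"] * 3, outgroup="out")
        with pytest.raises(ValueError, match="no SNPs survive"):
            cl.filter_snps(geno, min_per_pop=6, min_outgroup=3)
        g[6:8, 0] = 0
        out = cl.filter_snps(toy_genotypes(g, ["A"] * 6 + ["out"] * 3, outgroup="out"))
        assert out.n_snps == 1

    def test_idempotent(self, null_genotypes):
        once = cl.filter_snps(null_genotypes, min_per_pop=5, min_outgroup=3)
        twice = cl.filter_snps(once, min_per_pop=5, min_outgroup=3)
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)


class TestDStatistic:
    def fixed_site_dataset(self, n_sites=4):
        # p_W=1, p_X=0, p_Y=1, p_Z=0 at every site
        g = np.zeros((8, n_sites), dtype=np.int8)
        g[0:2] = 2  # W
        g[4:6] = 2  # Y
        return toy_genotypes(g, ["W", "W", "X", "X", "Y", "Y", "Z", "Z"])

    def test_fixed_difference_closed_form(self):
        geno = self.fixed_site_dataset()
        res = cl.d_statistic(geno, ("W", "X", "Y", "Z"), block_size_snps=2)
        assert res.D == pytest.approx(1.0, abs=1e-12)
        assert res.baba == pytest.approx(4.0, abs=1e-12)
        assert res.abba == pytest.approx(0.0, abs=1e-12)

    def test_sister_populations_equal_gives_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 50)
        gw = rng.binomial(2, p, (5, 50)).astype(np.int8)
        gy = rng.binomial(2, p, (5, 50)).astype(np.int8)
        gz = rng.binomial(2, p, (5, 50)).astype(np.int8)
        g = np.vstack([gw, gw, gy, gz])  # X is an exact copy of W
        geno = toy_genotypes(g, ["W"] * 5 + ["X"] * 5 + ["Y"] * 5 + ["Z"] * 5)
        res = cl.d_statistic(geno, ("W", "X", "Y", "Z"), block_size_snps=10)
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_jackknife_brute_force_oracle(self, null_genotypes):
        res = cl.d_statistic(null_genotypes, ("W", "X", "Y", "Z"),
                             block_size_snps=500)
        freqs = np.stack(
            [null_genotypes.allele_freqs(p) for p in ("W", "X", "Y", "Z")]
        )
        usable = ~np.isnan(freqs).any(axis=0)
        pw, px, py, pz = freqs[:, usable]
        num = (pw - px) * (py - pz)
        den = (pw + px - 2 * pw * px) * (py + pz - 2 * py * pz)
        assert res.n_blocks == 4
        assert res.se == pytest.approx(
            brute_force_jackknife_se(num, den, 4), abs=1e-12
        )

    def test_antisymmetry_under_swaps(self, null_genotypes):
        base = cl.d_statistic(null_genotypes, ("W", "X", "Y", "Z"), 500)
        wx = cl.d_statistic(null_genotypes, ("X", "W", "Y", "Z"), 500)
        yz = cl.d_statistic(null_genotypes, ("W", "X", "Z", "Y"), 500)
        both = cl.d_statistic(null_genotypes, ("X", "W", "Z", "Y"), 500)
        assert wx.D == pytest.approx(-base.D, abs=1e-12)
        assert yz.D == pytest.approx(-base.D, abs=1e-12)
        assert both.D == pytest.approx(base.D, abs=1e-12)

    def test_sign_matches_baba_minus_abba(self, null_genotypes):
        res = cl.d_statistic(null_genotypes, ("W", "X", "Y", "Z"), 500)
        assert np.sign(res.D) == np.sign(res.baba - res.abba)

    def test_admixture_shifts_d_positive(self):
        ds = []
        for i in range(20):
            geno = cl.generate_genotype_dataset(
                cl.SyntheticGenotypeSpec(n_snps=500, admix_f=0.3), seed=200 + i
            )
            ds.append(cl.d_statistic(geno, ("W", "X", "Y", "Z"), 100).D)
        assert np.mean(ds) > 0

    def test_too_few_blocks_rejected(self):
        geno = self.fixed_site_dataset(n_sites=3)
        with pytest.raises(ValueError, match="blocks"):
            cl.d_statistic(geno, ("W", "X", "Y", "Z"), block_size_snps=500)

    def test_no_informative_sites_rejected(self):
        g = np.full((8, 4), 2, dtype=np.int8)
        geno = toy_genotypes(g, ["W", "W", "X", "X", "Y", "Y", "Z", "Z"])
        with pytest.raises(ValueError, match="informative"):
            cl.d_statistic(geno, ("W", "X", "Y", "Z"), block_size_snps=2)

    def test_model_wrapper(self, null_genotypes):
        res = cl.PattersonD(null_genotypes, ("W", "X", "Y", "Z"), 500).fit()
        assert "Patterson's D" in res.summary()
        assert abs(res.D) <= 1


class TestWeightedJackknife:
    def test_reduces_to_plain_jackknife_for_equal_blocks(self):
        rng = np.random.default_rng(1)
        num = rng.normal(size=40)
        den = rng.uniform(0.5, 1.5, size=40)
        blocks = np.arange(40) // 10
        theta, se, g = _jackknife(num, den, blocks)
        assert g == 4
        assert theta == pytest.approx(num.sum() / den.sum(), abs=1e-15)
        assert se == pytest.approx(brute_force_jackknife_se(num, den, 4), abs=1e-12)


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        g = np.zeros((8, 5), dtype=np.int8)
        g[4:] = 2
        geno = toy_genotypes(g, ["A"] * 4 + ["B"] * 4)
        assert cl.weir_cockerham_fst(geno, "A", "B") == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_variance_components(self):
        # popA: 7 hom-ref, 2 het, 1 hom-alt -> p=0.2, het=0.2
        # popB mirrored -> p=0.8, het=0.2; n1=n2=10
        ga = np.array([0] * 7 + [1] * 2 + [2], dtype=np.int8)
        gb = np.array([2] * 7 + [1] * 2 + [0], dtype=np.int8)
        geno = toy_genotypes(
            np.concatenate([ga, gb]).reshape(-1, 1), ["A"] * 10 + ["B"] * 10
        )
        # independent scalar arithmetic
        n, r = 10.0, 2.0
        nbar, nc = 10.0, 10.0
        p1, p2, h = 0.2, 0.8, 0.2
        pbar = 0.5
        s2 = (n * (p1 - pbar) ** 2 + n * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - h / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * h)
        c = h / 2
        assert cl.weir_cockerham_fst(geno, "A", "B") == pytest.approx(
            a / (a + b + c), abs=1e-12
        )

    def test_symmetry(self, null_genotypes):
        ab = cl.weir_cockerham_fst(null_genotypes, "W", "Y")
        ba = cl.weir_cockerham_fst(null_genotypes, "Y", "W")
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_panmictic_samples_near_zero(self):
        # two n=20 samples drawn from one set of frequencies: theta ~ 0
        rng = np.random.default_rng(7)
        p = rng.uniform(0.05, 0.95, 1000)
        g = rng.binomial(2, p, (40, 1000)).astype(np.int8)
        geno = toy_genotypes(g, ["A"] * 20 + ["B"] * 20)
        assert abs(cl.weir_cockerham_fst(geno, "A", "B")) < 0.02

    def test_handles_missing_genotypes(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.4, (12, 200)).astype(np.int8)
        miss = rng.random(g.shape) < 0.15
        gm = g.copy()
        gm[miss] = -1
        geno = toy_genotypes(gm, ["A"] * 6 + ["B"] * 6)
        val = cl.weir_cockerham_fst(geno, "A", "B")
        assert np.isfinite(val) and val <= 1

    def test_monomorphic_only_rejected(self):
        g = np.zeros((8, 3), dtype=np.int8)
        geno = toy_genotypes(g, ["A"] * 4 + ["B"] * 4)
        with pytest.raises(ValueError):
            cl.weir_cockerham_fst(geno, "A", "B")


class TestFstPermutation:
    def test_strong_differentiation_minimum_p(self):
        geno = cl.generate_genotype_dataset(
            cl.SyntheticGenotypeSpec(
                n_snps=1000,
                drift={"internal": 0.0, "wx": 0.0, "w": 0.3, "x": 0.3,
                       "y": 0.0, "z": 0.0},
            ),
            seed=31,
        )
        res = cl.fst_permutation_test(geno, "W", "X", n_perm=199, seed=32)
        assert res.fst > 0.1
        assert res.p_perm == pytest.approx(1.0 / 200.0, abs=1e-12)

    def test_seed_determinism(self, null_genotypes):
        r1 = cl.fst_permutation_test(null_genotypes, "W", "X", n_perm=99, seed=5)
        r2 = cl.fst_permutation_test(null_genotypes, "W", "X", n_perm=99, seed=5)
        assert r1.p_perm == r2.p_perm
        assert "F_ST" in r1.summary()

    def test_model_wrapper(self, null_genotypes):
        res = cl.WeirCockerhamFst(null_genotypes, "W", "X", n_perm=49).fit(seed=6)
        assert 0 < res.p_perm <= 1
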