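import numpy as np
import pytest

from admixscan.fstats import (
    FreqTable,
    block_jackknife,
    f3,
    f4,
    f4_ratio,
)


def table_from_arrays(**pops):
    """pops: name -> (freq array, haploid size scalar or array)."""
    n = len(next(iter(pops.values()))[0])
    freqs, sizes = {}, {}
    for name, (f, s) in pops.items():
        freqs[name] = np.asarray(f, dtype=float)
        sizes[name] = np.full(n, s) if np.isscalar(s) else np.asarray(s)
    return FreqTable(chrom=np.full(n, "chr1", dtype=object),
                     pos=np.arange(1, n + 1), freqs=freqs, sizes=sizes)


class TestBlockJackknife:
    def test_identical_blocks_zero_se(self):
        terms = np.tile([1.0, 2.0, 3.0], 4)  # every block mean = 2
        est, se = block_jackknife(terms, block_size=3)
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_two_unequal_blocks_hand_computed(self):
        terms = np.array([1.0, 3.0, 2.0, 6.0, 4.0])  # blocks of 3 and 2
        est, se = block_jackknife(terms, block_size=3)
        # weighted delete-one jackknife, written out longhand
        n, g = 5.0, 2
        m = np.array([3.0, 2.0])
        theta = terms.mean()
        theta_del = np.array([terms[3:].mean(), terms[:3].mean()])
        h = n / m
        theta_dot = g * theta - ((1 - m / n) * theta_del).sum()
        tau = h * theta - (h - 1) * theta_del
        var = ((tau - theta_dot) ** 2 / (h - 1)).sum() / g
        assert est == pytest.approx(theta)
        assert se == pytest.approx(np.sqrt(var))

    def test_iid_normal_matches_naive_se(self):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(100):
            x = rng.normal(size=2000)
            _, se = block_jackknife(x, block_size=100)
            ratios.append(se / (x.std(ddof=1) / np.sqrt(len(x))))
        assert abs(np.mean(ratios) - 1.0) < 0.2

    def test_block_size_too_large(self):
        with pytest.raises(ValueError):
            block_jackknife(np.arange(10.0), block_size=10)


class TestF3:
    def test_target_equals_source_no_correction(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0.1, 0.9, 1000)
        ft = table_from_arrays(C=(f, 50), A=(f, 50),
                               B=(rng.uniform(0.1, 0.9, 1000), 50))
        res = f3(ft, "C", "A", "B", block_size=100, correction=False)
        assert res.value == pytest.approx(0.0, abs=1e-15)

    def test_four_snp_toy_vs_arithmetic_oracle(self):
        c = np.array([0.5, 0.2, 0.9, 0.4])
        a = np.array([0.1, 0.3, 0.8, 0.6])
        b = np.array([0.7, 0.1, 0.95, 0.2])
        n_c = 20
        ft = table_from_arrays(C=(c, n_c), A=(a, 40), B=(b, 40))
        res = f3(ft, "C", "A", "B", block_size=2)
        oracle = np.mean((c - a) * (c - b) - c * (1 - c) / (n_c - 1))
        assert res.value == pytest.approx(oracle)
        assert res.n_snps == 4
        res_nc = f3(ft, "C", "A", "B", block_size=2, correction=False)
        assert res_nc.value == pytest.approx(np.mean((c - a) * (c - b)))

    def test_admixed_target_negative(self, ds40):
        ft = FreqTable.from_genotypes(
            {"P": ds40.pop_p, "T": ds40.pop_admixed, "A": ds40.pop_a})
        res = f3(ft, "T", "P", "A")
        assert res.n_snps > 10_000
        assert res.value < 0
        assert res.z < -3

    def test_non_admixed_target_non_negative(self, ds40):
        # target drawn from source A itself: f3 >= 0 within 2 SE
        half = ds40.pop_a.n_samples // 2
        ft = FreqTable.from_genotypes({"P": ds40.pop_p})
        ft.subsample("A1", ds40.pop_a, np.arange(half))
        ft.subsample("A2", ds40.pop_a, np.arange(half, ds40.pop_a.n_samples))
        res = f3(ft, "A1", "P", "A2")
        assert res.value > -2 * res.se

    def test_flip_invariance(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(0.05, 0.95, 600)
        a = rng.uniform(0.05, 0.95, 600)
        b = rng.uniform(0.05, 0.95, 600)
        ft = table_from_arrays(C=(c, 30), A=(a, 30), B=(b, 30))
        flip = rng.random(600) < 0.5
        ft2 = table_from_arrays(C=(np.where(flip, 1 - c, c), 30),
                                A=(np.where(flip, 1 - a, a), 30),
                                B=(np.where(flip, 1 - b, b), 30))
        r1 = f3(ft, "C", "A", "B", block_size=100)
        r2 = f3(ft2, "C", "A", "B", block_size=100)
        assert r1.value == pytest.approx(r2.value)
        assert r1.se == pytest.approx(r2.se)

    def test_symmetry_in_sources(self):
        rng = np.random.default_rng(4)
        ft = table_from_arrays(C=(rng.uniform(0.1, 0.9, 300), 30),
                               A=(rng.uniform(0.1, 0.9, 300), 30),
                               B=(rng.uniform(0.1, 0.9, 300), 30))
        assert f3(ft, "C", "A", "B", 50).value == pytest.approx(
            f3(ft, "C", "B", "A", 50).value)

    def test_monomorphic_snp_contributes_zero_but_retained(self):
        c = np.array([0.0, 0.5, 0.8, 0.1])
        a = np.array([0.0, 0.2, 0.6, 0.3])
        b = np.array([0.0, 0.9, 0.9, 0.2])
        ft = table_from_arrays(C=(c, 20), A=(a, 20), B=(b, 20))
        res = f3(ft, "C", "A", "B", block_size=2)
        assert res.n_snps == 4


class TestF4:
    def test_c_equals_d_zero(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(0.1, 0.9, 400)
        ft = table_from_arrays(A=(rng.uniform(0.1, 0.9, 400), 30),
                               B=(rng.uniform(0.1, 0.9, 400), 30),
                               C=(f, 30), D=(f, 30))
        assert f4(ft, ("A", "B", "C", "D"), 100).value == pytest.approx(0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        ft = table_from_arrays(**{k: (rng.uniform(0.1, 0.9, 400), 30)
                                  for k in "ABCD"})
        r1 = f4(ft, ("A", "B", "C", "D"), 100)
        r2 = f4(ft, ("A", "B", "D", "C"), 100)
        r3 = f4(ft, ("B", "A", "C", "D"), 100)
        assert r1.value == pytest.approx(-r2.value)
        assert r1.value == pytest.approx(-r3.value)

    def test_toy_oracle(self):
        a = np.array([0.2, 0.8, 0.5, 0.3])
        b = np.array([0.6, 0.1, 0.5, 0.9])
        c = np.array([0.3, 0.4, 0.2, 0.8])
        d = np.array([0.9, 0.2, 0.7, 0.1])
        ft = table_from_arrays(A=(a, 30), B=(b, 30), C=(c, 30), D=(d, 30))
        res = f4(ft, ("A", "B", "C", "D"), 2)
        assert res.value == pytest.approx(np.mean((a - b) * (c - d)))


class TestF4Ratio:
    def test_target_is_denominator_proxy(self):
        rng = np.random.default_rng(7)
        ft = table_from_arrays(**{k: (rng.uniform(0.1, 0.9, 400), 30)
                                  for k in ("A", "O", "C", "P")})
        res = f4_ratio(ft, ("A", "O", "C", "P"), ("A", "O", "C", "P"), 100)
        assert res.value == pytest.approx(1.0)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_target_is_other_source(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.1, 0.9, 400)
        ft = table_from_arrays(A=(rng.uniform(0.1, 0.9, 400), 30),
                               O=(rng.uniform(0.1, 0.9, 400), 30),
                               C=(rng.uniform(0.1, 0.9, 400), 30),
                               P=(p, 30), P2=(p, 30))
        res = f4_ratio(ft, ("A", "O", "P2", "P"), ("A", "O", "C", "P"), 100)
        assert res.value == pytest.approx(0.0)

    def test_recovers_admixture_proportion(self, ds_outgroup):
        # alpha(A ancestry in admixed) = 1 - alpha_P = 0.754 within 2 SE;
        # the denominator target is a clean A proxy split at admixture time
        ds = ds_outgroup
        ft = FreqTable.from_genotypes(
            {"P": ds.pop_p, "T": ds.pop_admixed, "A": ds.pop_a,
             "X": ds.pop_proxy_a, "O": ds.pop_out})
        res = f4_ratio(ft, ("A", "O", "T", "P"), ("A", "O", "X", "P"))
        assert abs(res.value - 0.754) < 2 * res.se
        assert res.se < 0.05

    def test_zero_denominator(self):
        rng = np.random.default_rng(9)
        f = rng.uniform(0.1, 0.9, 300)
        ft = table_from_arrays(A=(rng.uniform(0.1, 0.9, 300), 30),
                               O=(rng.uniform(0.1, 0.9, 300), 30),
                               C=(f, 30), D=(f, 30),
                               T=(rng.uniform(0.1, 0.9, 300), 30))
        with pytest.raises(ZeroDivisionError):
            f4_ratio(ft, ("A", "O", "T", "D"), ("A", "O", "C", "D"), 100)


class TestFreqTable:
    def test_mismatched_snp_sets_rejected(self, ds40):
        from conftest import make_gm
        other = make_gm(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            FreqTable.from_genotypes({"a": ds40.pop_p, "b": other})

    def test_missing_handled(self):
        from conftest import make_gm
        geno = np.array([[0, -1], [2, 1]], dtype=np.int8)
        ft = FreqTable.from_genotypes({"x": make_gm(geno)})
        assert ft.freqs["x"][0] == pytest.approx(0.5)
        assert ft.freqs["x"][1] == pytest.approx(0.5)
        assert ft.sizes["x"][1] == 2
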