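import numpy as np
import pytest

from admixscan import DemographyConfig, SelectedLocusSpec
from admixscan import simulate as sim
from admixscan.wf_abc import simulate_trajectories


class TestDemographyConfig:
    @pytest.mark.parametrize("kwargs", [
        {"alpha_P": 1.2},
        {"alpha_P": -0.1},
        {"g": 2000},                       # g >= t_split
        {"sample_chromosomes": (49, 46, 90)},   # odd
        {"sample_chromosomes": (48, 46, 2001)}, # > 2N
        {"mu": -1e-9},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            DemographyConfig(**kwargs)


class TestSimulateNeutral:
    def test_alpha_zero_all_a(self):
        cfg = DemographyConfig(n_segments=3, alpha_P=0.0)
        ds = sim.simulate_neutral(cfg, 5)
        assert ds.n_snps > 0
        assert (ds.true_ancestry == 0).all()
        # admixed frequencies track source A within drift expectation
        fa = ds.pop_a.alt_freq()
        ft = ds.pop_admixed.alt_freq()
        assert np.abs(fa - ft).mean() < 0.1
        assert np.corrcoef(fa, ft)[0, 1] > 0.8

    def test_alpha_one_all_p(self):
        cfg = DemographyConfig(n_segments=2, alpha_P=1.0)
        ds = sim.simulate_neutral(cfg, 5)
        assert (ds.true_ancestry == 1).all()

    def test_mu_zero_no_sites(self):
        cfg = DemographyConfig(n_segments=2, mu=0.0)
        ds = sim.simulate_neutral(cfg, 5)
        assert ds.n_snps == 0

    def test_replicate_mean_ancestry(self):
        # one default segment per seed; replicate mean within 3 SE of alpha
        cfg = DemographyConfig(n_segments=1)
        fracs = [sim.simulate_neutral(cfg, s).true_p_fraction()
                 for s in range(50)]
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - cfg.alpha_P) < 3 * se

    def test_positions_strictly_increasing_per_chromosome(self, ds40):
        gm = ds40.pop_admixed
        for c in dict.fromkeys(gm.chrom):
            p = gm.pos[gm.chrom == c]
            assert (np.diff(p) > 0).all()

    def test_genome_wide_fraction_converges(self, ds300_inferred):
        ds, _ = ds300_inferred
        assert abs(ds.true_p_fraction() - 0.246) < 0.02

    def test_segment_independence(self, ds40):
        # per-haplotype mean ancestry per segment is uncorrelated across segments
        seg = sim.segment_ids(ds40)
        means = np.stack([ds40.true_ancestry[:, seg == s].mean(axis=1)
                          for s in range(40)])
        rng = np.random.default_rng(0)
        n_hap = ds40.true_ancestry.shape[0]
        rs = []
        for _ in range(10):
            i, j = rng.choice(40, 2, replace=False)
            rs.append(np.corrcoef(means[i], means[j])[0, 1])
        assert np.abs(np.mean(rs)) < 3 / np.sqrt(n_hap)

    def test_tract_length_expectation(self):
        # mean P tract ~ 1/(g(1-alpha)) Morgans; long segments limit censoring
        # and pooling seeds averages over founder-sharing correlation
        cfg = DemographyConfig(n_segments=1, segment_length=30_000_000,
                               segments_per_chromosome=1)
        tot, n_runs = 0.0, 0
        for seed in (3, 8, 15, 23, 31):
            ds = sim.simulate_neutral(cfg, seed)
            anc, pos = ds.true_ancestry, ds.pop_admixed.pos.astype(float)
            for row in anc:
                change = np.where(row[1:] != row[:-1])[0]
                bounds = np.r_[pos[0], (pos[change] + pos[change + 1]) / 2,
                               pos[-1]]
                labels = row[np.r_[0, change + 1]]
                lens = np.diff(bounds)
                tot += lens[labels == 1].sum()
                n_runs += int((labels == 1).sum())
        expected_bp = 1 / (cfg.g * (1 - cfg.alpha_P)) / cfg.rec
        assert abs(tot / n_runs - expected_bp) / expected_bp < 0.15

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError, match="exceeds 2N"):
            DemographyConfig(N=20, sample_chromosomes=(48, 46, 90))

    def test_reproducible(self):
        cfg = DemographyConfig(n_segments=2)
        a = sim.simulate_neutral(cfg, 9)
        b = sim.simulate_neutral(cfg, 9)
        assert a.pop_admixed.equals(b.pop_admixed)
        assert np.array_equal(a.true_ancestry, b.true_ancestry)


class TestAscertainment:
    def test_identity_when_target_is_all(self, ds40):
        out = sim.ascertain_snps(ds40, ds40.n_snps, np.ones(10), seed=1)
        assert out.n_snps == ds40.n_snps
        assert np.array_equal(np.sort(out.pop_admixed.pos),
                              np.sort(ds40.pop_admixed.pos))

    def test_reference_mass_in_top_bin(self, ds40):
        w = np.zeros(10)
        w[9] = 1.0
        out = sim.ascertain_snps(ds40, 50, w, seed=2)
        assert (sim.pooled_maf(out) > 0.4).all()

    def test_allocation_matches_largest_remainder_oracle(self):
        rng = np.random.default_rng(0)
        weights = rng.random(10) + 0.05
        available = np.full(10, 100)
        alloc = sim.maf_bin_allocation(weights, available, 500)
        # independent largest-remainder oracle
        quota = weights / weights.sum() * 500
        base = np.floor(quota).astype(int)
        order = np.argsort(-(quota - base), kind="stable")
        base[order[: 500 - base.sum()]] += 1
        assert np.array_equal(alloc, base)
        assert alloc.sum() == 500

    def test_exhausted_bin_keeps_all_and_redistributes(self, caplog):
        weights = np.ones(10)
        available = np.array([2, 50, 50, 50, 50, 50, 50, 50, 50, 50])
        alloc = sim.maf_bin_allocation(weights, available, 100)
        assert alloc[0] == 2
        assert alloc.sum() == 100

    def test_bin_counts_end_to_end(self, ds40):
        weights = np.ones(10)
        out = sim.ascertain_snps(ds40, 400, weights, seed=3)
        maf_all = sim.pooled_maf(ds40)
        maf_out = sim.pooled_maf(out)
        edges = np.arange(1, 10) * 0.05
        avail = np.bincount(np.digitize(maf_all[maf_all > 0], edges, right=True),
                            minlength=10)
        got = np.bincount(np.digitize(maf_out, edges, right=True), minlength=10)
        expected = sim.maf_bin_allocation(weights, avail, 400)
        assert np.array_equal(got, expected)

    def test_ancestry_kept_in_sync(self, ds40):
        out = sim.ascertain_snps(ds40, 500, seed=4)
        assert out.true_ancestry.shape == (46, 500)
        # spot-check: ancestry column of a retained SNP equals the original
        j = 123
        pos, chrom = out.pop_admixed.pos[j], out.pop_admixed.chrom[j]
        orig = np.where((ds40.pop_admixed.pos == pos)
                        & (ds40.pop_admixed.chrom == chrom))[0][0]
        assert np.array_equal(out.true_ancestry[:, j],
                              ds40.true_ancestry[:, orig])

    def test_bad_reference(self, ds40):
        with pytest.raises(ValueError):
            sim.ascertain_snps(ds40, 10, np.zeros(10), seed=0)
        with pytest.raises(ValueError):
            sim.ascertain_snps(ds40, ds40.n_snps + 1, seed=0)


@pytest.fixture(scope="module")
def small_neutral():
    return sim.simulate_neutral(DemographyConfig(n_segments=6), seed=21)


class TestInjectSelectedLocus:
    def test_invalid_s(self):
        with pytest.raises(ValueError):
            SelectedLocusSpec(segment_index=0, position=1, s=0.6)

    def test_out_of_bounds(self, small_neutral):
        with pytest.raises(ValueError):
            sim.inject_selected_locus(
                small_neutral, SelectedLocusSpec(99, 500_000, 0.02), seed=1)

    def test_neutral_injection_unbiased(self, small_neutral):
        # s = 0: focal-segment ancestry consistent with the neutral level
        spec = SelectedLocusSpec(segment_index=3, position=500_000, s=0.0)
        seg_means = []
        for seed in range(8):
            out = sim.inject_selected_locus(small_neutral, spec, seed=seed)
            seg = sim.segment_ids(out)
            seg_means.append(out.true_ancestry[:, seg == 3].mean())
        seg_means = np.array(seg_means)
        # null spread of per-segment means across the neutral dataset
        seg0 = sim.segment_ids(small_neutral)
        null = np.array([small_neutral.true_ancestry[:, seg0 == s].mean()
                         for s in range(6)])
        assert abs(seg_means.mean() - 0.246) < 2 * null.std(ddof=1)

    def test_selected_allele_rises(self, small_neutral):
        # s = 0.02, 100 generations from p0 ~ 0.25: final frequency in [0.6, 0.9]
        spec = SelectedLocusSpec(segment_index=2, position=500_000, s=0.02)
        finals, p0s = [], []
        for seed in range(12):
            out = sim.inject_selected_locus(small_neutral, spec, seed=seed)
            finals.append(out.selected_locus["final_frequency"])
            p0s.append(out.selected_locus["p0_expected"])
        hits = sum(0.6 <= f <= 0.9 for f in finals)
        # Monte-Carlo oracle from the trajectory simulator
        rng = np.random.default_rng(0)
        oracle = simulate_trajectories(float(np.mean(p0s)),
                                       np.full(4000, 0.02), 1000, 100, rng)
        oracle_rate = ((oracle >= 0.6) & (oracle <= 0.9)).mean()
        assert oracle_rate > 0.85
        assert hits >= 9

    def test_focal_ancestry_elevated(self, small_neutral):
        spec = SelectedLocusSpec(segment_index=2, position=500_000, s=0.02)
        wins = 0
        for seed in range(12):
            out = sim.inject_selected_locus(small_neutral, spec, seed=seed)
            sel = out.selected_locus
            gm = out.pop_admixed
            at_focal = np.where((gm.chrom == sel["chrom"])
                                & (gm.pos == sel["position"]))[0][0]
            focal_anc = out.true_ancestry[:, at_focal].mean()
            wins += focal_anc > out.true_ancestry.mean()
        assert wins >= 11

    def test_genotypes_consistent_with_sources(self, small_neutral):
        out = sim.inject_selected_locus(
            small_neutral, SelectedLocusSpec(1, 500_000, 0.01), seed=3)
        out.pop_admixed.validate()
        out.pop_p.validate()
        assert out.true_ancestry.shape == (46, out.n_snps)
        assert out.pop_p.n_snps == out.pop_admixed.n_snps == out.pop_a.n_snps


class TestTrueDosage:
    def test_alpha_extremes(self):
        for alpha, value in ((0.0, 0.0), (1.0, 2.0)):
            cfg = DemographyConfig(n_segments=1, alpha_P=alpha)
            ds = sim.simulate_neutral(cfg, 2)
            dm = sim.true_dosage(ds)
            assert (dm.dosage == value).all()

    def test_mean_identity(self, ds40):
        dm = sim.true_dosage(ds40)
        assert np.isclose(dm.dosage.mean() / 2, ds40.true_ancestry.mean())
        assert np.allclose(dm.mean_track(),
                           (ds40.true_ancestry[0::2]
                            + ds40.true_ancestry[1::2]).mean(axis=0) / 2)
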