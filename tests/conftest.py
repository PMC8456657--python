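import numpy as np
import pytest

from admixscan import DemographyConfig
from admixscan.ancestry import HMMParams, estimate_source_freqs, infer_dosage
from admixscan.io import GenotypeMatrix
from admixscan import simulate as sim


def make_gm(geno, pos=None, chrom=None, sample_ids=None):
    """Small helper to build a GenotypeMatrix from a (samples, snps) array."""
    geno = np.asarray(geno, dtype=np.int8)
    n_samples, n_snps = geno.shape
    if pos is None:
        pos = np.arange(1, n_snps + 1) * 1000
    if chrom is None:
        chrom = np.full(n_snps, "chr1", dtype=object)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_snps, "A", dtype=object),
        alt=np.full(n_snps, "T", dtype=object),
        geno=geno,
    )


def random_gm(rng, n_samples=4, n_snps=12, missing_rate=0.1):
    geno = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    geno[rng.random((n_samples, n_snps)) < missing_rate] = -1
    pos = np.sort(rng.choice(np.arange(1, 10**6), size=n_snps, replace=False))
    return make_gm(geno, pos=pos)


@pytest.fixture(scope="session")
def ds40():
    """Neutral 40-segment dataset at default demography."""
    return sim.simulate_neutral(DemographyConfig(n_segments=40), seed=11)


@pytest.fixture(scope="session")
def ds300_inferred():
    """Ascertained 300-segment dataset with inferred dosage (t7 scale)."""
    cfg = DemographyConfig(n_segments=300)
    ds = sim.simulate_neutral(cfg, seed=42)
    target = int(round(162_358 * cfg.n_segments / 3000))
    ds = sim.ascertain_snps(ds, target, seed=43)
    dm = infer_dosage(
        ds.pop_admixed,
        estimate_source_freqs(ds.pop_p),
        estimate_source_freqs(ds.pop_a),
        HMMParams(g=cfg.g, m=None, rec=cfg.rec),
        block_ids=sim.segment_ids(ds),
    )
    return ds, dm


@pytest.fixture(scope="session")
def ds_outgroup():
    """150-segment dataset with outgroup and source-A proxy panels."""
    cfg = DemographyConfig(n_segments=150, n_outgroup_chromosomes=40,
                           n_proxy_a_chromosomes=40)
    return sim.simulate_neutral(cfg, seed=17)
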