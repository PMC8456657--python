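"""Synthetic two-source admixture datasets with recorded true local ancestry.

A neutral dataset is generated by backward-in-time coalescent simulation
(msprime) of two source populations P and A that split ``t_split``
generations ago, plus an admixed population founded ``g`` generations ago
by a single pulse drawing fraction ``alpha_P`` of its haplotypes from P.
Independent 1 Mb segments are simulated and concatenated into
pseudo-chromosomes of ``segments_per_chromosome`` segments; recombination
between segments is treated as free by downstream consumers.

True local ancestry of every admixed haplotype is read off the tree
sequence through a census layer placed just above the admixture pulse.

An optional post-admixture selected locus is injected by re-simulating one
segment forward in time: founder haplotypes are drawn from the sources at
the admixture time and propagated through ``g`` generations of random
mating, recombination and additive selection on a diagnostic focal SNP.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import msprime
import numpy as np

from .ancestry import AncestryDosageMatrix
from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

MAF_BIN_WIDTH = 0.05
N_MAF_BINS = 10


@dataclass
class DemographyConfig:
    """Two-source admixture demography with per-population size ``N``."""

    N: int = 1000
    t_split: float = 1667.0
    g: int = 100
    alpha_P: float = 0.246
    mu: float = 1.2e-8
    rec: float = 1.3e-8
    n_segments: int = 3000
    segment_length: int = 1_000_000
    sample_chromosomes: tuple[int, int, int] = (48, 46, 90)
    segments_per_chromosome: int = 150
    # test scaffolding for f4-ratio validation (0 chromosomes = disabled):
    # an outgroup splitting from the root well before t_split, and a clean
    # source-A proxy splitting from A at the admixture time (so that proxy
    # and admixed A-ancestors share no post-admixture drift)
    n_outgroup_chromosomes: int = 0
    t_outgroup: float = 6667.0
    n_proxy_a_chromosomes: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_P <= 1.0:
            raise ValueError("alpha_P must be in [0, 1]")
        if not self.g < self.t_split:
            raise ValueError("g must be < t_split")
        if self.g < 1 or self.N < 1:
            raise ValueError("g and N must be >= 1")
        if self.mu < 0 or self.rec < 0:
            raise ValueError("rates must be >= 0")
        for n in (*self.sample_chromosomes, self.n_outgroup_chromosomes,
                  self.n_proxy_a_chromosomes):
            if n % 2 != 0:
                raise ValueError("sample chromosome counts must be even (diploids)")
            if n > 2 * self.N:
                raise ValueError(f"sample of {n} chromosomes exceeds 2N = {2 * self.N}")

    @property
    def n_chromosomes(self) -> int:
        return math.ceil(self.n_segments / self.segments_per_chromosome)


@dataclass
class SelectedLocusSpec:
    """Post-admixture selected locus for scan/ABC validation fixtures.

    ``position`` is the 1-based bp coordinate within the focal segment; the
    realized focal SNP is the most source-diagnostic polymorphic site near
    it.  The selected allele starts at the admixture-weighted average of its
    source-population frequencies (single-pulse founding) and is favored
    additively: genotype fitnesses 1, 1-s, 1-2s for 2/1/0 copies.
    """

    segment_index: int
    position: int
    s: float
    initial_frequency: str = "admixture-weighted source frequencies"

    def __post_init__(self) -> None:
        if not 0.0 <= self.s < 0.5:
            raise ValueError("s must satisfy 0 <= s < 0.5")


@dataclass
class SimulatedDataset:
    """Three genotype matrices plus true ancestry of the admixed haplotypes.

    ``true_ancestry`` is a ``(n_admixed_haplotypes, n_snps)`` uint8 array,
    1 = haplotype derives from source P at that SNP, 0 = source A.
    Haplotypes ``2i`` and ``2i+1`` belong to admixed individual ``i``.
    """

    pop_p: GenotypeMatrix
    pop_admixed: GenotypeMatrix
    pop_a: GenotypeMatrix
    true_ancestry: np.ndarray
    config: DemographyConfig
    seed: int
    pop_out: GenotypeMatrix | None = None
    pop_proxy_a: GenotypeMatrix | None = None
    selected_locus: dict | None = None

    def __post_init__(self) -> None:
        n_hap = self.pop_admixed.n_samples * 2
        if self.true_ancestry.shape != (n_hap, self.pop_admixed.n_snps):
            raise ValueError("true_ancestry shape does not match admixed samples/SNPs")

    @property
    def n_snps(self) -> int:
        return self.pop_admixed.n_snps

    def true_p_fraction(self) -> float:
        return float(self.true_ancestry.mean()) if self.true_ancestry.size else float("nan")


# ---------------------------------------------------------------------------
# neutral simulation
# ---------------------------------------------------------------------------

def _build_demography(cfg: DemographyConfig, census: bool = True) -> msprime.Demography:
    d = msprime.Demography()
    d.add_population(name="P", initial_size=cfg.N)
    d.add_population(name="A", initial_size=cfg.N)
    d.add_population(name="ADM", initial_size=cfg.N)
    d.add_population(name="ANC", initial_size=cfg.N)
    if cfg.n_proxy_a_chromosomes > 0:
        d.add_population(name="TWN", initial_size=cfg.N)
    if cfg.n_outgroup_chromosomes > 0:
        d.add_population(name="OUT", initial_size=cfg.N)
        d.add_population(name="ROOT", initial_size=cfg.N)
    if cfg.alpha_P <= 0.0:
        d.add_population_split(time=cfg.g, derived=["ADM"], ancestral="A")
    elif cfg.alpha_P >= 1.0:
        d.add_population_split(time=cfg.g, derived=["ADM"], ancestral="P")
    else:
        d.add_admixture(time=cfg.g, derived="ADM", ancestral=["P", "A"],
                        proportions=[cfg.alpha_P, 1.0 - cfg.alpha_P])
    if cfg.n_proxy_a_chromosomes > 0:
        d.add_population_split(time=cfg.g, derived=["TWN"], ancestral="A")
    if census:
        d.add_census(time=cfg.g + 0.5)
    d.add_population_split(time=cfg.t_split, derived=["P", "A"], ancestral="ANC")
    if cfg.n_outgroup_chromosomes > 0:
        d.add_population_split(time=cfg.t_outgroup, derived=["ANC", "OUT"],
                               ancestral="ROOT")
    d.sort_events()
    return d


def _segment_tables(ts, cfg: DemographyConfig):
    """Extract biallelic pooled-polymorphic sites, genotypes and ancestry."""
    n_hap_total = ts.num_samples
    geno = ts.genotype_matrix().astype(np.int8)  # (sites, haplotypes), binary model
    pos = ts.sites_position.astype(np.int64)
    derived = geno.sum(axis=1)
    keep = (derived > 0) & (derived < n_hap_total)
    geno, pos = geno[keep], pos[keep]

    # true ancestry of admixed haplotypes from the census layer
    nP, nT, nA = cfg.sample_chromosomes
    adm_nodes = np.arange(nP, nP + nT, dtype=np.int32)
    nodes = ts.tables.nodes
    census_nodes = np.where(nodes.time == cfg.g + 0.5)[0].astype(np.int32)
    p_id = 0  # population "P" is added first
    anc = np.zeros((nT, len(pos)), dtype=np.uint8)
    if len(pos) and len(census_nodes):
        link = ts.tables.link_ancestors(samples=adm_nodes, ancestors=census_nodes)
        pop_of = nodes.population
        for left, right, parent, child in zip(link.left, link.right,
                                              link.parent, link.child):
            if pop_of[parent] == p_id:
                lo, hi = np.searchsorted(pos, [left, right])
                anc[child - nP, lo:hi] = 1
    elif len(pos):
        # degenerate alpha handled without an admixture event
        anc[:] = 1 if cfg.alpha_P >= 1.0 else 0
    return pos, geno, anc


def _pair_diploid(hap_geno: np.ndarray) -> np.ndarray:
    """Collapse a (snps, haplotypes) array to (samples, snps) alt counts."""
    return (hap_geno[:, 0::2] + hap_geno[:, 1::2]).T.astype(np.int8)


def _make_matrix(prefix: str, n_ind: int, chrom, pos, hap_geno) -> GenotypeMatrix:
    return GenotypeMatrix(
        sample_ids=[f"{prefix}_{i}" for i in range(n_ind)],
        chrom=chrom, pos=pos,
        ref=np.full(len(pos), "A", dtype=object),
        alt=np.full(len(pos), "T", dtype=object),
        geno=_pair_diploid(hap_geno),
    )


def simulate_neutral(config: DemographyConfig, seed: int) -> SimulatedDataset:
    """Simulate ``config.n_segments`` independent neutral segments.

    All randomness flows from ``seed`` through a single
    :class:`numpy.random.SeedSequence` split.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    seeds = rng.integers(1, 2**31 - 1, size=(cfg.n_segments, 2))
    demography = _build_demography(cfg)
    nP, nT, nA = cfg.sample_chromosomes
    samples = [
        msprime.SampleSet(nP // 2, population="P"),
        msprime.SampleSet(nT // 2, population="ADM"),
        msprime.SampleSet(nA // 2, population="A"),
    ]
    if cfg.n_proxy_a_chromosomes > 0:
        samples.append(msprime.SampleSet(cfg.n_proxy_a_chromosomes // 2,
                                         population="TWN"))
    if cfg.n_outgroup_chromosomes > 0:
        samples.append(msprime.SampleSet(cfg.n_outgroup_chromosomes // 2,
                                         population="OUT"))

    chroms, poss, genos, ancs = [], [], [], []
    for k in range(cfg.n_segments):
        ts = msprime.sim_ancestry(
            samples=samples, demography=demography, ploidy=2,
            sequence_length=cfg.segment_length,
            recombination_rate=cfg.rec, random_seed=int(seeds[k, 0]),
        )
        ts = msprime.sim_mutations(
            ts, rate=cfg.mu, random_seed=int(seeds[k, 1]),
            model=msprime.BinaryMutationModel(),
        )
        pos, geno, anc = _segment_tables(ts, cfg)
        chrom_idx, seg_in_chrom = divmod(k, cfg.segments_per_chromosome)
        poss.append(pos + seg_in_chrom * cfg.segment_length + 1)
        chroms.append(np.full(len(pos), f"chr{chrom_idx + 1}", dtype=object))
        genos.append(geno)
        ancs.append(anc)

    pos = np.concatenate(poss) if poss else np.array([], dtype=np.int64)
    chrom = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    geno = (np.concatenate(genos, axis=0) if genos
            else np.zeros((0, nP + nT + nA + cfg.n_proxy_a_chromosomes
                           + cfg.n_outgroup_chromosomes), np.int8))
    anc = (np.concatenate(ancs, axis=1) if ancs
           else np.zeros((nT, 0), dtype=np.uint8))

    hap_slices = {
        "P": slice(0, nP),
        "T": slice(nP, nP + nT),
        "A": slice(nP + nT, nP + nT + nA),
    }
    cursor = nP + nT + nA
    proxy = None
    if cfg.n_proxy_a_chromosomes > 0:
        sl = slice(cursor, cursor + cfg.n_proxy_a_chromosomes)
        proxy = _make_matrix("X", cfg.n_proxy_a_chromosomes // 2, chrom, pos,
                             geno[:, sl])
        cursor += cfg.n_proxy_a_chromosomes
    out = None
    if cfg.n_outgroup_chromosomes > 0:
        sl = slice(cursor, cursor + cfg.n_outgroup_chromosomes)
        out = _make_matrix("O", cfg.n_outgroup_chromosomes // 2, chrom, pos,
                           geno[:, sl])
    return SimulatedDataset(
        pop_p=_make_matrix("P", nP // 2, chrom, pos, geno[:, hap_slices["P"]]),
        pop_admixed=_make_matrix("T", nT // 2, chrom, pos, geno[:, hap_slices["T"]]),
        pop_a=_make_matrix("A", nA // 2, chrom, pos, geno[:, hap_slices["A"]]),
        true_ancestry=anc,
        config=cfg,
        seed=seed,
        pop_out=out,
        pop_proxy_a=proxy,
    )


# ---------------------------------------------------------------------------
# SNP ascertainment
# ---------------------------------------------------------------------------

def pooled_maf(ds: SimulatedDataset) -> np.ndarray:
    """Minor-allele frequency in the pooled P + admixed + A sample."""
    alt = np.zeros(ds.n_snps, dtype=np.int64)
    n = np.zeros(ds.n_snps, dtype=np.int64)
    for gm in (ds.pop_p, ds.pop_admixed, ds.pop_a):
        a, c = gm.allele_counts()
        alt += a
        n += c
    with np.errstate(invalid="ignore"):
        f = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    return np.minimum(f, 1.0 - f)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    quota = weights / weights.sum() * total
    alloc = np.floor(quota).astype(np.int64)
    short = total - alloc.sum()
    order = np.argsort(-(quota - alloc), kind="stable")
    alloc[order[:short]] += 1
    return alloc


def maf_bin_allocation(weights: np.ndarray, available: np.ndarray,
                       target_count: int) -> np.ndarray:
    """Per-bin retained counts: largest-remainder allocation with caps.

    Bins whose allocation exceeds availability keep everything they have
    and the shortfall is re-allocated among the remaining bins.
    """
    weights = np.asarray(weights, dtype=float)
    alloc = np.zeros(len(weights), dtype=np.int64)
    open_bins = (weights > 0) & (available > 0)
    remaining = target_count
    while remaining > 0 and open_bins.any():
        step = np.zeros_like(alloc)
        step[open_bins] = _largest_remainder(weights[open_bins], remaining)
        step = np.minimum(step, available - alloc)
        alloc += step
        exhausted = alloc >= available
        if exhausted[open_bins].any():
            logger.warning("MAF bins exhausted during ascertainment: %s",
                           np.where(exhausted & (weights > 0))[0].tolist())
        open_bins &= ~exhausted
        remaining = target_count - alloc.sum()
        if step.sum() == 0:
            break
    return alloc


def ascertain_snps(ds: SimulatedDataset, target_count: int,
                   maf_reference: Sequence[float] | None = None,
                   seed: int = 0) -> SimulatedDataset:
    """Thin SNPs to ``target_count``, matching a reference MAF histogram.

    ``maf_reference`` gives relative mass per MAF bin of width 0.05 over
    (0, 0.5].  ``None`` uses the data's own pooled-MAF histogram, i.e.
    MAF-preserving random thinning (the array histogram being emulated is
    not published; a distribution-neutral default avoids distorting the
    spectrum the ancestry model is calibrated on).  Retention is random
    within bins under ``seed``.
    """
    weights = None if maf_reference is None else np.asarray(maf_reference, dtype=float)
    if weights is not None and (weights.size != N_MAF_BINS or weights.sum() <= 0):
        raise ValueError(f"maf_reference must be {N_MAF_BINS} non-negative "
                         "weights with positive sum")
    if target_count > ds.n_snps:
        raise ValueError("target_count exceeds available SNPs")

    maf = pooled_maf(ds)
    usable = maf > 0
    edges = (np.arange(1, N_MAF_BINS) * MAF_BIN_WIDTH)
    bins = np.digitize(maf, edges, right=True)
    available = np.array([(usable & (bins == b)).sum() for b in range(N_MAF_BINS)])
    if weights is None:
        weights = available.astype(float)
        if weights.sum() <= 0:
            raise ValueError("no polymorphic SNPs to ascertain")
    alloc = maf_bin_allocation(weights, available, target_count)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = []
    for b in range(N_MAF_BINS):
        if alloc[b] == 0:
            continue
        idx = np.where(usable & (bins == b))[0]
        chosen.append(rng.choice(idx, size=alloc[b], replace=False))
    keep = np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)
    return subset_dataset(ds, keep)


def subset_dataset(ds: SimulatedDataset, snp_index: np.ndarray) -> SimulatedDataset:
    """Dataset restricted to the given SNP indices, ancestry kept in sync."""
    return replace(
        ds,
        pop_p=ds.pop_p.take_snps(snp_index),
        pop_admixed=ds.pop_admixed.take_snps(snp_index),
        pop_a=ds.pop_a.take_snps(snp_index),
        true_ancestry=ds.true_ancestry[:, snp_index],
        pop_out=ds.pop_out.take_snps(snp_index) if ds.pop_out is not None else None,
        pop_proxy_a=(ds.pop_proxy_a.take_snps(snp_index)
                     if ds.pop_proxy_a is not None else None),
    )


# ---------------------------------------------------------------------------
# selected-locus injection
# ---------------------------------------------------------------------------

def _recombine(hap_a, hap_b, crossovers):
    """Merge two founder mosaics at the given crossover positions.

    Mosaics are tuples of (start_bp, founder_id) pieces; the gamete starts
    on ``hap_a`` and switches template at every crossover.
    """
    out = []
    templates = (hap_a, hap_b)
    t = 0
    left = 0.0
    for x in list(crossovers) + [np.inf]:
        cur = templates[t]
        for j, (start, fid) in enumerate(cur):
            end = cur[j + 1][0] if j + 1 < len(cur) else np.inf
            if end <= left or start >= x:
                continue
            out.append((max(start, left), fid))
        left = x
        t ^= 1
    # merge adjacent pieces copied from the same founder
    merged = [out[0]]
    for p in out[1:]:
        if p[1] != merged[-1][1]:
            merged.append(p)
    return tuple(merged)


def _mosaic_founder_at(hap, pos: float) -> int:
    fid = hap[0][1]
    for start, f in hap:
        if start <= pos:
            fid = f
        else:
            break
    return fid


def _forward_admixed_segment(founder_geno, founder_anc, site_pos, focal_idx,
                             fav_allele, s, cfg: DemographyConfig, rng,
                             n_sample_ind):
    """Wright-Fisher forward simulation of one admixed segment.

    Haplotypes are mosaics of founder haplotypes; selection is additive on
    the focal-site genotype (fitnesses 1, 1-s, 1-2s for 2/1/0 copies of the
    favored allele).  Returns sampled haplotype genotypes and ancestry.
    """
    N, g, L = cfg.N, cfg.g, float(cfg.segment_length)
    two_n = 2 * N
    focal_pos = float(site_pos[focal_idx])
    focal_carrier = (founder_geno[:, focal_idx] == fav_allele).astype(np.int8)

    haps = [((0.0, fid),) for fid in range(two_n)]
    focal = focal_carrier.copy()

    for _ in range(g):
        cnt = focal[0::2] + focal[1::2]
        w = 1.0 - s * (2 - cnt)
        probs = w / w.sum()
        parents = rng.choice(N, size=two_n, p=probs)
        which = rng.integers(0, 2, size=two_n)
        ncross = rng.poisson(cfg.rec * L, size=two_n)
        sel = 2 * parents + which
        new_haps = [haps[k] for k in sel]
        new_focal = focal[sel]
        for i in np.where(ncross > 0)[0]:
            xs = np.sort(rng.uniform(0.0, L, size=ncross[i]))
            a, b = haps[sel[i]], haps[2 * parents[i] + 1 - which[i]]
            hap = _recombine(a, b, xs)
            new_haps[i] = hap
            new_focal[i] = focal_carrier_of(hap, focal_pos, founder_geno,
                                            focal_idx, fav_allele)
        haps, focal = new_haps, new_focal

    ind = rng.choice(N, size=n_sample_ind, replace=False)
    hap_ids = np.ravel(np.column_stack((2 * ind, 2 * ind + 1)))
    n_sites = len(site_pos)
    out_geno = np.zeros((len(hap_ids), n_sites), dtype=np.int8)
    out_anc = np.zeros((len(hap_ids), n_sites), dtype=np.uint8)
    for row, h in enumerate(hap_ids):
        hap = haps[h]
        for j, (start, fid) in enumerate(hap):
            end = hap[j + 1][0] if j + 1 < len(hap) else L + 1
            lo, hi = np.searchsorted(site_pos, [start, end])
            out_geno[row, lo:hi] = founder_geno[fid, lo:hi]
            out_anc[row, lo:hi] = founder_anc[fid]
    return out_geno, out_anc


def focal_carrier_of(hap, focal_pos, founder_geno, focal_idx, fav_allele) -> int:
    fid = _mosaic_founder_at(hap, focal_pos)
    return int(founder_geno[fid, focal_idx] == fav_allele)


def inject_selected_locus(ds: SimulatedDataset, spec: SelectedLocusSpec,
                          seed: int) -> SimulatedDataset:
    """Replace one segment with a forward-simulated selected version.

    The focal segment's three population samples are re-generated: source
    samples from a fresh coalescent simulation of P and A, and the admixed
    sample from ``g`` generations of forward Wright-Fisher evolution of
    2N founder haplotypes drawn from the sources at the admixture time.
    """
    cfg = ds.config
    if not 0 <= spec.segment_index < cfg.n_segments:
        raise ValueError("segment index out of range")
    if not 1 <= spec.position <= cfg.segment_length:
        raise ValueError("position outside segment")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_p_founders = int(rng.binomial(2 * cfg.N, cfg.alpha_P))
    n_a_founders = 2 * cfg.N - n_p_founders

    nP, nT, nA = cfg.sample_chromosomes
    demog = msprime.Demography()
    demog.add_population(name="P", initial_size=cfg.N)
    demog.add_population(name="A", initial_size=cfg.N)
    demog.add_population(name="ANC", initial_size=cfg.N)
    demog.add_population_split(time=cfg.t_split, derived=["P", "A"],
                               ancestral="ANC")
    samples = [
        msprime.SampleSet(nP // 2, population="P", time=0),
        msprime.SampleSet(nA // 2, population="A", time=0),
        msprime.SampleSet(math.ceil(n_p_founders / 2), population="P", time=cfg.g),
        msprime.SampleSet(math.ceil(n_a_founders / 2), population="A", time=cfg.g),
    ]
    seeds = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=samples, demography=demog, ploidy=2,
        sequence_length=cfg.segment_length, recombination_rate=cfg.rec,
        random_seed=int(seeds[0]),
    )
    ts = msprime.sim_mutations(ts, rate=cfg.mu, random_seed=int(seeds[1]),
                               model=msprime.BinaryMutationModel())

    geno = ts.genotype_matrix().astype(np.int8)
    pos = ts.sites_position.astype(np.int64)
    derived = geno.sum(axis=1)
    keep = (derived > 0) & (derived < ts.num_samples)
    geno, pos = geno[keep], pos[keep]

    ref_p = geno[:, :nP]
    ref_a = geno[:, nP:nP + nA]
    founders_start = nP + nA
    f_p = geno[:, founders_start:founders_start + n_p_founders]
    a_start = founders_start + 2 * math.ceil(n_p_founders / 2)
    f_a = geno[:, a_start:a_start + n_a_founders]
    founder_geno = np.concatenate([f_p, f_a], axis=1).T  # (2N, sites)
    founder_anc = np.concatenate([
        np.ones(n_p_founders, dtype=np.uint8),
        np.zeros(n_a_founders, dtype=np.uint8),
    ])
    # founding haplotypes in random order, not P-block then A-block
    perm = rng.permutation(2 * cfg.N)
    founder_geno, founder_anc = founder_geno[perm], founder_anc[perm]

    # focal SNP: most source-diagnostic site near the requested position
    fp = f_p.mean(axis=1) if n_p_founders else np.zeros(len(pos))
    fa = f_a.mean(axis=1) if n_a_founders else np.zeros(len(pos))
    diag = np.abs(fp - fa)
    for window in (100_000, cfg.segment_length):
        near = np.abs(pos + 1 - spec.position) <= window
        if near.any():
            cand = np.where(near)[0]
            focal_idx = int(cand[np.argmax(diag[cand])])
            break
    else:
        raise ValueError("no polymorphic site available for the focal locus")
    fav_allele = 1 if fp[focal_idx] >= fa[focal_idx] else 0

    adm_geno_h, adm_anc = _forward_admixed_segment(
        founder_geno, founder_anc, pos, focal_idx, fav_allele, spec.s, cfg,
        rng, nT // 2)

    chrom_idx, seg_in_chrom = divmod(spec.segment_index, cfg.segments_per_chromosome)
    chrom_label = f"chr{chrom_idx + 1}"
    offset = seg_in_chrom * cfg.segment_length
    new_pos = pos + offset + 1
    new_chrom = np.full(len(pos), chrom_label, dtype=object)

    new_p = _make_matrix("P", nP // 2, new_chrom, new_pos, ref_p)
    new_p.sample_ids = list(ds.pop_p.sample_ids)
    new_a = _make_matrix("A", nA // 2, new_chrom, new_pos, ref_a)
    new_a.sample_ids = list(ds.pop_a.sample_ids)
    new_t = _make_matrix("T", nT // 2, new_chrom, new_pos, adm_geno_h.T)
    new_t.sample_ids = list(ds.pop_admixed.sample_ids)

    in_seg = ((ds.pop_admixed.chrom == chrom_label)
              & (ds.pop_admixed.pos > offset)
              & (ds.pop_admixed.pos <= offset + cfg.segment_length))
    before = np.where(~in_seg & _genomic_before(ds.pop_admixed, chrom_label,
                                                offset + 1))[0]
    after = np.setdiff1d(np.where(~in_seg)[0], before)

    def splice(old: GenotypeMatrix, new: GenotypeMatrix) -> GenotypeMatrix:
        return GenotypeMatrix(
            sample_ids=list(old.sample_ids),
            chrom=np.concatenate([old.chrom[before], new.chrom, old.chrom[after]]),
            pos=np.concatenate([old.pos[before], new.pos, old.pos[after]]),
            ref=np.concatenate([old.ref[before], new.ref, old.ref[after]]),
            alt=np.concatenate([old.alt[before], new.alt, old.alt[after]]),
            geno=np.concatenate([old.geno[:, before], new.geno,
                                 old.geno[:, after]], axis=1),
        )

    anc = np.concatenate([ds.true_ancestry[:, before], adm_anc,
                          ds.true_ancestry[:, after]], axis=1)
    out = replace(
        ds,
        pop_p=splice(ds.pop_p, new_p),
        pop_admixed=splice(ds.pop_admixed, new_t),
        pop_a=splice(ds.pop_a, new_a),
        true_ancestry=anc,
        pop_out=None,  # outgroup panels are neutral-only test scaffolding
        selected_locus={
            "chrom": chrom_label,
            "position": int(new_pos[focal_idx]),
            "s": spec.s,
            "favored_allele": "alt" if fav_allele == 1 else "ref",
            "p0_expected": float(
                (fp[focal_idx] if fav_allele == 1 else 1 - fp[focal_idx])
                * cfg.alpha_P
                + (fa[focal_idx] if fav_allele == 1 else 1 - fa[focal_idx])
                * (1 - cfg.alpha_P)),
            "final_frequency": float(
                (adm_geno_h[:, focal_idx] == fav_allele).mean()),
        },
    )
    return out


def _genomic_before(gm: GenotypeMatrix, chrom_label: str, pos: int) -> np.ndarray:
    """SNPs strictly before (chrom_label, pos) in the dataset's layout."""
    order = {c: i for i, c in enumerate(dict.fromkeys(gm.chrom))}
    c_rank = np.array([order[c] for c in gm.chrom])
    target = order.get(chrom_label, len(order))
    return (c_rank < target) | ((c_rank == target) & (gm.pos < pos))


# ---------------------------------------------------------------------------
# ground truth dosage
# ---------------------------------------------------------------------------

def true_dosage(ds: SimulatedDataset) -> AncestryDosageMatrix:
    """Per-individual count of P-labeled haplotypes at each SNP."""
    d = (ds.true_ancestry[0::2] + ds.true_ancestry[1::2]).astype(float)
    return AncestryDosageMatrix(
        sample_ids=list(ds.pop_admixed.sample_ids),
        chrom=ds.pop_admixed.chrom,
        pos=ds.pop_admixed.pos,
        dosage=d,
    )


def segment_ids(ds: SimulatedDataset) -> np.ndarray:
    """Per-SNP independent-segment identifier (HMM chains reset between)."""
    order = {c: i for i, c in enumerate(dict.fromkeys(ds.pop_admixed.chrom))}
    c_rank = np.array([order[c] for c in ds.pop_admixed.chrom])
    seg = (ds.pop_admixed.pos - 1) // ds.config.segment_length
    return c_rank * ds.config.segments_per_chromosome + seg
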