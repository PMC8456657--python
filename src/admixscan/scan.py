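"""Ancestry-excess scan: thresholds, region calling and null calibration.

The scan statistic is the per-SNP mean P-ancestry proportion across
admixed individuals.  Candidate regions are maximal runs of SNPs strictly
above ``mean + k * SD`` (population SD, n denominator); runs on the same
chromosome separated by both < 1 Mb and < 5 below-threshold SNPs are merged
into a single independent region.

The family-wise error rate of the ``mean + 5 SD`` rule is calibrated by
repeating the full neutral pipeline (simulate, ascertain, infer dosage,
threshold within-run) and counting runs with at least one region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MERGE_MAX_GAP_BP = 1_000_000
MERGE_MAX_GAP_SNPS = 5
THRESHOLD_KS = (2.0, 4.0, 5.0)


@dataclass
class ScanSummary:
    """Genome-wide moments of the ancestry track and k-SD thresholds."""

    mean: float
    sd: float
    thresholds: dict[float, float] = field(default_factory=dict)

    def threshold(self, k: float) -> float:
        return self.mean + k * self.sd


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    n_snps: int
    max_prop: float
    mean_prop: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.n_snps < 1:
            raise ValueError("region must contain at least one SNP")


def scan_stats(track: np.ndarray) -> ScanSummary:
    """Mean, population SD and mean + k*SD thresholds of the track."""
    track = np.asarray(track, dtype=float)
    if track.size < 2:
        raise ValueError("need at least two SNPs")
    mean = float(track.mean())
    sd = float(track.std(ddof=0))
    return ScanSummary(mean=mean, sd=sd,
                       thresholds={k: mean + k * sd for k in THRESHOLD_KS})


def call_regions(track: np.ndarray, positions: np.ndarray,
                 chromosomes: np.ndarray, threshold: float) -> list[Region]:
    """Maximal above-threshold runs, merged across short sparse gaps.

    The comparison is strict (``track > threshold``).  Region bounds are
    the positions of the first/last above-threshold SNP; ``n_snps`` counts
    above-threshold SNPs, the max/mean proportions are over all SNPs within
    the region span.
    """
    if threshold < 0.0:
        raise ValueError("threshold must be non-negative")
    # mean + k*SD can exceed 1 on noisy tracks; nothing can pass it then
    track = np.asarray(track, dtype=float)
    positions = np.asarray(positions)
    chromosomes = np.asarray(chromosomes)
    regions: list[Region] = []
    for c in dict.fromkeys(chromosomes):  # first-appearance order
        on_c = chromosomes == c
        t, p = track[on_c], positions[on_c]
        above = np.where(t > threshold)[0]
        if len(above) == 0:
            continue
        # split above-threshold SNPs into raw runs, then merge
        groups: list[list[int]] = [[above[0]]]
        for i in above[1:]:
            prev = groups[-1][-1]
            gap_snps = i - prev - 1
            gap_bp = p[i] - p[prev]
            if gap_snps < MERGE_MAX_GAP_SNPS and gap_bp < MERGE_MAX_GAP_BP:
                groups[-1].append(int(i))
            else:
                groups.append([int(i)])
        for grp in groups:
            lo, hi = grp[0], grp[-1]
            span = t[lo:hi + 1]
            regions.append(Region(
                chrom=str(c), start=int(p[lo]), end=int(p[hi]),
                n_snps=len(grp), max_prop=float(span.max()),
                mean_prop=float(span.mean()),
            ))
    return regions


def fdr_from_fwer(fwer: float, n_observed_regions: int) -> float:
    """FDR implied by the scan: FWER / number of observed regions."""
    if n_observed_regions < 1:
        raise ValueError("FDR undefined with zero observed regions")
    return fwer / n_observed_regions


def estimate_fwer(n_runs: int, demography, seed: int, *,
                  target_snps: int | None = None,
                  maf_reference=None, eps: float = 0.005,
                  k: float = 5.0) -> tuple[float, list[int]]:
    """Empirical FWER of the mean + k*SD rule under neutrality.

    Each run simulates the demography, ascertains SNPs, infers dosage with
    the run's own source samples as references, and calls regions above
    that run's own mean + k*SD.  Returns (FWER, per-run region counts).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    run_seeds = rng.integers(1, 2**31 - 1, size=n_runs)
    counts = []
    for r in range(n_runs):
        try:
            track, pos, chrom, _ = neutral_ancestry_track(
                demography, int(run_seeds[r]), target_snps=target_snps,
                maf_reference=maf_reference, eps=eps)
            summary = scan_stats(track)
            regions = call_regions(track, pos, chrom, summary.threshold(k))
        except Exception:
            logger.error("null calibration failed in run %d", r)
            raise
        counts.append(len(regions))
    fwer = float(np.mean([c >= 1 for c in counts]))
    return fwer, counts


def neutral_ancestry_track(demography, seed: int, *,
                           target_snps: int | None = None,
                           maf_reference=None, eps: float = 0.005):
    """One neutral pipeline pass: returns (track, positions, chromosomes, ds).

    The ascertainment target defaults to the genome-wide array density
    (162,358 SNPs at 3000 segments) scaled to ``n_segments``.  The
    polymorphic-in-each-population rule is a real-data driver filter and is
    not applied here: ascertained SNPs are pooled-polymorphic by
    construction and panel smoothing handles private variants.
    """
    from . import simulate as sim
    from .ancestry import HMMParams, estimate_source_freqs, infer_dosage

    cfg = demography
    ds = sim.simulate_neutral(cfg, seed)
    if target_snps is None:
        target_snps = int(round(162_358 * cfg.n_segments / 3000))
    target_snps = min(target_snps, ds.n_snps)
    sub_seed = int(np.random.default_rng(np.random.SeedSequence(seed)).integers(1, 2**31 - 1))
    ds = sim.ascertain_snps(ds, target_snps, maf_reference, seed=sub_seed)

    params = HMMParams(g=cfg.g, m=None, rec=cfg.rec, eps=eps)
    dm = infer_dosage(ds.pop_admixed, estimate_source_freqs(ds.pop_p),
                      estimate_source_freqs(ds.pop_a), params,
                      block_ids=sim.segment_ids(ds))
    track = dm.mean_track()
    return track, ds.pop_admixed.pos, ds.pop_admixed.chrom, ds
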