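"""f3 / f4 admixture statistics with block-jackknife standard errors.

Per-SNP terms follow the sample-frequency convention: for f3(C; A, B) the
term is (c-a)(c-b) minus a finite-sample correction c(1-c)/(n_C - 1)
removing the sampling variance of the target's frequency; f4(A,B; C,D)
uses (a-b)(c-d).  Standard errors come from a weighted delete-one-block
jackknife over contiguous SNP blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_SIZE = 500


@dataclass
class FreqTable:
    """Per-SNP sample allele frequencies and haploid sizes per population."""

    chrom: np.ndarray
    pos: np.ndarray
    freqs: dict[str, np.ndarray]
    sizes: dict[str, np.ndarray]

    @classmethod
    def from_genotypes(cls, pops: dict[str, GenotypeMatrix]) -> "FreqTable":
        mats = list(pops.values())
        first = mats[0]
        for gm in mats[1:]:
            if not (np.array_equal(gm.chrom, first.chrom)
                    and np.array_equal(gm.pos, first.pos)):
                raise ValueError("populations must share an identical SNP set")
        freqs, sizes = {}, {}
        for name, gm in pops.items():
            alt, n = gm.allele_counts()
            with np.errstate(invalid="ignore"):
                freqs[name] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
            sizes[name] = n
        return cls(chrom=first.chrom, pos=first.pos, freqs=freqs, sizes=sizes)

    def subsample(self, name: str, gm: GenotypeMatrix,
                  sample_index: np.ndarray) -> None:
        """Register a population from a subset of a matrix's samples."""
        sub = GenotypeMatrix(
            sample_ids=[gm.sample_ids[i] for i in sample_index],
            chrom=gm.chrom, pos=gm.pos, ref=gm.ref, alt=gm.alt,
            geno=gm.geno[sample_index],
        )
        alt, n = sub.allele_counts()
        with np.errstate(invalid="ignore"):
            self.freqs[name] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        self.sizes[name] = n


@dataclass
class FStatResult:
    value: float
    se: float
    z: float
    n_snps: int
    n_blocks: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("SE must be >= 0")
        if self.n_snps <= 0:
            raise ValueError("no SNPs used")


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

def _block_bounds(n: int, block_size: int) -> list[tuple[int, int]]:
    if block_size >= n:
        raise ValueError("block_size must be smaller than the SNP count")
    bounds = [(lo, min(lo + block_size, n)) for lo in range(0, n, block_size)]
    if len(bounds) < 2:
        raise ValueError("need at least 2 blocks")
    return bounds


def _weighted_jackknife_se(theta_hat: float, theta_del: np.ndarray,
                           m: np.ndarray) -> float:
    """Busing-style weighted delete-one jackknife standard error."""
    n = m.sum()
    g = len(m)
    h = n / m
    theta_dot = g * theta_hat - float(((1 - m / n) * theta_del).sum())
    tau = h * theta_hat - (h - 1) * theta_del
    var = float((np.square(tau - theta_dot) / (h - 1)).sum() / g)
    return float(np.sqrt(max(var, 0.0)))


def block_jackknife(per_snp_terms: np.ndarray,
                    block_size: int = DEFAULT_BLOCK_SIZE) -> tuple[float, float]:
    """(estimate, SE) of the mean of per-SNP terms, jackknifing blocks."""
    terms = np.asarray(per_snp_terms, dtype=float)
    n = len(terms)
    bounds = _block_bounds(n, block_size)
    total = terms.sum()
    est = total / n
    m = np.array([hi - lo for lo, hi in bounds], dtype=float)
    theta_del = np.array([(total - terms[lo:hi].sum()) / (n - (hi - lo))
                          for lo, hi in bounds])
    return float(est), _weighted_jackknife_se(est, theta_del, m)


# ---------------------------------------------------------------------------
# f statistics
# ---------------------------------------------------------------------------

def _complete_case(ft: FreqTable, names: tuple[str, ...]) -> np.ndarray:
    mask = np.ones(len(ft.pos), dtype=bool)
    for name in names:
        mask &= np.isfinite(ft.freqs[name]) & (ft.sizes[name] >= 2)
    return mask


def f3(ft: FreqTable, target: str, source_a: str, source_b: str,
       block_size: int = DEFAULT_BLOCK_SIZE, correction: bool = True) -> FStatResult:
    """f3(target; source_a, source_b): negative implies admixture in target."""
    mask = _complete_case(ft, (target, source_a, source_b))
    c = ft.freqs[target][mask]
    a = ft.freqs[source_a][mask]
    b = ft.freqs[source_b][mask]
    terms = (c - a) * (c - b)
    if correction:
        terms = terms - c * (1 - c) / (ft.sizes[target][mask] - 1)
    est, se = block_jackknife(terms, block_size)
    z = est / se if se > 0 else 0.0
    return FStatResult(value=est, se=se, z=z, n_snps=int(mask.sum()),
                       n_blocks=int(np.ceil(mask.sum() / block_size)))


def f4(ft: FreqTable, quadruple: tuple[str, str, str, str],
       block_size: int = DEFAULT_BLOCK_SIZE) -> FStatResult:
    """f4(A, B; C, D) = mean over SNPs of (a-b)(c-d)."""
    na, nb, nc, nd = quadruple
    mask = _complete_case(ft, quadruple)
    terms = ((ft.freqs[na][mask] - ft.freqs[nb][mask])
             * (ft.freqs[nc][mask] - ft.freqs[nd][mask]))
    est, se = block_jackknife(terms, block_size)
    z = est / se if se > 0 else 0.0
    return FStatResult(value=est, se=se, z=z, n_snps=int(mask.sum()),
                       n_blocks=int(np.ceil(mask.sum() / block_size)))


def f4_ratio(ft: FreqTable, numerator: tuple[str, str, str, str],
             denominator: tuple[str, str, str, str],
             block_size: int = DEFAULT_BLOCK_SIZE) -> FStatResult:
    """Ratio of two f4 means, SE by jackknifing the ratio over blocks."""
    mask = _complete_case(ft, tuple(set(numerator) | set(denominator)))
    idx = np.where(mask)[0]

    def terms_of(quad):
        na, nb, nc, nd = quad
        return ((ft.freqs[na][idx] - ft.freqs[nb][idx])
                * (ft.freqs[nc][idx] - ft.freqs[nd][idx]))

    num = terms_of(numerator)
    den = terms_of(denominator)
    den_res = f4(ft, denominator, block_size)
    if abs(den_res.z) < 3:
        logger.warning("f4-ratio denominator is weak (|Z| = %.2f < 3)",
                       abs(den_res.z))
    if den.sum() == 0:
        raise ZeroDivisionError("f4-ratio denominator is zero")

    n = len(num)
    bounds = _block_bounds(n, block_size)
    est = float(num.sum() / den.sum())
    m = np.array([hi - lo for lo, hi in bounds], dtype=float)
    theta_del = np.array([
        (num.sum() - num[lo:hi].sum()) / (den.sum() - den[lo:hi].sum())
        for lo, hi in bounds
    ])
    se = _weighted_jackknife_se(est, theta_del, m)
    z = est / se if se > 0 else 0.0
    return FStatResult(value=est, se=se, z=z, n_snps=n, n_blocks=len(bounds))
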