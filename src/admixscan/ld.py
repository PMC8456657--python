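"""Two-locus LD (D', r^2) from unphased genotypes via EM phasing.

Haplotype frequencies for two biallelic loci are estimated from unphased
genotype pairs by expectation-maximization over the double-heterozygote
phase ambiguity, starting from linkage-equilibrium product frequencies.
Missing-at-either-locus samples are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import MISSING

logger = logging.getLogger(__name__)

# haplotype order: (alt, alt), (alt, ref), (ref, alt), (ref, ref)
_HAP_ALLELES = ((1, 1), (1, 0), (0, 1), (0, 0))


@dataclass
class LDResult:
    hap_freqs: np.ndarray  # f11, f10, f01, f00
    d: float
    d_prime: float
    r2: float
    n_iter: int
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        f = np.asarray(self.hap_freqs, dtype=float)
        if (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must be >= 0 and sum to 1")
        if not (-1e-9 <= self.d_prime <= 1 + 1e-9
                and -1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("D' and r^2 must lie in [0, 1]")


def _genotype_pair_probs(f: np.ndarray) -> np.ndarray:
    """(3, 3) genotype-pair probabilities under random union of gametes."""
    probs = np.zeros((3, 3))
    for i, (a1, b1) in enumerate(_HAP_ALLELES):
        for j, (a2, b2) in enumerate(_HAP_ALLELES):
            probs[a1 + a2, b1 + b2] += f[i] * f[j]
    return probs


def loglik_of(f: np.ndarray, counts: np.ndarray) -> float:
    """Observed-data log-likelihood of genotype-pair counts."""
    probs = _genotype_pair_probs(f)
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    lp[counts == 0] = 0.0  # 0 * log(0) = 0
    if not np.isfinite(lp[counts > 0]).all():
        return -np.inf
    return float((counts * lp).sum())


def genotype_pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """(3, 3) table of complete-case genotype pairs."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("locus genotype vectors differ in length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        raise ValueError("need at least two complete samples")
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (g1[ok], g2[ok]), 1)
    return counts


def em_haplotypes(g1: np.ndarray, g2: np.ndarray, tol: float = 1e-8,
                  max_iter: int = 1000, restarts: int = 0,
                  seed: int = 0) -> LDResult:
    """EM haplotype-frequency estimate and LD statistics for two loci.

    ``restarts`` adds random restarts on top of the deterministic
    product-frequency initialization (normally unnecessary; the two-locus
    likelihood is unimodal in practice).
    """
    counts = genotype_pair_counts(g1, g2)
    n = counts.sum()
    p1 = (counts * np.arange(3)[:, None]).sum() / (2 * n)  # alt freq locus 1
    q1 = (counts * np.arange(3)[None, :]).sum() / (2 * n)
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        raise ValueError(
            "monomorphic locus among complete samples; report allele "
            "frequencies instead of LD")

    inits = [np.array([p1 * q1, p1 * (1 - q1), (1 - p1) * q1,
                       (1 - p1) * (1 - q1)])]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for _ in range(restarts):
        f = rng.dirichlet(np.ones(4))
        inits.append(f)

    best = None
    for f0 in inits:
        res = _run_em(f0, counts, n, tol, max_iter)
        if best is None or res[2] > best[2]:
            best = res
    f, n_iter, ll, converged = best
    d_prime, r2, d = d_prime_r2(f, return_d=True)
    return LDResult(hap_freqs=f, d=d, d_prime=d_prime, r2=r2,
                    n_iter=n_iter, loglik=ll, converged=converged)


def _run_em(f: np.ndarray, counts: np.ndarray, n: int, tol: float,
            max_iter: int):
    f = f.copy()
    ll = loglik_of(f, counts)
    converged = False
    it = 0
    # fixed haplotype contributions of each unambiguous genotype pair
    for it in range(1, max_iter + 1):
        hap = np.zeros(4)
        for i in range(3):
            for j in range(3):
                c = counts[i, j]
                if c == 0 or (i == 1 and j == 1):
                    continue
                # alleles split deterministically across the two haplotypes
                a_hi = 1 if i >= 1 else 0
                a_lo = 1 if i == 2 else 0
                b_hi = 1 if j >= 1 else 0
                b_lo = 1 if j == 2 else 0
                hap[_hap_index(a_hi, b_hi)] += c
                hap[_hap_index(a_lo, b_lo)] += c
        c_dh = counts[1, 1]
        if c_dh:
            cis = f[0] * f[3]
            trans = f[1] * f[2]
            w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
            hap[0] += c_dh * w
            hap[3] += c_dh * w
            hap[1] += c_dh * (1 - w)
            hap[2] += c_dh * (1 - w)
        f_new = hap / (2 * n)
        ll_new = loglik_of(f_new, counts)
        if ll_new < ll - 1e-9:
            raise AssertionError("EM decreased the log-likelihood")
        delta = np.abs(f_new - f).max()
        f, ll = f_new, ll_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    return f, it, ll, converged


def _hap_index(a: int, b: int) -> int:
    return {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(a, b)]


def d_prime_r2(hap_freqs: np.ndarray, return_d: bool = False):
    """Lewontin D' and squared correlation r^2 from 4 haplotype frequencies.

    Frequencies are ordered (f11, f10, f01, f00) where index 1 denotes the
    alt allele at each locus.
    """
    f = np.asarray(hap_freqs, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must sum to 1")
    p1 = f[0] + f[1]  # alt at locus 1
    q1 = f[0] + f[2]  # alt at locus 2
    if p1 <= 0 or p1 >= 1 or q1 <= 0 or q1 >= 1:
        raise ValueError("degenerate locus: allele fixed")
    d = f[0] - p1 * q1
    if d > 0:
        d_max = min(p1 * (1 - q1), (1 - p1) * q1)
    else:
        d_max = min(p1 * q1, (1 - p1) * (1 - q1))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p1 * (1 - p1) * q1 * (1 - q1))
    if return_d:
        return float(min(d_prime, 1.0)), float(min(r2, 1.0)), float(d)
    return float(min(d_prime, 1.0)), float(min(r2, 1.0))
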