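"""Expected ancestry dosage from unphased genotypes and two reference panels.

The hidden state for each admixed individual at each SNP is the unordered
number of haplotypes (0, 1 or 2) deriving from source P.  Each haplotype
follows an independent two-state Markov chain along the chromosome: between
adjacent SNPs at genetic distance ``d`` Morgans it switches into the
stationary ancestry distribution ``(m, 1-m)`` with probability
``1 - exp(-g * d)``, where ``g`` is the number of generations since
admixture.  The diploid transition kernel is the two-haplotype product
collapsed to counts.  Emissions treat each haplotype's allele as Bernoulli
in its ancestry's (error-adjusted, smoothed) panel frequency.

Posterior expected dosage is computed by a scaled forward-backward pass,
independently per chromosome (or per supplied block).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_POST_SUM_TOL = 1e-10


@dataclass
class AlleleFreqPanel:
    """Smoothed per-SNP alt-allele frequencies for one source population."""

    freq: np.ndarray          # in (0, 1) after add-half smoothing
    n_alleles: np.ndarray     # called allele count per SNP

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_alleles = np.asarray(self.n_alleles, dtype=np.int64)
        if ((self.freq <= 0) | (self.freq >= 1)).any():
            raise ValueError("panel frequencies must lie strictly in (0, 1)")


@dataclass
class HMMParams:
    """Ancestry-chain parameters.

    ``m`` is the stationary P-ancestry proportion; ``None`` requests
    self-consistent estimation (iterate m = genome-wide mean dosage / 2).
    """

    g: int = 100
    m: float | None = None
    rec: float = 1.3e-8
    eps: float = 0.005

    def __post_init__(self) -> None:
        if self.g < 1:
            raise ValueError("g must be >= 1")
        if self.m is not None and not 0.0 < self.m < 1.0:
            raise ValueError("m must be in (0, 1)")
        if not 0.0 <= self.eps < 0.5:
            raise ValueError("eps must be in [0, 0.5)")


@dataclass
class AncestryDosageMatrix:
    """Expected P-ancestry copies (0..2) per individual per SNP."""

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray  # (n_individuals, n_snps)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape[0] != len(self.sample_ids):
            raise ValueError("dosage rows must match sample count")
        if (self.dosage < -1e-9).any() or (self.dosage > 2 + 1e-9).any():
            raise ValueError("dosage values must lie in [0, 2]")

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def mean_track(self) -> np.ndarray:
        """Per-SNP mean P-ancestry proportion (mean dosage / 2)."""
        return mean_ancestry_track(self)


def estimate_source_freqs(gm: GenotypeMatrix) -> AlleleFreqPanel:
    """Panel frequencies with add-half smoothing: (alt + 0.5)/(called + 1)."""
    if gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    alt, n = gm.allele_counts()
    if (n == 0).any():
        logger.warning("%d SNPs with zero called alleles; frequency set to 0.5",
                       int((n == 0).sum()))
    return AlleleFreqPanel(freq=(alt + 0.5) / (n + 1), n_alleles=n)


def mean_ancestry_track(dm: AncestryDosageMatrix) -> np.ndarray:
    if len(dm.sample_ids) == 0:
        raise ValueError("need at least one individual")
    return dm.dosage.mean(axis=0) / 2.0


# ---------------------------------------------------------------------------
# HMM internals
# ---------------------------------------------------------------------------

def _stationary(m: float) -> np.ndarray:
    return np.array([(1 - m) ** 2, 2 * m * (1 - m), m * m])


def diploid_transitions(gaps_bp: np.ndarray, g: int, rec: float,
                        m: float) -> np.ndarray:
    """(n_gaps, 3, 3) transition kernels between adjacent SNPs.

    Per haplotype: stay on the current ancestry with probability
    ``e = exp(-g * rec * gap)``, otherwise redraw from (m, 1-m).  The
    diploid kernel composes two independent haplotypes into counts.
    """
    e = np.exp(-g * rec * np.asarray(gaps_bp, dtype=float))
    p_pp = e + (1 - e) * m        # P haplotype -> P
    p_ap = (1 - e) * m            # A haplotype -> P
    T = np.empty((len(e), 3, 3))
    for q in range(3):
        # q P-haplotypes and 2-q A-haplotypes transition independently
        for q2 in range(3):
            total = np.zeros_like(e)
            for kp in range(min(q, q2) + 1):
                ka = q2 - kp
                if ka > 2 - q:
                    continue
                total += (
                    _binom(q, kp) * p_pp**kp * (1 - p_pp)**(q - kp)
                    * _binom(2 - q, ka) * p_ap**ka * (1 - p_ap)**(2 - q - ka)
                )
            T[:, q, q2] = total
    return T


def _binom(n: int, k: int) -> float:
    from math import comb
    return float(comb(n, k))


def emission_probs(geno: np.ndarray, freq_p: np.ndarray, freq_a: np.ndarray,
                   eps: float) -> np.ndarray:
    """(n_snps, n_individuals, 3) genotype likelihoods given P-copy count.

    Given state q, haplotype alleles are independent Bernoulli draws with
    error-adjusted frequency f' = (1-eps) f + eps (1-f) of their ancestry's
    panel.  Missing genotypes emit likelihood 1.
    """
    fp = (1 - eps) * freq_p + eps * (1 - freq_p)
    fa = (1 - eps) * freq_a + eps * (1 - freq_a)
    n_snps = len(fp)
    probs = np.empty((n_snps, 3, 3))  # (snp, state, genotype)
    for q, (a, b) in enumerate(((fa, fa), (fp, fa), (fp, fp))):
        probs[:, q, 0] = (1 - a) * (1 - b)
        probs[:, q, 1] = a * (1 - b) + b * (1 - a)
        probs[:, q, 2] = a * b
    g = geno.T  # (n_snps, n_individuals)
    gidx = np.where(g == MISSING, 0, g)
    # advanced indices in dims 0 and 2 around the state slice: the broadcast
    # (snp, individual) shape leads, the state axis is appended
    E = probs[np.arange(n_snps)[:, None], :, gidx]
    E[g == MISSING] = 1.0
    return E


def _forward_backward(E: np.ndarray, T: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward over one block.

    Returns (posterior (n_snps, n_ind, 3), log-likelihood per individual).
    """
    n_snps, n_ind, _ = E.shape
    alpha = np.empty_like(E)
    scale = np.empty((n_snps, n_ind))
    a = pi[None, :] * E[0]
    scale[0] = a.sum(axis=1)
    _check_finite(scale[0], 0)
    alpha[0] = a / scale[0][:, None]
    for k in range(1, n_snps):
        a = (alpha[k - 1] @ T[k - 1]) * E[k]
        scale[k] = a.sum(axis=1)
        _check_finite(scale[k], k)
        alpha[k] = a / scale[k][:, None]
    beta = np.empty_like(E)
    beta[-1] = 1.0
    for k in range(n_snps - 2, -1, -1):
        beta[k] = (beta[k + 1] * E[k + 1]) @ T[k].T / scale[k + 1][:, None]
    post = alpha * beta
    norm = post.sum(axis=2)
    if np.abs(norm - 1.0).max() > _POST_SUM_TOL:
        raise AssertionError("posterior state probabilities do not sum to 1")
    post /= norm[:, :, None]
    return post, np.log(scale).sum(axis=0)


def _check_finite(scale: np.ndarray, snp_index: int) -> None:
    if not np.isfinite(scale).all() or (scale <= 0).any():
        raise FloatingPointError(
            f"non-finite likelihood at SNP index {snp_index}")


def infer_dosage(gm_admixed: GenotypeMatrix, panel_p: AlleleFreqPanel,
                 panel_a: AlleleFreqPanel, params: HMMParams,
                 block_ids: np.ndarray | None = None) -> AncestryDosageMatrix:
    """Posterior expected P-ancestry dosage per individual per SNP.

    ``block_ids`` partitions SNPs into independent chains (defaults to the
    chromosome labels); blocks must be contiguous runs.  When ``params.m``
    is None the stationary proportion is estimated self-consistently.
    """
    n = gm_admixed.n_snps
    if len(panel_p.freq) != n or len(panel_a.freq) != n:
        raise ValueError("panel SNP sets do not match the admixed matrix")
    if n == 0:
        raise ValueError("no SNPs to analyse")
    if block_ids is None:
        block_ids = gm_admixed.chrom
    block_ids = np.asarray(block_ids)
    if len(block_ids) != n:
        raise ValueError("block_ids length must match SNP count")

    E_cache = emission_probs(gm_admixed.geno, panel_p.freq, panel_a.freq,
                             params.eps)
    # contiguous block boundaries
    starts = np.r_[0, np.where(block_ids[1:] != block_ids[:-1])[0] + 1, n]
    blocks = [(starts[i], starts[i + 1]) for i in range(len(starts) - 1)]

    def run(m: float) -> np.ndarray:
        dosage = np.empty((gm_admixed.n_samples, n))
        pi = _stationary(m)
        q_values = np.arange(3.0)
        for lo, hi in blocks:
            gaps = np.diff(gm_admixed.pos[lo:hi].astype(float))
            T = diploid_transitions(gaps, params.g, params.rec, m)
            post, _ = _forward_backward(E_cache[lo:hi], T, pi)
            dosage[:, lo:hi] = (post @ q_values).T
        return dosage

    if params.m is not None:
        dosage = run(params.m)
    else:
        m = 0.5
        for _ in range(10):
            dosage = run(m)
            m_new = float(np.clip(dosage.mean() / 2.0, 1e-4, 1 - 1e-4))
            done = abs(m_new - m) < 1e-4
            m = m_new
            if done:
                break
        dosage = run(m)

    return AncestryDosageMatrix(
        sample_ids=list(gm_admixed.sample_ids),
        chrom=gm_admixed.chrom,
        pos=gm_admixed.pos,
        dosage=np.clip(dosage, 0.0, 2.0),
    )
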