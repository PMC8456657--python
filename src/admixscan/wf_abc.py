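"""Wright-Fisher forward model with additive selection and rejection ABC.

The favored allele (frequency ``p``) has genotype fitnesses 1, 1-s, 1-2s
for 2/1/0 copies.  Each generation applies the deterministic selection
update and then binomial resampling of 2N allele copies.  The selection
coefficient is estimated by rejection ABC: draw s from a uniform prior,
simulate the trajectory from the admixture-time initial frequency, and
accept draws whose final frequency falls in a window around the observed
present-day frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SelectionParams:
    s: float
    N: int = 1000
    g: int = 100
    p0: float = 0.26

    def __post_init__(self) -> None:
        if self.s >= 0.5:
            raise ValueError("s must be < 0.5")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")
        if self.N < 1 or self.g < 1:
            raise ValueError("N and g must be >= 1")


@dataclass
class ABCConfig:
    window: tuple[float, float]
    n_accept: int = 10_000
    prior: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    batch_size: int = 10_000

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("acceptance window must be a sub-interval of [0, 1]")
        if self.n_accept < 1:
            raise ValueError("need at least one accepted draw")


@dataclass
class ABCPosterior:
    accepted: np.ndarray
    mean: float
    ci95: tuple[float, float]
    n_attempted: int
    acceptance_rate: float

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if lo > hi:
            raise ValueError("credible interval bounds out of order")


def initial_frequency(freq_p: float, freq_a: float, alpha_p: float) -> float:
    """Admixture-weighted initial frequency of the focal allele."""
    for x in (freq_p, freq_a, alpha_p):
        if not 0.0 <= x <= 1.0:
            raise ValueError("inputs must be proportions in [0, 1]")
    return freq_p * alpha_p + freq_a * (1.0 - alpha_p)


def acceptance_window(observed_freq: float, tolerance: float) -> tuple[float, float]:
    """[observed*(1-tol), observed*(1+tol)], clipped to [0, 1]."""
    if not 0.0 < observed_freq < 1.0:
        raise ValueError("observed frequency must be in (0, 1)")
    if not 0.0 <= tolerance < 1.0:
        raise ValueError("relative tolerance must be in [0, 1)")
    lo = max(observed_freq * (1.0 - tolerance), 0.0)
    hi = min(observed_freq * (1.0 + tolerance), 1.0)
    return (lo, hi)


def freq_update(p: float, s: float) -> float:
    """One generation of deterministic selection on the favored allele.

    p' = [p^2 + p(1-p)(1-s)] / [p^2 + 2p(1-p)(1-s) + (1-p)^2 (1-2s)].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    num = p * p + p * (1 - p) * (1 - s)
    den = p * p + 2 * p * (1 - p) * (1 - s) + (1 - p) * (1 - p) * (1 - 2 * s)
    if den <= 0:
        raise ValueError(f"non-positive mean fitness (p={p}, s={s})")
    return num / den


def _batch_update(p: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Vectorized selection update, tolerant of prior draws with s >= 0.5.

    Genotype fitnesses are floored at 0 so that extreme prior draws remain
    well-defined; such draws push the allele to fixation and are rejected
    by any interior acceptance window.
    """
    w1 = np.maximum(1.0 - s, 0.0)
    w0 = np.maximum(1.0 - 2.0 * s, 0.0)
    num = p * p + p * (1 - p) * w1
    den = p * p + 2 * p * (1 - p) * w1 + (1 - p) * (1 - p) * w0
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    return np.clip(out, 0.0, 1.0)


def simulate_trajectories(p0: float, s: np.ndarray, N: int, g: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Final favored-allele frequencies for a vector of s values."""
    s = np.asarray(s, dtype=float)
    p = np.full(s.shape, p0, dtype=float)
    for _ in range(g):
        p_exp = _batch_update(p, s)
        p = rng.binomial(2 * N, p_exp) / (2.0 * N)
    return p


def simulate_trajectory(params: SelectionParams, seed: int,
                        full_path: bool = False):
    """One trajectory; returns the final frequency (or the whole path)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = params.p0
    path = [p]
    for _ in range(params.g):
        p_exp = freq_update(p, params.s)
        p = rng.binomial(2 * params.N, p_exp) / (2.0 * params.N)
        path.append(p)
    return np.array(path) if full_path else p


def abc_estimate(p0: float, N: int, g: int, config: ABCConfig) -> ABCPosterior:
    """Rejection ABC posterior for s.

    Draws s from the uniform prior in seeded batches, simulates the forward
    model and keeps draws whose final frequency lies in the acceptance
    window, until ``config.n_accept`` draws are collected.
    """
    lo, hi = config.window
    if lo > hi:
        raise ValueError("empty acceptance window")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    accepted: list[np.ndarray] = []
    n_acc = 0
    n_att = 0
    while n_acc < config.n_accept:
        s = rng.uniform(config.prior[0], config.prior[1], config.batch_size)
        final = simulate_trajectories(p0, s, N, g, rng)
        ok = (final >= lo) & (final <= hi)
        accepted.append(s[ok])
        n_acc += int(ok.sum())
        n_att += config.batch_size
        if n_att >= 10_000_000 and n_acc / n_att < 1e-6:
            raise RuntimeError("acceptance window appears unreachable")
    draws = np.concatenate(accepted)[:config.n_accept]
    return ABCPosterior(
        accepted=draws,
        mean=float(draws.mean()),
        ci95=(float(np.quantile(draws, 0.025)),
              float(np.quantile(draws, 0.975))),
        n_attempted=n_att,
        acceptance_rate=n_acc / n_att,
    )
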