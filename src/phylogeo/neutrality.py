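"""Neutrality tests: Tajima's D and Fu's Fs with coalescent-simulated p-values.

Both statistics contrast observed polymorphism with constant-size neutral
expectations.  Tajima's D compares the mean pairwise difference with the
scaled number of segregating sites; Fu's Fs asks how improbable the observed
number of distinct haplotypes is under the Ewens sampling distribution given
the observed pairwise diversity.  Jointly significant negative values signal
demographic expansion.

Significance is assessed by simulating constant-size coalescent samples
conditioned on the observed number of segregating sites (mutations dropped
uniformly on the genealogy), the convention used by Arlequin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

from .diversity import UndefinedStatisticError


@dataclass
class NeutralityResult:
    D: float
    p_D: float
    Fs: float
    p_Fs: float
    nreps: int
    seed: int | None
    # Fu recommends judging Fs at p < 0.02 for a nominal 5% level; recorded
    # here for the reader, never applied to the p-value itself.
    fs_alpha_note: str = "Fu (1997): treat Fs as significant at the 5% level when p < 0.02"


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's variance correction."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(n: int, S_seg: int, pi_seq: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise differences."""
    if n < 4:
        raise UndefinedStatisticError("Tajima's D requires n >= 4")
    if S_seg < 1:
        raise UndefinedStatisticError("Tajima's D undefined when S = 0")
    k = tajima_constants(n)
    var = k["e1"] * S_seg + k["e2"] * S_seg * (S_seg - 1.0)
    return float((pi_seq - S_seg / k["a1"]) / math.sqrt(var))


@lru_cache(maxsize=64)
def _log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    Standard recurrence |s(n+1,k)| = n*|s(n,k)| + |s(n,k-1)| carried in log
    space (all terms are non-negative, so no sign tracking is needed).
    """
    log_s = np.full(n + 1, -np.inf)
    log_s[0] = 0.0  # |s(0,0)| = 1
    for m in range(n):
        nxt = np.full(n + 1, -np.inf)
        # |s(m+1,k)| = m*|s(m,k)| + |s(m,k-1)|
        with np.errstate(divide="ignore"):
            shifted = np.concatenate(([-np.inf], log_s[:-1]))
            scaled = log_s + (math.log(m) if m > 0 else -np.inf)
        nxt = np.logaddexp(scaled, shifted)
        log_s = nxt
    return log_s


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | theta) for k = 0..n under the Ewens sampling distribution."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_s = _log_stirling_first(n)
    k = np.arange(n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return log_s + k * math.log(theta) - log_rising


def fus_fs(n: int, theta_pi: float, k_obs: int) -> float:
    """Fu's Fs = ln(S'/(1-S')) with S' = Pr(K >= k_obs | theta = theta_pi).

    Returns signed infinity (with a warning) when S' is numerically 0 or 1,
    which happens when k_obs = 1 (K >= 1 is certain) or when the tail
    probability underflows.
    """
    if n < 2:
        raise UndefinedStatisticError("Fu's Fs requires n >= 2")
    if not 1 <= k_obs <= n:
        raise ValueError("observed haplotype count must lie in [1, n]")
    if theta_pi <= 0:
        raise UndefinedStatisticError("Fu's Fs requires theta_pi > 0")
    logp = ewens_log_pmf(n, theta_pi)
    log_tail = float(logsumexp(logp[k_obs:]))  # log S'
    log_head = float(logsumexp(logp[:k_obs])) if k_obs > 1 else -np.inf
    if log_head == -np.inf:
        logger.warning("Fu's Fs: S' = 1 exactly (k_obs = %d); returning +inf", k_obs)
        return math.inf
    if log_tail == -np.inf:
        logger.warning("Fu's Fs: S' underflowed to 0; returning -inf")
        return -math.inf
    return log_tail - log_head


# ---------------------------------------------------------------------------
# Fixed-S coalescent null simulation


def _simulate_branches(n: int, rng: np.random.Generator
                       ) -> tuple[list[np.ndarray], np.ndarray]:
    """One constant-size coalescent genealogy: branch tip-sets and lengths.

    Times are in arbitrary units (only relative branch lengths matter for
    fixed-S mutation placement).  Returns one entry per branch, where the
    tip-set is the boolean mask of samples below the branch.
    """
    lineages = [np.zeros(n, dtype=bool) for _ in range(n)]
    for i, m in enumerate(lineages):
        m[i] = True
    start = np.zeros(n)
    t = 0.0
    sets: list[np.ndarray] = []
    lens: list[float] = []
    active = list(range(n))
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for idx in (a, b):
            sets.append(lineages[idx])
            lens.append(t - start[idx])
        merged = lineages[a] | lineages[b]
        lineages.append(merged)
        start = np.append(start, t)
        new = len(lineages) - 1
        active = [x for x in active if x not in (a, b)] + [new]
    return sets, np.asarray(lens)


def simulate_fixed_s_sample(n: int, S_seg: int, rng: np.random.Generator
                            ) -> tuple[float, int]:
    """Simulate (pi_seq, K) for a constant-size sample conditioned on S.

    S mutations are dropped on the genealogy with probability proportional
    to branch length, each at a fresh (infinite-sites) position.
    """
    sets, lens = _simulate_branches(n, rng)
    probs = lens / lens.sum()
    hits = rng.multinomial(S_seg, probs)
    npairs = n * (n - 1) / 2.0
    pi = 0.0
    sig = np.zeros((n, len(sets)), dtype=bool)
    col = 0
    for b_idx, h in enumerate(hits):
        if h == 0:
            continue
        size = int(sets[b_idx].sum())
        pi += h * size * (n - size) / npairs
        sig[:, col] = sets[b_idx]
        col += 1
    # haplotype count: identical mutation signatures share a haplotype;
    # multiplicity of mutations on one branch does not split haplotypes.
    uniq = {row.tobytes() for row in sig[:, :col]} if col else {b""}
    return pi, len(uniq)


def neutrality_pvalues(n: int, S_seg: int, D_obs: float, Fs_obs: float,
                       nreps: int = 1000, seed: int | None = None
                       ) -> tuple[float, float]:
    """One-tailed (low) p-values for D and Fs from fixed-S null simulations.

    p = fraction of simulated statistics <= the observed value; significantly
    small p for negative statistics indicates expansion.
    """
    if nreps < 100:
        raise ValueError("use at least 100 simulation replicates")
    rng = np.random.default_rng(seed)
    d_le = 0
    fs_le = 0
    for _ in range(nreps):
        pi, k = simulate_fixed_s_sample(n, S_seg, rng)
        d_sim = tajimas_d(n, S_seg, pi)
        fs_sim = fus_fs(n, pi, k) if pi > 0 else math.inf
        if d_sim <= D_obs:
            d_le += 1
        if fs_sim <= Fs_obs:
            fs_le += 1
    return d_le / nreps, fs_le / nreps


def neutrality_test(n: int, S_seg: int, pi_seq: float, k_obs: int,
                    nreps: int = 1000, seed: int | None = None
                    ) -> NeutralityResult:
    """Compute D, Fs and their simulated p-values for one sample."""
    D = tajimas_d(n, S_seg, pi_seq)
    Fs = fus_fs(n, pi_seq, k_obs)
    p_D, p_Fs = neutrality_pvalues(n, S_seg, D, Fs, nreps=nreps, seed=seed)
    return NeutralityResult(D=D, p_D=p_D, Fs=Fs, p_Fs=p_Fs,
                            nreps=nreps, seed=seed)
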