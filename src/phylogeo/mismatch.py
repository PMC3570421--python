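"""Mismatch distributions and sudden-expansion demographic inference.

The mismatch distribution is the histogram of pairwise sequence differences
among individuals.  Under a sudden demographic expansion it is smooth and
unimodal, and the Rogers-Harpending model gives the expected class
probabilities.  With the post-expansion size taken as infinite (the
approximation used when only tau is reported) these are

    F_i(tau, theta0) = exp(-tau) * sum_{j=0..i} theta0^j/(theta0+1)^(j+1)
                                   * tau^(i-j)/(i-j)!

where tau = 2*u*t is the expansion age in mutational time (u = per-sequence
mutation rate per year, t = years).  Parameters are fitted by minimising the
sum of squared deviations (SSD) between observed and expected frequencies;
goodness of fit for SSD and Harpending's raggedness index is assessed by
parametric bootstrap under the fitted model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .seqdata import HaplotypeTable


@dataclass
class SuddenExpansionFit:
    tau: float
    theta0: float
    theta1: float  # inf under the default two-parameter model
    SSD: float
    converged: bool = True


@dataclass
class MismatchResult:
    histogram: np.ndarray
    fit: SuddenExpansionFit
    raggedness: float
    p_SSD: float | None = None
    p_rag: float | None = None
    t_years: float | None = None
    nreps: int = 0
    seed: int | None = None


class FitError(RuntimeError):
    """Optimisation failed; carries the best parameters found so far."""

    def __init__(self, msg: str, best: SuddenExpansionFit):
        super().__init__(msg)
        self.best = best


def mismatch_histogram(t: HaplotypeTable, d, populations=None) -> np.ndarray:
    """Counts of individual pairs with i differences, i = 0..max observed.

    Every unordered pair of individuals in scope contributes once; pairs
    sharing a haplotype fall in class 0.
    """
    cnt = t.haplotype_counts(populations)
    n = int(cnt.sum())
    if n < 2:
        raise ValueError("mismatch histogram requires >= 2 individuals")
    dm = np.asarray(d)
    dmax = int(dm[np.ix_(cnt > 0, cnt > 0)].max()) if (cnt > 0).sum() > 1 else 0
    hist = np.zeros(dmax + 1, dtype=float)
    idx = np.nonzero(cnt)[0]
    for ai, i in enumerate(idx):
        hist[0] += cnt[i] * (cnt[i] - 1) / 2.0
        for j in idx[ai + 1:]:
            hist[int(dm[i, j])] += cnt[i] * cnt[j]
    assert hist.sum() == n * (n - 1) / 2.0
    return hist


def histogram_from_pairs(diffs: np.ndarray) -> np.ndarray:
    """Histogram from an explicit vector of per-pair difference counts."""
    diffs = np.asarray(diffs, dtype=int)
    hist = np.bincount(diffs)
    return hist.astype(float)


def expected_probabilities(tau: float, theta0: float, n_classes: int,
                           renormalize: bool = False) -> np.ndarray:
    """Rogers-Harpending expected class probabilities F_0..F_{n_classes-1}.

    The infinite support means sum_i F_i < 1 over any finite class range;
    with ``renormalize`` the deficit (tail mass) is folded in so the vector
    sums to one.
    """
    i = np.arange(n_classes)
    # geometric equilibrium term g_j = theta0^j/(theta0+1)^(j+1)
    log_g = i * math.log(theta0) - (i + 1) * math.log(theta0 + 1.0) \
        if theta0 > 0 else np.where(i == 0, 0.0, -np.inf)
    log_pois = np.where(tau > 0, i * math.log(max(tau, 1e-300)) - gammaln(i + 1),
                        np.where(i == 0, 0.0, -np.inf))
    g = np.exp(log_g)
    pois = np.exp(log_pois - tau)
    F = np.convolve(g, pois)[:n_classes]
    if renormalize:
        s = F.sum()
        if s > 0:
            F = F / s
    return F


def _ssd(params: np.ndarray, obs_freq: np.ndarray) -> float:
    tau, theta0 = params
    F = expected_probabilities(tau, theta0, obs_freq.size)
    return float(np.sum((obs_freq - F) ** 2))


def fit_sudden_expansion(histogram, n_starts: int = 8, tol: float = 1e-10
                         ) -> SuddenExpansionFit:
    """Fit (tau, theta0) of the sudden-expansion model by multi-start SSD minimisation.

    Starts are placed on a log-spaced tau x theta0 grid around the observed
    mean; each start runs a bounded derivative-free (Nelder-Mead) search.
    The post-expansion theta1 is treated as infinite.
    """
    hist = np.asarray(histogram, dtype=float)
    if (hist > 0).sum() < 1:
        raise ValueError("empty histogram")
    obs = hist / hist.sum()
    mean_d = float(np.arange(hist.size) @ obs)
    if hist.size == 1 or (hist[0] == hist.sum()):
        # all pairs identical: degenerate boundary optimum
        F0 = expected_probabilities(0.0, 0.0, hist.size)
        return SuddenExpansionFit(tau=0.0, theta0=0.0, theta1=math.inf,
                                  SSD=float(np.sum((obs - F0) ** 2)))
    tau_grid = np.geomspace(max(mean_d, 0.5) / 4.0, max(mean_d, 0.5) * 4.0, 4)
    th_grid = np.geomspace(0.05, max(mean_d, 1.0), max(2, n_starts // 4))
    starts = [(t0, th) for t0 in tau_grid for th in th_grid]
    # rank the grid starts by their SSD and polish the most promising ones
    # with a bounded derivative-free search
    starts.sort(key=lambda s: _ssd(np.asarray(s), obs))
    best = None
    bounds = [(0.0, 4.0 * hist.size), (0.0, 10.0 * max(mean_d, 1.0))]
    for t0, th in starts[:3]:
        res = minimize(_ssd, x0=np.array([t0, th]), args=(obs,),
                       method="Nelder-Mead", bounds=bounds,
                       options={"xatol": 1e-8, "fatol": tol, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    fit = SuddenExpansionFit(tau=float(best.x[0]), theta0=float(best.x[1]),
                             theta1=math.inf, SSD=float(best.fun),
                             converged=bool(best.success))
    if not best.success and best.fun > 1e-3:
        raise FitError("sudden-expansion fit did not converge", fit)
    return fit


def raggedness(histogram) -> float:
    """Harpending's raggedness index r = sum (x_i - x_{i-1})^2 over frequencies.

    The sum runs from class 1 to d+1 with x_{d+1} = 0, so a histogram with
    all mass in one interior class scores 2 and smooth distributions score
    near 0.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.size == 0:
        raise ValueError("empty histogram")
    x = hist / hist.sum()
    padded = np.concatenate(([0.0], x, [0.0]))
    return float(np.sum(np.diff(padded) ** 2))


# ---------------------------------------------------------------------------
# Coalescent simulation under sudden expansion (mutational time units)


def simulate_expansion_pairs(n: int, tau: float, theta0: float, theta1: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Pairwise-difference counts for a coalescent sample under sudden expansion.

    Time is measured in mutational units x = 2*u*t, in which the pairwise
    coalescence rate is 1/theta(x) (theta1 before the expansion looking
    backward, theta0 after) and each branch of length x accumulates
    Poisson(x/2) mutations.  Returns the n(n-1)/2 vector of pair differences.
    """
    if not math.isfinite(theta1):
        theta1 = 1e7  # effectively star-like recent phase
    theta1 = max(theta1, 1e-9)
    theta0 = max(theta0, 1e-9)
    masks = np.eye(n, dtype=bool)
    lineages = list(range(n))
    starts = np.zeros(n)
    branch_masks: list[np.ndarray] = []
    branch_lens: list[float] = []
    x = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        pair_rate = k * (k - 1) / 2.0
        th = theta1 if x < tau else theta0
        wait = rng.exponential(th / pair_rate)
        if x < tau and x + wait > tau:
            # rate changes at the expansion: restart wait in the older epoch
            x = tau
            continue
        x += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        for idx in (a, b):
            branch_masks.append(masks[idx])
            branch_lens.append(x - starts[idx])
        masks = np.vstack([masks, masks[a] | masks[b]])
        starts = np.append(starts, x)
        lineages = [v for v in lineages if v not in (a, b)] + [len(masks) - 1]
    lens = np.asarray(branch_lens)
    muts = rng.poisson(lens / 2.0)
    iu = np.triu_indices(n, k=1)
    diffs = np.zeros(len(iu[0]), dtype=int)
    for m, mask in zip(muts, branch_masks):
        if m == 0:
            continue
        split = mask[iu[0]] != mask[iu[1]]
        diffs[split] += m
    return diffs


def bootstrap_gof(histogram, fit: SuddenExpansionFit, n_individuals: int,
                  nreps: int = 1000, seed: int | None = None
                  ) -> tuple[float, float]:
    """Parametric-bootstrap p-values for SSD and raggedness.

    Simulates ``nreps`` coalescent samples of the same size under the fitted
    expansion parameters, re-fits each with the same optimiser settings, and
    reports the fraction of replicates whose statistic is >= the observed
    one (large SSD or raggedness indicating lack of fit).
    """
    rng = np.random.default_rng(seed)
    hist = np.asarray(histogram, dtype=float)
    ssd_obs = fit.SSD
    rag_obs = raggedness(hist)
    ssd_ge = 0
    rag_ge = 0
    for _ in range(nreps):
        diffs = simulate_expansion_pairs(n_individuals, fit.tau, fit.theta0,
                                         fit.theta1, rng)
        h = histogram_from_pairs(diffs)
        f = fit_sudden_expansion(h)
        if f.SSD >= ssd_obs:
            ssd_ge += 1
        if raggedness(h) >= rag_obs:
            rag_ge += 1
    return ssd_ge / nreps, rag_ge / nreps


def expansion_time(tau: float, rate: float, L: int) -> float:
    """Expansion age in years from tau = 2*u*t.

    ``rate`` is in % substitutions per site per million years (1.086 means
    1.086e-8 /site/year); u = rate*1e-8 * L is the per-sequence rate per
    year, so t = tau / (2u).  The per-year rate is what reproduces published
    expansion ages from published tau values.
    """
    if rate <= 0 or L <= 0:
        raise ValueError("rate and L must be positive")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    u = rate * 1e-8 * L
    return tau / (2.0 * u)


def mismatch_analysis(t: HaplotypeTable, d, populations=None,
                      rate: float | None = None, nreps: int = 1000,
                      seed: int | None = None) -> MismatchResult:
    """Full mismatch analysis for one scope: histogram, fit, GOF, dating."""
    hist = mismatch_histogram(t, d, populations)
    n = int(t.haplotype_counts(populations).sum())
    fit = fit_sudden_expansion(hist)
    r = raggedness(hist)
    p_ssd = p_rag = None
    if nreps:
        p_ssd, p_rag = bootstrap_gof(hist, fit, n, nreps=nreps, seed=seed)
    t_years = expansion_time(fit.tau, rate, t.L) if rate else None
    return MismatchResult(histogram=hist, fit=fit, raggedness=r,
                          p_SSD=p_ssd, p_rag=p_rag, t_years=t_years,
                          nreps=nreps, seed=seed)
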