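"""Diversity indices and theta-based effective-size conversion.

Gene (haplotype) diversity ``h`` is the unbiased probability that two
randomly drawn sequences carry different haplotypes,

    h = n/(n-1) * (1 - sum p_i^2),

with Nei's sampling variance

    V(h) = 2/(n(n-1)) * {2(n-2)[sum p_i^3 - (sum p_i^2)^2]
                         + sum p_i^2 - (sum p_i^2)^2}.

Nucleotide diversity ``pi`` is the mean per-site pairwise difference between
sequences; Watterson's theta estimates the population mutation parameter
from the number of segregating sites.  For mitochondrial (effectively
haploid, maternally inherited) loci theta = 2*Ne*mu, which converts an
empirical theta into an effective number of females.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdata import HaplotypeTable


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given sample (e.g. n < 2)."""


@dataclass
class DiversityStats:
    h: float
    se_h: float
    pi: float
    se_pi: float
    theta_w: float
    Ne: float | None = None


def haplotype_diversity(counts) -> tuple[float, float]:
    """Unbiased gene diversity and its standard error from haplotype counts."""
    c = np.asarray(list(counts), dtype=float)
    if np.any(c < 1):
        raise ValueError("all haplotype counts must be >= 1")
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError("gene diversity requires n >= 2")
    p = c / n
    s2 = float(np.sum(p ** 2))
    s3 = float(np.sum(p ** 3))
    h = n / (n - 1.0) * (1.0 - s2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2 ** 2) + s2 - s2 ** 2)
    return float(h), float(np.sqrt(max(var, 0.0)))


def mean_pairwise_differences(t: HaplotypeTable, d: pd.DataFrame,
                              populations: list[str] | None = None,
                              unbiased: bool = True) -> float:
    """Mean number of pairwise differences per sequence within a scope."""
    cnt = t.haplotype_counts(populations)
    n = cnt.sum()
    if n < 2:
        raise UndefinedStatisticError("pairwise diversity requires n >= 2")
    p = cnt / n
    dm = d.to_numpy()
    raw = float(p @ dm @ p)
    if unbiased:
        raw *= n / (n - 1.0)
    return raw


def nucleotide_diversity(t: HaplotypeTable, d: pd.DataFrame,
                         populations: list[str] | None = None,
                         unbiased: bool = True) -> tuple[float, float]:
    """Per-site nucleotide diversity pi and an approximate standard error.

    The standard error uses Nei's total-variance formula (stochastic plus
    sampling variance), which is approximate for finite samples:

        V(pi) = (n+1)/(3(n-1)) * pi/L + 2(n^2+n+3)/(9n(n-1)) * pi^2
    """
    if t.L <= 0:
        raise ValueError("haplotype table has no alignment length")
    n = float(t.haplotype_counts(populations).sum())
    pi_seq = mean_pairwise_differences(t, d, populations, unbiased=unbiased)
    pi = pi_seq / t.L
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    var = b1 * pi / t.L + b2 * pi ** 2
    return float(pi), float(np.sqrt(max(var, 0.0)))


def watterson_theta(S_seg: int, n: int) -> float:
    """Watterson's theta per sequence: S / a_n with a_n = sum_{i=1}^{n-1} 1/i."""
    if n < 2:
        raise UndefinedStatisticError("Watterson's theta requires n >= 2")
    if S_seg < 0:
        raise ValueError("segregating sites must be >= 0")
    a_n = float(np.sum(1.0 / np.arange(1, n)))
    return S_seg / a_n


def effective_size(theta_w: float, rate: float, L: int, gen_time: float) -> float:
    """Convert per-sequence theta to effective size via theta = 2*Ne*mu_g.

    Parameters
    ----------
    theta_w : per-sequence mutation parameter (>= 0)
    rate : substitution rate in % per site per million years
        (e.g. 1.086 means 1.086e-8 substitutions/site/year)
    L : sequence length in sites
    gen_time : generation time in years

    The per-generation, per-sequence rate is mu_g = rate*1e-8 * L * gen_time;
    using a per-generation rate keeps Ne on the same scale as coalescent
    simulation time (generations).
    """
    if rate <= 0 or L <= 0 or gen_time <= 0:
        raise ValueError("rate, L and gen_time must be positive")
    if theta_w < 0:
        raise ValueError("theta must be >= 0")
    mu_g = rate * 1e-8 * L * gen_time
    return theta_w / (2.0 * mu_g)


def diversity_table(t: HaplotypeTable, d: pd.DataFrame | None = None,
                    by: str = "population",
                    rate: float | None = None, gen_time: float = 4.0,
                    ) -> pd.DataFrame:
    """Per-scope diversity summary (one row per population or lineage).

    Scopes with a single individual get NaN diversity entries, mirroring the
    usual convention of reporting a dash for singleton localities.
    """
    from .seqdata import segregating_sites

    scopes: dict[str, list[str]]
    if by == "population":
        scopes = {p: [p] for p in t.populations}
    elif by == "lineage":
        if t.meta is None or "lineage" not in t.meta.columns:
            raise ValueError("lineage scoping requires population metadata")
        scopes = {}
        for p in t.populations:
            scopes.setdefault(str(t.meta.loc[p, "lineage"]), []).append(p)
    elif by == "total":
        scopes = {"Total": list(t.populations)}
    else:
        raise ValueError(f"unknown scope {by!r}")

    rows = []
    have_seqs = all(t.haplotypes[h].size for h in t.haplotype_ids)
    for name, pops in scopes.items():
        cnt = t.haplotype_counts(pops)
        cnt = cnt[cnt > 0]
        n = int(cnt.sum())
        row: dict[str, object] = {by: name, "n": n, "K": int((cnt > 0).sum())}
        if n >= 2:
            row["h"], row["se_h"] = haplotype_diversity(cnt)
            if d is not None:
                row["pi"], row["se_pi"] = nucleotide_diversity(t, d, pops)
            if have_seqs:
                present = [h for h in t.haplotype_ids
                           if t.counts.loc[h, pops].sum() > 0]
                S = segregating_sites([t.haplotypes[h] for h in present])
                row["S_seg"] = S
                row["theta_w"] = watterson_theta(S, n)
                if rate is not None:
                    row["Ne"] = effective_size(row["theta_w"], rate, t.L, gen_time)
        rows.append(row)
    return pd.DataFrame(rows).set_index(by)
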