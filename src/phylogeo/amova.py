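"""Analysis of molecular variance (AMOVA) and SAMOVA group search.

AMOVA partitions molecular variance hierarchically from squared pairwise
distances between individuals (here: haplotype site differences, the
convention for mtDNA data).  For groups of populations of individuals the
three-level decomposition yields variance components sigma2_a (among
groups), sigma2_b (among populations within groups) and sigma2_c (within
populations), and the fixation indices

    Phi_CT = sigma2_a / sigma2_T
    Phi_SC = sigma2_b / (sigma2_b + sigma2_c)
    Phi_ST = (sigma2_a + sigma2_b) / sigma2_T.

Significance comes from permutation: populations among groups for Phi_CT,
individuals among populations within groups for Phi_SC, and individuals
among populations for Phi_ST.  Negative components are reported as
computed (method-of-moments estimates can legitimately go negative).

SAMOVA searches for the grouping of populations into K groups that
maximises Phi_CT by simulated annealing over single-population moves, with
an optional geographic-contiguity constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqdata import HaplotypeTable, expand_individual_distances


@dataclass
class AmovaResult:
    sigma2_a: float
    sigma2_b: float
    sigma2_c: float
    pct_a: float
    pct_b: float
    pct_c: float
    phi_st: float
    phi_sc: float
    phi_ct: float
    p_phi_st: float | None = None
    p_phi_sc: float | None = None
    p_phi_ct: float | None = None
    df: tuple[int, int, int] = (0, 0, 0)
    n_permutations: int = 0
    seed: int | None = None

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_a + self.sigma2_b + self.sigma2_c


@dataclass
class SamovaResult:
    partition: dict[str, int]
    phi_ct: float
    K: int
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None

    def groups(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for p, g in self.partition.items():
            out.setdefault(g, []).append(p)
        return [sorted(v) for _, v in sorted(out.items())]


def _ss_within(dist: np.ndarray, members: np.ndarray) -> float:
    """SS within one unit: (1/2n) * sum of squared distances over its members."""
    sub = dist[np.ix_(members, members)]
    return float(sub.sum() / (2.0 * members.size))


def _components(dist: np.ndarray, pop_idx: np.ndarray, grp_of_pop: np.ndarray
                ) -> tuple[float, float, float, tuple[int, int, int]]:
    """Three-level AMOVA variance components from an individual distance matrix.

    ``dist`` holds squared distances (pairwise differences used directly).
    """
    N = pop_idx.size
    pops = np.unique(pop_idx)
    P = pops.size
    grp_idx = grp_of_pop[pop_idx]
    grps = np.unique(grp_idx)
    G = grps.size

    all_idx = np.arange(N)
    ss_total = _ss_within(dist, all_idx)
    ss_wp = sum(_ss_within(dist, all_idx[pop_idx == p]) for p in pops)
    ss_wg = sum(_ss_within(dist, all_idx[grp_idx == g]) for g in grps)
    ss_ap = ss_wg - ss_wp          # among populations within groups
    ss_ag = ss_total - ss_wg       # among groups

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    sigma2_c = ss_wp / df_wp if df_wp > 0 else 0.0

    n_p = np.array([(pop_idx == p).sum() for p in pops], dtype=float)
    g_of = grp_of_pop[pops]
    n_g = np.array([n_p[g_of == g].sum() for g in grps])
    sum_np2_over_ng = sum((n_p[g_of == g] ** 2).sum() / n_g[gi]
                          for gi, g in enumerate(grps))
    if df_ap > 0:
        n_prime = (N - sum_np2_over_ng) / df_ap
        sigma2_b = (ss_ap / df_ap - sigma2_c) / n_prime
    else:
        sigma2_b = 0.0
    if df_ag > 0:
        n_dprime = (sum_np2_over_ng - (n_p ** 2).sum() / N) / df_ag
        n_tprime = (N - (n_g ** 2).sum() / N) / df_ag
        ms_ag = ss_ag / df_ag
        sigma2_a = (ms_ag - sigma2_c - n_dprime * sigma2_b) / n_tprime
    else:
        sigma2_a = 0.0
    return sigma2_a, sigma2_b, sigma2_c, (df_ag, df_ap, df_wp)


def _phis(sa: float, sb: float, sc: float) -> tuple[float, float, float]:
    tot = sa + sb + sc
    phi_st = (sa + sb) / tot if tot else 0.0
    phi_sc = sb / (sb + sc) if (sb + sc) else 0.0
    phi_ct = sa / tot if tot else 0.0
    return phi_st, phi_sc, phi_ct


def amova(t: HaplotypeTable, d: pd.DataFrame, grouping: dict[str, str | int],
          n_perm: int = 1000, seed: int | None = None) -> AmovaResult:
    """Hierarchical AMOVA with permutation tests.

    ``grouping`` maps every population to a group label.  With a single
    group the design collapses to two levels (populations within the total)
    and only Phi_ST is meaningful.
    """
    import warnings

    pops = t.populations
    missing = [p for p in pops if p not in grouping]
    if missing:
        raise ValueError(f"populations without group assignment: {missing}")
    dist, pop_idx = expand_individual_distances(t, d)
    labels = sorted({grouping[p] for p in pops}, key=str)
    grp_of_pop = np.array([labels.index(grouping[p]) for p in pops])

    counts = np.bincount(grp_of_pop)
    if len(labels) > 1 and np.any(counts == 1):
        warnings.warn("a group contains a single population; "
                      "Phi_CT is unstable", stacklevel=2)

    sa, sb, sc, dfs = _components(dist, pop_idx, grp_of_pop)
    phi_st, phi_sc, phi_ct = _phis(sa, sb, sc)
    tot = sa + sb + sc

    rng = np.random.default_rng(seed)
    p_st = p_sc = p_ct = None
    if n_perm:
        P = len(pops)
        N = pop_idx.size
        # Phi_ST: permute individuals among populations (all together)
        ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(pop_idx)
            a, b, c = _components(dist, perm, grp_of_pop)[:3]
            if _phis(a, b, c)[0] >= phi_st:
                ge += 1
        p_st = (ge + 1) / (n_perm + 1)
        if len(labels) > 1:
            # Phi_CT: permute whole populations among groups
            ge = 0
            for _ in range(n_perm):
                a, b, c = _components(dist, pop_idx,
                                      rng.permutation(grp_of_pop))[:3]
                if _phis(a, b, c)[2] >= phi_ct:
                    ge += 1
            p_ct = (ge + 1) / (n_perm + 1)
            # Phi_SC: permute individuals among populations within groups
            ge = 0
            grp_of_ind = grp_of_pop[pop_idx]
            for _ in range(n_perm):
                perm = pop_idx.copy()
                for g in range(len(labels)):
                    sel = np.nonzero(grp_of_ind == g)[0]
                    perm[sel] = perm[rng.permutation(sel)]
                a, b, c = _components(dist, perm, grp_of_pop)[:3]
                if _phis(a, b, c)[1] >= phi_sc:
                    ge += 1
            p_sc = (ge + 1) / (n_perm + 1)

    return AmovaResult(
        sigma2_a=sa, sigma2_b=sb, sigma2_c=sc,
        pct_a=100.0 * sa / tot if tot else 0.0,
        pct_b=100.0 * sb / tot if tot else 0.0,
        pct_c=100.0 * sc / tot if tot else 0.0,
        phi_st=phi_st, phi_sc=phi_sc, phi_ct=phi_ct,
        p_phi_st=p_st, p_phi_sc=p_sc, p_phi_ct=p_ct,
        df=dfs, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# SAMOVA


def _phi_ct_of(dist: np.ndarray, pop_idx: np.ndarray, assign: np.ndarray) -> float:
    sa, sb, sc, _ = _components(dist, pop_idx, assign)
    return _phis(sa, sb, sc)[2]


def _delaunay_neighbours(coords: np.ndarray) -> list[set[int]]:
    from scipy.spatial import Delaunay

    tri = Delaunay(coords)
    nb: list[set[int]] = [set() for _ in range(coords.shape[0])]
    for simplex in tri.simplices:
        for i in simplex:
            for j in simplex:
                if i != j:
                    nb[i].add(int(j))
    return nb


def samova(t: HaplotypeTable, d: pd.DataFrame, K: int,
           coords: pd.DataFrame | None = None, contiguity: bool = False,
           n_starts: int = 10, steps: int = 10_000, t0: float = 1.0,
           cooling: float = 0.995, seed: int | None = None,
           candidate_partitions: list[dict[str, int]] | None = None
           ) -> SamovaResult:
    """Search for the K-group partition of populations maximising Phi_CT.

    Simulated annealing over single-population moves between groups; moves
    that would empty a group are rejected.  With ``contiguity`` a move is
    allowed only if the population has a Delaunay neighbour (on ``coords``
    rows ``lat``/``lon``) already in the target group.
    """
    pops = t.populations
    P = len(pops)
    if not 2 <= K < P:
        raise ValueError("K must satisfy 2 <= K < number of populations")
    if contiguity and coords is None:
        raise ValueError("contiguity constraint requires coordinates")
    dist, pop_idx = expand_individual_distances(t, d)
    rng = np.random.default_rng(seed)

    nb = None
    if contiguity:
        xy = coords.loc[pops, ["lat", "lon"]].to_numpy()
        nb = _delaunay_neighbours(xy)

    def allowed(assign: np.ndarray, p: int, g_new: int) -> bool:
        if nb is None:
            return True
        return any(assign[q] == g_new for q in nb[p])

    best_assign = None
    best_phi = -math.inf
    trace = []
    for cand in candidate_partitions or []:
        assign = np.array([int(cand[p]) for p in pops])
        phi = _phi_ct_of(dist, pop_idx, assign)
        if phi > best_phi:
            best_phi, best_assign = phi, assign.copy()
    for _ in range(n_starts):
        # random initial partition with all K groups non-empty
        assign = rng.integers(0, K, size=P)
        assign[rng.permutation(P)[:K]] = np.arange(K)
        phi = _phi_ct_of(dist, pop_idx, assign)
        temp = t0
        for _ in range(steps):
            p = int(rng.integers(P))
            g_old = assign[p]
            if (assign == g_old).sum() == 1:
                temp *= cooling
                continue
            g_new = int(rng.integers(K))
            if g_new == g_old or not allowed(assign, p, g_new):
                temp *= cooling
                continue
            assign[p] = g_new
            phi_new = _phi_ct_of(dist, pop_idx, assign)
            dphi = phi_new - phi
            if dphi >= 0 or rng.random() < math.exp(dphi / max(temp, 1e-12)):
                phi = phi_new
            else:
                assign[p] = g_old
            if phi > best_phi:
                best_phi = phi
                best_assign = assign.copy()
            temp *= cooling
        trace.append(phi)
    partition = {p: int(best_assign[i]) for i, p in enumerate(pops)}
    return SamovaResult(partition=partition, phi_ct=float(best_phi), K=K,
                        trace=np.asarray(trace), seed=seed)
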