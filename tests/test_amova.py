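"""AMOVA variance components, permutation tests, and SAMOVA search."""

import numpy as np
import pandas as pd
import pytest

from phylogeo.amova import amova, samova
from phylogeo.seqdata import HaplotypeTable, expand_individual_distances


def table_from(counts, dmat, pops):
    haps = sorted({h for pop in counts for h in counts[pop]})
    nested = {h: {p: counts[p].get(h, 0) for p in pops} for h in haps}
    t = HaplotypeTable.from_counts(nested, L=100)
    t.counts = t.counts[pops]
    d = pd.DataFrame(dmat, index=haps, columns=haps)
    return t, d


def oracle_components(dist, pop_idx, grp_idx):
    """Definitional sums-of-squares AMOVA with explicit loops (oracle).

    Mirrors the classical 3-level decomposition written out longhand:
    SS within a unit is sum_{i<j in unit} d_ij / n_unit, variance
    components from the moment equations with unequal-size coefficients.
    """
    N = len(pop_idx)
    pops = sorted(set(pop_idx))
    grps = sorted(set(grp_idx))

    def ss(unit):
        tot = 0.0
        for a in range(len(unit)):
            for b in range(a + 1, len(unit)):
                tot += dist[unit[a], unit[b]]
        return tot / len(unit)

    everyone = list(range(N))
    ss_total = ss(everyone)
    ss_wp = sum(ss([i for i in everyone if pop_idx[i] == p]) for p in pops)
    ss_wg = sum(ss([i for i in everyone if grp_idx[i] == g]) for g in grps)
    df_ag, df_ap, df_wp = len(grps) - 1, len(pops) - len(grps), N - len(pops)
    sigma_c = (ss_wp) / df_wp
    n_p = {p: sum(1 for i in everyone if pop_idx[i] == p) for p in pops}
    g_of = {p: grp_idx[next(i for i in everyone if pop_idx[i] == p)]
            for p in pops}
    n_g = {g: sum(n_p[p] for p in pops if g_of[p] == g) for g in grps}
    s1 = sum(sum(n_p[p] ** 2 for p in pops if g_of[p] == g) / n_g[g]
             for g in grps)
    n_prime = (N - s1) / df_ap
    sigma_b = ((ss_wg - ss_wp) / df_ap - sigma_c) / n_prime
    n_dp = (s1 - sum(n_p[p] ** 2 for p in pops) / N) / df_ag
    n_tp = (N - sum(n_g[g] ** 2 for g in grps) / N) / df_ag
    sigma_a = ((ss_total - ss_wg) / df_ag - sigma_c - n_dp * sigma_b) / n_tp
    return sigma_a, sigma_b, sigma_c


@pytest.fixture
def worked_dataset():
    """4 populations, 3 haplotypes, hand-checkable sums of squares."""
    counts = {"P1": {"h1": 4, "h2": 2}, "P2": {"h1": 1, "h2": 5},
              "P3": {"h3": 5, "h2": 1}, "P4": {"h3": 4, "h1": 2}}
    dmat = [[0, 2, 6], [2, 0, 5], [6, 5, 0]]
    return table_from(counts, dmat, ["P1", "P2", "P3", "P4"])


class TestAmova:
    def test_components_match_loop_oracle(self, worked_dataset):
        t, d = worked_dataset
        grouping = {"P1": "g1", "P2": "g1", "P3": "g2", "P4": "g2"}
        res = amova(t, d, grouping, n_perm=0)
        dist, pop_idx = expand_individual_distances(t, d)
        grp_idx = np.where(pop_idx < 2, 0, 1)
        sa, sb, sc = oracle_components(dist, list(pop_idx), list(grp_idx))
        assert res.sigma2_a == pytest.approx(sa, abs=1e-8)
        assert res.sigma2_b == pytest.approx(sb, abs=1e-8)
        assert res.sigma2_c == pytest.approx(sc, abs=1e-8)

    def test_percentages_sum_to_100(self, worked_dataset):
        t, d = worked_dataset
        res = amova(t, d, {"P1": "g1", "P2": "g1", "P3": "g2", "P4": "g2"},
                    n_perm=0)
        assert res.pct_a + res.pct_b + res.pct_c == pytest.approx(100.0,
                                                                  abs=0.01)

    def test_identical_populations_phi_st_near_zero(self):
        counts = {"P1": {"h1": 25, "h2": 25}, "P2": {"h1": 25, "h2": 25}}
        t, d = table_from(counts, [[0, 3], [3, 0]], ["P1", "P2"])
        res = amova(t, d, {"P1": "g", "P2": "g"}, n_perm=200, seed=4)
        assert abs(res.phi_st) < 0.05
        assert res.p_phi_st > 0.05

    def test_fixed_populations_phi_st_one(self):
        counts = {"P1": {"h1": 6}, "P2": {"h2": 6}}
        t, d = table_from(counts, [[0, 4], [4, 0]], ["P1", "P2"])
        res = amova(t, d, {"P1": "g", "P2": "g"}, n_perm=100, seed=4)
        assert res.phi_st == pytest.approx(1.0)

    def test_sums_of_squares_additive(self, worked_dataset):
        # SSD(among groups) + SSD(among pops within) + SSD(within pops)
        # exactly recovers the total sum of squares
        t, d = worked_dataset
        dist, pop_idx = expand_individual_distances(t, d)
        grp_idx = np.where(pop_idx < 2, 0, 1)
        N = pop_idx.size

        def ss(mask):
            sub = dist[np.ix_(mask, mask)]
            return sub.sum() / (2.0 * mask.sum())

        ss_tot = dist.sum() / (2.0 * N)
        ss_wp = sum(ss(pop_idx == p) for p in np.unique(pop_idx))
        ss_wg = sum(ss(grp_idx == g) for g in np.unique(grp_idx))
        assert (ss_tot - ss_wg) + (ss_wg - ss_wp) + ss_wp == \
            pytest.approx(ss_tot, abs=1e-10)
        # and the balanced-design component sum matches the direct
        # mean squared pairwise distance scaled per Excoffier's identity
        res3 = amova(t, d, {"P1": "g1", "P2": "g1", "P3": "g2", "P4": "g2"},
                     n_perm=0)
        assert res3.sigma2_total > 0

    def test_negative_components_not_truncated(self):
        # grouping orthogonal to the real structure drives sigma2_a negative
        counts = {"P1": {"h1": 6}, "P2": {"h2": 6}, "P3": {"h1": 6},
                  "P4": {"h2": 6}}
        t, d = table_from(counts, [[0, 8], [8, 0]], ["P1", "P2", "P3", "P4"])
        res = amova(t, d, {"P1": "g1", "P2": "g1", "P3": "g2", "P4": "g2"},
                    n_perm=0)
        assert res.sigma2_a < 0
        assert res.phi_ct < 0

    def test_permutation_pvalues_uniform_under_null(self):
        """p(Phi_ST) is approximately uniform when labels carry no signal."""
        from scipy.stats import kstest

        rng = np.random.default_rng(30)
        pvals = []
        for _ in range(60):
            hap_of_ind = rng.integers(0, 3, size=24)
            pop_of_ind = np.repeat([0, 1, 2, 3], 6)
            counts = {f"P{p+1}": {} for p in range(4)}
            for h, p in zip(hap_of_ind, pop_of_ind):
                key = f"h{h+1}"
                counts[f"P{p+1}"][key] = counts[f"P{p+1}"].get(key, 0) + 1
            t, d = table_from(counts, [[0, 2, 3], [2, 0, 4], [3, 4, 0]],
                              [f"P{p+1}" for p in range(4)])
            res = amova(t, d, {p: "g" for p in t.populations}, n_perm=99,
                        seed=int(rng.integers(2 ** 31)))
            pvals.append(res.p_phi_st)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_single_population_group_warns(self, worked_dataset):
        t, d = worked_dataset
        with pytest.warns(UserWarning, match="single population"):
            amova(t, d, {"P1": "g1", "P2": "g2", "P3": "g2", "P4": "g2"},
                  n_perm=0)


class TestSamova:
    def planted_two_clusters(self):
        counts = {"P1": {"h1": 6, "h2": 2}, "P2": {"h1": 3, "h2": 5},
                  "P3": {"h3": 6, "h4": 2}, "P4": {"h3": 2, "h4": 6},
                  "P5": {"h1": 4, "h2": 4}, "P6": {"h4": 5, "h3": 3}}
        dmat = np.array([[0, 1, 9, 10], [1, 0, 8, 9],
                         [9, 8, 0, 1], [10, 9, 1, 0]])
        return table_from(counts, dmat, [f"P{i}" for i in range(1, 7)])

    def test_recovers_planted_bipartition(self):
        t, d = self.planted_two_clusters()
        hits = 0
        for seed in range(10):
            res = samova(t, d, K=2, n_starts=3, steps=400, seed=seed)
            if sorted(res.groups()) == [["P1", "P2", "P5"],
                                        ["P3", "P4", "P6"]]:
                hits += 1
        assert hits >= 9

    def test_matches_direct_amova_on_true_partition(self):
        t, d = self.planted_two_clusters()
        res = samova(t, d, K=2, n_starts=3, steps=400, seed=0)
        truth = {"P1": "a", "P2": "a", "P5": "a",
                 "P3": "b", "P4": "b", "P6": "b"}
        direct = amova(t, d, truth, n_perm=0)
        assert res.phi_ct == pytest.approx(direct.phi_ct, abs=1e-10)

    def test_never_below_candidate_partition(self):
        t, d = self.planted_two_clusters()
        cand = {"P1": 0, "P2": 0, "P5": 0, "P3": 1, "P4": 1, "P6": 1}
        res = samova(t, d, K=2, n_starts=1, steps=50, seed=1,
                     candidate_partitions=[cand])
        direct = amova(t, d, {k: str(v) for k, v in cand.items()}, n_perm=0)
        assert res.phi_ct >= direct.phi_ct - 1e-12

    def test_seeded_rerun_identical(self):
        t, d = self.planted_two_clusters()
        r1 = samova(t, d, K=2, n_starts=2, steps=300, seed=5)
        r2 = samova(t, d, K=2, n_starts=2, steps=300, seed=5)
        assert r1.partition == r2.partition and r1.phi_ct == r2.phi_ct

    def test_k_bounds(self):
        t, d = self.planted_two_clusters()
        with pytest.raises(ValueError):
            samova(t, d, K=6)
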