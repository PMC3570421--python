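# Methods

This note records the models implemented, the defaults chosen where the
design was genuinely open, and what the synthetic-data experiments do and
do not demonstrate.

## Data model

Sequences are rectangular nucleotide alignments over {A,C,G,T,-,N};
IUPAC ambiguity codes other than N are demoted to N with a warning.
Identical sequences are collapsed to haplotypes labelled H1..HK in order of
first appearance. Pairwise haplotype distances count sites where both
sequences carry an unambiguous base and differ (pairwise deletion). The
gap/ambiguity convention is a package decision — the protein-coding
fragment of the motivating survey has no indels, the control region may —
and matches Arlequin's default closely enough for the statistics built on
top of it.

## Diversity statistics

Gene diversity uses the unbiased estimator h = n/(n−1)(1 − Σp²) and Nei's
sampling variance

    V(h) = 2/(n(n−1)) · {2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)²}.

These reproduce, to all four printed decimals, every published h ± se pair
in the survey's sampling table (15 populations with n ≥ 2 plus the pooled
total of 146; tested exhaustively). Nucleotide diversity applies the same
n/(n−1) correction (a biased variant is selectable); its standard error
uses Nei's total-variance formula and is approximate. Watterson's θ_W is
S/a_n per sequence.

θ → Ne uses θ = 2Neμ_g with a per-generation, per-sequence rate
μ_g = rate · 10⁻⁸ · L · g, where `rate` is in **percent substitutions per
site per million years** (the survey's clock, 1.086), L the alignment
length and g the generation time (4 years). Per-generation units keep Ne
on the same scale as coalescent time. Expansion dating, by contrast, uses
the **per-year** sequence rate u = rate · 10⁻⁸ · L in t = τ/(2u): this is
the convention that reproduces the published expansion ages (0.129 and
0.119 Mya) from the published τ values, and it is dimensionally the
natural one since τ is estimated from data without reference to g.

## Neutrality tests

Tajima's D follows the standard constants (a₁…e₂). Fu's Fs computes
S′ = Pr(K ≥ k_obs | θ = θ_π) under the Ewens sampling distribution with
unsigned Stirling numbers of the first kind carried in log space (cached
per n; the exact-oracle comparison holds to 10⁻⁸ for n ≤ 30), and returns
ln(S′/(1−S′)), with signed-infinity sentinels when S′ reaches 0 or 1.

Significance is simulated under a constant-size coalescent **conditioned
on the observed S** (mutations multinomially placed on branches by
length), the Arlequin-style convention that removes θ as a nuisance
parameter; a θ-conditioned mode is not provided. p-values are one-tailed
low: small p for negative D/Fs indicates expansion. Fu's recommendation to
judge Fs at p < 0.02 is carried in the result metadata, not applied.
Calibration: at n = 25, S = 12, 200 null replicates per test, the 5%-level
rejection rate over 500 trials sits inside the binomial 95% band.

## Mismatch distributions

The sudden-expansion expectation uses the θ₁ → ∞ simplification

    F_i(τ, θ₀) = e^(−τ) Σ_{j≤i} [θ₀^j/(θ₀+1)^(j+1)] · τ^(i−j)/(i−j)!,

fitted by SSD minimisation over (τ, θ₀): an 8-point log-spaced grid is
scored and the best three starts are polished with bounded Nelder–Mead
(SSD tolerance 10⁻¹⁰). Only the two-parameter model is fitted, since the
dating uses τ alone. Goodness of fit is a parametric bootstrap: coalescent
samples are drawn under the fitted parameters in mutational time (pairwise
coalescence rate 1/θ per unit τ, Poisson(x/2) mutations per branch of
length x; θ₁ = ∞ is approximated by 10⁷), each replicate re-fitted with
identical optimiser settings, and p is the fraction of replicates with
SSD (or raggedness) at least the observed value. Recovery: over 50
simulated expansions (n = 50, τ* = 6.6, θ₀ = 1) the median fitted τ is
within 20% of truth; bootstrap p(SSD) is near-uniform under the model
(KS, 100 trials × 100 replicates).

## Coalescent simulation within population trees

A population tree has divergence times in years BP, a haploid
(mitochondrial) Ne per branch, and a generation time g. Within a branch,
each lineage pair coalesces at rate 1/Ne per generation (so E[T₂] = Ne;
cross-checked against msprime with ploidy 1), with continuous exponential
waiting times; lineages surviving a divergence time move into the parent
branch. The five refugial hypotheses hard-code the published divergence
times (18 ky LGM splits; refugial joins at 830/760/710 ky; within-refugium
divergence at the lineage TMRCAs 250/70/290/530 ky for hypothesis e), with
member populations splitting from a refugium as a star polytomy since the
hypotheses specify no internal topology.

The overall Ne defaults to the empirical estimate from pooled θ_W
(S = 144, n = 146 → Ne ≈ 125,700). "Proportional" apportionment gives each
refugial and population branch Ne scaled by its share of sampled
individuals (an "equal" rule divides evenly); branches ancestral to the
refugia keep the overall Ne. These sampling-design defaults are the
conditions under which all simulation-based checks run.

## S statistic, refugia test, RLR

S is the parsimony length of the population/locality character on the
rooted genealogy, computed with Hartigan's bottom-up pass (equal to Fitch
on binary trees, exact on polytomies; verified against exhaustive
assignment enumeration on 500 random trees). A hypothesis is rejected when
the observed S falls outside the equal-tailed empirical 2.5–97.5%
interval of S over simulated genealogies (1000 by default; the discrete
distribution makes the interval slightly conservative).

RLR takes each genealogy's set of most-parsimonious root states (the
Hartigan root set), scores 1 for a unique state or 1/n for n tied states,
and normalises by the number of genealogies, so scores sum to 1. For
clade-level reconstruction the trees are pruned to the clade's tips first.
In recovery experiments a planted source population (deep, large, with
recently founded satellites) attains the top score in ≥ 95% of runs of
500 genealogies.

## AMOVA and SAMOVA

AMOVA uses pairwise differences directly as squared distances (the mtDNA
convention). Sums of squares follow the classical partition
(SS within a unit = Σ pairwise d / unit size); variance components come
from the three-level moment equations with unequal-sample-size
coefficients; negative components are reported as computed, because
method-of-moments estimates legitimately go negative and published tables
print them. Permutation schemes: individuals among populations (Φ_ST),
individuals among populations within groups (Φ_SC), whole populations
among groups (Φ_CT); p = (g+1)/(m+1).

SAMOVA maximises Φ_CT by simulated annealing over single-population moves
(moves emptying a group rejected), geometric cooling 0.995, default 10
starts × 10,000 steps — enough to recover planted bipartitions in ≥ 95% of
seeded runs on test fixtures; all schedule parameters are exposed. A
Delaunay-neighbour contiguity constraint is available but off by default,
since groupings of interest need not be geographically contiguous.

## Synthetic data generator

The study fixture simulates one hypothesis-e genealogy with the published
per-population sample sizes (Σn = 146), rejecting and resampling (≤ 1000
tries) until the four lineages are reciprocally monophyletic — mirroring
the deeply divergent clades of the empirical data — then evolves 2373
sites of HKY sequence (κ = 4, base frequencies 0.30/0.25/0.15/0.30; rate
heterogeneity omitted) from a stationary root. Realised haplotype numbers
land near the empirical 58 (e.g. 57–70 across seeds) but are not matched
exactly, and realised segregating sites run higher than the empirical 144;
only the sampling structure, lineage structure and scale are emulated.
What passing tests show is therefore that the *methods* behave correctly
under the survey's design — not that the generator replicates the survey's
sequences, its site-rate heterogeneity, or any geographic signal beyond
lineage membership (coordinates in fixture metadata are synthetic
placeholders).

Expansion datasets place the coalescent in mutational time (expansion at
x = τ*, growth factor 1000 by default) and scatter mutations over distinct
sites (infinite-sites over L), so that mismatch and neutrality statistics
can be calibrated against known truth.

## Numerical choices and limitations

- Problem sizes in the test suite (200-replicate S distributions,
  500-trial calibrations, 100-trial bootstrap-uniformity checks) were
  chosen to give stable Monte-Carlo verdicts at interactive runtimes;
  all simulations accept seeds and reproduce exactly.
- Under hypothesis e with the empirical Ne, the simulated S distribution
  concentrates just above its topological floor (typically {18, 19}),
  narrower than published simulation figures whose generator settings are
  not fully specified; the qualitative contrast against LGM-era
  hypotheses is unaffected and is what the tests assert.
- The Ewens/Stirling recurrence is O(n²) per sample size and cached;
  fine for single-locus sample sizes (n ≤ a few hundred).
- Sequence-dependent published values (Φ tables, D/Fs/τ magnitudes, the
  empirical S = 25, MRCA percentages) require the deposited haplotype
  sequences and are validated structurally, not numerically.
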