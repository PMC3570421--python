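"""Coalescent simulation of gene trees within population-divergence models.

A :class:`PopulationTreeModel` is a rooted tree of populations: leaves are
sampled populations (present-day), internal nodes are divergence events at
known times (years BP), and every branch carries a (haploid, mitochondrial)
effective size Ne.  Gene lineages coalesce within branches at the standard
n-coalescent rate — each pair merges at rate 1/Ne per generation, so for a
sample of two E[T2] = Ne generations — and lineages surviving at a split
time move into the parent branch.

Five competing glacial-refugia hypotheses are provided as builders:

=====  =====================================================================
label  scenario
=====  =====================================================================
a      single refugium; all populations diverge at the end of the LGM
       (18 kya)
b      two refugia (southern lineage vs the rest) isolated 830 kya;
       populations diverge 18 kya
c      three refugia (830 and 760 kya splits); populations diverge 18 kya
d      four refugia (830/760/710 kya splits); populations diverge 18 kya
e      four refugia isolated before the LGM, with within-refugium
       population divergence at each lineage's TMRCA (250/70/290/530 kya)
=====  =====================================================================

Within a refugium the member populations split simultaneously (a star
polytomy): the hypotheses specify no internal topology below the refugial
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DEFAULT_GENERATION_TIME = 4.0  # years, a newt generation

#: lineage membership of the 19 sampled populations
LINEAGES: dict[str, list[str]] = {
    "A": ["JP", "LC", "ZB"],
    "B": ["PL", "SHZ"],
    "C": ["GF", "PM", "GY"],
    "D": ["WBL", "SB", "JD", "NJ", "DY", "YD", "CJ", "SJ", "LL", "MC", "HS"],
}

#: published per-population sample sizes (146 individuals total)
DEFAULT_SAMPLE_SIZES: dict[str, int] = {
    "JP": 10, "LC": 12, "ZB": 1, "PL": 10, "SHZ": 10, "GF": 8, "PM": 14,
    "GY": 1, "WBL": 4, "SB": 13, "JD": 10, "NJ": 1, "DY": 14, "YD": 13,
    "CJ": 5, "SJ": 4, "LL": 13, "MC": 2, "HS": 1,
}


def years_to_generations(t_years: float, g: float = DEFAULT_GENERATION_TIME) -> float:
    """Convert absolute time (years BP) to coalescent time (generations)."""
    if t_years < 0:
        raise ValueError("time must be >= 0")
    if g <= 0:
        raise ValueError("generation time must be positive")
    return t_years / g


@dataclass
class PopNode:
    """One branch of the population tree.

    ``time_years`` is the age of the node's origin: for a leaf, when the
    population came into existence (diverged from its siblings); for an
    internal node, when its children merged into it.  The root branch
    extends indefinitely into the past.
    """

    name: str
    time_years: float
    ne: float = 0.0
    children: list["PopNode"] = field(default_factory=list)
    n_samples: int = 0
    refugium: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def total_samples(self) -> int:
        if self.is_leaf:
            return self.n_samples
        return sum(c.total_samples() for c in self.children)


@dataclass
class PopulationTreeModel:
    root: PopNode
    generation_time: float = DEFAULT_GENERATION_TIME
    label: str = "custom"

    def validate(self) -> None:
        for node in self.root.walk():
            if node.ne <= 0:
                raise ValueError(f"branch {node.name} has non-positive Ne")
            for c in node.children:
                if not c.time_years < node.time_years:
                    raise ValueError(
                        f"child {c.name} split time must precede parent {node.name}")
        leaves = [n.name for n in self.root.walk() if n.is_leaf]
        if len(set(leaves)) != len(leaves):
            raise ValueError("population names must be unique")

    def leaves(self) -> list[PopNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def describe(self) -> str:
        lines = [f"model {self.label} (generation time {self.generation_time} y)"]
        for node in self.root.walk():
            kind = "leaf" if node.is_leaf else "node"
            lines.append(f"  {kind} {node.name}: origin {node.time_years:.0f} y BP, "
                         f"Ne {node.ne:.0f}" +
                         (f", n={node.n_samples}" if node.is_leaf else ""))
        return "\n".join(lines)


def _star(names: list[str], split_years: float, sample_sizes: dict[str, int]
          ) -> list[PopNode]:
    return [PopNode(name=p, time_years=split_years,
                    n_samples=sample_sizes.get(p, 0)) for p in names]


def build_refugia_model(hypothesis: str, overall_ne: float,
                        sample_sizes: dict[str, int] | None = None,
                        apportion: str = "samples",
                        generation_time: float = DEFAULT_GENERATION_TIME,
                        ) -> PopulationTreeModel:
    """Population-divergence model for one of the refugial hypotheses a-e.

    ``overall_ne`` is the empirical (total) effective size; refugial-branch
    Ne values sum to it.  ``apportion`` sets how it is shared out:
    ``"samples"`` (default) in proportion to the sampled individuals
    descending from each branch, or ``"equal"`` equally among the refugia
    (and equally among populations within a refugium).  Branches ancestral
    to the refugia keep the overall Ne.
    """
    if overall_ne <= 0:
        raise ValueError("overall Ne must be positive")
    ss = dict(DEFAULT_SAMPLE_SIZES if sample_sizes is None else sample_sizes)
    pops_of = {k: [p for p in v if ss.get(p, 0) >= 1] for k, v in LINEAGES.items()}
    all_pops = [p for pops in pops_of.values() for p in pops]
    LGM = 18_000.0

    if hypothesis == "a":
        root = PopNode("refugium", time_years=math.inf, refugium=True,
                       children=_star(all_pops, LGM, ss))
    elif hypothesis == "b":
        rest = pops_of["B"] + pops_of["C"] + pops_of["D"]
        ra = PopNode("refugium-A", 830_000.0, refugium=True,
                     children=_star(pops_of["A"], LGM, ss))
        rb = PopNode("refugium-BCD", 830_000.0, refugium=True,
                     children=_star(rest, LGM, ss))
        root = PopNode("ancestor", math.inf, children=[ra, rb])
    elif hypothesis == "c":
        ra = PopNode("refugium-A", 830_000.0, refugium=True,
                     children=_star(pops_of["A"], LGM, ss))
        rd = PopNode("refugium-D", 760_000.0, refugium=True,
                     children=_star(pops_of["D"], LGM, ss))
        rbc = PopNode("refugium-BC", 760_000.0, refugium=True,
                      children=_star(pops_of["B"] + pops_of["C"], LGM, ss))
        anc_bcd = PopNode("ancestor-BCD", 830_000.0, children=[rd, rbc])
        root = PopNode("ancestor", math.inf, children=[ra, anc_bcd])
    elif hypothesis in ("d", "e"):
        if hypothesis == "d":
            split = {"A": LGM, "B": LGM, "C": LGM, "D": LGM}
        else:
            # within-refugium divergence at each lineage's TMRCA
            split = {"A": 250_000.0, "B": 70_000.0, "C": 290_000.0,
                     "D": 530_000.0}
        ra = PopNode("refugium-A", 830_000.0, refugium=True,
                     children=_star(pops_of["A"], split["A"], ss))
        rb = PopNode("refugium-B", 710_000.0, refugium=True,
                     children=_star(pops_of["B"], split["B"], ss))
        rc = PopNode("refugium-C", 710_000.0, refugium=True,
                     children=_star(pops_of["C"], split["C"], ss))
        rd = PopNode("refugium-D", 760_000.0, refugium=True,
                     children=_star(pops_of["D"], split["D"], ss))
        anc_bc = PopNode("ancestor-BC", 760_000.0, children=[rb, rc])
        anc_bcd = PopNode("ancestor-BCD", 830_000.0, children=[rd, anc_bc])
        root = PopNode("ancestor", math.inf, children=[ra, anc_bcd])
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}; expected a-e")

    _apportion_ne(root, overall_ne, apportion)
    model = PopulationTreeModel(root=root, generation_time=generation_time,
                                label=hypothesis)
    model.validate()
    return model


def _apportion_ne(root: PopNode, overall_ne: float, rule: str) -> None:
    if rule not in ("samples", "equal"):
        raise ValueError(f"unknown apportion rule {rule!r}")
    total_n = root.total_samples()
    if total_n == 0:
        raise ValueError("model has no sampled individuals")
    refugia = [n for n in root.walk() if n.refugium]
    inside = {id(x) for r in refugia for x in r.walk()}
    # branches ancestral to the refugial level keep the overall size
    for node in root.walk():
        if id(node) not in inside:
            node.ne = overall_ne
    for r in refugia:
        if rule == "samples":
            for node in r.walk():
                node.ne = overall_ne * node.total_samples() / total_n
        else:
            r.ne = overall_ne / len(refugia)
            members = [x for x in r.walk() if x is not r]
            leaves = [x for x in members if x.is_leaf]
            for x in members:
                x.ne = r.ne / max(len(leaves), 1)


# ---------------------------------------------------------------------------
# Gene trees


@dataclass
class GeneNode:
    """Node of a simulated genealogy; times in generations before present."""

    time: float
    children: list["GeneNode"] = field(default_factory=list)
    individual: str | None = None
    population: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self) -> list["GeneNode"]:
        return [n for n in self.walk() if n.is_leaf]


@dataclass
class GeneTree:
    root: GeneNode
    generation_time: float = DEFAULT_GENERATION_TIME

    def leaves(self) -> list[GeneNode]:
        return self.root.leaves()

    @property
    def tmrca(self) -> float:
        return self.root.time

    def to_newick(self) -> str:
        def fmt(node: GeneNode, parent_time: float) -> str:
            bl = parent_time - node.time
            if node.is_leaf:
                return f"{node.individual}|{node.population}:{bl:.6g}"
            inner = ",".join(fmt(c, node.time) for c in node.children)
            return f"({inner}):{bl:.6g}"
        inner = ",".join(fmt(c, self.root.time) for c in self.root.children)
        return f"({inner});"

    def tip_labels(self) -> dict[str, str]:
        """individual -> population for every tip."""
        return {n.individual: n.population for n in self.leaves()}


def _coalesce_within(lineages: list[GeneNode], ne: float, t_start: float,
                     t_end: float, rng: np.random.Generator) -> list[GeneNode]:
    """Merge lineages at pairwise rate 1/Ne per generation until t_end."""
    t = t_start
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / ne
        t_next = t + rng.exponential(1.0 / rate)
        if t_next >= t_end:
            return lineages
        t = t_next
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        merged = GeneNode(time=t, children=[a, b])
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    return lineages


def simulate_gene_tree(model: PopulationTreeModel, seed=None) -> GeneTree:
    """Simulate one gene genealogy constrained within the population tree.

    Branch lengths are continuous times in generations; sampling is
    contemporaneous, so the tree is ultrametric from the tips.
    """
    if model.root.total_samples() < 2:
        raise ValueError("need at least 2 sampled individuals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = model.generation_time

    def recurse(node: PopNode) -> list[GeneNode]:
        t_origin = years_to_generations(node.time_years, g) \
            if math.isfinite(node.time_years) else math.inf
        if node.is_leaf:
            lineages = [GeneNode(time=0.0, individual=f"{node.name}_{i + 1}",
                                 population=node.name)
                        for i in range(node.n_samples)]
            t_start = 0.0
        else:
            lineages = []
            for c in node.children:
                lineages.extend(recurse(c))
            t_start = years_to_generations(
                max(c.time_years for c in node.children), g)
        return _coalesce_within(lineages, node.ne, t_start, t_origin, rng)

    out = recurse(model.root)
    if len(out) != 1:
        raise RuntimeError("root branch failed to fully coalesce")  # unreachable
    return GeneTree(root=out[0], generation_time=g)


@dataclass
class SDistribution:
    """Simulated null distribution of the minimum-sorting-events statistic."""

    samples: np.ndarray
    lo95: float
    hi95: float
    nreps: int
    seed: int | None = None
    label: str = ""


def simulate_s_distribution(model: PopulationTreeModel,
                            grouping: dict[str, str] | None = None,
                            nreps: int = 1000, seed: int | None = None
                            ) -> SDistribution:
    """Distribution of S over simulated genealogies, with its central 95% interval.

    ``grouping`` maps population name to character state; by default each
    population is its own state (the locality character).  The interval is
    the equal-tailed 2.5-97.5 empirical percentile range.
    """
    from .treestats import s_statistic

    if nreps < 100:
        raise ValueError("use at least 100 replicates")
    rng = np.random.default_rng(seed)
    vals = np.empty(nreps, dtype=int)
    for r in range(nreps):
        tree = simulate_gene_tree(model, rng)
        if grouping is None:
            labels = {n.individual: n.population for n in tree.leaves()}
        else:
            labels = {n.individual: grouping[n.population]
                      for n in tree.leaves()}
        vals[r] = s_statistic(tree, labels)
    lo, hi = np.percentile(vals, [2.5, 97.5], method="midpoint")
    return SDistribution(samples=np.sort(vals), lo95=float(lo), hi95=float(hi),
                         nreps=nreps, seed=seed, label=model.label)
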