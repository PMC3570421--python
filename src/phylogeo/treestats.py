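"""Parsimony statistics on genealogies: sorting events and root-locality scores.

The minimum number of sorting events S is the parsimony length of an
unordered multistate character (population or locality membership) on a
rooted genealogy: the smallest number of state changes needed to explain
how the character is distributed across the tips.  Deep incomplete lineage
sorting inflates S; reciprocally monophyletic groups attain the floor
S = k - 1 for k states.

Refugia-localization reconstruction (RLR) averages the most-parsimonious
root states of the locality character over a sample of genealogies: each
genealogy votes 1 for a unique most-parsimonious root locality, or 1/n for
each of n tied localities, and the totals are normalised into a relative
probability that each sampling site harboured the clade's MRCA.

Both computations use Hartigan's bottom-up pass, which equals Fitch's
method on binary trees and extends it correctly to polytomies; the set of
states attaining the maximum child vote at the root is exactly the set of
most-parsimonious root assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalsim import GeneTree, GeneNode, SDistribution


class UnlabelledTipError(KeyError):
    """A tip of the genealogy has no character state assigned."""


def _resolve_tree(tree) -> GeneNode:
    if isinstance(tree, GeneTree):
        return tree.root
    if isinstance(tree, GeneNode):
        return tree
    return read_newick(tree).root


def _hartigan(root: GeneNode, state_of: dict[str, object]
              ) -> tuple[int, frozenset]:
    """Parsimony length and most-parsimonious root-state set (iterative)."""
    length = 0
    sets: dict[int, frozenset] = {}
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if node.is_leaf:
            try:
                sets[id(node)] = frozenset([state_of[node.individual]])
            except KeyError as exc:
                raise UnlabelledTipError(
                    f"tip {node.individual!r} has no state assigned") from exc
            continue
        if not done:
            stack.append((node, True))
            stack.extend((c, False) for c in node.children)
            continue
        votes: dict[object, int] = {}
        for c in node.children:
            for s in sets[id(c)]:
                votes[s] = votes.get(s, 0) + 1
        m = max(votes.values())
        sets[id(node)] = frozenset(s for s, v in votes.items() if v == m)
        length += len(node.children) - m
    return length, sets[id(root)]


def s_statistic(tree, labels: dict[str, str]) -> int:
    """Minimum sorting events: parsimony length of the state character.

    ``tree`` is a :class:`GeneTree`, a :class:`GeneNode`, a newick string or
    a path to a newick file; ``labels`` maps tip (individual) name to state.
    """
    root = _resolve_tree(tree)
    states = {labels[lf.individual] for lf in root.leaves()
              if lf.individual in labels}
    missing = [lf.individual for lf in root.leaves() if lf.individual not in labels]
    if missing:
        raise UnlabelledTipError(f"unlabelled tips: {missing[:5]}")
    if len(states) < 2:
        return 0
    length, _ = _hartigan(root, labels)
    return length


def mp_root_states(tree, labels: dict[str, str]) -> frozenset:
    """Set of most-parsimonious root states for the labelled character."""
    root = _resolve_tree(tree)
    _, root_set = _hartigan(root, labels)
    return root_set


@dataclass
class RefugiaTestResult:
    S_obs: int
    lo95: float
    hi95: float
    reject: bool
    tail_prop: float
    model_label: str = ""


def refugia_test(S_obs: int, dist: SDistribution) -> RefugiaTestResult:
    """Reject the divergence model if S_obs falls outside the 95% interval.

    ``tail_prop`` is the smaller of the two empirical tail proportions
    (fraction of simulated S <= or >= the observed value).
    """
    if dist.samples.size == 0:
        raise ValueError("empty S distribution")
    reject = S_obs < dist.lo95 or S_obs > dist.hi95
    lo_tail = float(np.mean(dist.samples <= S_obs))
    hi_tail = float(np.mean(dist.samples >= S_obs))
    return RefugiaTestResult(S_obs=S_obs, lo95=dist.lo95, hi95=dist.hi95,
                             reject=bool(reject),
                             tail_prop=min(lo_tail, hi_tail),
                             model_label=dist.label)


@dataclass
class RLRResult:
    scores: dict[str, float]
    n_genealogies: int

    def top(self) -> str:
        return max(self.scores, key=self.scores.get)

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.scores.items()}


def rlr_root_probabilities(genealogies, labels: dict[str, str],
                           tips: list[str] | None = None) -> RLRResult:
    """Root-origin probability score per locality over a genealogy sample.

    For each genealogy the most-parsimonious root localities are computed;
    a unique locality receives 1 and each of n tied localities 1/n.  Totals
    are divided by the number of genealogies, so scores sum to 1.  With
    ``tips`` given, every genealogy is pruned to that tip set first
    (clade-level reconstruction).
    """
    scores: dict[str, float] = {}
    n_trees = 0
    tip_set: frozenset | None = None
    for tree in genealogies:
        root = _resolve_tree(tree)
        if tips is not None:
            root = prune_to_tips(root, set(tips))
        observed = frozenset(lf.individual for lf in root.leaves())
        if tip_set is None:
            tip_set = observed
        elif observed != tip_set:
            raise ValueError("genealogies do not share one tip set")
        _, root_states = _hartigan(root, labels)
        w = 1.0 / len(root_states)
        for s in root_states:
            scores[s] = scores.get(s, 0.0) + w
        n_trees += 1
    if n_trees == 0:
        raise ValueError("no genealogies supplied")
    scores = {k: v / n_trees for k, v in sorted(scores.items())}
    return RLRResult(scores=scores, n_genealogies=n_trees)


def prune_to_tips(root: GeneNode, keep: set[str]) -> GeneNode:
    """Restriction of a rooted genealogy to a tip subset.

    Internal nodes left with a single child are suppressed, so the result
    is the induced subtree on the kept tips.
    """
    def rec(node: GeneNode) -> GeneNode | None:
        if node.is_leaf:
            return node if node.individual in keep else None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return GeneNode(time=node.time, children=kids)
    out = rec(root)
    if out is None:
        raise ValueError("no requested tips present in genealogy")
    return out


# ---------------------------------------------------------------------------
# newick I/O for externally supplied genealogies


def read_newick(source) -> GeneTree:
    """Read a rooted genealogy from a newick string or file path.

    Tip labels of the form ``individual|population`` carry the population
    through; plain labels leave the population unset.  Node ages are
    reconstructed from branch lengths assuming contemporaneous tips.
    """
    import dendropy

    text = None
    s = str(source)
    if "(" in s and ");" in s.replace("\n", ""):
        text = s
    if text is not None:
        dt = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True)
    else:
        dt = dendropy.Tree.get(path=s, schema="newick",
                               preserve_underscores=True)

    def rec(dnode) -> GeneNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            ind, _, pop = label.partition("|")
            return GeneNode(time=0.0, individual=ind, population=pop or None)
        return GeneNode(time=0.0, children=[rec(c) for c in dnode.child_nodes()])

    root = rec(dt.seed_node)

    # convert branch lengths to node depths, then depths to ages
    depth: dict[int, float] = {id(root): 0.0}
    pairs = list(zip(root.walk(), dt.seed_node.preorder_iter()))
    for gnode, dnode in pairs:
        for gc, dc in zip(gnode.children, dnode.child_nodes()):
            depth[id(gc)] = depth[id(gnode)] + (dc.edge.length or 0.0)
    max_depth = max(depth[id(lf)] for lf in root.leaves())
    for gnode, _ in pairs:
        gnode.time = max_depth - depth[id(gnode)]
    return GeneTree(root=root)


def read_newick_list(path) -> list[GeneTree]:
    """Read a file containing one newick genealogy per line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(read_newick(line))
    return trees
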