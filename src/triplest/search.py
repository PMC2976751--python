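"""Search for the maximum pseudo-likelihood species tree over topologies.

For small taxon sets (N <= 6 by default) every labelled rooted binary
topology is scored; otherwise a steepest-ascent nearest-neighbour
interchange (NNI) hill climb with restarts is used.  The first restart
starts from a greedy triple-agreement join tree; the remaining restarts
start from uniformly random rooted topologies.  All tie-breaks are by
canonical newick string, so searches are fully reproducible from the
seed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .treecore import RootedTree, TreeError, parse_newick
from .pseudolik import BranchLengthFit, EstimationError, optimize_branch_lengths
from .triples import TripleCountTable

__all__ = [
    "SearchResult",
    "enumerate_rooted_topologies",
    "exhaustive_search",
    "nni_neighbors",
    "hill_climb",
    "estimate_species_tree",
]

MAX_EXHAUSTIVE_N = 7
AUTO_EXHAUSTIVE_N = 6


@dataclass
class SearchResult:
    """Outcome of a topology search."""

    best_fit: BranchLengthFit
    n_evaluated: int
    trajectories: list = field(default_factory=list)
    seed: int | None = None
    method: str = "exhaustive"

    @property
    def best_tree(self) -> RootedTree:
        return self.best_fit.tree

    @property
    def best_log_pl(self) -> float:
        return self.best_fit.log_pl


# ---------------------------------------------------------------------
# enumeration of labelled rooted binary topologies
# ---------------------------------------------------------------------


def _shape_insertions(shape, leaf):
    """All shapes obtained by attaching ``leaf`` on any edge of ``shape``,
    including above the root.  Shapes are labels or 2-tuples of shapes."""
    out = [(shape, leaf)]
    if isinstance(shape, tuple):
        a, b = shape
        out.extend((x, b) for x in _shape_insertions(a, leaf))
        out.extend((a, x) for x in _shape_insertions(b, leaf))
    return out


def _shape_newick(shape) -> str:
    if isinstance(shape, tuple):
        return "(" + ",".join(sorted(_shape_newick(s) for s in shape)) + ")"
    return shape


def _shape_to_tree(shape) -> RootedTree:
    return parse_newick(_shape_newick(shape) + ";")


def enumerate_rooted_topologies(taxa) -> list[RootedTree]:
    """Every labelled rooted binary topology on the taxon set, exactly
    once; there are (2N-3)!! of them.  Guarded to 3 <= N <= 7."""
    labels = sorted(set(taxa))
    n = len(labels)
    if not 3 <= n <= MAX_EXHAUSTIVE_N:
        raise TreeError(
            f"exhaustive enumeration supports 3..{MAX_EXHAUSTIVE_N} taxa, got {n}"
        )
    shapes = [labels[0]]
    for leaf in labels[1:]:
        shapes = [s2 for s in shapes for s2 in _shape_insertions(s, leaf)]
    return [_shape_to_tree(s) for s in shapes]


def _random_topology(labels, rng: random.Random) -> RootedTree:
    """Uniform labelled rooted binary topology via stepwise insertion
    (each topology corresponds to exactly one insertion sequence for a
    fixed label order, so uniform edge choice gives a uniform tree)."""
    labels = sorted(labels)
    shape = labels[0]
    for leaf in labels[1:]:
        options = _shape_insertions(shape, leaf)
        shape = options[rng.randrange(len(options))]
    return _shape_to_tree(shape)


# ---------------------------------------------------------------------
# exhaustive search
# ---------------------------------------------------------------------


def exhaustive_search(counts: TripleCountTable) -> SearchResult:
    """Score every rooted binary topology and return the argmax.

    Deterministic: score ties (within 1e-9) are broken by the canonical
    newick string of the topology.
    """
    best = None
    best_key = None
    n_eval = 0
    for topo in enumerate_rooted_topologies(counts.taxa):
        fit = optimize_branch_lengths(topo, counts)
        n_eval += 1
        key = topo.topology_newick()
        if (
            best is None
            or fit.log_pl > best.log_pl + 1e-9
            or (abs(fit.log_pl - best.log_pl) <= 1e-9 and key < best_key)
        ):
            best, best_key = fit, key
    return SearchResult(best_fit=best, n_evaluated=n_eval, method="exhaustive")


# ---------------------------------------------------------------------
# NNI neighbourhood
# ---------------------------------------------------------------------


def nni_neighbors(topology: RootedTree) -> list[RootedTree]:
    """The nearest-neighbour-interchange neighbourhood of a rooted binary
    topology: for each internal edge, the two topologies obtained by
    exchanging one child of the edge's lower endpoint with the sibling
    subtree.  Every neighbour is at rooted RF distance exactly 2; the
    list is duplicate-free.  Empty for N < 4.
    """
    if not topology.is_binary():
        raise TreeError("NNI requires a binary topology")
    if topology.n_leaves() < 4:
        return []
    neighbors: dict[str, RootedTree] = {}
    base = topology.topology_newick()
    # work on node paths so we can redo the swap on a fresh copy
    def node_at(tree: RootedTree, path: tuple[int, ...]):
        node = tree.root
        for i in path:
            node = node.children[i]
        return node

    paths = []

    def collect(node, path):
        if node.parent is not None and not node.is_leaf():
            paths.append(path)
        for i, c in enumerate(node.children):
            collect(c, path + (i,))

    collect(topology.root, ())

    for path in paths:
        for child_idx in (0, 1):
            t = topology.copy()
            v = node_at(t, path)
            u = v.parent
            sib = next(c for c in u.children if c is not v)
            c = v.children[child_idx]
            u.remove_child(sib)
            v.remove_child(c)
            v.add_child(sib)
            u.add_child(c)
            for n in t.root.postorder():
                n.length = None
            key = t.topology_newick()
            if key != base:
                neighbors[key] = t
    return list(neighbors.values())


# ---------------------------------------------------------------------
# greedy start tree and hill climbing
# ---------------------------------------------------------------------


def greedy_join_tree(counts: TripleCountTable) -> RootedTree:
    """Agglomerative start tree: repeatedly join the pair of clusters
    with the highest average pooled cherry frequency
    s(A, B) = sum_c x(AB|c) / M_j, breaking ties lexicographically."""
    taxa = list(counts.taxa)
    pair_score: dict[frozenset, float] = {}
    for trio in counts.trios():
        row = counts.row(trio)
        m = row.sum()
        if m <= 0:
            continue
        from .triples import canonical_cherries

        for slot, cherry in enumerate(canonical_cherries(trio)):
            pair_score[cherry] = pair_score.get(cherry, 0.0) + row[slot] / m

    clusters: list[tuple[tuple[str, ...], object]] = [
        ((t,), t) for t in sorted(taxa)
    ]

    def cluster_score(c1, c2) -> float:
        vals = [
            pair_score.get(frozenset((a, b)), 0.0)
            for a in c1[0]
            for b in c2[0]
        ]
        return sum(vals) / len(vals)

    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            s = cluster_score(clusters[i], clusters[j])
            key = (-s, clusters[i][0], clusters[j][0])
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        ci, cj = clusters[i], clusters[j]
        merged = (tuple(sorted(ci[0] + cj[0])), (ci[1], cj[1]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return _shape_to_tree(clusters[0][1])


def hill_climb(
    counts: TripleCountTable, restarts: int = 10, seed: int = 0
) -> SearchResult:
    """Steepest-ascent NNI hill climb with restarts.

    From each start topology, repeatedly move to the best-scoring NNI
    neighbour while it strictly improves (by more than 1e-9) the
    optimized log pseudo-likelihood; the best local optimum across
    restarts is returned.  Fully reproducible from ``seed``.
    """
    if restarts < 1:
        raise EstimationError("restarts must be >= 1")
    rng = random.Random(seed)
    cache: dict[str, BranchLengthFit] = {}
    n_eval = 0

    def score(topo: RootedTree) -> BranchLengthFit:
        nonlocal n_eval
        key = topo.topology_newick()
        if key not in cache:
            cache[key] = optimize_branch_lengths(topo, counts)
            n_eval += 1
        return cache[key]

    starts = [greedy_join_tree(counts)]
    while len(starts) < restarts:
        starts.append(_random_topology(counts.taxa, rng))

    best: BranchLengthFit | None = None
    best_key = None
    trajectories = []
    for start in starts:
        current = start
        current_fit = score(current)
        traj = [(current.topology_newick(), current_fit.log_pl)]
        while True:
            candidates = []
            for nb in nni_neighbors(current):
                fit = score(nb)
                candidates.append((fit.log_pl, nb.topology_newick(), nb, fit))
            if not candidates:
                break
            candidates.sort(key=lambda c: (-c[0], c[1]))
            top_pl, _, top_tree, top_fit = candidates[0]
            if top_pl > current_fit.log_pl + 1e-9:
                current, current_fit = top_tree, top_fit
                traj.append((current.topology_newick(), current_fit.log_pl))
            else:
                break
        trajectories.append(traj)
        key = current.topology_newick()
        if (
            best is None
            or current_fit.log_pl > best.log_pl + 1e-9
            or (abs(current_fit.log_pl - best.log_pl) <= 1e-9 and key < best_key)
        ):
            best, best_key = current_fit, key
    return SearchResult(
        best_fit=best,
        n_evaluated=n_eval,
        trajectories=trajectories,
        seed=seed,
        method="nni-hill-climb",
    )


def estimate_species_tree(
    counts: TripleCountTable, restarts: int | None = None, seed: int = 0
) -> SearchResult:
    """Maximum pseudo-likelihood species tree from a triple count table.

    Uses exhaustive enumeration for N <= 6 taxa and the NNI hill climb
    (default 10 restarts up to 20 taxa, 25 above) otherwise.
    """
    uncovered = counts.uncovered_trios()
    if uncovered:
        raise EstimationError(f"trios covered by no gene tree: {uncovered}")
    n = counts.n_taxa
    if n <= AUTO_EXHAUSTIVE_N:
        return exhaustive_search(counts)
    if restarts is None:
        restarts = 10 if n <= 20 else 25
    return hill_climb(counts, restarts=restarts, seed=seed)
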