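"""The pseudo-likelihood of a species tree given gene-tree triple counts.

Model
-----
For a species-tree trio with internal branch length B (coalescent units,
T = 2*tau/theta), the multispecies coalescent gives the matching
gene-tree resolution probability 1 - (2/3) e^{-B}, and (1/3) e^{-B} for
each of the two others.  Treating the C(N,3) per-trio multinomial tables
as independent yields the log pseudo-likelihood

    sum_j [ x_j1 log(1 - (2/3) e^{-B_j}) + (x_j2 + x_j3) (log(1/3) - B_j) ]

where x_j1 counts the resolution matching the species tree and B_j is
the sum of the internal species-tree edges on the path from the cherry
MRCA to the trio MRCA.  The multinomial coefficient is constant in the
parameters and never computed.

Each term is concave in B_j and the B_j are linear in the edge lengths
T_i, so the log pseudo-likelihood is concave in T: a box-constrained
quasi-Newton ascent from the pooled closed-form warm start reaches the
global maximum for a fixed topology.

An internal branch whose every relevant gene-tree triple matches the
species tree has an unbounded-above length estimate; such branches are
reported with the conventional sentinel value 99 rather than a length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .treecore import RootedTree, TreeError
from .triples import TripleCountTable, canonical_cherries, resolve_triple

__all__ = [
    "SENTINEL",
    "T_CAP",
    "TripleDecomposition",
    "decompose",
    "log_pseudo_likelihood",
    "triple_mle",
    "optimize_branch_lengths",
    "BranchLengthFit",
]

#: Conventional value written for an inestimable internal branch.
SENTINEL = 99.0

#: Optimizer box bound in coalescent units; e^{-10} ~ 4.5e-5 is beyond
#: any resolvable topological signal.
T_CAP = 10.0

LOG_ONE_THIRD = math.log(1.0 / 3.0)


class EstimationError(ValueError):
    """The table does not support estimation (e.g. an uncovered trio)."""


@dataclass(frozen=True)
class TripleDecomposition:
    """For each trio of a binary species tree: its resolution (cherry and
    canonical slot) and the internal edges whose lengths sum to B_j.

    Edges are identified by the clade below them.  The edge set of a trio
    is exactly the internal edges on the path from the MRCA of the cherry
    pair up to (excluding) the MRCA of the whole trio.
    """

    taxa: tuple[str, ...]
    edges: tuple[frozenset, ...]  # all internal edges, deterministic order
    entries: dict = field(hash=False)  # trio -> (match_slot, tuple of edge clades)


def decompose(species_tree: RootedTree) -> TripleDecomposition:
    """Decompose every trio's internal branch into species-tree edges."""
    if not species_tree.is_binary():
        raise TreeError("species tree must be binary for decomposition")
    taxa = tuple(sorted(species_tree.leaf_labels))
    if len(taxa) < 3:
        raise TreeError("a species tree needs at least 3 taxa")

    cm = species_tree.clade_map()
    # node lookup by clade (binary rooted tree: clades are unique)
    node_by_clade = {
        cm[id(n)]: n for n in species_tree.root.postorder() if not n.is_leaf()
    }
    internal_edges = species_tree.internal_edge_clades()

    import itertools

    entries: dict = {}
    for trio in itertools.combinations(taxa, 3):
        res = resolve_triple(species_tree, trio)
        cherry = res.cherry  # binary tree: always resolved
        slot = res.slot()
        # MRCA of the cherry pair: smallest clade containing the pair
        pair = tuple(cherry)
        mrca_cherry = min(
            (c for c in node_by_clade if cherry <= c), key=len
        )
        mrca_trio = min(
            (c for c in node_by_clade if set(trio) <= c), key=len
        )
        edge_list = []
        node = node_by_clade[mrca_cherry]
        target = node_by_clade[mrca_trio]
        while node is not target:
            edge_list.append(cm[id(node)])
            node = node.parent
        entries[trio] = (slot, tuple(edge_list))
    return TripleDecomposition(taxa, tuple(internal_edges), entries)


def _edge_lengths(species_tree: RootedTree) -> dict[frozenset, float]:
    """Lengths of the internal edges, keyed by the clade below each."""
    cm = species_tree.clade_map()
    out = {}
    for node in species_tree.root.postorder():
        if node.is_leaf() or node.parent is None:
            continue
        if node.length is None:
            raise TreeError(
                f"internal edge above clade {sorted(cm[id(node)])} has no length"
            )
        out[cm[id(node)]] = float(node.length)
    return out


def log_pseudo_likelihood(
    species_tree: RootedTree, counts: TripleCountTable
) -> float:
    """Log pseudo-likelihood (multinomial coefficient omitted) of a
    species tree with internal branch lengths, given triple counts.

    Branch lengths equal to the sentinel 99 are treated as infinite
    (matching probability 1); this is only finite when the corresponding
    trios are fully matching.  Negative lengths are rejected.
    """
    dec = decompose(species_tree)
    if tuple(sorted(counts.taxa)) != dec.taxa:
        raise EstimationError(
            f"count table taxa {counts.taxa} differ from tree taxa {dec.taxa}"
        )
    lengths = _edge_lengths(species_tree)
    for clade, t in lengths.items():
        if t != SENTINEL and t < 0:
            raise EstimationError(f"negative branch length {t}")
    total = 0.0
    for trio, (slot, edge_clades) in dec.entries.items():
        row = counts.row(trio)
        m = row.sum()
        if m <= 0:
            raise EstimationError(f"trio {trio} is covered by no gene tree")
        x_match = row[slot]
        x_other = m - x_match
        if any(lengths[e] == SENTINEL for e in edge_clades):
            if x_other > 0:
                return -math.inf
            continue  # p_match = 1 contributes log(1) = 0
        b = sum(lengths[e] for e in edge_clades)
        total += x_match * math.log(1.0 - (2.0 / 3.0) * math.exp(-b))
        total += x_other * (LOG_ONE_THIRD - b)
    return total


def triple_mle(x: float, m: float) -> float:
    """Closed-form branch length MLE for a single trio.

    ``x`` is the count of the most frequent (species-tree-matching)
    resolution out of ``m`` genes.  Returns -log{3(1 - x/m)/2} for
    m/3 < x < m, 0 for x <= m/3 (the star frequency; clamped), and the
    sentinel 99 when x = m (not estimable).
    """
    if m <= 0:
        raise EstimationError(f"M must be positive, got {m}")
    if x < 0 or x > m:
        raise EstimationError(f"count x={x} outside [0, M={m}]")
    if x == m:
        return SENTINEL
    frac = x / m
    if frac <= 1.0 / 3.0:
        return 0.0
    return -math.log(3.0 * (1.0 - frac) / 2.0)


@dataclass
class BranchLengthFit:
    """Fitted internal branch lengths for a fixed topology.

    ``lengths`` maps each internal edge (clade below it) to its estimate;
    inestimable edges appear in ``sentinel_edges`` and carry the value 99
    in ``lengths`` and in the fitted tree.  ``log_pl`` is the maximized
    log pseudo-likelihood (fully matching trios behind sentinel edges
    contribute their limit, 0).
    """

    tree: RootedTree
    lengths: dict
    sentinel_edges: frozenset
    log_pl: float

    @property
    def species_tree(self) -> RootedTree:
        return self.tree


def _apply_lengths(topology: RootedTree, lengths: dict) -> RootedTree:
    fitted = topology.copy()
    cm = fitted.clade_map()
    for node in fitted.root.postorder():
        if node.is_leaf():
            node.length = None
        elif node.parent is None:
            node.length = None
        else:
            node.length = lengths[cm[id(node)]]
    fitted.units = "coalescent"
    return fitted


def optimize_branch_lengths(
    topology: RootedTree, counts: TripleCountTable
) -> BranchLengthFit:
    """Maximize the log pseudo-likelihood over internal branch lengths
    for a fixed binary rooted topology.

    The objective is concave, so a single box-constrained L-BFGS-B run
    from the pooled closed-form warm start finds the global optimum.
    Edges whose every trio is fully matching, and edges driven to the box
    bound ``T_CAP``, are reported as sentinels.
    """
    dec = decompose(topology)
    if tuple(sorted(counts.taxa)) != dec.taxa:
        raise EstimationError(
            f"count table taxa {counts.taxa} differ from tree taxa {dec.taxa}"
        )
    uncovered = counts.uncovered_trios()
    if uncovered:
        raise EstimationError(f"trios covered by no gene tree: {uncovered}")

    edges = list(dec.edges)
    edge_index = {e: i for i, e in enumerate(edges)}
    n_edges = len(edges)

    trio_rows = []
    for trio, (slot, edge_clades) in dec.entries.items():
        row = counts.row(trio)
        m = row.sum()
        trio_rows.append((trio, float(row[slot]), float(m), edge_clades))

    # sentinel rule: an edge is inestimable iff every trio containing it
    # is fully matching (x_match = M_j)
    fully_matching = {
        trio: (m - x) <= 1e-9 for trio, x, m, _ in trio_rows
    }
    sentinel = set()
    for e in edges:
        touching = [t for t, _, _, ecl in trio_rows if e in ecl]
        if touching and all(fully_matching[t] for t in touching):
            sentinel.add(e)

    # trios behind a sentinel edge are fully matching; their contribution
    # tends to 0 as the sentinel length grows, so they drop out
    active = [
        (trio, x, m, ecl)
        for trio, x, m, ecl in trio_rows
        if not any(e in sentinel for e in ecl)
    ]
    free = [e for e in edges if e not in sentinel]

    lengths: dict = {e: SENTINEL for e in sentinel}
    log_pl = 0.0

    if free:
        free_index = {e: i for i, e in enumerate(free)}
        design = np.zeros((len(active), len(free)))
        x_match = np.empty(len(active))
        m_tot = np.empty(len(active))
        for r, (trio, x, m, ecl) in enumerate(active):
            x_match[r] = x
            m_tot[r] = m
            for e in ecl:
                design[r, free_index[e]] = 1.0
        x_other = m_tot - x_match

        def neg_ll_and_grad(t: np.ndarray):
            b = design @ t
            eb = np.exp(-b)
            p_match = 1.0 - (2.0 / 3.0) * eb
            ll = np.dot(x_match, np.log(p_match)) + np.dot(
                x_other, LOG_ONE_THIRD - b
            )
            # d ll / d b_j
            g_b = x_match * ((2.0 / 3.0) * eb / p_match) - x_other
            return -ll, -(design.T @ g_b)

        # warm start: pooled closed form per edge, spread over path length
        t0 = np.empty(len(free))
        for e, i in free_index.items():
            vals = []
            for trio, x, m, ecl in active:
                if e in ecl:
                    b_hat = triple_mle(min(x, m * (1 - 1e-12)), m)
                    vals.append(b_hat / len(ecl))
            t0[i] = min(max(np.mean(vals) if vals else 0.1, 0.01), 5.0)

        res = minimize(
            neg_ll_and_grad,
            t0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, T_CAP)] * len(free),
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 1000},
        )
        t_hat = res.x
        log_pl = -float(res.fun)
        for e, i in free_index.items():
            if t_hat[i] >= T_CAP - 1e-6:
                sentinel.add(e)
                lengths[e] = SENTINEL
            else:
                lengths[e] = float(t_hat[i])

    fitted = _apply_lengths(topology, lengths)
    return BranchLengthFit(
        tree=fitted,
        lengths=lengths,
        sentinel_edges=frozenset(sentinel),
        log_pl=log_pl,
    )
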