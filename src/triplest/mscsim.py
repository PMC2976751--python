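"""Multispecies-coalescent simulation and related generators.

Within each branch of a species tree (branch lengths in coalescent
units, T = 2*tau/theta), every pair of extant gene lineages coalesces at
rate 1 per coalescent time unit; lineages that fail to coalesce enter
the parent branch, and the root branch runs until a single lineage
remains.  One lineage is sampled per species.

Also here: the unit conversion T = 2*tau/theta, a triple-level simulator
for the horizontal-gene-transfer perturbation (matching probability
e^{-2*lambda*L} - (2/3) e^{-B}, the complementary mass split equally
between the two non-matching resolutions), and a birth--death species
tree generator (via dendropy) with per-branch population sizes drawn
uniformly, used to build realistic test fixtures.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .treecore import Node, RootedTree, TreeError, parse_newick
from .pseudolik import SENTINEL

__all__ = [
    "HGTConfig",
    "to_coalescent_units",
    "simulate_gene_tree",
    "simulate_gene_trees",
    "simulate_topology_counts",
    "simulate_triple_counts_hgt",
    "random_species_tree",
    "species_tree_to_coalescent_units",
]


def to_coalescent_units(tau: float, theta: float) -> float:
    """Convert a branch length from mutation units to coalescent units,
    T = 2*tau/theta."""
    if theta <= 0:
        raise TreeError(f"population size theta must be positive, got {theta}")
    if tau < 0:
        raise TreeError(f"branch length tau must be non-negative, got {tau}")
    return 2.0 * tau / theta


@dataclass(frozen=True)
class HGTConfig:
    """Homogeneous horizontal-gene-transfer model for one species trio.

    ``rate`` is the HGT rate lambda per gene per generation between each
    donor-acceptor species pair that can alter the trio topology;
    ``divergence_time`` is the divergence time L of the cherry species in
    generations.  The number of topology-changing events is Poisson with
    mean 2*lambda*L, so the no-event probability is e^{-2*lambda*L}.
    """

    rate: float
    divergence_time: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise TreeError(f"HGT rate must be >= 0, got {self.rate}")
        if self.divergence_time <= 0:
            raise TreeError(
                f"divergence time must be positive, got {self.divergence_time}"
            )


# ---------------------------------------------------------------------
# gene-tree simulation under the MSC
# ---------------------------------------------------------------------


def _species_plan(species_tree: RootedTree):
    """Postorder plan of (children-or-leaf-label, branch duration, height
    at branch bottom) for the simulator.  Requires finite coalescent-unit
    lengths on all non-root edges.  Node heights are leaf-to-node path
    sums (the max over children when the tree is not ultrametric, e.g.
    after per-branch theta conversion); recorded gene-tree node times are
    exact for ultrametric input, while topologies are exact always since
    only branch durations enter the within-branch coalescent."""
    plan = []
    index: dict[int, int] = {}
    heights: dict[int, float] = {}
    for node in species_tree.root.postorder():
        if node.is_leaf():
            h = 0.0
        else:
            for c in node.children:
                if c.length is None:
                    raise TreeError(
                        "every non-root species-tree edge needs a length"
                    )
            h = max(heights[id(c)] + c.length for c in node.children)
        heights[id(node)] = h
        if node.parent is None:
            duration = math.inf
        else:
            if node.length is None:
                raise TreeError("every non-root species-tree edge needs a length")
            if node.length == SENTINEL:
                raise TreeError(
                    "species tree has a sentinel (inestimable) branch; "
                    "it cannot be simulated from"
                )
            duration = float(node.length)
        entry = (
            node.label if node.is_leaf() else [index[id(c)] for c in node.children],
            duration,
            h,
        )
        index[id(node)] = len(plan)
        plan.append(entry)
    return plan


def _simulate_lineages(plan, rng: random.Random):
    """One MSC realization; returns the final lineage as a nested
    structure ((child, child), height) with leaves (label, 0.0)."""
    # per-plan-entry list of lineages exiting that species branch
    out: list[list] = [None] * len(plan)
    for i, (content, duration, h_bottom) in enumerate(plan):
        if isinstance(content, str):
            lineages = [(content, 0.0)]
        else:
            lineages = []
            for ci in content:
                lineages.extend(out[ci])
        t = h_bottom
        h_top = h_bottom + duration
        k = len(lineages)
        while k > 1:
            t += rng.expovariate(k * (k - 1) / 2.0)
            if t > h_top:
                break
            i1 = rng.randrange(k)
            i2 = rng.randrange(k - 1)
            if i2 >= i1:
                i2 += 1
            a = lineages[i1]
            b = lineages[i2]
            lineages = [
                lin for j, lin in enumerate(lineages) if j not in (i1, i2)
            ]
            lineages.append(((a, b), t))
            k -= 1
        out[i] = lineages
    (final,) = out[-1]
    return final


def _lineage_key(lineage) -> str:
    node, h = lineage
    if isinstance(node, str):
        return node
    a, b = sorted((_lineage_key(node[0]), _lineage_key(node[1])))
    return f"({a},{b})"


def _lineage_to_node(lineage, parent_height: float | None) -> Node:
    content, h = lineage
    if isinstance(content, str):
        node = Node(label=content)
    else:
        node = Node()
        for child in content:
            node.add_child(_lineage_to_node(child, h))
    node.length = None if parent_height is None else parent_height - h
    return node


def _coerce_rng(seed) -> random.Random:
    return seed if isinstance(seed, random.Random) else random.Random(seed)


def simulate_gene_tree(species_tree: RootedTree, seed=0) -> RootedTree:
    """Simulate one rooted gene tree (topology and coalescent-unit node
    times) from a species tree with coalescent-unit branch lengths.

    ``seed`` may be an integer or a ``random.Random`` instance (the
    latter lets callers draw many trees from one generator).
    """
    plan = _species_plan(species_tree)
    rng = _coerce_rng(seed)
    lineage = _simulate_lineages(plan, rng)
    tree = RootedTree(_lineage_to_node(lineage, None), units="coalescent")
    return tree


def simulate_gene_trees(species_tree: RootedTree, n: int, seed=0) -> list[RootedTree]:
    """Simulate ``n`` independent gene trees from one seeded generator."""
    plan = _species_plan(species_tree)
    rng = _coerce_rng(seed)
    return [
        RootedTree(_lineage_to_node(_simulate_lineages(plan, rng), None), "coalescent")
        for _ in range(n)
    ]


def simulate_topology_counts(
    species_tree: RootedTree, n: int, seed=0
) -> Counter:
    """Counter of canonical gene-tree topology strings over ``n``
    simulated genes.  Equivalent to simulating full gene trees and
    tallying their topologies, but without building tree objects."""
    plan = _species_plan(species_tree)
    rng = _coerce_rng(seed)
    counts: Counter = Counter()
    for _ in range(n):
        counts[_lineage_key(_simulate_lineages(plan, rng)) + ";"] += 1
    return counts


# ---------------------------------------------------------------------
# HGT-perturbed triple counts
# ---------------------------------------------------------------------


def hgt_match_probability(b: float, config: HGTConfig) -> float:
    """Probability that a gene-tree triple matches the species-tree triple
    with internal branch B under the HGT model:
    e^{-2*lambda*L} - (2/3) e^{-B}.  Errors when the model leaves no
    matching probability (large lambda and/or small B)."""
    if b < 0:
        raise TreeError(f"branch length must be >= 0, got {b}")
    p = math.exp(-2.0 * config.rate * config.divergence_time) - (
        2.0 / 3.0
    ) * math.exp(-b)
    if p < 0:
        raise TreeError(
            f"HGT model leaves no matching probability (p={p:.4g}) for "
            f"B={b}, 2*lambda*L={2 * config.rate * config.divergence_time:.4g}"
        )
    return p


def simulate_triple_counts_hgt(
    b: float, config: HGTConfig, n_genes: int, seed: int = 0
) -> np.ndarray:
    """Draw triple counts (x1, x2, x3) for one trio under the HGT model.

    x1 counts the species-tree-matching resolution; the complementary
    mass is split equally between the two non-matching resolutions (the
    two transfer routes are symmetric).
    """
    p_match = hgt_match_probability(b, config)
    p_other = (1.0 - p_match) / 2.0
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_genes, [p_match, p_other, p_other]).astype(float)


# ---------------------------------------------------------------------
# random species trees (birth-death, via dendropy)
# ---------------------------------------------------------------------


def random_species_tree(
    n_taxa: int,
    birth_rate: float = 10.0,
    death_rate: float = 0.1,
    theta_range: tuple[float, float] = (0.005, 0.01),
    seed: int = 0,
):
    """Ultrametric species tree from a birth--death process conditioned
    on ``n_taxa`` surviving tips (branch lengths in mutation units), with
    i.i.d. uniform per-branch population sizes theta.

    Returns ``(tree, thetas)`` where ``thetas`` maps each non-root
    node's clade (the edge above it) to its theta.  Convert to
    coalescent units with :func:`species_tree_to_coalescent_units`.
    """
    if n_taxa < 3:
        raise TreeError(f"need at least 3 taxa, got {n_taxa}")
    if not birth_rate > death_rate >= 0:
        raise TreeError(
            f"need birth rate > death rate >= 0, got {birth_rate}, {death_rate}"
        )
    lo, hi = theta_range
    if not 0 < lo <= hi:
        raise TreeError(f"invalid theta range {theta_range}")

    import dendropy
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"S{i + 1}" for i in range(n_taxa)])
    # generalized-sampling conditioning: grow the process past n_taxa and
    # sample a time slice during which exactly n_taxa lineages exist, so
    # pendant edges have proper positive lengths
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_taxa,
        gsa_ntax=2 * n_taxa,
        taxon_namespace=taxa,
        rng=rng,
    )
    newick = dtree.as_string(
        schema="newick", suppress_rooting=True, suppress_internal_node_labels=True
    ).strip()
    tree = parse_newick(newick, units="mutation")

    cm = tree.clade_map()
    thetas = {}
    for node in tree.root.postorder():
        if node.parent is not None:
            thetas[cm[id(node)]] = rng.uniform(lo, hi)
    return tree, thetas


def species_tree_to_coalescent_units(
    tree: RootedTree, thetas: dict | float
) -> RootedTree:
    """Convert a mutation-unit species tree to coalescent units using
    per-branch thetas (a clade-keyed dict) or a single constant theta."""
    out = tree.copy()
    cm = out.clade_map()
    for node in out.root.postorder():
        if node.parent is None or node.length is None:
            continue
        theta = thetas if isinstance(thetas, (int, float)) else thetas[cm[id(node)]]
        node.length = to_coalescent_units(node.length, theta)
    out.units = "coalescent"
    return out
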