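"""Shared fixtures and independent oracles for the test suite.

dendropy is used as an *independent* newick parser / clade enumerator so
that tree-structural results are never checked against the code that
produced them.
"""

from __future__ import annotations

import random

import dendropy
import pytest

import triplest as tp
from triplest.examples import (
    WORKED_EXAMPLE_GENE_TREES,
    WORKED_EXAMPLE_TOPOLOGY,
)


# ---------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------


def dendropy_clades(newick: str) -> set[frozenset]:
    """Internal-node leaf-label sets via dendropy (independent parser)."""
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_internal():
            out.add(frozenset(leaf.taxon.label for leaf in node.leaf_iter()))
    return out


def dendropy_nontrivial_clades(newick: str) -> set[frozenset]:
    clades = dendropy_clades(newick)
    full = max(clades, key=len)
    return {c for c in clades if 1 < len(c) < len(full)}


# ---------------------------------------------------------------------
# random tree generation (for property tests)
# ---------------------------------------------------------------------


def random_topology(labels, rng: random.Random) -> tp.RootedTree:
    """Uniform labelled rooted binary topology built by stepwise random
    insertion (used to *generate* inputs, never as an oracle)."""
    labels = sorted(labels)
    shape = labels[0]

    def insertions(s, leaf):
        out = [(s, leaf)]
        if isinstance(s, tuple):
            a, b = s
            out.extend((x, b) for x in insertions(a, leaf))
            out.extend((a, x) for x in insertions(b, leaf))
        return out

    def to_newick(s):
        if isinstance(s, tuple):
            return "(" + ",".join(sorted(to_newick(x) for x in s)) + ")"
        return s

    for leaf in labels[1:]:
        options = insertions(shape, leaf)
        shape = options[rng.randrange(len(options))]
    return tp.parse_newick(to_newick(shape) + ";")


def random_tree_with_lengths(labels, rng: random.Random) -> tp.RootedTree:
    t = random_topology(labels, rng)
    for node in t.root.postorder():
        if node.parent is not None:
            node.length = round(rng.uniform(0.0, 3.0), 6)
    return t


# ---------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------


@pytest.fixture(scope="session")
def worked_gene_trees():
    return [tp.parse_newick(s) for s in WORKED_EXAMPLE_GENE_TREES]


@pytest.fixture(scope="session")
def worked_counts(worked_gene_trees):
    return tp.count_triples(worked_gene_trees)


@pytest.fixture(scope="session")
def worked_topology():
    return tp.parse_newick(WORKED_EXAMPLE_TOPOLOGY)


@pytest.fixture(scope="session")
def five_taxon_species_tree():
    """Fixed ultrametric 5-taxon species tree (coalescent units) with all
    internal edges >= 0.2, used by the consistency experiments."""
    return tp.parse_newick(
        "((((A:1,B:1):0.3,C:1.3):0.3,D:1.6):0.5,E:2.1);", units="coalescent"
    )


def counts_from_simulation(species_tree, n_genes, seed, taxa=None):
    """Triple counts from simulated gene trees, via topology tallies."""
    tallies = tp.simulate_topology_counts(species_tree, n_genes, seed=seed)
    weighted = [(tp.parse_newick(k), v) for k, v in tallies.items()]
    return tp.count_triples_weighted(weighted, taxa=taxa)
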