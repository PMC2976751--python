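"""Multilocus (gene-level) bootstrap of the species-tree estimate.

Replicates resample whole genes with replacement; each replicate is
re-estimated and the replicate topologies are summarized by a
majority-rule-extended consensus whose clade frequencies are the
bootstrap supports.  Branch lengths are those of the full-data fit (the
consensus provides topology supports only).

Two-level resampling (sites within genes, which requires re-estimating
gene trees from sequences with an external ML program) is out of scope;
externally produced per-replicate gene-tree files can be fed through
:func:`bootstrap_from_replicates` instead.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .treecore import RootedTree, TreeError, SupportTree, majority_consensus
from .triples import count_triples
from .search import SearchResult, estimate_species_tree

__all__ = [
    "BootstrapRun",
    "gene_bootstrap",
    "estimate_replicates",
    "bootstrap_support",
    "bootstrap_from_replicates",
]


@dataclass
class BootstrapRun:
    """Gene-level bootstrap replicates (and, once estimated, their trees)."""

    gene_trees: list
    replicate_indices: list
    seed: int
    estimates: list | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_indices)

    def replicate(self, r: int) -> list:
        return [self.gene_trees[i] for i in self.replicate_indices[r]]


def gene_bootstrap(gene_trees, n_replicates: int, seed: int = 0) -> BootstrapRun:
    """Draw ``n_replicates`` multisets of genes, each of the original
    size, i.i.d. with replacement; deterministic from ``seed``."""
    gene_trees = list(gene_trees)
    m = len(gene_trees)
    if m < 1:
        raise TreeError("bootstrap needs at least one gene tree")
    if n_replicates < 1:
        raise TreeError("need at least one bootstrap replicate")
    rng = random.Random(seed)
    indices = [
        [rng.randrange(m) for _ in range(m)] for _ in range(n_replicates)
    ]
    return BootstrapRun(gene_trees, indices, seed)


def estimate_replicates(
    run: BootstrapRun, restarts: int | None = None, seed: int = 0
) -> BootstrapRun:
    """Estimate a species tree for every replicate (in place and returned).

    The taxon set is fixed to the union over the original genes so every
    replicate is estimated over the same taxa.
    """
    taxa = set().union(*(t.leaf_labels for t in run.gene_trees))
    estimates = []
    for r in range(run.n_replicates):
        counts = count_triples(run.replicate(r), taxa=taxa)
        result = estimate_species_tree(counts, restarts=restarts, seed=seed + r)
        estimates.append(result.best_tree)
    run.estimates = estimates
    return run


def bootstrap_support(run: BootstrapRun, threshold: float = 0.5) -> SupportTree:
    """Majority-rule-extended consensus of the replicate topologies with
    clade frequencies as supports.  Requires estimated replicates."""
    if run.estimates is None:
        raise TreeError(
            "replicates have not been estimated; call estimate_replicates first"
        )
    return majority_consensus(run.estimates, threshold=threshold, extended=True)


def bootstrap_from_replicates(replicate_trees, threshold: float = 0.5) -> SupportTree:
    """Consensus supports from externally estimated replicate trees
    (the file-based hook for two-level, site-and-gene resampling)."""
    return majority_consensus(list(replicate_trees), threshold=threshold, extended=True)
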