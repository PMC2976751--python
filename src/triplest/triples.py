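"""Rooted-triple extraction and the triple count table.

For every 3-subset {a, b, c} of the taxa, each gene tree displays one of
the three rooted resolutions ab|c, ac|b, bc|a (the pair whose most recent
common ancestor excludes the third taxon), or no resolution at all when
the induced subtree is a tritomy.  The table of per-trio resolution
counts across gene trees is the sufficient statistic of the
pseudo-likelihood method: unresolved triples contribute 1/3 to each of
the three slots, and genes missing a member of the trio contribute
nothing to that trio's row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .treecore import RootedTree, TreeError

__all__ = [
    "TripleResolution",
    "TripleCountTable",
    "canonical_cherries",
    "resolve_triple",
    "count_triples",
    "count_triples_weighted",
]


def canonical_cherries(trio: Sequence[str]) -> tuple[frozenset, frozenset, frozenset]:
    """The three cherry pairs of a trio in canonical slot order.

    For the sorted trio (a, b, c) the slots are (ab|c, ac|b, bc|a), i.e.
    cherries {a,b}, {a,c}, {b,c}.  All tables in this package index
    resolutions this way.
    """
    a, b, c = sorted(trio)
    return (frozenset((a, b)), frozenset((a, c)), frozenset((b, c)))


@dataclass(frozen=True)
class TripleResolution:
    """Resolution of one trio in one gene tree.

    ``cherry`` is the 2-set grouped to the exclusion of the third taxon,
    or ``None`` when the induced subtree is unresolved (a tritomy).
    """

    trio: tuple[str, str, str]
    cherry: frozenset | None

    @property
    def is_resolved(self) -> bool:
        return self.cherry is not None

    def slot(self) -> int | None:
        if self.cherry is None:
            return None
        return canonical_cherries(self.trio).index(self.cherry)


def _pair_mrca_clades(tree: RootedTree) -> dict[frozenset, frozenset]:
    """Map each unordered leaf pair to the clade of its MRCA."""
    mrca: dict[frozenset, frozenset] = {}
    leafsets: dict[int, frozenset] = {}
    for node in tree.root.postorder():
        if node.is_leaf():
            leafsets[id(node)] = frozenset((node.label,))
            continue
        child_sets = [leafsets[id(c)] for c in node.children]
        clade = frozenset().union(*child_sets)
        leafsets[id(node)] = clade
        for s1, s2 in itertools.combinations(child_sets, 2):
            for x in s1:
                for y in s2:
                    mrca[frozenset((x, y))] = clade
    return mrca


def resolve_triple(gene_tree: RootedTree, trio: Iterable[str]) -> TripleResolution:
    """Resolution of ``trio`` displayed by a rooted gene tree.

    Returns the cherry whose MRCA excludes the third taxon, or an
    unresolved result when the induced subtree is a tritomy.  Raises
    :class:`TreeError` if any trio member is not a leaf of the tree.
    """
    trio_t = tuple(sorted(trio))
    if len(trio_t) != 3:
        raise TreeError(f"a trio needs exactly 3 distinct labels, got {trio_t}")
    leaves = gene_tree.leaf_labels
    missing = [x for x in trio_t if x not in leaves]
    if missing:
        raise TreeError(f"taxa {missing} are not leaves of the gene tree")
    mrca = _pair_mrca_clades(gene_tree)
    return TripleResolution(trio_t, _resolve_from_mrca(trio_t, mrca))


def _resolve_from_mrca(
    trio: tuple[str, str, str], mrca: dict[frozenset, frozenset]
) -> frozenset | None:
    for cherry in canonical_cherries(trio):
        (third,) = set(trio) - cherry
        if third not in mrca[cherry]:
            return cherry
    return None


class TripleCountTable:
    """Per-trio resolution weights over all C(N, 3) trios of a taxon set.

    Row ``j`` holds weights (x_j1, x_j2, x_j3) >= 0 in canonical slot
    order (see :func:`canonical_cherries`); the row sum M_j is the number
    of gene trees containing all three taxa of the trio (unresolved
    triples contribute exact thirds, so M_j is reproduced to within
    1e-9).  Trios covered by no gene at all have M_j = 0 and are flagged
    by :meth:`uncovered_trios`; estimation refuses such tables.
    """

    def __init__(self, taxa: Iterable[str]):
        self.taxa: tuple[str, ...] = tuple(sorted(set(taxa)))
        if len(self.taxa) < 3:
            raise TreeError("a triple count table needs at least 3 taxa")
        self._rows: dict[tuple[str, str, str], np.ndarray] = {
            trio: np.zeros(3) for trio in itertools.combinations(self.taxa, 3)
        }

    # -- access --------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def trios(self) -> list[tuple[str, str, str]]:
        return list(self._rows)

    def row(self, trio: Sequence[str]) -> np.ndarray:
        return self._rows[tuple(sorted(trio))]

    def m(self, trio: Sequence[str]) -> float:
        """Effective gene count M_j for the trio."""
        return float(self.row(trio).sum())

    def uncovered_trios(self) -> list[tuple[str, str, str]]:
        return [t for t, r in self._rows.items() if r.sum() <= 0.0]

    # -- construction --------------------------------------------------

    def add_gene_tree(self, tree: RootedTree, weight: float = 1.0) -> None:
        labels = [n.label for n in tree.root.leaf_nodes()]
        leafset = set(labels)
        if len(labels) != len(leafset):
            raise TreeError(
                "gene tree has repeated labels; a single lineage must be "
                "sampled from each species"
            )
        extra = leafset - set(self.taxa)
        if extra:
            raise TreeError(f"gene tree contains unknown taxa {sorted(extra)}")
        mrca = _pair_mrca_clades(tree)
        for trio in itertools.combinations(sorted(leafset), 3):
            cherry = _resolve_from_mrca(trio, mrca)
            row = self._rows[trio]
            if cherry is None:
                row += 1.0 / 3.0 * weight
            else:
                row[canonical_cherries(trio).index(cherry)] += weight

    def set_row(self, trio: Sequence[str], weights: Sequence[float]) -> None:
        """Directly set a row (used for tables given as data)."""
        w = np.asarray(weights, dtype=float)
        if w.shape != (3,) or (w < 0).any():
            raise TreeError("a row is three non-negative weights")
        self._rows[tuple(sorted(trio))] = w

    # -- serialization -------------------------------------------------

    def to_tsv(self) -> str:
        lines = ["trio\tx1\tx2\tx3\tM"]
        for trio, row in self._rows.items():
            lines.append(
                "{}\t{:.9g}\t{:.9g}\t{:.9g}\t{:.9g}".format(
                    ",".join(trio), row[0], row[1], row[2], row.sum()
                )
            )
        return "\n".join(lines) + "\n"


def count_triples(
    gene_trees: Sequence[RootedTree], taxa: Iterable[str] | None = None
) -> TripleCountTable:
    """Build the triple count table from a collection of rooted gene trees.

    ``taxa`` defaults to the union of all gene-tree leaf sets.  Genes
    missing some taxa contribute only to the trios they cover.
    """
    return count_triples_weighted([(t, 1.0) for t in gene_trees], taxa=taxa)


def count_triples_weighted(
    weighted_trees: Sequence[tuple[RootedTree, float]],
    taxa: Iterable[str] | None = None,
) -> TripleCountTable:
    """Like :func:`count_triples` but each tree carries a multiplicity.

    Useful when many genes share a topology (e.g. simulated data): the
    resulting table is identical to counting each copy separately.
    """
    if not weighted_trees:
        raise TreeError("at least one gene tree is required")
    if taxa is None:
        taxa = set().union(*(t.leaf_labels for t, _ in weighted_trees))
    table = TripleCountTable(taxa)
    for tree, weight in weighted_trees:
        table.add_gene_tree(tree, weight)
    return table
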