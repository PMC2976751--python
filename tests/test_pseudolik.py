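"""Triple decomposition, log pseudo-likelihood, and branch-length fits."""

import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import triplest as tp
from triplest.pseudolik import SENTINEL, T_CAP, EstimationError
from triplest.treecore import TreeError
from triplest.triples import TripleCountTable, canonical_cherries

from conftest import random_topology


def independent_trio_edges(tree, trio):
    """Independent path characterization: an internal edge (clade c) lies
    on a trio's internal branch iff it contains the cherry MRCA's clade
    and not the whole trio."""
    clades = tree.clades()
    res = tp.resolve_triple(tree, trio)
    cherry_mrca = min((c for c in clades if res.cherry <= c), key=len)
    edges = set()
    full = tree.leaf_labels
    for c in clades:
        if c == full:
            continue
        if cherry_mrca <= c and not set(trio) <= c:
            edges.add(c)
    return edges


class TestDecompose:
    def test_worked_example_topology(self, worked_topology):
        dec = tp.decompose(worked_topology)
        assert len(dec.entries) == 4  # C(4,3) rooted triples
        ab, cd = frozenset("AB"), frozenset("CD")
        assert dec.entries[("A", "B", "C")][1] == (ab,)
        assert dec.entries[("A", "B", "D")][1] == (ab,)
        assert dec.entries[("A", "C", "D")][1] == (cd,)
        assert dec.entries[("B", "C", "D")][1] == (cd,)
        # matching slots: AB|C, AB|D, CD|A, CD|B
        assert dec.entries[("A", "B", "C")][0] == 0
        assert dec.entries[("A", "C", "D")][0] == 2

    def test_three_taxon_single_edge(self):
        dec = tp.decompose(tp.parse_newick("((A,B),C);"))
        assert dec.entries[("A", "B", "C")] == (0, (frozenset("AB"),))

    def test_caterpillar_deep_triple_sums_all_edges(self):
        t = tp.parse_newick("((((A,B),C),D),E);")
        dec = tp.decompose(t)
        assert set(dec.entries[("A", "B", "E")][1]) == {
            frozenset("AB"),
            frozenset("ABC"),
            frozenset("ABCD"),
        }

    def test_nonbinary_rejected(self):
        with pytest.raises(TreeError):
            tp.decompose(tp.parse_newick("(a,b,c,d);"))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_path_rule_matches_independent_enumeration(self, seed):
        rng = random.Random(seed)
        labels = [f"t{i}" for i in range(6)]
        tree = random_topology(labels, rng)
        dec = tp.decompose(tree)
        for trio, (slot, edges) in dec.entries.items():
            assert set(edges) == independent_trio_edges(tree, trio)
        # every internal edge appears in at least one trio's path
        used = set().union(*(set(e) for _, e in dec.entries.values()))
        assert used == set(tree.internal_edge_clades())


def set_lengths(tree, lengths):
    t = tree.copy()
    cm = t.clade_map()
    for node in t.root.postorder():
        if node.parent is not None and not node.is_leaf():
            node.length = lengths[cm[id(node)]]
    return t


def naive_log_pl(tree, lengths, counts):
    """Term-by-term product oracle for the log pseudo-likelihood."""
    total = 0.0
    for trio in counts.trios():
        res = tp.resolve_triple(tree, trio)
        b = sum(lengths[e] for e in independent_trio_edges(tree, trio))
        p_match = 1 - (2 / 3) * math.exp(-b)
        p_other = (1 / 3) * math.exp(-b)
        row = counts.row(trio)
        for slot, cherry in enumerate(canonical_cherries(trio)):
            p = p_match if cherry == res.cherry else p_other
            total += row[slot] * math.log(p)
    return total


class TestLogPseudoLikelihood:
    def test_worked_example_value(self, worked_topology, worked_counts):
        t = set_lengths(
            worked_topology,
            {frozenset("AB"): math.log(2.0), frozenset("CD"): 0.0},
        )
        assert tp.log_pseudo_likelihood(t, worked_counts) == pytest.approx(
            -11.797, abs=5e-4
        )

    def test_star_limit_all_zero_lengths(self, worked_topology, worked_counts):
        t = set_lengths(
            worked_topology, {frozenset("AB"): 0.0, frozenset("CD"): 0.0}
        )
        total_m = sum(worked_counts.m(trio) for trio in worked_counts.trios())
        expected = total_m * math.log(1 / 3)
        assert tp.log_pseudo_likelihood(t, worked_counts) == pytest.approx(expected)

    def test_always_nonpositive(self, worked_topology, worked_counts):
        rng = random.Random(4)
        for _ in range(20):
            t = set_lengths(
                worked_topology,
                {
                    frozenset("AB"): rng.uniform(0, 5),
                    frozenset("CD"): rng.uniform(0, 5),
                },
            )
            assert tp.log_pseudo_likelihood(t, worked_counts) <= 0

    def test_negative_length_rejected(self, worked_topology, worked_counts):
        t = set_lengths(
            worked_topology, {frozenset("AB"): -0.1, frozenset("CD"): 0.0}
        )
        with pytest.raises(EstimationError):
            tp.log_pseudo_likelihood(t, worked_counts)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_naive_product_oracle(self, seed):
        rng = random.Random(seed)
        labels = [f"t{i}" for i in range(5)]
        tree = random_topology(labels, rng)
        lengths = {e: rng.uniform(0, 3) for e in tree.internal_edge_clades()}
        counts = TripleCountTable(labels)
        for trio in counts.trios():
            counts.set_row(trio, [rng.randint(0, 30) + 1 for _ in range(3)])
        t = set_lengths(tree, lengths)
        assert tp.log_pseudo_likelihood(t, counts) == pytest.approx(
            naive_log_pl(tree, lengths, counts), abs=1e-10
        )


class TestTripleMLE:
    def test_pooled_worked_example_value(self):
        assert tp.triple_mle(4, 6) == pytest.approx(math.log(2.0), abs=1e-12)

    def test_star_frequency_gives_zero(self):
        assert tp.triple_mle(2, 6) == 0.0
        assert tp.triple_mle(1, 6) == 0.0  # clamped below the star frequency

    def test_all_matching_gives_sentinel(self):
        assert tp.triple_mle(6, 6) == SENTINEL

    @pytest.mark.parametrize("x,m", [(7, 6), (-1, 6), (1, 0)])
    def test_invalid_counts_rejected(self, x, m):
        with pytest.raises(EstimationError):
            tp.triple_mle(x, m)

    def test_strictly_increasing_above_one_third(self):
        m = 90
        values = [tp.triple_mle(x, m) for x in range(31, 90)]
        assert all(b2 > b1 for b1, b2 in zip(values, values[1:]))


def refined_grid_max(fn, n_dims, lo=0.0, hi=5.0, coarse=50, zooms=6):
    """Independent optimizer oracle: coarse grid then repeated zooming."""
    import numpy as np

    centers = [np.linspace(lo, hi, coarse) for _ in range(n_dims)]
    best, best_t = -math.inf, None
    span = hi - lo
    lo_v = [lo] * n_dims
    hi_v = [hi] * n_dims
    for _ in range(zooms):
        axes = [np.linspace(lo_v[d], hi_v[d], coarse) for d in range(n_dims)]
        for point in itertools.product(*axes):
            v = fn(point)
            if v > best:
                best, best_t = v, point
        for d in range(n_dims):
            step = (hi_v[d] - lo_v[d]) / (coarse - 1)
            lo_v[d] = max(lo, best_t[d] - 2 * step)
            hi_v[d] = min(hi, best_t[d] + 2 * step)
    return best, best_t


class TestOptimizeBranchLengths:
    def test_worked_example_estimates(self, worked_topology, worked_counts):
        fit = tp.optimize_branch_lengths(worked_topology, worked_counts)
        assert fit.lengths[frozenset("AB")] == pytest.approx(0.693, abs=5e-4)
        assert fit.lengths[frozenset("CD")] == pytest.approx(0.0, abs=1e-6)
        assert fit.log_pl == pytest.approx(-11.797, abs=5e-4)
        assert not fit.sentinel_edges

    def test_three_taxon_matches_closed_form(self):
        rng = random.Random(11)
        topo = tp.parse_newick("((A,B),C);")
        for _ in range(10):
            x = rng.randint(0, 29)
            counts = TripleCountTable("ABC")
            counts.set_row("ABC", [x, 30 - x, 0])
            fit = tp.optimize_branch_lengths(topo, counts)
            expected = tp.triple_mle(x, 30)
            got = fit.lengths[frozenset("AB")]
            if expected == SENTINEL:
                assert got == SENTINEL
            else:
                assert got == pytest.approx(expected, abs=1e-6)

    def test_disjoint_edges_match_pooled_closed_form(self, worked_topology):
        # on ((A,B),(C,D)) the T1 and T2 trios share no edges, so each
        # edge's optimum is the pooled closed-form estimate
        rng = random.Random(3)
        for _ in range(8):
            counts = TripleCountTable("ABCD")
            rows = {}
            for trio in counts.trios():
                row = [rng.randint(1, 40) for _ in range(3)]
                counts.set_row(trio, row)
                rows[trio] = row
            fit = tp.optimize_branch_lengths(worked_topology, counts)
            # matching slots: AB|C is slot 0 of ABC/ABD; CD|* is slot 2
            x1 = rows[("A", "B", "C")][0] + rows[("A", "B", "D")][0]
            m1 = sum(rows[("A", "B", "C")]) + sum(rows[("A", "B", "D")])
            x2 = rows[("A", "C", "D")][2] + rows[("B", "C", "D")][2]
            m2 = sum(rows[("A", "C", "D")]) + sum(rows[("B", "C", "D")])
            for clade, x, m in [
                (frozenset("AB"), x1, m1),
                (frozenset("CD"), x2, m2),
            ]:
                expected = tp.triple_mle(x, m)
                if expected == SENTINEL:
                    assert fit.lengths[clade] == SENTINEL
                else:
                    assert fit.lengths[clade] == pytest.approx(expected, abs=1e-5)

    def test_matches_refined_grid_search(self):
        # caterpillar 4-taxon topology: trios share the two edges, so the
        # optimum is a genuine 2-d joint maximization
        topo = tp.parse_newick("(((A,B),C),D);")
        rng = random.Random(23)
        for _ in range(3):
            counts = TripleCountTable("ABCD")
            for trio in counts.trios():
                counts.set_row(trio, [rng.randint(1, 25) for _ in range(3)])
            fit = tp.optimize_branch_lengths(topo, counts)
            edges = [frozenset("AB"), frozenset("ABC")]

            def fn(point):
                t = set_lengths(topo, dict(zip(edges, point)))
                return tp.log_pseudo_likelihood(t, counts)

            grid_best, grid_t = refined_grid_max(fn, 2)
            assert fit.log_pl >= grid_best - 1e-8
            for e, g in zip(edges, grid_t):
                if fit.lengths[e] != SENTINEL:
                    assert fit.lengths[e] == pytest.approx(g, abs=1e-4)

    def test_single_repeated_gene_tree_all_sentinels(self):
        genes = [tp.parse_newick("(((A,B),C),D);")] * 5
        counts = tp.count_triples(genes)
        fit = tp.optimize_branch_lengths(tp.parse_newick("(((A,B),C),D);"), counts)
        assert fit.sentinel_edges == {frozenset("AB"), frozenset("ABC")}
        assert all(v == SENTINEL for v in fit.lengths.values())
        assert fit.log_pl == 0.0

    def test_uncovered_trio_refused(self):
        genes = [tp.parse_newick("((a,b),c);"), tp.parse_newick("((a,b),d);")]
        counts = tp.count_triples(genes)
        with pytest.raises(EstimationError):
            tp.optimize_branch_lengths(tp.parse_newick("(((a,b),c),d);"), counts)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_concavity_along_random_segments(self, seed):
        rng = random.Random(seed)
        topo = tp.parse_newick("(((A,B),C),D);")
        counts = TripleCountTable("ABCD")
        for trio in counts.trios():
            counts.set_row(trio, [rng.randint(1, 20) for _ in range(3)])
        edges = [frozenset("AB"), frozenset("ABC")]
        p0 = [rng.uniform(0, 4), rng.uniform(0, 4)]
        p1 = [rng.uniform(0, 4), rng.uniform(0, 4)]

        def value(alpha):
            point = [a + alpha * (b - a) for a, b in zip(p0, p1)]
            return tp.log_pseudo_likelihood(
                set_lengths(topo, dict(zip(edges, point))), counts
            )

        alphas = np.linspace(0, 1, 21)
        vals = [value(a) for a in alphas]
        second_diffs = np.diff(vals, 2)
        assert (second_diffs <= 1e-6).all()
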