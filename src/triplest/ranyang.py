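"""Per-population coalescent likelihood in the Rannala--Yang
parameterization, and the executable demonstration that the joint
maximum-likelihood species tree (topology, branch lengths tau, and
population sizes theta, all in mutation units) does not exist.

For population i and gene k, with m_ik lineages entering, n_ik leaving,
coalescent time intervals t_ikj (j = n_ik+1..m_ik) and branch duration
tau_i, the gene's contribution is

    exp{-n(n-1)/theta * (tau - sum_j t_j)} * prod_j (2/theta) e^{-j(j-1) t_j / theta}

Multiplying over genes, the population likelihood collapses to
(2/theta)^a e^{-b/theta} with sufficient statistics

    a = sum_k (m_ik - n_ik)
    b = sum_k [ n(n-1)(tau - sum_j t_j) + sum_j j(j-1) t_j ].

The non-existence argument: for three fixed 3-taxon gene trees and the
species tree ((A:X, B:X):W, C:X+W), let X -> 0.01 (the earliest a--b
coalescence) and W -> 0 while theta_2 = 0.01 - X + 2W.  The ancestral
AB-population likelihood (2/theta_2) e^{-2} grows without bound while
the root population's likelihood stays bounded, so no maximizer exists.
This module evaluates the likelihood along that path; it deliberately
offers no optimization over (tau, theta).

All times here are mutation units, segregated by the tree unit tag from
the coalescent-unit world of the pseudo-likelihood modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .treecore import RootedTree, TreeError, parse_newick

__all__ = [
    "PopulationRecord",
    "PopulationSufficientStats",
    "sufficient_stats",
    "population_log_likelihood",
    "NONEXISTENCE_GENE_TREES",
    "nonexistence_records",
    "mle_nonexistence_path",
    "path_log_likelihood_from_log_s",
]


@dataclass(frozen=True)
class PopulationRecord:
    """One gene's passage through one population.

    ``m`` lineages enter, ``n`` leave, with the ``m - n`` coalescent
    interval times in ``times`` (mutation units) and branch duration
    ``tau`` (``None`` for the root population, which has unbounded
    duration and therefore no survival term; it must end with n = 1).
    """

    m: int
    n: int
    times: tuple[float, ...]
    tau: float | None

    def __post_init__(self) -> None:
        if not self.m >= self.n >= 1:
            raise TreeError(f"need m >= n >= 1, got m={self.m}, n={self.n}")
        if len(self.times) != self.m - self.n:
            raise TreeError(
                f"expected {self.m - self.n} interval times, got {len(self.times)}"
            )
        if any(t < 0 for t in self.times):
            raise TreeError(f"negative interval time in {self.times}")
        if self.tau is None:
            if self.n != 1:
                raise TreeError("the root population must coalesce to one lineage")
        elif sum(self.times) > self.tau + 1e-15:
            raise TreeError(
                f"interval times {self.times} exceed branch duration {self.tau}"
            )


@dataclass(frozen=True)
class PopulationSufficientStats:
    """(a, b) such that the population likelihood is (2/theta)^a e^{-b/theta}."""

    a: int
    b: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise TreeError(f"invalid sufficient stats a={self.a}, b={self.b}")


def sufficient_stats(records) -> PopulationSufficientStats:
    """Collapse one population's per-gene records into (a, b)."""
    a = 0
    b = 0.0
    for rec in records:
        a += rec.m - rec.n
        if rec.tau is not None:
            b += rec.n * (rec.n - 1) * (rec.tau - sum(rec.times))
        # times are stored in chronological order: the first interval has
        # m lineages, the last has n+1
        for offset, t in enumerate(rec.times):
            j = rec.m - offset
            b += j * (j - 1) * t
    return PopulationSufficientStats(a=a, b=b)


def population_log_likelihood(
    stats: PopulationSufficientStats, theta: float
) -> float:
    """log[(2/theta)^a e^{-b/theta}] = a log(2/theta) - b/theta."""
    if theta <= 0:
        raise TreeError(f"theta must be positive, got {theta}")
    return stats.a * math.log(2.0 / theta) - stats.b / theta


# ---------------------------------------------------------------------
# the non-existence example
# ---------------------------------------------------------------------

#: The three fixed ultrametric gene trees of the non-existence example
#: (mutation units).
NONEXISTENCE_GENE_TREES = (
    "((A:0.01,B:0.01):0.01,C:0.02);",
    "((A:0.015,C:0.015):0.01,B:0.025);",
    "((A:0.02,B:0.02):0.01,C:0.03);",
)


def _gene_tree_events(newick: str) -> tuple[frozenset, float, float]:
    """(cherry pair, first coalescence time, root coalescence time) of a
    3-taxon ultrametric gene tree."""
    tree = parse_newick(newick, units="mutation")
    root = tree.root
    if len(root.children) != 2:
        raise TreeError("expected a binary 3-taxon gene tree")
    internal = [c for c in root.children if not c.is_leaf()]
    if len(internal) != 1:
        raise TreeError("expected a 3-taxon caterpillar gene tree")
    (inner,) = internal
    t1 = inner.children[0].length  # cherry coalescence height (ultrametric)
    t2 = t1 + inner.length  # root coalescence height
    cherry = frozenset(c.label for c in inner.children)
    return cherry, float(t1), float(t2)


def nonexistence_records(
    x: float, w: float, gene_trees=NONEXISTENCE_GENE_TREES
) -> dict:
    """Decompose the example gene trees over the species tree
    ((A:x, B:x):w, C:x+w) into per-population records.

    Populations: ``"ab"`` (the ancestral A--B population of duration w)
    and ``"root"``.  Requires every gene coalescence to postdate the
    relevant species divergence (x below every a--b coalescence in the
    AB population, y = x + w below every root-population coalescence).
    """
    y = x + w
    if not (x > 0 and w > 0):
        raise TreeError(f"need X > 0 and W > 0, got X={x}, W={w}")
    ab_records = []
    root_records = []
    for nwk in gene_trees:
        cherry, t1, t2 = _gene_tree_events(nwk)
        if cherry == frozenset(("A", "B")) and t1 < y:
            # a and b coalesce inside the AB population
            if t1 <= x:
                raise TreeError(
                    f"gene coalescence at {t1} predates species divergence X={x}"
                )
            ab_records.append(PopulationRecord(2, 1, (t1 - x,), w))
            if t2 <= y:
                raise TreeError(
                    f"root coalescence at {t2} predates species divergence Y={y}"
                )
            root_records.append(PopulationRecord(2, 1, (t2 - y,), None))
        else:
            # both a and b survive the AB population; three lineages at root
            if t1 <= y:
                raise TreeError(
                    f"gene coalescence at {t1} predates species divergence Y={y}"
                )
            ab_records.append(PopulationRecord(2, 2, (), w))
            root_records.append(PopulationRecord(3, 1, (t1 - y, t2 - t1), None))
    return {"ab": ab_records, "root": root_records}


def mle_nonexistence_path(
    s: float,
    delta: float = 0.001,
    delta_prime: float = 0.0012,
    theta1: float = 0.01,
    gene_trees=NONEXISTENCE_GENE_TREES,
) -> float:
    """Total log-likelihood of the example along the degeneracy path.

    For s in (0, 1]: X = 0.01 - s*delta, W = s*delta', theta_2 =
    0.01 - X + 2W (all positive by construction).  The value is strictly
    increasing as s -> 0 and is unbounded above -- the executable form of
    the MLE non-existence argument.

    The defaults keep delta' - delta < theta_1 / 14 so that the bounded
    root-population term (whose exponent varies linearly with
    Y = X + W) never outpaces the -log s growth of the degenerate
    AB-population term: the path is then monotone on all of (0, 1].
    """
    if not 0 < s <= 1:
        raise TreeError(f"path parameter s must be in (0, 1], got {s}")
    if delta <= 0 or delta_prime <= delta:
        raise TreeError("need 0 < delta < delta_prime")
    x = 0.01 - s * delta
    w = s * delta_prime
    theta2 = 0.01 - x + 2 * w
    recs = nonexistence_records(x, w, gene_trees)
    return population_log_likelihood(
        sufficient_stats(recs["ab"]), theta2
    ) + population_log_likelihood(sufficient_stats(recs["root"]), theta1)


def path_log_likelihood_from_log_s(
    log_s: float,
    delta: float = 0.001,
    delta_prime: float = 0.0012,
    theta1: float = 0.01,
    gene_trees=NONEXISTENCE_GENE_TREES,
) -> float:
    """Exact log-likelihood along the same path, parameterized by log(s).

    Algebraically identical to :func:`mle_nonexistence_path` (the AB
    population has a = 1 and b = 2*theta_2, so its term is
    log 2 - log theta_2 - 2 with log theta_2 = log s + log(delta + 2*delta')),
    but evaluated in log space so the divergence can be followed far past
    floating-point underflow of s itself: the value exceeds any preset
    bound, e.g. 1e6 at log_s ~ -1e6.
    """
    if log_s > 0:
        raise TreeError(f"log_s must be <= 0, got {log_s}")
    if delta <= 0 or delta_prime <= delta:
        raise TreeError("need 0 < delta < delta_prime")
    ab_term = math.log(2.0) - (log_s + math.log(delta + 2.0 * delta_prime)) - 2.0
    # the root population's statistics vary continuously with Y = X + W
    # and stay bounded; evaluate them at a representable point of the path
    # (for log_s below log 1e-6 the Y-dependence is < 1e-6 log units)
    s_eff = max(math.exp(max(log_s, -700.0)), 1e-6)
    recs = nonexistence_records(0.01 - s_eff * delta, s_eff * delta_prime, gene_trees)
    root_term = population_log_likelihood(sufficient_stats(recs["root"]), theta1)
    return ab_term + root_term
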