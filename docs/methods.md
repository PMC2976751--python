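# Methods

## Model

A rooted binary species tree on N species has N−2 internal edges with
lengths $T_i \ge 0$ in coalescent units ($T = 2\tau/\theta$, where
$\tau$ is the branch length in expected substitutions per site and
$\theta = 4N_e\mu$).  External branches carry no length: with a single
sampled lineage per species no coalescence can occur in a terminal
population, so terminal lengths are not identifiable and the package
never reports them.

Each of the $\binom{N}{3}$ rooted triples of the species tree has an
internal branch of length $B_j$, the sum of the internal edges on the
path from the MRCA of the cherry pair to the MRCA of the trio.  Under
the multispecies coalescent the probability that a gene tree displays
the matching resolution is $1-\frac23 e^{-B_j}$ and $\frac13 e^{-B_j}$
for each alternative.  Gene trees enter only through their per-trio
resolution counts $(x_{j1}, x_{j2}, x_{j3})$; the pseudo-likelihood is
the product of the per-trio multinomials, with the count-only
multinomial coefficient omitted throughout since it does not depend on
the parameters.  An unresolved gene-tree triple contributes 1/3 to each
slot; a gene missing one of the trio's taxa contributes nothing to that
trio, so each trio has its own effective count $M_j$ (this generalizes
the common-M model exactly as required when taxa are missing at
random).  A trio covered by zero genes makes the table unusable and
estimation refuses it with an error listing the trio, rather than
guessing.

## Branch-length optimization

$\log(1-\frac23 e^{-B})$ is concave in $B$ and each $B_j$ is linear in
the $T_i$, so the log pseudo-likelihood is concave in $T$; any interior
stationary point is the global maximum.  The fitter uses L-BFGS-B with
an analytic gradient, box bounds $[0, T_{\text{cap}}]$ with
$T_{\text{cap}} = 10$ (beyond $e^{-10} \approx 4.5\times10^{-5}$ there
is no resolvable topological signal), convergence tolerances
`ftol=1e-14` / `gtol=1e-10`, and a warm start from the pooled
closed-form estimate $-\log\{3(1-x/M)/2\}$ averaged over the trios that
contain each edge (clamped to [0.01, 5]).

Inestimability: an internal edge is reported with the sentinel value 99
when every trio containing it is fully matching ($x_{j1} = M_j$, so its
length is unbounded above), or when the optimum hits the box bound
(near-degenerate numerics that the all-matching rule does not cover).
Fully matching trios behind a sentinel edge contribute their limiting
value 0 to the reported log pseudo-likelihood.  An optimum of exactly 0
is reported as a zero-length branch and flagged "polytomy-consistent" in
the CLI log, since zero length means the three resolutions are
equiprobable.

## Topology search

For N ≤ 6 every labelled rooted binary topology ((2N−3)!! of them) is
scored.  Above that, a steepest-ascent NNI hill climb: restart 1 starts
from a greedy agglomerative tree that repeatedly joins the cluster pair
with the highest average pooled cherry frequency
$s(A,B)=\sum_c x(AB|c)/M_j$; the remaining restarts (10 by default up to
20 taxa, 25 above) start from uniformly random rooted topologies drawn
by seeded stepwise insertion.  Moves are accepted only on strict
improvement (> 1e-9); all ties — among equal-scoring neighbours and
among equal-scoring optima — are broken by canonical newick string
order, so results are bit-for-bit reproducible from the seed.  The
search neighbourhood and acceptance schedule are this package's own
design; correctness is defined by reaching the exhaustive-search optimum
on small instances, which the test suite checks on 20 seeded 5-taxon
instances (M = 500, 10 restarts).

## Simulator

`simulate_gene_tree` implements the multispecies coalescent directly:
within each species-tree branch of duration T (coalescent units), each
pair of extant lineages coalesces at rate 1 (exponential waiting times,
uniform pair choice); survivors enter the parent branch and the root
branch runs to completion.  Recorded node heights are exact for
ultrametric input; for non-ultrametric input (e.g. after converting a
mutation-unit tree with *per-branch* $\theta$) topologies remain exact —
only branch durations enter the process — while heights are
branch-local bookkeeping.  Species trees containing sentinel (99)
branches are refused.

The HGT model operates at the triple level, as the perturbation itself
does: topology-changing transfers between the cherry species and the
outgroup species of a trio arrive as a Poisson process with mean
$2\lambda L$, so the matching probability becomes
$e^{-2\lambda L} - \frac23 e^{-B}$.  The complementary mass is split
equally between the two non-matching resolutions because the two
transfer routes are symmetric.  Parameter regimes in which the formula
goes negative (large $\lambda$, small B) are rejected with an error
rather than truncated — the model simply does not cover them.  Editing
whole simulated gene trees with transfer events is out of scope.

`random_species_tree` delegates the birth–death process to dendropy with
generalized-sampling conditioning on the number of surviving tips
(growing the process past n and sampling a slice while exactly n
lineages exist, so pendant edges have proper positive lengths — plain
stopping at the n-th birth leaves a zero-length cherry).  Defaults
(birth 10, death 0.1, $\theta \sim U(0.005, 0.01)$ per branch) produce
mutation-unit trees whose coalescent-unit internal edges are mostly
short (ILS-heavy), the regime this estimator is designed for.

## Bootstrap

Gene-level resampling only: replicates draw M genes with replacement,
each replicate is re-estimated, and the replicate topologies are
summarized by majority-rule-extended consensus with clade frequencies
as supports.  Among equal-frequency incompatible clades the extension
prefers the lexicographically smallest sorted leaf tuple — a documented
deterministic stand-in for unpublished consensus tie-breaking rules.
Branch lengths always come from the full-data fit; the consensus carries
supports only.  Site-level resampling within genes would require
re-estimating gene trees from sequences with external ML software;
`bootstrap_from_replicates` accepts externally produced per-replicate
trees for that two-level scheme.

## Full-likelihood non-existence

The `ranyang` module makes executable the argument for why the method
works on triple counts rather than the full Rannala–Yang likelihood
over (topology, $\tau$, $\theta$): collapsing each population's per-gene
terms to sufficient statistics $(a_i, b_i)$ gives the population
likelihood $(2/\theta_i)^{a_i} e^{-b_i/\theta_i}$, and along the path
$X = 0.01 - s\delta$, $W = s\delta'$, $\theta_2 = 0.01 - X + 2W$ for the
three shipped example gene trees, the ancestral-population term
$\log 2 - \log\theta_2 - 2$ grows without bound as $s \to 0$ while the
root population's term stays bounded.  The module is evaluation-only by
design — offering an optimizer for a likelihood with no maximum would be
misleading.  Defaults $\delta = 0.001$, $\delta' = 0.0012$ keep
$\delta' - \delta < \theta_1/14$, which makes the path monotone on all
of (0, 1], not merely eventually.  Because reaching log-likelihood
values beyond ~700 requires $s$ below floating-point range, a log-space
evaluator (`path_log_likelihood_from_log_s`) computes the same quantity
exactly from $\log s$; the bounded root term is evaluated at a
representable path point, introducing error below 1e-6 log units.  One
caveat uncovered while deriving the oracle: the combined root-population
exponent for this example is $0.29 - 14Y$; the tests assert the
independently derived decomposition, not any printed constant.

## Numerical and interface conventions

- Canonical newick output orders children by smallest descendant label;
  topology identity is string identity of `topology_newick()`.
- The newick dialect is strict: quoted labels and bracketed comments are
  rejected with position-reporting errors; internal-node labels are
  parsed and preserved (they carry consensus supports on output).
- RF distance is the rooted clade-set convention.  It differs from the
  unrooted bipartition RF most software reports; for the 5-taxon
  anomaly-zone pair the rooted distance is 2.
- Table weights are doubles; row sums reproduce $M_j$ to within 1e-9
  (unresolved triples contribute exact binary-representable sums of
  thirds only up to rounding).

## Test scales, and what passing does and does not show

Simulated data in the tests come from the package's own coalescent
simulator, which realizes the exact model the estimator assumes: no
gene-tree estimation error, no missing-data mechanism beyond random
taxon deletion, no rate variation, one allele per species.  Passing
therefore demonstrates internal correctness and the method's
statistical behaviour *under its model*, not robustness on real
multilocus data.  Experiment sizes were chosen as the smallest that
separate the compared conditions cleanly: consistency uses a fixed
5-taxon tree (internal edges ≥ 0.3) with 50 seeds at M ∈ {10, 1000} and
20 seeds for branch-length RMSE at M ∈ {100, 2000}; anomaly-zone
recovery uses 15 seeds at M ∈ {100, 5000}; the modal-gene-tree check
simulates 200,000 genes; frequency-law checks use M = 10,000 (3 binomial
SEs) and the HGT law M = 100,000.
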