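# triplest

Maximum pseudo-likelihood species-tree estimation from rooted gene trees
under the multispecies coalescent.

## The problem

Different loci in a genome have different genealogies: incomplete lineage
sorting makes gene trees disagree with each other and with the species
tree, and for species trees with very short internal branches (the
*anomaly zone*) the single most common gene-tree topology is not even the
species-tree topology.  Concatenating alignments or taking a plain
consensus of gene trees is therefore inconsistent in general.  This
package estimates a rooted species tree — topology **and** internal
branch lengths in coalescent units — from a collection of rooted
gene-tree topologies, for phylogeneticists working with multilocus data
where gene trees are estimated per locus and rooted by a known outgroup.

## The method

A rooted species tree on N species is characterized by its
$\binom{N}{3}$ rooted triples.  For a species-tree triple AB|C whose
internal branch has length $B_j$ (coalescent units, $T = 2\tau/\theta$),
the multispecies coalescent gives the probability that a random gene
tree displays the matching triple ab|c as

$$P(ab|c) = 1 - \tfrac{2}{3}e^{-B_j}, \qquad P(ac|b) = P(bc|a) = \tfrac{1}{3}e^{-B_j}.$$

With $x_{j1}, x_{j2}, x_{j3}$ the per-trio resolution counts over $M$
gene trees, each trio's counts are multinomial, and the *pseudo*-
likelihood of the species tree multiplies these marginal multinomials
over all trios (their dependence is ignored — hence "pseudo"):

$$\log \Phi(S^*) = \sum_j \Big[ x_{j1}\log\big(1-\tfrac{2}{3}e^{-B_j}\big) + (x_{j2}+x_{j3})\big(\log\tfrac{1}{3} - B_j\big) \Big],$$

where each $B_j$ is the sum of the internal species-tree edges on the
path from the cherry's MRCA to the trio's MRCA.  The maximizer is
statistically consistent for both topology and branch lengths as
$M \to \infty$.  For a single trio the branch-length MLE is closed-form,
$\hat B = -\log\{3(1-x/M)/2\}$; a branch whose every relevant triple
matches the species tree is not estimable and is reported with the
conventional sentinel length 99.  The log pseudo-likelihood is concave
in the branch lengths, so a box-constrained quasi-Newton ascent finds
the per-topology optimum; topology search is exhaustive for few species
and a seeded steepest-ascent NNI hill climb with restarts otherwise.

The package also ships a multispecies-coalescent gene-tree simulator, a
triple-level horizontal-gene-transfer perturbation model (matching
probability $e^{-2\lambda L} - \tfrac{2}{3}e^{-B_j}$), a gene-level
bootstrap with majority-rule-extended consensus supports, and an
executable demonstration of why the *full* Rannala–Yang likelihood over
(topology, $\tau$, $\theta$) admits no MLE, which is what motivates the
coalescent-unit reparameterization and the pseudo-likelihood.

## Worked example

Three gene trees over species A–D, evaluated on the fixed species-tree
topology ((A,B),(C,D)):

```python
>>> import triplest as tp
>>> genes = [tp.parse_newick(s) for s in
...          ("((A,B),(C,D));", "((A,C),(B,D));", "(((A,B),C),D);")]
>>> counts = tp.count_triples(genes)
>>> counts.row("ABC")          # slots: (AB|C, AC|B, BC|A)
array([2., 1., 0.])
>>> fit = tp.optimize_branch_lengths(tp.parse_newick("((A,B),(C,D));"), counts)
>>> round(fit.lengths[frozenset("AB")], 3)
0.693
>>> round(fit.lengths[frozenset("CD")], 3)
0.0
>>> round(fit.log_pl, 3)
-11.797
```

The T1 edge (above the {A,B} cherry) is supported by 4 of 6 relevant
triples, giving $\hat T_1 = -\log\{3(1-4/6)/2\} = 0.693$ coalescent
units; the trios behind the {C,D} edge each occur at the star frequency
1/3, so $\hat T_2 = 0$ (a polytomy-consistent zero-length branch).  The
maximized log pseudo-likelihood, without the constant multinomial
coefficient, is −11.797.

The same estimate from the shell, with a search over all 15 topologies:

```sh
triplest est --genetrees tests/data/worked_example_genetrees.nwk
```

Other subcommands: `sim` (coalescent simulation, plus an HGT
triple-count mode), `boot` (gene-level bootstrap supports), `rf`,
`consensus`, and `demo ry-divergence`.

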