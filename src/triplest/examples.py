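"""Small published example inputs used by the documentation, the tests
and the demo subcommands.

``WORKED_EXAMPLE_GENE_TREES`` are three 4-taxon gene trees whose triple
count table is the textbook worked example of the pseudo-likelihood
(pooled matching counts 4/6 for the T1 edge and 2/6 for the T2 edge of
the species tree ((A,B),(C,D)), giving T1-hat = -log(1/2) = 0.693,
T2-hat = 0 and log pseudo-likelihood -11.797).

``ANOMALOUS_SPECIES_TREE`` is a 5-taxon caterpillar species tree inside
the anomaly zone (coalescent units): its most probable gene tree,
``ANOMALOUS_MODAL_GENE_TREE``, differs from the species tree itself
(rooted RF distance 2).
"""

WORKED_EXAMPLE_GENE_TREES = (
    "((A,B),(C,D));",
    "((A,C),(B,D));",
    "(((A,B),C),D);",
)

WORKED_EXAMPLE_TOPOLOGY = "((A,B),(C,D));"

ANOMALOUS_SPECIES_TREE = (
    "((((A:0.5,B:0.5):0.025,C:0.525):0.025,D:0.55):1,E:1.55);"
)

ANOMALOUS_MODAL_GENE_TREE = "(((A,B),(C,D)),E);"
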