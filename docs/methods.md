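# Methods

This note documents the statistical model behind `gogonet`, the defaults and
why they are what they are, what the synthetic-data generator does and does
not emulate, and the numerical/design choices made where the design was
genuinely open.

## First-DE-day labeling

Differential-expression calling happens upstream; the package consumes a
table of adjusted p-values per gene and time point. A gene's label is the
*earliest* day with adjusted p strictly below α (default 0.01; boundary
values are not significant). Genes never below α carry no label. The label
is what gives GO–GO edges their temporal direction: a gene significant on
days 2 and 6 is a "day 2" gene — later re-appearances are deliberately
ignored, the hypothesis being that the first perturbation matters for
propagation.

Genes present in the DEG table but absent from the interactome keep their
labels (they still count in per-term DE fractions when the term's gene is in
the relevant universe); the DEG-vs-non-DEG degree comparison, by contrast,
is computed only over interactome nodes, because degree is undefined
elsewhere. That comparison uses a one-way ANOVA with two groups, which is
identical to a pooled-variance two-sample t-test (F = t²); when the group
means coincide exactly, floating-point can produce a minute negative F, and
the p-value is clamped to 1.

## Temporal GO–GO networks

For a consecutive day pair (d, d′), the observed statistic for an ordered GO
term pair (X, Y) is the number of interactome edges {g₁, g₂} with g₁
annotated to X and labeled d, and g₂ annotated to Y and labeled d′. A
multi-annotated gene fans out over all its terms, so one gene edge can feed
many term pairs — intended: term pairs are the unit of inference, and the
permutation null preserves exactly this sharing. Edges whose endpoints share
a first-DE day contribute nothing.

### The permutation null

Each round draws one uniform bijection of gene names onto the network's node
positions; a gene's annotation and label travel with its name, the topology
stays fixed. This breaks the association between a gene's attributes and its
position (degree, neighbourhood) while preserving the degree sequence, the
label multiset, the annotation structure, and — because one bijection is
shared by all term pairs in a round — the joint dependence between term
pairs. The alternative null (degree-preserving edge rewiring) answers a
different question (is the wiring special given where the labels sit); the
name-shuffling null asks whether the *placement* of labeled, annotated genes
on the fixed interactome is special, which is the propagation hypothesis.

Only term pairs with an observed count ≥ 1 are tested. The one-sided
empirical p-value is (1 + r)/(1 + N) with r the number of rounds reaching
the observed count and N the number of rounds; p can never be 0 and never
falls below 1/(N + 1), so N must exceed 99 for the default 0.01 retention
cutoff to be reachable (the default N is 10,000). No multiple-testing
correction is applied by default — retention is at raw p < 0.01 — but a
Benjamini–Hochberg option exists (`bh_correction`). Unannotated genes in the
network still occupy positions during shuffling and can absorb labels;
labeled genes absent from the network contribute nothing. GO annotations are
used exactly as given: no true-path ancestor propagation (feed the reader a
pre-propagated annotation file if that is wanted). Self-pairs X → X across
days are tested like any other pair. The same term pair may be retained in
several day pairs; these are distinct parallel edges in the output
multigraph.

### A calibration caveat worth knowing

Because only observed pairs are tested, the *fraction of tested pairs*
retained is a selective quantity. The p-values themselves are marginally
valid — P(p ≤ α) ≤ α under the null for every pair — but a pair whose null
probability of being observed at all is below the cutoff is significant
whenever it is tested. In data where GO terms are small and labels sparse
(one gene per term-day cell), such rare-but-automatic pairs can push the
retained fraction above the nominal level even with no planted structure.
With terms of realistic size (tens of genes, several labeled genes per
term-day cell) the effect vanishes: the package's calibration runs (200
unplanted datasets, 100 genes, 8 terms of 15–40 genes, attachment parameter
6, background DE probability 0.5, N = 999) measure ~4% of tested pairs at
p < 0.05 and ~0.6% retained at p < 0.01. Interpret small-term edges in
sparse datasets with corresponding caution — or switch on the BH option.

### Node attributes

Retained terms carry `gene_count` (annotated genes present in the gene
network) and `de_fraction` (the share of those genes labeled on any day) —
the quantities a Cytoscape style maps to node size and colour. For condition
networks the universe is the CEIN's own gene set.

## Condition-specific co-expression

### Correlations

The pairwise statistic is the sample Pearson correlation with (n − 1)
normalisation, computed three times per interactome edge: over treated
samples, over control samples, over all samples. A constant vector makes the
correlation undefined; such pairs are classified `none` and logged rather
than guessed. The all-sample cutoff is applied to the *signed* PCC_all (a
strongly anti-correlated pair is not "developmental"); an `abs_full_pcc`
option applies it to the magnitude instead.

### Factorial ANOVA

Each pair is analysed as a balanced 2 (treatment) × D (day) × 2 (gene)
factorial with r replicates per cell: the response stacks both genes'
values, each observation tagged with its sample's treatment and day and with
which gene it came from. Sums of squares are the classical balanced-design
decomposition (verified against a sum-contrast OLS fit to 1e-8 relative
error and additive to the total to 1e-10); every F uses the full model's
residual mean square. For the default 2×4×2 design with 4 replicates the
numerator dfs are (1, 3, 1, 3, 1, 3, 3) and the residual df is 48 on 64
observations. Unbalanced layouts are rejected with a pointer to the
balancedness flag rather than silently approximated — Type I/II/III sums of
squares diverge there, and the classification rules were defined for the
balanced case.

F critical values are taken from the F distribution at each effect's
(numerator df, residual df) by default. A `paper_df` option instead fixes
the denominator df at 19 (numerator 1 for treatment-involving effects, D−1
for day effects), reproducing F thresholds such as F(0.95; 1, 19) ≈ 4.38
used in some published analyses of this design; that denominator is not
derivable from the balanced 64-observation layout, so both conventions are
supported and neither is silently imposed.

### Classification

Condition-specific rules are evaluated first: a pair with one strong arm
correlation, a large normalised between-arm difference, and at least one
significant treatment-involving effect (TREAT, TREAT×GENE, TREAT×DAY×GENE at
`alpha_effect` = 0.05) is assigned to the arm with the larger |PCC|; an
exact tie carries no information about which arm and falls through. The
normalised difference |PCC_treat − PCC_control| / max(|PCC_treat|,
|PCC_control|) is used exactly as defined, so two strong opposite-sign
correlations can exceed 1 and qualify — faithful to the rule even though
such pairs deserve a manual look. Developmental pairs require PCC_all >
full_PCC, a significant day effect at 0.05, and a day×gene interaction
*below* its 0.2 critical value — the lenient `alpha_sync` makes the
synchrony requirement strict (the interaction must be small even by a
generous test). Precedence is condition-specific > developmental > none,
making the three predicates mutually exclusive as implemented.

Defaults min_PCC = 0.9, diff_PCC = 0.6, full_PCC = 0.9, α_effect = 0.05,
α_sync = 0.2, DE α = 0.01, N = 10,000 permutations, retention p < 0.01 are
the method's published operating point and are asserted as defaults in the
run configuration.

## Synthetic data

The generator emulates the modelled study: a 2-treatment × 4-day ×
4-replicate design (32 samples; days 2, 4, 6, 7 standing for 48–168 hours
post fertilisation), a preferential-attachment interactome (heavy-tailed
degrees, edge count exactly m·(n − m) for the growth rule used), GO terms of
varied size with every gene carrying 1–3 terms, a DEG table in which planted
term A is first-DE on the earlier day and planted term B on the later day
with `n_bridge_edges` added between them, and an expression matrix with
planted co-expressed pairs.

A planted condition-specific pair shares a *day-dependent* profile in its
arm (standardised so the planted correlation equals the target in
expectation) plus a constant arm shift of `treat_shift` noise-sd units. The
shift is what makes the treatment main effect register in the ANOVA: a
purely random shared latent would reproduce the target correlation but carry
no mean structure, and the classification's ANOVA gate would reject the pair
at the nominal rate of a null test. Real treated co-expression almost always
rides on a treatment response, which is exactly this structure.
Developmental pairs share a monotone day trend in both arms. Background
expression is i.i.d. Gaussian around per-gene baselines.

What the generator does *not* emulate: count noise (values are continuous,
log-like; a Poisson count mode exists only for I/O exercises),
gene-correlated baselines, library-size artefacts, annotation bias toward
hubs, or dependence between DE calling and expression values (the DEG table
and the matrix are generated independently). Passing tests therefore
demonstrate the statistics and the machinery, not robustness to RNA-seq
artefacts — upstream normalisation remains the user's responsibility, and
the `log2_cpm` reader flag is a convenience, not a pipeline.

Expected behaviour worth knowing when interpreting power numbers: at 16
samples per arm, a null arm correlation exceeds 0.388 about 7% of the time,
and such a pair fails the diff_PCC = 0.6 gate; planted-pair sensitivity
therefore plateaus near 0.93 at the 0.9/0.6/0.9 cutoffs regardless of how
strong the planted correlation is. This is a property of the rule at this
sample size, not of the implementation.

## Problem sizes used in validation runs

Validation is property-based (the original study's inputs are not publicly
deposited, so its headline counts are not reproducible): counting is checked
exactly against a brute-force double loop on 100 random instances of ≤ 50
genes; the Monte-Carlo null (N = 10,000) against exact enumeration of all
5040 bijections on 7-gene networks; calibration on 200 unplanted datasets as
above; temporal power on the planted 8-edge bridge between 10-gene terms in
500-gene networks over 50 seeds (N = 1999, i.e. a p floor of 5·10⁻⁴, well
under the 0.01 cutoff); classification on 30 planted treated pairs among
~500 background edges over 20 seeds. These sizes were chosen as the smallest
at which each property is sharply testable; all scale linearly if increased.

## Determinism

Every stochastic step takes an explicit seed (numpy `default_rng`);
`run_all` derives per-stage sub-seeds from the master seed by hashing the
stage name, so any stage can be reproduced in isolation. Identical seeds
yield byte-identical output files; the manifest records a SHA-256 checksum
per artifact.
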