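# Methods

## Problem

Gene-set interpretation usually proceeds by testing individual GO terms for
enrichment, which yields long, redundant lists of highly specific terms.
`gocat` instead lets the analyst define a small number of *categories of
interest*, each seeded by one or more GO terms, and assigns each gene to the
biologically best-fitting categories by exploiting the DAG structure of the
ontology and an information-content (IC) notion of biological closeness.
Category enrichment in a test gene set is then assessed against a background
set with a randomization null model that respects multi-assignment.

## Information content

Annotations are counted under the true-path rule: a record (gene, term) also
counts toward every ancestor of the term reached through `is_a`/`part_of`
edges, at most once per term even when the DAG offers several paths.  With
per-namespace record totals `T_ns`,

    p(x) = count(x) / T_ns,      I(x) = -ln p(x).

Each namespace root therefore has `p = 1` and `I = 0` (annotating with a root
term carries no information).  Per-namespace totals are used rather than a
global denominator precisely so this root property holds when several
namespaces are loaded at once.  The counting unit is the deduplicated
annotation record, not the gene.  Terms absent from the corpus receive the
smallest nonzero `p` of their namespace, i.e. the largest observed IC: an
unused term is at least as specific as the rarest used one.  The log base is
configurable (natural log by default); IC magnitudes are corpus- and
base-specific and only ever enter the similarity through differences and
ratios.

## Semantic similarity for categorization

Categorization is directional: it asks how well a term *belongs under* an
ancestor, not how alike two terms are, so the score is defined only for
ancestor-descendant pairs (plus the identity).  For term `x` and
category-assigned ancestor `p`, with `d(a, b) = |I(a) - I(b)|` and `mic(t)`
the most informative descendant of `t` (`t` itself for leaves; ties broken
by term id):

    alpha = d(root, p) = I(p)
    beta  = (d(p, mic(p)) + d(x, mic(x))) / 2
    gamma = d(p, x)
    S(p, x) = (alpha / (alpha + beta)) * (1 / (1 + gamma)),  0 <= S <= 1.

`alpha` rewards specific anchors; `beta` penalizes anchors (and terms) whose
subtrees still contain much unexploited information; `gamma` penalizes a
large specificity gap between the pair.  S is clamped to [0, 1]; when
`alpha + beta = 0` (a root-level anchor with no informative descendants) the
anchor factor is taken as 1, so `S = 1/(1+gamma)`, and a warning is logged.
"Child terms" in the `beta` definition means all proper descendants, not
only direct children.

## Categorization

Anchors are propagated top-down through the DAG.  Seeds always carry their
category.  A term whose labelled ancestors-or-self fall in exactly one
category is resolved to that category with score 1 and becomes an anchor for
its own descendants; topological processing makes this a single pass, and
the test suite checks it against an order-independent fixpoint reference.
A term whose anchors span several categories is scored per category as the
maximum similarity over that category's anchors (max, rather than mean,
matches selection of the single best-fitting anchor); `best` mode keeps the
argmax category, `multi` mode keeps every category at or above the threshold
while always retaining the argmax.  Argmax ties are broken by lexicographic
category name in `best` mode (logged) and all tied categories are kept in
`multi` mode.

The default threshold is 0.3.  It is calibrated against the typical
similarity of randomly chosen ancestor-descendant pairs (about 0.10 with
spread 0.12 on a large curated corpus), i.e. roughly two spreads above the
random expectation; it is exposed as a CLI flag, and the IC-precomputation
command lets users rebuild the underlying IC table from any annotation
corpus.

A gene's score in a category is the maximum over its annotated terms, with
the supporting term recorded; genes whose annotations reach no category are
reported unclassified.

## Enrichment null model

Multi-assignment makes categories overlap, so a fixed-margin test
(hypergeometric, Fisher) is misspecified.  The null model instead:

1. estimates category probabilities from the background,
   `p(c) = sum_i f_i(c) / sum_c' sum_i f_i(c')`;
2. in each replicate reassigns every background gene its observed number of
   categories `k_i` ("degree"), drawn as `k_i` *distinct* categories with
   probability proportional to `p(c)`;
3. draws `L` genes (the test-set size) uniformly without replacement and
   counts genes per category;
4. over 1000 replicates (default) computes `mu(c)` and `sigma(c)`, then
   `z(c) = (observed(c) - mu(c)) / sigma(c)` with one-sided normal tails for
   enrichment and depletion.

Step 2's sequential sampling without replacement with renormalization is the
Plackett-Luce distribution; it is implemented with the equivalent Gumbel
top-k construction (add iid Gumbel noise to `log p(c)`, keep the `k_i`
largest), which vectorizes over genes and replicates; the tests compare it
distributionally against a literal sequential sampler.  Degree conservation
is asserted inside every replicate.  When `sigma = 0` and the observed count
differs from `mu`, the outcome was never seen in the randomization and the
p-value is reported as `1/reps` with a `degenerate` flag.  Raw one-sided
p-values are primary; Benjamini-Hochberg adjustment is available behind a
flag and off by default.  Unclassified genes keep degree 0 and contribute
only through `L`.

Two properties of this null are worth knowing.  Drawing distinct categories
without replacement does not preserve per-category marginals when degrees
exceed 1 and `p(c)` is non-uniform, so `z` for a full-background test set is
exactly centred only for degree-1 backgrounds (the test suite pins this
down).  And because the observed counts come from an `L`-of-`N` draw without
replacement while the null re-randomizes assignments, observed variance
carries a finite-population factor `(N-L)/(N-1)` the null lacks; for
`L << N` this is negligible and the test is mildly conservative otherwise.

## Evaluation

Gold and predicted multi-label assignments are compared as aligned binary
matrices `G` and `P` over genes × categories:

    accuracy = (1 / (N * N_C)) * sum_g sum_c [G(g,c) = P(g,c)]

counts correct assignment *and* correct non-assignment, so sparse problems
score high by true negatives alone; the Matthews correlation coefficient
over the flattened cells (micro MCC; any zero factor in the denominator
yields 0) is reported alongside, with a macro (per-category mean) variant as
an option.  A uniform random assigner of `k` distinct categories per gene
(default `k = 3`, near the typical multi-assignment degree of about 2.5) is
the chance baseline; its MCC centres on 0.

## Synthetic data

The `fixtures` module provides the package's study conditions:

* `toy_instance` — the eleven-term worked example (root G0; seeds G22 → A,
  G23 → B) with *injected* ICs.  The ICs of G0, G22, G32, G41, G43 and all
  `printed` registry values are the authoritative worked-example numbers;
  the remaining six ICs are synthetic placeholders chosen to respect edge
  monotonicity and preserve the example's categorization outcomes, and are
  deliberately excluded from reference assertions.
* `random_ontology(n, max_parents, seed)` — connected single-rooted DAGs,
  acyclic by construction (each term attaches only to earlier terms).
* `synthetic_corpus(graph, n_genes, ann_per_gene, skew, seed)` — annotation
  corpora with term usage proportional to `exp(skew · depth)`; positive skew
  emulates curators' preference for specific terms.  Defaults (3 annotations
  per gene, skew 1) give realistically leaf-heavy corpora.
* `spike_in_geneset` — positive controls for enrichment.

What the generators do *not* emulate: real GO's size (tens of thousands of
terms), its namespace structure (toy graphs are single-namespace),
evidence-code heterogeneity, and the long-tailed, correlated annotation
patterns of curated corpora.  Passing tests therefore demonstrate
correctness of the algorithms and calibration of the statistics under the
stated generative conditions, not performance on any organism's real
annotation corpus.

## Numerical and testing choices

* Calibration check: background of 800 genes, 6 equiprobable categories,
  degrees 1-3, test sets of L = 60, 1000 replicates, 250 null draws; the
  empirical type-I rate at nominal 0.05 must fall in the binomial 95% band.
  Equiprobable categories with L << N keep the null correctly specified
  (see the marginal-distortion note above).
* Oracle equivalence: count propagation and term categorization are checked
  against naive references (per-record ancestor closure; fixpoint labelling
  with definitional similarity) on 50 random instances of up to ~55 terms.
* Worked-example scores are asserted to ±0.001; component distances to
  printed precision.
* IC table round-trips through TSV at 17 significant digits (`%.17g`),
  which is exact for doubles.
* Ties (most informative descendant, argmax categories) always break
  lexicographically so runs are reproducible.

## Known limitations

* Only `is_a` and `part_of` edges are traversed (the true-path relations);
  `regulates`-family relations are out of scope.
* Obsolete terms are dropped at parse time; annotations to them are counted
  as unresolvable and reported.
* The enrichment p-values rely on a normal approximation to the replicate
  count distribution; for very small expected counts the discreteness makes
  them conservative.
* No multiple-testing correction is applied by default.
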