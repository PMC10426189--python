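# Methods

## Task and model

Gene–disease association prediction is cast as balanced binary
classification over (gene, disease) pairs.  Genes and diseases are not
instances of ontology classes; they are instance entities connected to the
classes that describe them by `hasAnnotation` edges.  All learning signal
therefore flows through the ontology layer, which is why the richness of
that layer — one ontology vs two, with or without cross-ontology links — is
the experimental variable of interest.

### Knowledge-graph variants

Ontologies are merged by subordinating every ontology root (a phenotype
ontology may have several independent subontology roots) to a single virtual
root.  Logical definitions are materialized in the "full" variants as a
two-hop structure (defined class → expression node → each referenced class),
which preserves walkable paths through the axiom; in the "simplified"
variants the axiom collapses to one direct equivalence triple per referenced
function-ontology class.  Mapping records are kept when confidence ≥ 0.8;
the boundary is inclusive.  Triples asserted by both a logical definition
and a mapping are stored once with both provenance tags.  The `LD+Map`
variant is exactly the triple-set union of the `LD` and `Map` variants, and
the test suite asserts this identity.

### Embedding engines

All engines default to 200 dimensions and are deterministic given a seed
under single-threaded execution.

* **rdf2vec** — uniform random walks over the directed triple graph;
  equivalence edges are traversed in both directions, literals are never
  walked.  Sentences interleave predicate tokens between entity tokens.  The
  skip-gram trainer is this package's own vectorized implementation of
  skip-gram with negative sampling: fixed symmetric window, negatives drawn
  from the unigram distribution raised to 3/4, logits clamped to ±6,
  linearly decaying learning rate (0.025 → 1e-4), and down-sampling of
  frequent tokens by the usual √(t/f) rule applied only to tokens with more
  than 100 occurrences so that small corpora are left intact.  Default walk
  budget is 500 walks per start entity (walk methods embed only the
  requested start entities — by default genes and diseases) at depth 4 with
  window 5; these are configuration values.
* **axiom-sentence** — one three-token sentence per triple plus one sentence
  per labelled entity (the entity token followed by its tokenized label),
  fed to the same skip-gram trainer.  This combines structural and lexical
  signal without any pretrained text model and is deliberately tagged
  `axiom-sentence`, not as a reimplementation of any published
  literature-pretrained method.
* **transe** — margin ranking loss (margin 1.0, L2 norm by default), one
  corrupted negative per positive with head or tail replaced uniformly
  (resampling collisions with known triples), entity vectors projected to
  the unit ball each epoch.
* **distmult** — logistic loss on positives vs corrupted negatives with L2
  regularization 1e-4.  Both triple models embed every registered entity.

### Pair representation and evaluation

Binary operators: Hadamard (elementwise product), average, weighted-L1
(|g−d|), weighted-L2 (|g−d|²) preserve the dimension; concatenation doubles
it.  All but concatenation are symmetric in the pair.  Classifiers are a
random forest and gradient-boosted trees with a small inner grid search run
on a single stratified 80/20 split of each training fold (grids are
configuration, not code; the probability cut-off is 0.5 on balanced data),
plus a similarity baseline that thresholds the cosine of the raw gene and
disease vectors, the threshold learned on the training folds over a grid of
101 values in [−1, 1] (smallest maximizer on ties).  Zero-norm vectors get
similarity 0.

Evaluation is stratified 10-fold cross-validation; the fold plan is computed
once per dataset and reused across every condition so per-fold metrics are
paired.  The headline metric is the support-weighted average of per-class
F-measures (WAF), reported per fold and as a median.  Two runs sharing a
fold plan are compared with a two-sided Wilcoxon signed-rank test on the
per-fold WAFs at α = 0.05 (exact distribution at k = 10; zero differences
dropped; all-tied comparisons report p = 1).  The test is a concrete choice
of paired test where the protocol requires one without naming it.

### Dataset construction

Association records whose *every* provenance source is in the banned set
(default: the curation pipelines that also feed ontology annotations) are
dropped; records with at least one independent source, or with no recorded
source, are kept.  Coverage filtering keeps pairs whose gene has ≥1
phenotype and ≥1 function annotation and whose disease has ≥1 phenotype
annotation.  Negatives are sampled uniformly without replacement from the
(positive genes) × (positive diseases) grid minus the positive cells — no
degree matching — to exact balance, so 8,189 positives always yield 16,378
pairs.  Branch ablation removes (or keeps only) annotations whose class lies
under a branch root by `is_a` subsumption; classes themselves are never
removed.

## The synthetic generator

`FixtureSpec` generates two rooted DAG ontologies with disjoint prefixes
(`HPX` with five branch roots, `GOX` with three), genes annotated to both,
diseases to the phenotype ontology only, and `n_cross_links` planted
equivalences emitted both as logical definitions (Turtle) and as mapping
records with confidences uniform in [0.5, 1].  Defaults: 150 phenotype
classes, 80 function classes, 200 genes × 100 diseases, 2 phenotype + 12
function annotations per gene, 10 phenotype annotations per disease, 80
cross-links.

Two deliberate asymmetries mirror the real resources:

* one phenotype branch is **dominant** — it accrues ~60 % of classes and
  ~90 % of phenotype annotations, as the phenotypic-abnormality branch does
  in the real ontology, where the vast majority of disease annotations live;
* all planted cross-links lie under that dominant branch, so ablating it
  removes the cross-ontology signal entirely.

Each pair's score is `w_direct · |shared phenotype annotations| + w_cross ·
|disease phenotype classes whose link partner is annotated to the gene| +
logistic noise` (scale 0.15).  Labels follow a **per-disease top-k** rule:
each disease is positively associated with its `k = positive_rate ·
n_genes` best-scoring genes (default k = 8).  This mirrors how curated
catalogues list a handful of causal genes per disease and keeps the
per-disease positive count constant, so a classifier cannot score above
chance by memorizing how often a particular disease appears positive — a
real hazard when negatives are sampled uniformly.  A global-quantile rule is
available as an alternative.  Per-stage independent RNG streams (ontology,
links, annotations, noise) guarantee that removing the cross-links perturbs
nothing else, which the tests exploit.

What the generator does **not** emulate: realistic ontology topology
statistics, evidence codes, literature provenance, annotation-frequency
distributions, or inter-gene correlation structure.  Passing benchmarks on
these bundles therefore demonstrates that the pipeline recovers the kinds of
relational signal it plants — not that any particular WAF level would be
attained on real ontology releases and association catalogues, whose
absolute results depend on the specific data versions.

## The benchmark study

`ontogda.benchmark.cross_signal_study` fixes the study conditions: the
default bundle with `w_direct = 0` (signal reachable only through the
links), one balanced dataset and one 10-fold plan shared by all runs, and
three graph conditions — single ontology (`HPf`), link-enriched
(`HPs+GO+LD`), and link-enriched with the signal branch's annotations
removed.  Embeddings are random-walk skip-gram at 200 dimensions with 150
walks per start entity (classes included as walk starts), depth 2, window 2,
10 epochs — short walks with a tight window concentrate co-occurrence mass
on annotation classes and their equivalence partners, where the planted
signal lives, and keep the study inside a single-CPU budget.  The readout is
the cosine-similarity pipeline: the planted signal is a global alignment
between gene and disease vectors, which the similarity baseline measures
directly, and a similarity readout cannot exploit entity-identity
memorization, making the single-ontology control a clean chance-level
reference.  Tree-model readouts remain available through the same API and
are exercised elsewhere in the test suite.

## Numerical and design notes

* CURIEs are canonicalized to `PREFIX:LOCAL` with the prefix uppercased;
  gene and disease identifiers are taken verbatim.
* Annotations to obsolete or unknown classes are routed to a row-level
  rejects report, never silently dropped; accepted + rejected = input rows.
* GAF rows with a `NOT` qualifier are excluded (standard practice); all
  evidence codes are accepted unless an allow-list is supplied.
* Logical definitions referencing several target-prefix classes emit one
  simplified triple each; `owl:onProperty` objects are properties and are
  never treated as referenced classes.
* Concatenation is implemented as true vector concatenation (size 2·dim).
* The transitive closure of `is_a` is not materialized before embedding;
  walks traverse asserted edges only.
* Isolated start entities emit singleton walks so that a vector always
  exists for every dataset entity, including after extreme ablations.
* Random draws all trace to explicit seeds (numpy `SeedSequence` spawning
  inside the generator); identical configs reproduce byte-identical
  datasets, fold plans and corpora.

## Known limitations

* The skip-gram and triple-model trainers are plain SGD in numpy: adequate
  for graphs up to tens of thousands of triples, not engineered for
  full-size ontology releases.
* The cosine baseline's threshold grid assumes similarities in [−1, 1];
  degenerate embeddings concentrated near a point can make the learned
  threshold uninformative.
* Wilcoxon at k = 10 folds has limited power; only large, consistent
  differences reach significance, which is the conservative direction.
* The leakage filter is provenance-based only; it cannot detect leakage
  through sources absent from the record's source list.
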