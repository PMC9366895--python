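# Methods

This note documents the models, numerical choices and synthetic study
conditions implemented in `phenosim`, and what the synthetic experiments
do and do not establish about real data.

## Ontology model

A phenotype ontology is a directed acyclic graph of classes with subclass
(`is_a`) edges. Cross-species integration declares classes from different
species-specific vocabularies *equivalent*; we realize equivalence by
union-find merging onto a canonical representative (the lexicographically
smallest member), rather than by reciprocal subclass edges. This makes
ancestor sets — and therefore the most informative common ancestor — well
defined across species: every member of an equivalence set shares one
ancestor closure. Labeled relation edges (part-of, results-from, during,
has-quality, has-central-participant, occurs-in, towards) are stored and
exported to the embedding graphs but never enter the taxonomic closure;
Resnik similarity deliberately uses only the taxonomy.

Abnormal-anatomy phenotype classes ("phenotypic abnormality of wing") are
represented structurally as a (entity, quality, Abnormal) pattern rather
than as rendered logical axioms: all downstream computation consumes only
the graph structure the pattern induces. The construction is idempotent,
places new classes under a per-species abnormality root, and mirrors the
anatomy hierarchy where abnormal counterparts of an entity's parents
already exist. Anyone porting real description-logic axioms should treat
this structural pattern as a stand-in for the full logical form.

Class depth is **longest-path** depth in the canonical DAG. An earlier
draft used ancestor-set size, which double-counts both species' superclass
chains for bridged classes and silently distorts any depth-weighted
computation; longest-path depth is invariant under equal-depth equivalence
merging.

The OBO flat-file subset reader is backed by `obonet`, with an added raw
duplicate-id check and two equivalence encodings: an `equivalent_to` tag
(not part of OBO 1.2, but unambiguous) and paired reciprocal `is_a` edges
as a portable fallback.

## Information content and similarity

IC(c) = −log₂ p(c), where p(c) is the fraction of entities whose
*propagated* (ancestor-closed) annotation set contains c. Log base 2 only
fixes the unit (bits); rankings are scale-invariant. p is computed over
the union of the organism gene corpora and the disease corpus, each entity
counted once: the merged cross-species ancestors then receive frequency
from both sides, which is what makes them usable as informative common
ancestors. Classes never annotated are absent from the table and excluded
from MICA candidacy (rather than given infinite IC), keeping scores finite;
two classes sharing only such ancestors score 0.

Set-level similarity is the symmetric best-match average over the **direct**
annotation sets — the MICA search already walks the closure, so using
propagated sets would double-count it. Empty sets (entities without
informative phenotypes) score 0 with a logged warning instead of raising;
such genes simply rank at the bottom.

## Embedding methods

Three corpus flavors approximate the published graph/axiom embedding
procedures with their stated hyperparameters (walk counts and lengths,
windows, mincounts, negatives, embedding size 100). The axiom-sentence
flavor uses class labels as auxiliary text only; no definition text mining
is attempted. The skip-gram with negative sampling trainer is a numpy
implementation: unigram^0.75 noise distribution, linearly decaying learning
rate, mini-batched updates whose per-token gradients are *averaged* over
duplicate indices within a batch (a summed update multiplies the effective
step size and diverges on small vocabularies), and masking of negative
samples that accidentally hit the true context (irrelevant at realistic
vocabulary sizes, decisive at toy sizes). Exposed vectors are the sum of
input and output embeddings, so first-order co-occurrence — which the
training objective stores in the input·output inner product — is visible
to cosine similarity even after short training. Training is exactly
reproducible for a fixed seed in single-worker mode.

## Supervised link prediction

The predictor is scikit-learn's MLPClassifier on concatenated
(gene ‖ disease) vectors: one hidden layer of half the input width,
logistic output, Adam with learning rate 0.001, full-batch, up to 300
iterations (the convergence tolerance is lowered so the full budget is
actually used), 5 negatives sampled per positive without replacement
within a disease, re-sampled per fold. Cross-validation partitions
**diseases** into 10 folds, so a held-out disease never contributes any
pair to training; an alternative mode partitions individual associations
instead (a disease's scores are then averaged over the folds holding out
one of its associations). The disease-holdout reading prevents leakage and
matches the per-disease ranking evaluation; the fold audit (no training
pair involves a held-out disease) is part of the test suite.

## Evaluation protocol

Per disease, all genes are ranked (ties broken by ascending gene id for
determinism); TPR and FPR are recorded at every rank cutoff k ∈ {0..n}.
Curves are macro-averaged pointwise on this shared rank grid — not
interpolated onto an FPR grid — which is exact when every disease ranks
the same gene universe. AUC is the trapezoid area; on a single disease it
equals the Mann–Whitney statistic, an equivalence asserted in the tests.
Diseases whose associated genes all lack annotations cannot be ranked and
are dropped with a logged count. Method comparison uses a paired bootstrap
over diseases (resample diseases with replacement, recompute both macro
AUCs, two-sided p from the difference distribution with add-one
smoothing); the choice of a bootstrap is ours — the underlying analysis
this package operationalizes does not name its test.

## Bias diagnostics

`total_ic` sums each gene's direct-annotation IC (canonicalized first:
the IC table is keyed by canonical ids, and an annotation to a bridged
class must resolve to the merged class's IC — an early version missed this
and silently zeroed bridged annotations). `study_bias_test` is a classic
equal-variance unpaired t-test, one-tailed with the disease-gene group
hypothesized higher.

The IC gap of a model-organism class c is |IC(c) − max IC(h)| over human
superclasses h of c, reflexively — a class bridged to a human class by
equivalence has gap 0 — and 0 when no human superclass exists. Per-gene
aggregation is the sum over direct annotations (a mean option exists);
the sum matches the per-gene "total IC" framing of the study-bias probe.

## Synthetic study conditions

The generator emulates the statistical structure of an integrated
cross-species phenotype resource:

- **Trees.** One shared root; a human and a model subtree grown by seeded
  preferential branching (attachment weight = children + `branching`,
  default 3), giving bushy trees of depth ≈ 2–14. Default 800 classes per
  species: large enough relative to the annotation volume that class
  frequencies stay low and IC is informative (on much smaller vocabularies,
  annotation mass erodes the IC of exactly the classes it concentrates on).
- **Bridges.** When any bridging is enabled the two species roots are
  equivalenced (every integrated resource relates at least its top-level
  phenotype classes; without this, unbridged model classes would have *no*
  human superclass and the IC gap would be undefined rather than large).
  A `bridge_fraction` of model classes — selected with probability
  decaying in depth, since equivalences exist mostly for general,
  homologous structures — are made equivalent to human classes of exactly
  equal depth. Equal-depth merging keeps every subclass edge strictly
  depth-decreasing, so the merged graph is acyclic by construction.
- **Annotations.** Diseases receive ~Poisson(6) human classes, sampled
  with probability proportional to depth (specific classes carry the
  information). Each disease has one associated gene; its model ortholog
  mirrors each disease phenotype with probability `fidelity`, via the
  model member of the phenotype's deepest bridged ancestor (sometimes
  descending one child step). Non-associated genes draw ~Poisson(6)
  uniform random model classes. At fidelity 0 associated genes are
  statistically identical to the rest — the null is exactly
  label-independent.
- **Study bias.** `bias_multiplier` m inflates associated genes' target
  annotation counts m-fold. `depth_bias` s refines each of their random
  draws ~s child steps down the tree — modeling curators of well-studied
  genes recording the more specific term. Refinement follows the tree's
  own branching, so it deepens annotations without concentrating them on
  a small set of classes; a global depth-power reweighting was tried and
  rejected because it concentrates draws on the deep tail, erodes those
  classes' frequency-based IC, and cancels (or reverses) the intended
  effect. Even with refinement, the depth knob *alone* moves the mean IC
  gap only weakly — the biased draws still lower the IC of the classes
  they hit — so the IC-gap contrast is demonstrated under the full bias
  (m = 3 with depth refinement), which is also the configuration that
  mirrors real disease-gene orthologs ("more, and more specific"
  annotations). The gap experiment uses 2000-class vocabularies and
  sparse bridging (0.3), the regime of a distant organism whose anatomy
  is mostly unbridged.
- **Truth and orthology.** One gene per disease; a 1:1 human↔model
  orthology table is emitted, and the truth table references model gene
  ids directly (the 1:1 map makes the human-gene indirection redundant,
  while the table still exercises the orthology file format and the
  combination machinery).

Problem sizes for the shipped experiments — 300 genes × 100 diseases for
signal recovery and the naive-classifier probe, 400 × 200 for the IC-gap
groups, 200 × 500 for the random-ranking calibration — are chosen so that
each experiment completes in seconds while the relevant test statistics
are far from their decision boundaries.

**What passing these experiments does not show.** The generator's trees
are random, annotations are conditionally independent given the knobs,
diseases have a single associated gene, orthology is 1:1 and complete,
and there is no correlation structure between phenotypes (no body-system
modules, no pleiotropy, no shared etiology between diseases). Results
establish that the pipeline's machinery behaves correctly and that the
bias mechanisms are sufficient to produce the qualitative phenomena; they
do not quantify how strong those phenomena are in any real corpus.

## Supervised sanity constructions

The separable benchmark places each associated gene's vector at its
disease's vector plus a constant offset (‖offset‖ = 4, dimension 16, 40
diseases, 800 genes). Matching a specific gene to a specific disease is
inherently bilinear, so a held-out evaluation of *any* classifier on this
construction has a ceiling set by the other offset genes; the chosen sizes
keep that ceiling comfortably above the asserted 0.95. The null replaces
gene vectors with independent noise while keeping the label structure;
held-out performance is asserted at chance as a mean over repeats, since a
single 40-disease macro average has a standard error of ≈ 0.05 on its own.

## Known limitations

- The axiom-sentence flavor uses labels only; no NLP over definitions.
- OPA2Vec/DL2Vec/OWL2Vec* are re-implemented approximations (shared SGNS
  core), not the published codebases.
- The significance procedure for AUC differences (bootstrap) is a design
  choice; other resampling schemes are defensible.
- Multi-gene diseases, incomplete orthology and allele-level rollup are
  out of scope of the generator's default truth structure.
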