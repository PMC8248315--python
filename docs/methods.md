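# Methods

## Axiom model and transformation

The package consumes subclass and equivalence axioms whose subject is a
named class and whose right-hand side is a chain of quantified relations
over a filler that is either a single class or a *flat* union or
intersection of classes. Three dialects parse into this model:
a `tsv_simple` dialect designed so tests and fixtures never need an OWL
toolchain, OBO 1.4 (through `obonet`; `is_a`, `relationship`,
`intersection_of`/`union_of` tags), and OWL 2 functional syntax through
a small reader restricted to the same fragment. Boolean fillers nested
deeper than one level, axioms with complex subjects, and OBO
intersections with relational differentia are outside the fragment;
they are counted and logged, never silently dropped, so
`parsed + skipped` always equals the number of logical records.

Transformation: an axiom with an empty chain and a named filler yields
one `SubClassOf`/`EquivalentTo` triple. Any axiom with a non-empty
quantifier chain yields one triple per filler member, with the chain's
relation names joined by `.` into a single edge-label token
(`has-part.part-of`). Design choices worth noting:

* Existential, universal and cardinality restrictions map to identical
  edges, and cardinality numbers are discarded; the graph deliberately
  ignores restriction semantics.
* Equivalence axioms with complex right-hand sides are transformed by
  the same rule as subclass axioms.
* A chain-less *boolean* filler (`A ⊑ B₁ ⊔ B₂`) is handled by the
  natural extension — one `SubClassOf`/`EquivalentTo` triple per
  member.
* The graph has set semantics: repeated assertions carry no weight.
* No reasoning is performed and no transitive closure is taken;
  asserted axioms only.

## Walks and embeddings

The graph is traversed as undirected: each directed triple is listed in
the adjacency of both endpoints with its forward label (no inverse
markers). Walks are first-order and uniform over the incident-edge
multiset, with immediate backtracking allowed and no restart. A walk of
*k* steps emits up to 2k + 1 tokens, alternating nodes and edge labels;
it ends early only at an isolated node. Defaults are 80 walks of 20
steps per node, switched to 200 walks of 30 steps when interaction
edges are present (higher node degree). Each start node draws from its
own RNG stream derived from `(seed, node index)`, so corpora are
byte-identical for a fixed seed regardless of generation order.

Embeddings are trained with skip-gram and negative sampling implemented
in a single-threaded numba kernel (classic word2vec layout: per-position
reduced window, unigram^0.75 noise distribution, 5 negatives, linear
learning-rate decay 0.025 → 1e-4). Defaults: window 10, min_count 1,
20 epochs, 200 dimensions. Determinism is exact for a fixed seed
because training is single-threaded with a counter-based RNG; this
trades away multi-core speed for reproducibility. Edge-label tokens are
embedded alongside nodes but only node vectors feed the ranker.

## Ranking model

The scorer is a two-tower pointwise model: each tower applies two
linear layers (widths 256 then 50), each followed by dropout 0.2 and a
leaky rectifier (slope 0.01; note that dropout-then-LeakyReLU and
LeakyReLU-then-dropout are mathematically identical because the
activation is positively homogeneous and maps zero to zero). The score
is the sigmoid of the inner product of the two tower outputs, trained
with binary cross-entropy and Adam (batch 128), 20 sampled negatives
per positive, early stopping on validation loss (patience 10, max 200
epochs). Input embeddings are L2-normalized.

**Initialization.** With abundant supervision a randomly initialized
metric network is forced toward a transferable similarity function, but
with few known associations (the synthetic benchmark trains on ~100
positive pairs) gradient descent reaches the class-prior loss by
near-collapse of the tower outputs and then memorizes the training
diseases — validation loss on *unseen* diseases never improves, even
though a one-parameter logistic model on embedding cosine separates the
classes almost perfectly. The default initialization therefore makes
the network *start* as a calibrated similarity function:

* the first layer stacks an orthonormal map `M` with its negation, so
  `leaky(Mx) − leaky(−Mx) = (1 + slope)·Mx` makes the tower exactly
  linear at initialization;
* the second layer maps back through the leading principal directions
  of the (unit-normalized) input embeddings — computed unsupervised
  from the training pairs — so the initial score is
  `σ(s·⟨Pg, Pd⟩ + b)` with `P` the top-(49) PCA projection, `s = 10`,
  `b = −3` (one output coordinate is reserved for the constant bias
  pair);
* the freshly initialized model is itself an early-stopping candidate,
  so training can only keep weights that beat it on validation loss.

Both towers start from the same weights but remain independent
parameters throughout training. Plain He initialization is available
via `init="random"`. The default learning rate is 1e-4 — small, so
refinement of the informed initialization does not destroy it before
the validation signal can arbitrate.

**Protocol.** Cross-validation is split by disease identity, never by
association pair: 10 folds, each disease in exactly one test fold;
within a fold the non-test diseases are split 90/10 into train and
validation (also by disease). Negatives are drawn once per fold
(seeded), uniformly without replacement from the genes not known
positive for the disease. A leakage assertion verifies test diseases
never enter training. Scoring at evaluation time is deterministic
(dropout off).

## Evaluation

Per disease, all candidate genes (by default every gene in the
evaluated universe) are ranked by score, ties broken by ascending gene
id. The macro ROC curve averages per-disease TPR and FPR at each rank
of the shared candidate grid and takes the trapezoid area; per-disease
areas use the Mann–Whitney identity `AUC = U/(n₊·n₋)` with average
ranks for ties. Hits@n is the fraction of true associations whose gene
ranks ≤ n. The cross-validation interval reported alongside the ROCAUC
is the min–max over fold-level macro areas. Model comparison is a
two-sided Mann–Whitney U test on true-positive ranks (exact for small
tie-free samples, asymptotic without continuity correction otherwise,
so identical inputs give P = 1.0), read against the conventional 0.05
threshold.

## Synthetic benchmark

The generator builds three subclass trees of 200 classes each
(branching 3) standing in for phenotype, function and anatomy
ontologies, plus 80 cross-ontology defining axioms in entity–quality
style on randomly chosen phenotype classes, cycling through three
shapes (`∃has-part.F`, `∃has-part.(F ⊔ A)`, `∃has-part.∃part-of.A`) so
unions and quantifier chains are all exercised. 40 diseases receive 6
phenotype annotations each; 300 genes receive 6 function/anatomy
annotations each; each disease has 3 causal genes (the gold standard).
A `signal` fraction of a disease's annotations are cross-axiom
phenotypes and its causal genes are annotated to those axioms' filler
classes, so at signal 1 every gold pair is linked by an axiom path of
length ≤ 3; `noise` appends a corresponding fraction of uniformly
random annotations to every entity. Defaults: signal 0.8, noise 0.2.

All *non-noise* annotations — including those of decoy genes and the
random annotations of diseases — are drawn from the same cross-axiom
class pools, so causal and decoy entities have matched annotation
marginals. This matters for the negative controls: if only causal
genes touched the cross-axiom region of the graph, they would be
generically closer to every disease and a label-shuffled control would
sit well above chance for reasons unrelated to the planted pairing.
With matched marginals the shuffled control and the signal-0
configuration both measure at chance (≈ 0.5).

What the generator does not emulate: realistic ontology size or depth,
annotation frequency bias, degree distributions, or correlated
annotations between related genes. Passing the benchmark shows the
pipeline recovers axiom-mediated relational signal under clean
conditions; it does not certify real-data performance.

## Benchmark problem sizes

The full-scale regime (80 walks × 20 steps, 200-dimensional vectors,
20 skip-gram epochs) is the module default and is what a real-data run
would use. The end-to-end benchmark protocol (`PipelineConfig`) uses
20 walks of 20 steps per node, window 10, 100-dimensional vectors and
5 skip-gram epochs on the ~940-node synthetic graphs, which recovers
the planted signal with margin while keeping the full 3-seed ×
4-condition benchmark suite to roughly ten minutes of single-core
compute. These are the sizes used by `scripts/acceptance.py` and the
acceptance tests.

## Degenerate inputs and numerical notes

Empty graphs and corpora produce warnings and empty outputs rather than
errors; an empty corpus cannot be embedded (error). Negative TPM values
and malformed axiom records are hard errors naming the line. Logits are
clipped at ±30 before the sigmoid; BCE uses an epsilon of 1e-12.
Diseases without positives (or without negatives) are excluded from
evaluation with a warning. Score ties are resolved by a stable sort on
gene id wherever an explicit ordering is required, and by average ranks
inside U statistics.

## Known limitations

* The approach is transductive: embeddings must be retrained to score
  entities not present in the graph.
* Skip-gram training is single-threaded by design (determinism); large
  real-data corpora would need hours, not minutes.
* The OWL functional reader covers only the transformed fragment; it is
  not a general OWL parser.
* No hyperparameter search is performed; "tuning" is epoch selection on
  validation loss only.
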