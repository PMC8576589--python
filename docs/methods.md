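# Methods

## Problem setting

Literature-derived biomedical knowledge graphs (KGs) are built by NLP systems
that extract `[subject-predicate-object]` predications from text. Extraction
is noisy: concept mapping fails, sentences are misparsed, and rare assertions
may be wrong. Unlike curated databases, however, these stores attach
confidence metadata to every predication — a subject and object mapping score
(how confidently a text span was mapped to the stated concept, on a 0–1000
scale in SemMedDB-style stores) and a co-occurrence count (how many times the
triplet was extracted). `confkg` treats this metadata as a first-class signal
during graph representation learning and evaluates whether doing so improves
two downstream tasks: drug–adverse-drug-event (ADE) pair prediction and
polypharmacy side-effect prediction.

## Models

### Triplet confidence weight

Every aggregated predication receives the raw weight

    W = (w_j · s_subj) · (w_i · s_obj) · (w_p · c)

with tunable nonnegative multipliers `w_j, w_i, w_p` (default 1; an optional
grid-search utility selects them by downstream validation score). Zero scores
are lifted to `score_floor` (default 1e-6) so no triplet ever has weight
exactly zero. Raw weights are max-normalized over the whole graph,

    f = W / max(W)  ∈ (0, 1],

using a single global denominator computed before any training. The raw
products can be enormous (the observed maxima of a real predication store —
1000, 1000 and 33,478 — give W ≈ 3.3×10^10), and a global constant keeps
softmax comparisons consistent across neighborhoods while taming the scale.

### Weighted DeepWalk

DeepWalk generates, for each vertex, N random walks of up to L vertices, and
feeds the token sequences to skip-gram negative sampling (SGNS). Two changes
produce the weighted variant:

1. **Edge-aware neighborhoods.** The unit of traversal is a
   (predicate, neighbor) pair, so the same neighbor reached through two
   different predicates counts as two distinct next-step outcomes. This
   handles heterogeneous KGs without fixed metapath schemes.
2. **Confidence-biased sampling.** At each step the next pair is drawn from a
   softmax over the `f` values of the current neighborhood,
   `p_k ∝ exp(f_k / T)`, instead of uniformly. Walks therefore spend more
   time on well-supported predications. The temperature `T` (default 1) is
   exposed for sensitivity analysis only.

Because `f ∈ (0, 1]`, the softmax odds ratio between the best and worst
entry of a neighborhood is at most `e ≈ 2.7`: the bias is deliberately
gentle, reweighting rather than pruning.

Learned vectors are L2-normalized to unit norm before downstream use, so
cosine similarity equals the dot product.

The SGNS trainer is a vectorized numpy implementation of minibatch SGD on
the standard objective (sigmoid loss with k noise tokens drawn from the
unigram^0.75 distribution, dynamic window, linear learning-rate decay). It is
deterministic given its seed, and its vocabulary is ordered by
(frequency, first occurrence), which makes training equivariant under token
relabeling — a property the test suite asserts on the pairwise cosine matrix.

### Weighted TransE

TransE embeds entities and relations so that `h + l ≈ t`, minimizing the
margin-ranking loss over corrupted triplets (head *or* tail, never both,
replaced by a random entity):

    L = Σ [ γ + d(h+l, t) − d(h'+l, t') ]_+

The weighted variant divides the energy of the true triplet by its
confidence:

    L_w = Σ [ γ + d(h+l, t)/f − d(h'+l, t') ]_+

with `f` clipped to `[f_min, 1]` (default `f_min` = 1e-3) before the
division. With all `f = 1` this reduces bit-for-bit to the unweighted loss.
Entities initialize uniform in `[−6/√k, 6/√k]` and are renormalized to unit
L2 after every update step; relations are normalized once at initialization.
The margin defaults to 1 and the dissimilarity to L2 (L1 available).

**A known tension, on purpose.** Dividing the positive energy by `f` makes a
*low*-confidence triplet's effective energy larger inside the hinge, so the
optimizer works *harder* to fit exactly the triplets one would want to
discount, with gradient scale `1/f`. On the bundled synthetic benchmark,
where spurious triplets have `f ≈ 0.005` and true ones `f ≈ 0.3`, this
inverts the intended bias: spurious triplets receive ~60× the gradient mass
of true ones, training never converges (the epoch-mean loss stays flat or
rises at every learning rate tried), and Weighted TransE *underperforms* its
unweighted baseline by a wide margin (held-out AUC ≈ 0.46 vs ≈ 1.00 across
five generator seeds). The division form is nevertheless the reference
behavior of this package because it is the stated formulation; a
`multiply_by_f` ablation flag implements the alternative `d·f` reading
(which relaxes, rather than tightens, the target for low-confidence
triplets) and is off by default. At matched hyperparameters the ablation
merely rescales the effective learning rate by `f` and is similarly
undertrained, so neither form beats unweighted TransE on this benchmark —
see Limitations.

### Downstream pipelines

Features are plain concatenations of unit-norm embeddings: drug ⧺ disease
(length 2·dim) for ADE pairs, drug1 ⧺ drug2 ⧺ side-effect (length 3·dim,
e.g. 300 at dim 100 and 768 at dim 256) for polypharmacy triples, with
unordered drug pairs canonicalized lexicographically. Concepts lacking an
embedding are removed (and reported) before feature construction.

Classifiers are pinned configurations: logistic regression with L1
regularization, k-nearest neighbors with k = 5, and random forest with the
information-gain (entropy) criterion; the polypharmacy forest uses 100 trees
with maximum depth 20. Every hyperparameter is written out explicitly so
results do not drift with library-version default changes.

Cross-validation: leave-one-out (LOO), stratified 5-fold (S5F, folds seeded
once per experiment so all methods share them), and a cross-dataset protocol
(train on one full dataset, evaluate on the other's five stratified folds).
For LOO the singleton test predictions are pooled and scored once, since
per-fold AUC is undefined at test size 1; S5F reports per-fold metrics with
mean and SD.

Metrics: F1 on the positive class at probability threshold 0.5 (no threshold
is otherwise implied by the task), AUC with midrank tie handling, AUPRC as
the step-wise integral of the precision-recall curve (average precision),
and AP@50 = Σ_{i≤50} precision@i · rel(i) / min(50, #positives) over the
descending score ranking. Invalid polypharmacy triples are drawn uniformly
from the unordered-drug-pair × side-effect space, excluding all known
triples. The occurrence score of a triple counts the triples sharing its
drug pair regardless of side effect; when valid triples are converted to KG
predications for representation learning, that count becomes the
co-occurrence and the subject/object scores are set to 1.

## Synthetic benchmark

The generator emulates the one property of literature-derived KGs this
package is about: *confidence scores correlate with truth*. Concepts
(50 drugs, 10 diseases, 100 filler concepts by default) are assigned
round-robin to causal blocks; true predications connect two concepts of the
same block under one of 4 predicates, spurious ones connect uniformly random
concepts. Scores are drawn conditionally: true triplets get mapping scores ~
Uniform[600, 1000] and co-occurrence ~ 1 + Poisson(8); spurious ones
Uniform[50, 400] and 1 + Poisson(1). The triplet budget is
`round(edges_per_vertex · n_vertices)` with exactly `noise_rate` of it
spurious (budgeted, not sampled, so counts are deterministic). Benchmark ADE
pairs are labeled positive iff drug and disease share a block, 100 per class
by default. Everything derives from one seed; exports are byte-reproducible.

Two generator parameters are free calibration choices rather than emulated
statistics: 2 blocks and 12 edges per vertex. They were set so that the
planted signal is recoverable by the *unweighted* baseline (uniform DeepWalk
+ random forest reaches held-out AUC ≈ 0.75, five-seed mean, at the default
30% noise) while leaving the task nontrivial — a benchmark saturated at
AUC 1.0 or stuck at chance could not measure the weighted-vs-unweighted
difference in either direction.

What the generator does **not** emulate: real predicate semantics, the
heavy-tailed degree and co-occurrence distributions of literature KGs
(where most triplets are extracted exactly once and the confidence scale is
effectively binary after clipping), correlated extraction errors, or
false-negative edges (absence noise arises only implicitly from the finite
edge budget). Passing the directional test here shows the machinery exploits
truth-correlated confidence when it exists; it does not certify gains on any
real corpus.

## Desk-scale profiles and problem sizes

The shipped `drug_ade_*` and `polypharmacy_*` profiles carry the full-scale
settings (e.g. ADE DeepWalk: N = 20, L = 500, window 4, dim 256, α = 0.025;
ADE TransE: α = 0.001, batch 256, 100 epochs, 1 negative, dim 100; the
`semmeddb_augmented_*` profiles — N = 375 or 1500 epochs with 2 negatives —
are cluster-scale). The bundled benchmark uses `synthetic_*` profiles chosen
as this package's own desk-scale study conditions: DeepWalk keeps N = 20 and
window 4 but shortens walks to L = 40 and the dimension to 64 for a
160-vertex graph; TransE keeps batch 256 and 1 negative at dimension 32,
with the learning rate raised to 0.01 over 60 epochs because at this scale
α = 0.001 leaves the epoch-mean loss visibly unconverged (learning rates
were compared on training loss only, the same selection rule used for the
full-scale settings).

## Numerical choices

- Softmax is computed with max-shift; probabilities sum to 1 within 1e-12.
- Duplicate (s, p, o) records aggregate by summing co-occurrence (a count)
  and maximizing mapping scores (confidences).
- Undirected traversal is the default graph mode — each triplet is mirrored
  so walks never strand at sink objects; directed mode is a flag, and walks
  hitting a directed dead end terminate early rather than restart.
- Walk RNG streams derive from (seed, start-vertex index, walk index), so
  corpora are reproducible regardless of iteration order.
- L2-gradient of the energy uses `diff / max(d, 1e-12)` to avoid division by
  zero at perfect translations.
- Embedding files round-trip at 12 significant digits; unit norms survive
  re-reading to within 1e-9. Triplet TSVs write scores with full float
  precision (`repr`) so synthetic exports round-trip exactly.
- The embedding-table vocabulary check rejects duplicate tokens; zero-vector
  normalization errors name the offending token.

## Limitations

- The Weighted TransE division form does not converge when confidences span
  a wide ratio (see above); on the bundled benchmark the weighted-vs-
  unweighted comparison for the TransE family fails in the weighted
  direction, and the corresponding end-to-end test documents this honestly
  rather than passing. The Weighted DeepWalk comparison shows the expected
  small positive mean improvement under noise and no detectable difference
  on noise-free graphs.
- The unweighted TransE baseline saturates (AUC ≈ 1.0) on the default
  synthetic benchmark; even a well-behaved weighting could not measurably
  improve on it there.
- SGNS and TransE trainers are single-stream implementations; they are
  exactly reproducible but do not exploit multiple cores.
- The softmax bias over max-normalized scores is bounded (odds ratio ≤ e per
  neighborhood entry), so weighted walks shift visit mass only moderately;
  large effects require large confidence separations.
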