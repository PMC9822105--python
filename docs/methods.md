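# Methods

## Problem setting

Given per-protein embedding vectors from a pre-trained protein language
model and a corpus of proteins with experimental GO annotations, predict
per-term confidence scores for unannotated queries, one GO aspect
(MF/BP/CC) at a time. Embeddings are consumed as opaque `3 × D` arrays —
three views per protein, intended as the mean-pooled outputs of the
model's final three hidden layers (for ESM-1b-style models, layers 31–33
with `D = 1280`; any fixed-width representation works). The package never
runs a language model itself.

## Ontology handling

The GO DAG is read from OBO 1.2/1.4 (via obonet), keeping `is_a` and
`part_of` edges only. `part_of` is included alongside `is_a` by default —
the GOA propagation convention — and is configurable by filtering the
input ontology. Obsolete terms are dropped, `alt_id` accessions map to
their canonical ids, cross-aspect edges are discarded, and acyclicity and
root-reachability are verified at parse time.

Annotations obey the **true-path rule**: `propagate_annotations` closes
every protein's term set under the parent relation. Aspect roots
(`GO:0003674`, `GO:0008150`, `GO:0005575`) are excluded from propagated
sets, predictions and evaluation by default (`include_root` restores
them); carrying the root would hand every predictor one free
true-positive per protein and, symmetrically, hierarchical
post-processing would hand every predictor one systematic false positive.

Prediction scores are made hierarchically consistent by child-max
propagation in reverse topological order:
`s(q)_post = max(s(q), max_children s(child)_post)`. Terms absent from a
score vector are implicit zeros, so a confident child lifts an unscored
parent. The operation is idempotent, never decreases a score, and
guarantees parent ≥ child on every edge.

Term **information content** is the standard negative log relative
annotation frequency over the propagated training corpus,
`IC(q) = −log₂(n_q / N)` (base configurable). Terms never seen in
training answer with a ceiling `−log₂(1/(N+1))` — the IC a term would
have if observed once in a corpus one protein larger — so unseen terms
are treated as maximally informative rather than breaking weighted sums.

## Functional similarity and triplet supervision

Protein-pair functional similarity is the F1 overlap of the two
propagated term sets, `2|a∩b| / (|a|+|b|)`, with Jaccard and IC-weighted
variants (`weighted_f1`, `weighted_jaccard`) replacing cardinalities by
IC sums. Two proteins are *same-function* when similarity strictly
exceeds the cutoff `c_f` (default 0.5).

The network has three per-view dense layers (width `N₁ = 1024` by
default, ReLU), a concatenation, and a **linear** fused layer producing
the metric embedding (width `N₂ = 1024`). The hidden nonlinearity and the
absence of dropout are deliberate minimal choices; the fused layer is
kept linear because a linear metric head is the common convention in
triplet-embedding architectures and makes the embedding scale directly
interpretable against the margin. A sigmoid head over the ordered
candidate term set `Q` (all non-root terms seen in training) produces
`s_saf`.

The batch-hard triplet loss takes, per anchor, the farthest positive and
the closest negative within the batch; the expectation is over the
anchors of a batch. An anchor is never its own positive (identity by
protein index), anchors lacking either a positive or a negative are
skipped with a warning, and a batch with no valid anchor raises. The
hinge is computed as `(d_pos − d_neg) + margin` so that equal distances
cancel exactly in floating point. Gradients follow the standard
subgradient: only the selected hardest positive/negative and the anchor
receive contributions, with zero gradient at coincident points.

The composite objective is `L_triplet + α · L_ce`, with `L_ce` the mean
binary cross-entropy (natural log, scores clamped to
`[1e−7, 1 − 1e−7]`). Defaults `margin = 1.0`, `c_f = 0.5`, `α = 1.0`,
`K = 10` are exposed in `TrainingConfig` and are meant to be tuned on
validation Fmax, which the training loop reports per epoch when a
validation split is given.

Optimisation is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8, default learning
rate 1e−3) implemented directly on numpy arrays together with the
network's backward pass. At the problem sizes this package targets
(hundreds of proteins, hidden widths ≤ 1024) this keeps runs
single-threaded, dependency-light and bit-reproducible under a fixed
seed; two runs with the same seed produce identical score vectors.
Batches are plain random shuffles by default; a `similarity_aware`
sampler that pairs each batch seed with a random positive partner is
available for datasets where plain shuffling leaves too few valid
triplets. One model is trained per GO aspect; `n_runs` (default 10)
seeded replicas are trained and their score vectors arithmetically
averaged.

## Predictors

- **Guilt-by-association** (`gba_scores`): the `K` training proteins
  nearest to the query in the trained metric space vote for their terms
  with rank weights `wₖ = 1 − (rₖ−1)/K`; the score of a term is its
  weight fraction. Distance ties break lexicographically on protein ID
  for determinism. With `K = 1` this is the nearest template's indicator.
- **Internal combination**: `w · s_gba + (1−w) · s_saf`, `w = 0.5` by
  default, validation-tunable.
- **Homology consensus** (`sagp_scores`): hits with e-value ≤ 1e−3, top
  10 by bitscore, each retained template votes its terms with its
  bitscore as weight; the score is the weighted fraction. The weighting
  scheme is isolated in this one function so an alternative (identity or
  −log e-value) is a one-line change. Queries with no retained hits stay
  uncovered.
- **Single-template baseline** (`blast_baseline_scores`): the maximum
  sequence identity (as a fraction) among templates carrying the term.
- **Naive prior** (`ngp_scores`): the training annotation frequency of
  each term, identical for every query; coverage 1 by construction.
- **PPI vote** (`ppigp_scores`): confidence-weighted vote over annotated
  interaction partners; isolated proteins stay uncovered.
- **Composite**: `β · s_network + (1−β) · s_homology` with per-aspect
  `β` (0.57 MF / 0.60 BP / 0.67 CC defaults); uncovered homology
  contributes zero, so the composite score of such proteins is a scaled
  network score.

Uncovered proteins are reported as-is (empty score maps) so the coverage
column of an evaluation report means what it says.

## Evaluation

`fmax_sweep` thresholds the score vector at each `t` on a grid (default
`0.00–1.00` in steps of 0.01; `"exact"` sweeps every distinct score —
Fmax is then invariant under strictly monotone score transforms). Two
pooling modes: `micro` pools tp/fp/fn over all proteins (the printed
precision/recall definition); `cafa` (default) averages precision over
proteins with ≥ 1 prediction and recall over all proteins, the CAFA
assessment rule. On a single protein at a fixed threshold, micro F1
equals the per-protein F1.

AUPR integrates the non-increasing precision envelope of the swept curve
stepwise in recall (at recall `r`, precision is the maximum among curve
points with recall ≥ r), from recall 0 to the largest attained recall.
AUROC ranks all (protein, term) pairs jointly (micro; average-rank tie
handling), with a per-term mode for rare-term analyses. Coverage is the
fraction of test proteins with at least one nonzero score. **ICW-Fmax**
is the same threshold sweep with tp/fp/fn counts replaced by IC sums of
the corresponding term sets; with all-equal IC it reduces exactly to the
unweighted Fmax. Truth whose terms all carry zero IC is rejected as
degenerate.

Method comparison at the individual-protein level uses the Friedman test
(tie-corrected, via scipy) on within-protein ranks of per-protein F1,
followed by a Nemenyi post-hoc from the studentized-range distribution of
mean-rank differences (df = ∞). Pairwise p-values are clamped to
[1e−3, 0.9], the range in which the approximation is reliable; all-rows
constant input is rejected as degenerate.

## Synthetic data generator

The generator emulates every pipeline input from a seed, which fully
determines all outputs:

- **DAG**: the real aspect root plus synthetic terms `GO:9xxxxxx`
  (clear of real accessions); term *i* draws one parent among recent
  earlier terms (for depth) and a second with probability rising with the
  branching knob. Acyclic by construction.
- **Annotations**: each of `n_clusters` functional clusters is anchored
  at a DAG leaf; a member's annotation is the leaf's ancestor closure
  (root excluded), optionally plus one random extra closure per protein
  with probability `noise_rate`. Anchor leaves are chosen greedily so
  cluster closures are pairwise functionally distinct (F1 ≤
  `max_cluster_similarity`, default 0.5): without this, clusters can
  overlap so heavily that no protein pair counts as different-function
  and triplet mining has no negatives. Output is propagated by
  construction.
- **Embeddings**: cluster centres drawn from `N(0, signal² I_d)`; each of
  the three views is the centre plus independent unit-variance noise.
  `signal` is therefore the ratio of between-centre spread to
  within-cluster spread: 0 means no functional information, large values
  make clusters linearly separable.
- **Hits / PPI**: same-cluster alignment hits carry identity 60–95%,
  cross-cluster 10–35% (disjoint ranges, so identity separates clusters
  exactly); bitscore and e-value are monotone in identity. PPI edges are
  drawn preferentially within clusters with heavier weights. An
  `orphan_fraction` of proteins receives no hits / no edges, exercising
  coverage < 1. An optional `unseen_cluster_fraction` reserves whole
  clusters for the test split, emulating queries from species absent from
  training.

What passing tests on this generator do **not** show: real language-model
embeddings are anisotropic and their geometry correlates with function
far more weakly than a Gaussian cluster model; real annotation sets share
structure beyond common ancestry; real homology hit identity does not
separate functions cleanly. Results on synthetic data certify the
machinery (losses, transfer, combination, evaluation), not biological
accuracy.

## Study sizes and measurement choices

The parameter-recovery study uses 4 clusters, 200 proteins, `d = 32`,
50-term DAG, hidden widths 64, 30 epochs, 3 replicas — sizes at which the
full train→predict→evaluate loop completes in seconds while leaving the
triplet objective non-trivial. At `signal = 4.0` the held-out Fmax
reaches ≥ 0.95 (1.0 in practice) with coverage 1; at `signal = 0` the
pipeline's Fmax sits within 0.05 of the naive-prior baseline, as it must
when embeddings carry no information.

The margin-violation comparison (fraction of anchors whose hardest
triplet violates the margin, before vs after training) is measured at
moderate separation (`signal = 1.5`, same sizes): at large separations a
randomly initialised linear map usually satisfies the 1.0 margin already
(violation rate 0), so "training strictly decreases violations" would be
vacuous there. Off the floor, the decrease is strict at every seed
tried.

## Numerical choices and degenerate inputs

- Cross-entropy clamp 1e−7; natural-log convention.
- Triplet hinge computed as `(d_pos − d_neg) + margin`; zero-distance
  pairs contribute zero gradient.
- Batch-hard ties (equal hardest distances) resolve to the lowest
  protein index; GBA distance ties to lexicographically smaller ID.
- Fmax threshold ties keep the smallest threshold.
- Glorot-uniform initialisation seeded per run; all randomness flows
  from `numpy.random.default_rng(seed)`.
- Rejected as errors: empty truth sets (undefined recall), empty training
  corpora, scores outside [0, 1], K larger than the training set,
  all-zero-IC truth, single-point PR curves, constant Friedman rows,
  cyclic ontologies, malformed OBO lines (reported with line number).

## Known limitations

- The numpy training loop is single-threaded and not GPU-capable; it is
  sized for desk-scale experiments, not 100k-protein corpora.
- The homology consensus weighting (bitscore fraction) is one reasonable
  convention; it is isolated behind one function precisely because other
  conventions exist.
- AUPR/AUROC are micro-aggregated by default; macro (per-term) AUROC is
  available, macro AUPR is not.
- No Smin / semantic-distance evaluation, no bootstrap confidence
  intervals, no GO term enrichment.
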