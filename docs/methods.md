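# Methods

`htinet` predicts herb–target interactions (HTIs) on a heterogeneous graph
of Herb (H), Efficacy (E), Ingredient (I) and Target (T) nodes. This note
records the model as implemented, the choices made where the design was
genuinely open, what the synthetic generator does and does not emulate,
and the numerical conventions that make runs reproducible.

## The graph

Six typed relations connect the four node types: H–I, H–E, I–T, H–H, T–T
and the H–T links being predicted. Symmetric relations (H–H, T–T, and an
optional ingredient-similarity relation I–I) store each undirected edge
once and are expanded to both directions during message passing, so that
attention softmaxes never count an edge twice. Node ids are strings;
each type assigns contiguous integer indices in manifest order, which
fixes the row/column semantics of every derived matrix. Edge weights
default to 1.0; similarity-derived edges carry their cosine similarity.

The H–H and T–T networks are not observed data: they are derived. Herbs
are profiled by their efficacies and by their targets; targets by their
ingredients and by their herbs. Each profile pair is compared by cosine
similarity on binary incidence vectors, the two views per entity are
averaged, and a closed top-k pruning (top-α per herb, top-β per target;
ties at the k-th rank are all kept, and an edge survives if either
endpoint selects it) yields the similarity networks. α = β = 10 by
default; no published value exists for either. One wrinkle is documented
rather than resolved: the source description says the herb network is
built from ingredient-derived similarity yet defines its edges by shared
efficacies; we follow the averaging formulation (efficacy-based and
target-based views averaged for herbs; ingredient-based and herb-based
views averaged for targets).

## Metapaths

A metapath schema is an alternating node-type pattern that starts and
ends at the anchor type and has at most 5 nodes. The shipped defaults are
10 schemas for herb anchors (HH, HTH, HIH, HEH, HTTH, HTHTH, HIIH, HEHEH,
HTITH, HITIH) and 8 for target anchors (TT, THT, TIT, THHT, TITIT, THTHT,
THIHT, TIHIT). These lists are configuration, not derivation: brute-force
enumeration over the relation registry would produce patterns (HHH,
THEHT, …) that the curated lists deliberately omit. HIIH traverses an
ingredient–ingredient similarity relation; when a graph carries no I–I
edges the schema is skipped with a logged warning.

Instances follow walk semantics — nodes may repeat, so H1–I2–H1 is a
valid H-I-H instance. This makes instance counts equal to entries of the
ordered product of step biadjacency matrices, which both the auxiliary
propagation and the test oracles exploit. Enumeration is depth-first
over sorted neighbor lists, so instance lists are lexicographic and
platform-independent. A node's metapath neighbors are the instance
endpoints plus the node itself.

Metapath-level attention assigns each anchor a distribution over its
schemas: the preliminary weight is the cosine between the anchor's
features and the schema's pooled terminal features (mean over instance
endpoints, weighted by instance multiplicity — a config switch can
binarize this); the final weight is a softmax over schemas of a learned
affine map of [preliminary weight ⊕ schema embedding]. Schemas with no
instances at an anchor are masked and get weight exactly 0.

## Representation learning

One forward pass:

1. **Relation-level attention.** For each relation r and edge (u → v),
   attention `α_{r,u→v} = softmax_u LeakyReLU(a_r^T [W_r h_u ‖ W_r h_v])`
   (slope 0.2), with `log(weight)` added to the logit so that
   similarity-weighted edges enter the softmax proportionally. Messages
   are `W_r^l h_u + e_r^l` with a learned per-relation, per-layer feature
   `e_r^l`; the relation-wise sums are added (the cross-relation
   aggregate is the same reduction as the inner sum). Metapath-derived
   auxiliary messages are added for herb and target anchors: per schema,
   the instance-count-normalized neighbor average, transformed by a
   per-anchor-type matrix and combined with the schema-attention weights.
2. **Skip-connected depth.** The first `k_dense` layers (default 2 of
   L = 4) use dense connectivity: the layer's output is
   `ReLU(W [h^0 ‖ … ‖ h^l ‖ u^{l+1}] + b)` where `u^{l+1}` is the fresh
   attention aggregate. Deeper layers are residual graph convolutions
   `h^{l+1} = ReLU(Σ_j (1/√(deg_i deg_j)) W h_j + h_i)` on the union
   adjacency of all relations.
3. **Cross-hierarchical pooling.** Multi-head scaled dot-product
   attention over the L per-layer embeddings; each token is
   `h_v^l ⊕ r^l` with a learned per-layer embedding `r^l` shared across
   relations. Head outputs are averaged over tokens, concatenated, and
   affinely mapped to the output dimension.
4. **Meta-relational scoring.** Channel weights
   `β_φ = softmax_φ w^T [μ_φ ⊕ h̄]` over learned prototypes `μ_φ`
   (global context `h̄` = mean of all herb and target embeddings; the
   number of channels is a hyperparameter, default 3), and the relation
   matrix `M = Σ_φ β_φ σ(H_herb W_φ H_target^T)` with a sigmoid per
   channel, so entries are convex combinations of values in (0, 1).

Reference dimensions are 256 (node), 64 (output), 64 (hidden), 4 heads;
the desk-scale configuration used throughout the tests is 64/64/32 with
2 heads and L = 3, which keeps a full training run in tens of seconds on
one CPU.

### Initialization

Two schemes exist for the input features. `embedding` draws learnable
per-node vectors (seeded). `incidence` — the desk default — embeds all
four node types in one shared ingredient feature space: ingredient i maps
to row i of a seeded random projection P, a herb to the sum of its
ingredients' rows, a target to the sum of its ingredients' rows, an
efficacy to the mean of its herbs' vectors. By the Johnson–Lindenstrauss
property, herb–target inner products then approximate shared-ingredient
path counts, so the bilinear relation matrix carries structural signal
before any training. An earlier variant that initialized herbs from
efficacy profiles and targets from ingredient profiles was discarded:
with disjoint projection spaces the herb–target inner product is
structurally meaningless at initialization.

`init_scheme="identity"` extends the same philosophy to the weights
(in the spirit of identity-mapping initializations for deep networks):
dense blocks start as a pass-through of the previous layer plus a
low-gain aggregate, residual convolutions start at low gain, the pooling
value/output projections start at (rectangular) identity plus 2% noise,
and query/key projections start small so token attention is
near-uniform. The untrained network then approximately preserves its
structural input features through every layer. With Xavier
initialization everywhere the same architecture must first unscramble
its own random transforms, which on small graphs it does unreliably.

The bilinear score transforms are the deliberate exception: they start
at (or near) zero, never at identity. An untrained model therefore
scores every pair exactly 0.5 — it has structure-rich *features* but no
ranking *skill*; the herb–target alignment must be learned from labels.
This split keeps the label-permutation control meaningful: a model
whose scorer started at identity would rank held-out pairs at AUC ≈0.88
with no supervision at all, and shuffled-label training could never
drive it to chance. Two scorer details matter in practice. First, each
channel carries a scalar bias inside the sigmoid, seeded at the
base-rate logit of the training labels; without it, imbalanced (5:1)
supervision forces the bilinear direction itself to absorb the negative
base rate, which measurably inverts the learned ranking. Second, the
desk configuration restricts each transform to a learned diagonal
(`score_form="diag"`, the DistMult-style low-parameter bilinear): 64
parameters per channel are well determined by a few hundred labels,
where a dense 64×64 transform is an optimization lottery. The full
transform remains the default form.

## Prediction head and readouts

The N×M relation matrix is flattened (row-major, herb-major) and
projected to a global feature `Z = ReLU(W_p vec(M) + b_p)`; a reverse
projection `Z' = reshape(W_q Z + b, (N, M, d))` produces per-pair
relational vectors; each candidate pair is scored by a two-hidden-layer
MLP (hidden sizes d_h and d_h/2, d_h = 64) with sigmoid output on the
fused feature `f_ij = [h_i ‖ h_j ‖ Z'_ij]`. The reverse-projection bias
is an independent parameter (the projection bias cannot serve both
shapes). The pair grid is capped at N·M ≤ 20,000 because W_q scales as
d × (N·M·d).

The head is deliberately described as *transductive*: W_q and its bias
hold one parameter block per grid pair, and blocks of pairs that never
appear in training remain at initialization. The model therefore exposes
two readouts: the fused MLP probability (`readout="fused"`), which is
the calibrated classifier for supervised pairs, and the relation matrix
(`readout="relation"`), the association-strength output used to rank
pairs outside the training set. Link-recovery experiments evaluate the
relation readout; on held-out pairs the fused readout is near chance by
construction, which the acceptance script reports side by side.

## Training protocol

The reference protocol (TrainConfig defaults) is Adam with learning rate
1e-5, weight decay 1e-5, 200 epochs, early stopping on validation loss
with patience 50, 9:1 train/test split and 10-fold cross-validation over
the training positives, negatives sampled uniformly from non-edges 1:1
per fold, classification threshold 0.5, and optional post-training global
magnitude pruning (default off).

The desk-scale protocol (`desk_train_config`) — used for the synthetic
experiments so a full run finishes in under a minute — differs in
documented ways:

- learning rate 2e-3 for 150 epochs, with a ×10 factor on the scorer
  parameters (1e-5 would not move the scaled-down model at all);
- the encoder is **frozen** (`representation_lr_factor = 0`): the
  structurally initialized message-passing/pooling stack acts as a
  fixed feature extractor and only the bilinear scorer, the
  meta-relational weights and the fusion head are fit — the
  linear-probing regime. Fine-tuning the encoder at small rates was
  tried and consistently *reduced* held-out recovery on small graphs:
  a few hundred labels cannot improve several hundred thousand encoder
  weights, but they can destabilize them;
- 5:1 negatives, sampled once with a run-derived seed;
- a BCE term on the relation-matrix entries of the training pairs is
  added to the head BCE (deep supervision: the matrix is itself an
  association score, and supervising it directly trains the generalizing
  path);
- strong decay (1e-2) on W_p, b_p, W_q, b_q — the parameters able to
  memorize one label per pair — and mild L2 (3e-3) on the bilinear
  scorer, which measurably closes the gap to a converged regularized
  logistic fit on the same features;
- model selection by ranking rather than loss: 25% of the observed
  positives are held back from the supervised pairs, and every 5 epochs
  the state is scored by the AUC of those validation positives against
  every non-positive grid pair on the relation readout; the untrained
  state is a candidate. The selection uses the labels as the experiment
  sees them, so a label-shuffle control selects by its shuffled labels.
  Loss-based stopping remains the default config behavior, but under
  5:1 sampling the raw validation BCE drifts with score calibration
  while ranking improves, which makes it a poor selector here.

Negatives are never resampled per epoch: doing so eventually shows the
model nearly every grid negative, which inflates held-out AUC through a
seen-versus-unseen artifact rather than genuine recovery.

Counterfactual edge hiding (hide a seeded fraction of known H–T edges,
retrain, classify each hidden edge as recovered if its association
score reaches the 0.5 threshold) is run with 1:1 negatives: the
probability scale then reflects a balanced prior and the fixed 0.5
threshold is meaningful. Under 5:1 sampling the same model ranks hidden
edges equally well but calibrates all probabilities toward the low base
rate, so threshold-based counts would be vacuously zero.

One honest caveat about the label-permutation control: with 58 observed
positives and 5:1 sampling, a random permutation leaves roughly ten true
positives labeled 1 by chance, and a scorer over structural features can
amplify that overlap well above 0.5 on an individual seed (values up to
~0.7 were observed). The chance-level band holds for the mean over five
seeds, which is how the control is evaluated.

Evaluation ranks each held-out positive against **all** grid pairs
outside the full true-positive set. A sampled negative set has the same
expected AUC but far higher variance at this graph size; the exhaustive
background makes 5-seed means meaningful.

## Synthetic data

`generate` plants a latent-factor world: herbs, ingredients, targets and
efficacy prototypes receive Gaussian latent vectors (dimension 4); H–I
and I–T edges are Bernoulli with a logistic link on latent affinity
(slope 3.0, intercept bisected to hit the target density); each herb
joins its 3 most affine efficacies; the true H–T positives are the
top-affinity pairs at the configured density, with a noise fraction
(default 5%) replaced by random pairs; a seeded 20% of positives is
masked as the held-out evaluation set. The small preset (30 H / 20 E /
80 I / 60 T, densities 0.056 / 0.05 / 0.04) mirrors the relation-count
ratios of the reference data set (128 herbs, 139 efficacies, 419 H–E,
14,302 H–I, 7,902 H–T); `reference_shape_config()` reproduces its node
counts directly. The affinity slope of 3.0 was chosen so that the
planted signal is actually present in the observed graph: at gentler
slopes even the exact H-I-T path-count statistic cannot recover the
held-out edges, which would make link-recovery experiments tests of
nothing. H–H and T–T edges are not generated; they are derived by the
similarity pipeline, mirroring the intended data flow.

What the generator does **not** emulate: real TCM chemistry (no
compound structures, no dose), hub-dominated degree distributions,
curation biases of herb databases, or correlated noise. Passing the
recovery bar here shows the architecture can extract a planted
shared-ingredient/efficacy signal end to end — not that it reaches any
particular performance on clinical data.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; two runs with the same seed and config are bitwise identical.
- Softmaxes subtract a per-row (or per-segment) maximum as a constant
  shift; segment softmaxes with empty segments return empty (not NaN).
- BCE clamps probabilities to [1e-7, 1 − 1e-7] and warns if clamping was
  active; gradients do not flow through clamped values.
- Cosine similarities of all-zero rows are defined as 0.
- Ranking ties break by target id (stable), making top-k tables
  deterministic.
- The automatic-differentiation engine is a minimal reverse-mode tape
  over numpy arrays written for this package (no GPU, whole-graph
  training only); gradient correctness is property-tested against
  central finite differences for every operation the model uses.

## Known limitations

- The fused head does not generalize to unsupervised pairs (see above);
  candidate ranking for discovery should use the relation readout, and
  the CLI's `predict` trains on all observed edges so ranked pairs are
  scored in-distribution.
- Whole-graph training with a dense N×M head caps practical problem
  sizes (N·M ≤ 20,000); the reference-scale data set would need a
  factorized or mini-batched head.
- The cross-validation driver retrains the full model per fold; 10-fold
  CV on the small preset takes a few minutes on one CPU.
- Metapath auxiliary propagation recomputes schema attention per layer
  from current features; its walk-count matrices are static per graph.
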