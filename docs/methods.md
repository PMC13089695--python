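# Methods

## Problem setting

A multi-contact nerve-cuff electrode — 7 rings of 8 contacts wrapped
around the sciatic nerve, 56 channels in total — records naturally evoked
compound action potentials (nCAPs) elicited by three afferent activities:
dorsiflexion, plantarflexion and pricking.  Each detected nCAP yields a
*spatiotemporal signature*, a 56 × 100 matrix (contacts × time samples),
labeled with the activity and the subject it came from.  The package
classifies these signatures with a graph neural network whose topology
encodes the cuff's cylindrical geometry, and evaluates cross-subject
generalization (leave-one-subject-out) and within-subject performance.

## Electrode graphs

Contacts are graph nodes at grid coordinates (ring x, circumferential
position y), node index = x·8 + y (row-major, matching the signature's row
order).  Distances between contacts:

* **geodesic** — `|x_i − x_j| + min(|y_i − y_j|, 8 − |y_i − y_j|)`, the
  shortest path along the cylinder: the circumferential term wraps, so
  contacts on opposite sides of the unrolled grid's seam are adjacent.
  This equals the BFS hop count on the cylindrical grid graph (asserted
  exhaustively in the tests).
* **euclidean** — the planar distance on the unrolled grid, deliberately
  ignoring the wrap-around; used as an ablation.
* **random** — no distance at all: the same number of undirected edges as
  the geodesic graph at the same `k`, drawn uniformly among node pairs
  (weight 1), preserving sparsity while removing the spatial prior.

For the distance metrics, each node selects its `k` nearest other nodes
(ties broken by ascending node index — many grid distances are tied, and a
deterministic rule is required for reproducibility); the directed relation
is symmetrized by union, so degrees may exceed `k`.  Retained edges carry
Gaussian weights `exp(−d²/2σ²)`.  Self-loops are excluded at construction
because the graph convolution adds them itself.  Defaults `k = 5`,
`σ = 2` are the best-performing connectivity for this cuff.  Euclidean
coordinates are the integer grid indices: no physical inter-contact
spacing is modeled, and only relative distances matter after k-NN
selection and the kernel.

## Model

1. **Temporal encoder.**  One shared-parameter sequence encoder applied
   independently to each channel's 100-sample series.  Default: an LSTM
   (256 units at reference scale); the node feature is either the final
   hidden state (`node_feature="last"`, default) or the time-mean of
   hidden states (`"mean"`).  The ablation encoder is a 1-D CNN: two
   convolution blocks (kernels 7 and 5, ReLU) with global average pooling
   and a linear projection to the same width.
2. **Edge convolution** (32 units at reference scale).  Each node i
   receives `Σ_{j∈N(i)} φ(h_i, h_j, A_ij)` with sum aggregation; φ is a
   one-hidden-layer ReLU perceptron on the concatenation of receiver
   features, sender features and the scalar edge weight (the
   concatenation's linear map is evaluated block-wise, which is
   algebraically identical).  `A_ij` enters only through φ, not as an
   outer multiplier.  Isolated nodes receive a zero vector.
3. **Graph convolution** (128 units at reference scale).
   `H' = ReLU(D̃^{−1/2} Ã D̃^{−1/2} H W)` with `Ã = A + I`.  The propagation
   matrix is symmetric with spectral radius ≤ 1.
4. **Head.**  Global average pooling over nodes, dense ReLU layers
   (default one 64-unit layer) with 20% dropout at training time, softmax
   over the three classes.

L2 regularization (default 5·10⁻³) applies to the two graph layers'
weight matrices.  Both graph layers are permutation-equivariant and the
full classifier permutation-invariant; this is asserted end to end in the
tests, and it has a design consequence for synthetic data discussed below.

## Training

Adam (learning rate 10⁻³, batch 1024 at reference scale; batches are
capped at the training-set size), categorical cross-entropy plus the L2
penalty.  Gaussian-noise augmentation — sd equal to 5% of each
signature's RMS by default — is applied to training batches only.  Early
stopping monitors loss on a 10% slice of the training data, stratified on
(subject, label) where possible, and the best checkpoint is restored.
Signatures are z-scored per channel with statistics computed on the
training portion only, so no test information leaks into normalization.

**Variance-calibrated initialization.**  With Glorot initialization alone
the forward signal attenuates roughly tenfold across the stack (the
encoder's node features have standard deviation well below one, and each
downstream stage shrinks it further), which leaves early training stuck
predicting the class prior.  After the standard Glorot draw, one forward
pass on a batch of training data rescales the graph-layer and head
weights so every stage's output has approximately unit standard deviation
(in the spirit of layer-sequential unit-variance initialization).  This
measurably shortens the initial plateau and is applied in every training
run.

## Evaluation

* **LOSO**: one fold per subject; train on the rest, test on the held-out
  subject.  Aggregate mean ± SD excludes any subjects designated as the
  hyperparameter-validation set (their folds are still reported).
* **Within-subject**: stratified 3-fold cross-validation inside each
  subject (two folds train, one tests, each fold testing once);
  per-subject scores are unweighted fold means; the aggregate includes
  every subject.  Folds are stratified by class because macro-F1 on small
  unstratified folds is unstable.
* **Metrics**: accuracy and macro-averaged F1 (percent).  A class absent
  from both truth and prediction contributes F1 = 0 — the conservative
  convention.
* **Comparisons**: paired Student t-test on per-subject macro-F1
  differences for matched runs; Welch's two-sample t-test otherwise
  (variances across held-out subjects are not assumed equal).  Two-sided
  p-values, α = 0.05.

## Synthetic data

No public accession exists for the rat dataset, so every stage is
exercised on synthetic signatures designed to carry class information the
way the real task does — in *where* activity appears on the cuff:

* a biphasic (difference-of-Gaussians) pulse, width 4 samples, placed on
  every channel with amplitude `exp(−d_geo(channel, origin)²/(2·1.5²))`
  around a class-specific origin contact;
* a conduction delay of 3 samples per ring away from the origin ring,
  emulating propagation along the nerve;
* per-subject multiplicative gain (lognormal, sd 0.2) and onset jitter
  (sd 2 samples) for subject heterogeneity, i.i.d. Gaussian measurement
  noise (sd 0.1; the paper-scale recordings' SNR is not published
  anywhere, so this is a free parameter chosen so that the task is
  neither trivial nor untrainable at desk scale);
* class origins (ring, circumference) = (0,0), (2,3), (5,6).  These are
  deliberately **non-automorphic**: the cylinder's symmetry group
  (circumferential rotations and reflections, ring-order reversal) maps
  no class template onto another.  Because the classifier is invariant
  under graph automorphisms, classes placed at symmetric positions (for
  example pure rotations of one another, or origins at mirrored rings)
  would be provably indistinguishable no matter how long one trains.
  Distinct ring offsets |x₀ − 3| guarantee non-equivalence and give each
  class a distinct conduction-delay profile.

What the generator does *not* emulate: correlated physiological
background activity, electrode impedance differences, drift, imperfect
nCAP detection, or class-dependent waveform shapes.  Passing benchmarks
on this data therefore demonstrate that the pipeline recovers spatial
structure through the cuff geometry — not that it reaches any particular
accuracy on real recordings.

## Desk-scale benchmark protocol

The reference configuration is far beyond a single-CPU smoke benchmark
(the original setting trains a 256-unit-encoder model on tens of
thousands of signatures for thousands of optimizer steps on a deep
learning framework; this package's compute engine is pure numpy).  The
benchmark protocol in `cuffgraph.protocols` therefore scales everything
down and documents the choice:

* data: 4 subjects × 120 signatures (40 per class), default generator
  conditions;
* model: 8-unit LSTM encoder with time-mean node features (a pulse that
  ends ~50 samples before the window's end is forgotten by the final
  hidden state at this scale), 8-unit edge convolution, 16-unit graph
  convolution, one 16-unit dense layer, no dropout, L2 5·10⁻⁴;
* training: Adam at 10⁻², batch 96, a small fixed epoch budget
  (40 epochs for the benchmark script's single replicate, 6 for the
  quick multi-replicate test-suite runs).
  Early stopping is configured with patience equal to the epoch budget:
  validation loss is flat during the initial optimization plateau, so a
  short patience would terminate runs before learning begins; the best
  checkpoint is still restored at the end.

Interpreting desk-scale results needs care.  Near convergence (about 60
epochs per run) the topology comparison behaves as the geometry argument
predicts: in a one-replicate check the geodesic graph reached 87.3% LOSO
macro-F1 versus 76.1% for the sparsity-matched random graph (the planar
Euclidean graph was comparable to geodesic at 87.7%; the seam effect is
small for this task).  At the truncated budgets the quick protocols can
afford, however, runs sit in or just past the initial optimization
plateau, where run-to-run escape-time variance dominates and the ordering
can even invert: the geodesic cylinder graph is the most *symmetric*
topology, so early in training its message passing gives nodes the least
positional identifiability, whereas the unwrapped Euclidean boundary and
the random graph's degree heterogeneity break symmetry and let the
location-coded classes be separated sooner.  Truncated-budget comparisons
are therefore reported for completeness but should not be read as
estimates of converged performance.

## Numerical and implementation notes

* The compute engine is a minimal reverse-mode autodiff over numpy arrays
  with fused LSTM and softmax-cross-entropy kernels; every operation's
  gradient is checked against central finite differences in the tests.
  Work buffers for the recurrent loop are pooled between same-shaped
  calls, which matters on cold-page-fault-dominated systems.
* k-NN ties, fold shuffling, graph randomization and noise draws all flow
  from explicit seeds; two runs with the same seeds are bit-identical
  (asserted).
* Dropout is disabled at evaluation; repeated evaluation passes are
  bit-identical (asserted).
* Degenerate inputs: empty or single-class training sets are rejected;
  paired comparisons with zero-variance differences raise a dedicated
  error rather than returning an undefined statistic; within-subject
  folds that cannot be stratified skip the subject with a warning.

## Known limitations

* No deep-learning backend: at desk scale the benchmark cannot train to
  convergence within a reasonable single-CPU budget, so the
  topology-comparison benchmarks probe the early-training regime only.
* The synthetic task is a single fixed template per class; real nCAP
  signatures vary within class far more richly.
* Physical units (inter-contact spacing in mm, nerve diameter) are not
  modeled; distances are in grid units.
* The cnn1d encoder is provided for the encoder ablation and is
  architecturally faithful but has not been tuned.
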