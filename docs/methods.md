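# Methods

## Scope and design

`histofuse` implements a complete histology-classification method — a
six-branch CNN feature extractor, a residual reference extractor, three
feature selectors, serial fusion, and an ensemble evaluation harness — in
plain NumPy/scikit-learn. The CNN layers (convolution, ReLU, max pooling,
batch normalisation, global max pooling, dropout, fully connected, softmax)
are written here with explicit forward and backward passes; standard
learners (SVMs, boosted trees, k-NN bases) and cross-validation splitting
are delegated to scikit-learn. Everything stochastic takes an explicit
seed, and repeated runs are bit-reproducible apart from recorded wall
times.

## The six-branch network

The canonical graph (input 227×227×3) is: conv 9×9/2 ×128 → ReLU → max
pool 5×5/2 → six parallel branches (conv k×k/2 ×96 → ReLU → batch norm,
k ∈ {13, 11, 9, 7, 5, 3}) → depth concatenation (576 channels) → ReLU →
global max pool → 1×1 conv to 9216 channels → ReLU → max pool 5×5/1 →
dropout 0.5 → fc 4096 → ReLU → dropout 0.5 → fc K → softmax →
classification. That inventory counts 35 layer nodes and 39 directed
edges, which the tests audit structurally.

Points where the architecture description admits more than one reading
were fixed as follows, as package design decisions:

- **Activation.** The branch and stem activations are standard ReLU
  max(0, x). A 0/1 step would discard activation magnitudes and make the
  feature taps useless.
- **Global max pooling depth.** The pool operates over the full 576
  concatenated channels (depth preserved); the per-branch depth of 96 is a
  property of each branch, not of the merged tensor.
- **The 1×1 "grouped" convolution.** Implemented as a 1×1 convolution with
  group count 1 and 9216 output channels, which gives the following
  4096-unit fc a well-defined fan-in (9216 after the 1×1 spatial output of
  global pooling).
- **Branch merge.** The merge is an explicit depth-concatenation node
  followed by ReLU — a merge node is structurally required between six
  parallel tails and one head.
- **Class head.** The second fully connected layer maps 4096 directly to
  the K class scores.

`build_6bnet(num_classes, input_side, width_scale)` exposes two desk-scale
knobs. `input_side` shrinks the spatial extent (the fc fan-in is
unaffected because global pooling reduces to 1×1 regardless);
`width_scale` thins every channel dimension proportionally. Neither
changes the topology: the graph always has 35 nodes, 39 edges and six
branches, so the audit holds at any scale. Defaults (227, 1.0) are the
canonical network.

## Training

Plain mini-batch SGD on the softmax cross-entropy. Weight init is He
fan-in scaling for convolutions, Xavier for hidden fc layers, and a
near-zero (σ = 0.01) init for the class-score layer so initial losses are
O(log K) rather than dominated by the deep unnormalised head. Per-batch
gradients are clipped to a global L2 norm of 5.0; without clipping the
head occasionally blows up in the first epochs at usable learning rates.
Batch normalisation uses biased mini-batch variance in train mode
(batches of one are rejected), running moments (momentum 0.1) at
inference, ε = 1e-5. Dropout is inverted (scaled at train time). The
whole training loop is deterministic per seed: init, shuffling and
dropout masks all derive from it.

The backward pass is verified against central finite differences in the
test suite, and the im2col convolution against a nested-loop
cross-correlation oracle.

## Feature extraction

FV2 is the row-per-image activation of the 4096-unit fc layer of the
six-branch net (any named layer can be tapped). FV1 comes from a standard
50-layer bottleneck residual network (stages 3/4/6/3, expansion 4, global
average pool, fc 1000) implemented forward-only. Pretrained weights can be
supplied as a parameter dict; by default the reference net runs with
seeded He-initialised random weights. Random-weight features are
deterministic image-dependent projections — weakly class-informative
through colour/texture statistics but far from trained-feature quality;
selection and fusion logic is therefore validated primarily on planted
feature tables where ground truth is known. Images are bilinear-resized to
each backbone's input side and scaled to [−0.5, 0.5]; channel order is
RGB.

## Selection

**Wrapper objective** (both PSO and ACS): stratified 3-fold 1-NN accuracy
on the masked columns minus λ·(selected fraction), λ = 0.01. Cheap,
standard for wrapper selection, and monotone-comparable across masks; the
CV fold seed is fixed per run so a given mask always scores identically
(this is what makes the elitist best-so-far traces non-decreasing).

**Binary PSO** defaults: 20 particles, 30 iterations, inertia W = 0.7,
a₁ = a₂ = 1.5, velocity clamp ±6 (the sigmoid is saturated beyond),
positions initialised Bernoulli(0.5), velocities zero. Ties on fitness
prefer the smaller mask. Any all-zero candidate mask is repaired by
forcing one random bit on. One refinement of the threshold rule: a
velocity component exactly at zero expresses no preference, so the bit is
retained instead of re-randomised — this makes the degenerate swarm
(a₁ = a₂ = 0, zero velocities) stationary, which a selector should be.

**ACS** defaults: 15 ants, 25 iterations, α = 1, β = 2, evaporation
ρ = 0.1, subset size d/5 (minimum 1). The heuristic is the Fisher score
(between-class variance of class means over pooled within-class variance);
a 1e-12 floor keeps zero-score features reachable. Subsets are built by
sequential sampling without replacement from the inclusion probabilities,
renormalised after each pick. The global update is elitist: evaporate
everywhere, deposit ρ·max(fitness, 0) on the iteration-best subset,
pheromone floored at 1e-6.

**Entropy-based selection** discretises each feature into 16 equal-width
bins over its observed range and scores it by Shannon entropy in bits
(non-negative convention, −Σ p log₂ p); constant features score 0. The
selector keeps the top `keep` (count or fraction; default half) by
*descending* entropy — a well-spread activation distribution carries more
usable variation than a near-constant one. The direction is an open
modelling choice and is exposed as a flag (`direction='low'` flips it).
Ties break toward the lower column index.

**Fusion** is column-wise concatenation over identical sample order
(checked against the label vectors), swarm-selected vector first. The
fuse-then-entropy-select path contains no randomness.

## Classification and evaluation

Subspace ensembles default to 30 learners on random feature subspaces of
⌈d/2⌉ columns; bases are 1-NN (ESKNN) or a nearest-mean linear
discriminant with pooled covariance regularised by λI, λ = 1e-3 (ESD);
votes are pooled with ties to the lowest class index. EBT is AdaBoost over
depth-3 trees, 50 rounds; LSVM/QSVM/CSVM are linear, quadratic and cubic
polynomial-kernel SVMs (one-vs-one for K > 2). These hyperparameters are
package defaults mirroring common presets; none are claimed optimal.

Evaluation uses stratified k-fold CV (k ∈ {3, 5, 10}); every sample is
predicted exactly once, the confusion matrix is pooled over folds, and the
reported accuracy is exactly 100·trace/total. Wall-clock training time is
recorded in reports but never asserted — it is hardware noise. The
evaluation protocol applies CV to the full matrix; an optional additional
70:30 hold-out split is available via the CLI and reported separately,
since the two protocols cannot be merged unambiguously.

The pipeline reports five matrices: raw FV1, raw FV2, the two selected
vectors (colony on FV1, swarm on FV2 — together they form the "selected"
configuration), and fused+entropy-selected.

## Synthetic data

The image generator produces K-class sets from a minimal texture model: a
pale eosin-like background, a Poisson number of dark disks ("nuclei")
whose rate (10 + 8k per 64² area), radius (2 + 0.8k px) and hue (rotating
through a purple band) depend on the class k, plus σ = 8 Gaussian pixel
noise clipped to 8 bits. Classes are thus separable by cheap texture
statistics — by construction, a 1-NN classifier on mean-channel +
blob-count features exceeds 60% CV accuracy at K = 4 (chance 25%). The
generator does **not** emulate real H&E morphology: no stain variation,
no magnification levels, no nucleus shape/chromatin structure, no
inter-patient variability. Passing tests therefore demonstrate that the
machinery (training, extraction, selection, fusion, evaluation) behaves
correctly and recovers planted signal — not that the method reaches any
particular accuracy on real archives.

The table generator plants `k_informative` columns with equally spaced
class-conditional means separated by `effect_size` noise standard
deviations; remaining columns are N(0, 1). This makes the Fisher-score
oracle analytic and selector recovery exactly scoreable.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the full
suite completes in a few minutes on one CPU: images 64×64 (50 per class,
4 classes), network input 48 with width scale 0.25, 3 epochs, batch 16,
lr 0.02; reference extractor at input side 64; pipeline selectors at 10
particles/ants × 10 iterations; selector-recovery studies at the full
defaults (20×30 swarm, 15×25 colony) on 200×60 tables over 10 seeds;
end-to-end comparisons over 5 seeds. The canonical 227-input, full-width
network is built and audited structurally but not trained at full scale.

## Known limitations

- With random reference weights, FV1 is only weakly informative, so at
  desk scale the fused configuration's advantage over the best single
  selected vector is small (a few accuracy points at most) and can dip
  slightly negative on individual seeds; the on-average ordering is what
  the end-to-end test asserts.
- The NumPy trainer is single-threaded (BLAS aside) and desk-scale only;
  no augmentation, learning-rate schedules or GPU paths.
- Equal-width entropy binning is sensitive to outliers in a feature's
  range; robust binning was not pursued.
- Recorded training times vary between runs and machines and are
  informational only.
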