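# Methods

`reachscore` scores rodent movement deficits from video-derived features and
then extracts, from the trained scorer itself, which movement elements carry
the deficit signal.  This note documents the model, the synthetic cohort that
stands in for animal videos, the numerical choices, and the limits of what
the test suite shows.

## The scoring model

Each behavioral trial is a 125-frame clip (300 × 300 px at 30 frames/s).  A
convolutional image encoder maps every frame to 2,048 non-negative features;
the sequence of feature vectors is scored by a recurrent network:

    features (125 × 2048) → LSTM (U units, per-timestep outputs)
      → temporal max-pool → dropout (0.1) → dense head

Four heads share this trunk:

| head | outputs | activation | target |
|---|---|---|---|
| `cumulative` | 1 | ReLU | summed expert deficit score, 0–7 |
| `elements` | 7 | sigmoid | per-element scores on {0, 0.5, 1} |
| `categorical` | 2 | sigmoid | one-hot group (stroke, control) |
| `lesion` | 1 | sigmoid | min–max-normalized lesion volume (mm³) |
| `element_class` | n classes | softmax | movement-element category of a 7-frame window |

The two categorical votes combine into a continuous severity score
`Nsc = (n0 + (1 − n1))/2`: a network trained only on 0/1 group labels emits
intermediate Nsc values for intermediately impaired animals.

Regression heads train with Adam and mean squared error.  The full-scale
parity preset is 2,048 LSTM units, learning rate 1e-6, batch 8, 1,000
epochs.  CPU-sized runs (tests, synthetic experiments) use 32–64 units,
learning rate 1e-3, batch 32, a few dozen to a few hundred epochs, and
decoupled (AdamW-style) weight decay 0.1.  The weight decay matters beyond
regularization: Adam's per-parameter step normalization makes weights on
*uninformative* input dimensions random-walk away from zero, which blurs
post-hoc attribution; decay shrinks any weight that receives no coherent
gradient, so relevance concentrates on the dimensions the scorer actually
uses.  The element-class head trains with softmax cross-entropy (the natural
loss for a multi-class output; regression heads keep MSE).

Two standard conditioning steps are part of training.  Inputs are centered
on the per-feature training-set mean, stored in the model: encoder
activations carry a large positive offset, and summed over 2,048 inputs it
drives the LSTM gates deep into saturation, freezing training entirely.
The ReLU head's bias is warm-started at the mean target, since for unlucky
initializations the single rectified output unit can be born dead (always
negative pre-activation) and would then never receive gradient.

The network core is implemented directly on NumPy arrays (float32
activations, exact BPTT, seeded Glorot initialization, forget-gate bias 1,
target-mean ReLU-head bias warm-start).  This
makes training and attribution bit-reproducible from a seed on any platform,
with no deep-learning-runtime dependency; the pretrained convolutional
encoder backend, which does need such a runtime plus a weight artifact, is
declared but optional, and a deterministic stub encoder (seeded random
projection of 32 × 32 grayscale + ReLU) serves tests and synthetic
end-to-end runs.

Generalization is always reported under leave-one-animal-out
cross-validation (or leave-one-day-out for recording-condition robustness):
one model per fold, every trial predicted only by a model whose training set
excluded that animal/day.

## Knowledge extraction

ε-layer-wise relevance propagation distributes the scalar head output
backwards; through any linear map, input *i* receives
`R_i = Σ_j a_i w_ij / (z_j + ε·sign(z_j)) · R_j` (ε = 1e-4 by default,
recorded with every result).  Through the recurrent scorer the rule is
applied in its modified-gradient form: relevance equals the (centered)
input times a backward pass in which the derivative of every
zero-preserving nonlinearity (tanh, ReLU) is replaced by the stabilized
ratio act(z)/(z + ε·sign z); sigmoid gates keep their true derivative (the
ratio σ(z)/z diverges at z = 0 because σ(0) = ½), and multiplicative LSTM
interactions pass relevance through both factors.  This matches the
semantics of gradient-override LRP implementations for recurrent networks;
a candidate-path-only (signal-takes-all) recursion was evaluated and
discarded because it systematically missed planted informative features the
trained scorer demonstrably used.  The temporal max-pool passes each unit's
relevance to its winning timestep.  Gradient × input and |gradient|
saliency are available as
assumption-free cross-checks; on linear networks gradient × input equals
ε-LRP in the ε → 0 limit, which the tests verify, along with manual-recursion
oracles on toy networks and approximate conservation (≤ 5 % at ε = 1e-4) on
bias-free piecewise-linear stacks.

Global feature importance is the mean |relevance| per encoder feature over
frames and clips.  Importance vectors from scorers trained on different
tasks are compared by Pearson correlation of log-transformed values
(importances span orders of magnitude; values are floored at 1e-12 before
the log).

## Discovery analytics

The ~200 features with the highest importance are selected (ties to the
lower index), frames are embedded by PCA on those features (centered on the
pooled pre/post-stroke frame set; partial least squares against the group
contrast is the alternative for tasks where PCA mixes groups), and the first
7 components are clustered by k-means, k = 40, with 10 seeded restarts
(best inertia kept; conclusions are robust for k in 20–60).  Per cluster:

* selectivity index `(Ns − Nc)/(Ns + Nc)` over stroke/control frame counts;
* a movement category from the 8 member frames nearest the center, assigned
  when ≥ 4 agree, ties and failed quorums labeled "not clear" (clusters
  smaller than 8 probe all members);
* day-wise occupation probabilities `p_j(day)` (counts normalized per day;
  frames from days outside the clustered pool are assigned to nearest
  centers), and the stabilized ratios `M1 = (p1 + ε)/(p0 + ε)`,
  `M6 = (p6 + ε)/(p0 + ε)` with ε = 1e-4, where p0 is pre-stroke, p1 day 1,
  p6 the pooled later recovery days.  M1 ≫ 1 flags a novel compensatory
  movement, M1 ≪ 1 a movement lost to stroke.

Trajectory variability: each trial's path through the 7-component embedding
is flattened component-wise into one vector; similarity of two trials is the
maximum of their circular normalized cross-correlogram (identical trials
give exactly 1; a circularly shifted copy gives 1 at the shift lag, making
the measure robust to reach-onset misalignment).  Circular correlation was
chosen over windowed normalization because it makes the shift identity
exact.  Dynamic time warping (classic O(T²) dynamic program on frame-wise
Euclidean distances) is the velocity-robust alternative (identity → 0).
Least-squares ellipse fits (Fitzgibbon's direct conic method) are provided
for visualization only.

## Evaluation statistics

Per-animal network scores, expert scores, and lesion volumes are min–max
normalized to a common [0, 1] scale (z-scoring is the variant; both preserve
orderings).  Whether the network or the expert sits closer to the anatomical
ground truth is tested by a Wilcoxon signed-rank test on the paired
per-animal |score − lesion| distances — exact distribution for n ≤ 25,
normal approximation with continuity correction above.  Inter-rater
agreement is the mean absolute per-animal score difference ± SEM (over
animals), compared across raters by paired t-tests.  Lesion volume is also
regressed on the seven element scores (OLS with intercept,
leave-one-animal-out; rank-deficient designs fall back to the
pseudo-inverse with a warning), which weights elements instead of summing
them.  The parallel-beam walking task uses the mean of three min–max
normalized measures (paw-placement deviation, traversal time, placing
attempts per step) as its composite disability score.

## The synthetic cohort

No public accession exists for the study's videos, so all pipeline stages
are validated on a generated cohort with planted ground truth
(`reachscore.synthetic`).  Defaults mirror the real study design: 8 animals
(half stroke), days −1/1/6/11/15, 20 trials per day, 125-frame clips, 2,048
features of which 200 are informative.

* **Severity** σ ∈ [0, 1] per animal and day: 0 pre-stroke and for controls;
  stroke animals start near `severity_day1` = 0.8 (per-animal ±20 % jitter)
  on day 1 and decay geometrically (`recovery_rate` = 0.1/day), reaching
  ~0.2 by day 15 — monotone recovery in expectation.
* **Grammar**: each trial is a contiguous ordered element sequence
  (lift … supination II, then eating; mean element durations 8–10 frames,
  log-normal jitter).  With probability `0.8·σ` the mid-reach phase is
  replaced by compensatory "reach with mouth"; the terminal phase is normal
  "eat with both hands" only when σ < 0.25, else generic eating.  These two
  condition-specific categories are the planted targets of the clustering
  stage.
* **Features**: `baseline + prototype(category) + σ·impairment-shift +
  day-nuisance + AR(1) noise`, rectified at zero.  Category prototypes and
  impairment shifts live only on the informative set F*; day-specific
  nuisance offsets (sd 0.2) live only off F* (a config switch can
  contaminate F* to stress leave-one-day-out); AR(1) noise (sd 0.3,
  ρ = 0.6) is everywhere, with its scale amplified by (1 + σ) so
  post-stroke trajectories are less reproducible.  The baseline is kept well
  above zero so rectification almost never clips off-F* dimensions —
  clipping would couple their means to the severity-scaled noise variance
  and break the planted independence from σ.
* **Expert scores**: each element scored `0 / 0.5 / 1` by thresholding
  σ + N(0, 0.08) at 1/3 and 2/3; the cumulative score is the sum.
* **Lesion volume**: `50·peak σ + N(0, 3)` mm³, clipped at 0; exactly 0 for
  controls.  The scale is in the range of rodent photothrombotic
  motor-cortex lesions.

All randomness flows from one seed through named substreams (cohort
structure, per-trial noise, rater noise), so a config is a complete,
bit-reproducible specification.

What the generator does **not** emulate: photorealistic appearance, encoder
artifacts and correlations of real convolutional features, behavioral
nonstationarity within a session, off-task frames (rearing, walking away),
and inter-rater systematic biases.  Passing tests on this cohort therefore
demonstrates that the pipeline recovers structure *of the planted kind* at
realistic sizes and noise levels — not that the real-data effect sizes
would be reproduced.

## Problem sizes in the test suite

The suite exercises the full default cohort (800 clips × 125 × 2,048) for
the end-to-end recovery checks, with scaled-down scorers (32 LSTM units) and
a few dozen training epochs; cross-validation folds subsample the training
side to a fixed number of trials per animal-day.  These sizes are the
package's CPU-sized preset: they converge on the planted signal (verified on
training-loss curves) while keeping a full run on one core in the minutes
range.  Unit tests use miniature cohorts (tens of features) for plumbing
and oracle checks.

## Known limitations

* ε-LRP through the LSTM follows the modified-gradient convention;
  relevance conservation is only approximate for gated architectures, which
  is why gradient × input is carried as a cross-check everywhere.
* Pixel-level relevance through a real pretrained convolutional backbone is
  out of scope; frame saliency uses the gradient pulled back through the
  encoder (closed form for the stub).
* The element-class segmentation head assumes the canonical element order
  for its ±1-category tolerance; vocabularies without ordinal structure
  would need a different tolerance rule.
* `KMeans` inertia ties across restarts resolve by restart order
  (scikit-learn's behavior); cluster identities are stable only given the
  seed.
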