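# Methods

This note records the models, parameters and numerical choices behind
`synemclass`, and what the synthetic experiments do and do not show.

## Coordinate handling and patch extraction

Annotations live in section coordinates (microns); images carry an
independent geometric transform.  A point is mapped to image pixels by
inverting the trace transform and applying the image transform forward.
Each transform composes translation, rotation, isotropic scale and a
small polynomial deformation over the basis {xy, x², y², x²y}:

    q = s·R(θ)·p + t + C·basis(p)

The inverse is Newton iteration started from the affine inverse, with an
analytic Jacobian; it raises rather than returning a bad point when the
deformation is too strong to invert (the map is only guaranteed
invertible for deformation gradients small against the affine part).
Round-trip error is < 1e-6 px for valid transforms; in practice it sits
near machine precision.

Conventions, used everywhere: 0-based coordinates, x = column,
y = row, pixel centres at integers.  Patches are cropped with the window
starting at `round(c) − size//2`; borders are reflect-padded so every
patch has exactly the configured size, which keeps training tensors
uniform.  Annotation names encode the connection as `preID-postID`
(configurable regex).  The primary annotation format is a documented
JSON manifest; a simplified RECONSTRUCT-style XML dialect is read
through the same function.

## Synthetic EM generator

The generator emulates what a transmission-EM patch of a chemical
synapse shows: a dark membrane curve between two cells, a presynaptic
cluster of vesicles (dark rims, lighter lumen), and a postsynaptic
density band hugging the membrane, over a smooth background field with
Gaussian pixel noise.  Non-synaptic distractor patches render a coated
vesicle (spiked ring), botrysome (blob cluster) or autophagosome (double
ring) without the synapse geometry.

Class signal is injected through the vesicle count and size
distributions and the PSD band depth, because those are the structural
features the CAM analysis highlights.  Defaults (full scale 500 px;
structural sizes are fractions of patch size, so scaled-down patches
keep their geometry):

| parameter | excitatory | inhibitory | generic synapse |
|---|---|---|---|
| vesicle count (mean, sd) | 30, 6 | 18, 6 | 24, 8 |
| vesicle radius (fraction of patch) | 0.018, 0.004 | 0.025, 0.005 | 0.020, 0.005 |
| PSD depth | 0.35 | 0.15 | 0.25 |

Other defaults: membrane contrast 0.35, vesicle rim contrast 0.45 with
rim width max(1.2 px, 0.3·r), background field amplitude 0.02, noise sd
0.05, 3–10 frames per synapse, 1–41 synapses per presynaptic cell.  Rim
contrast and background amplitude were set so that the configured
structural differences are actually visible at the 128-px test scale;
with fainter rendering the "class signal" existed only in metadata, not
in pixels.

Each synapse's frames share one geometry (same vesicle layout, membrane,
background) with per-frame jitter: ~1% patch-size translation, 5%
vesicle dropout, independent noise.  This reproduces the strong
z-correlation of 60-nm serial sections, which is exactly why splits must
be grouped by cell.  Randomness is a splittable SeedSequence hierarchy
(dataset → cell → synapse → frame), so any subset regenerates
identically.

What the generator does *not* model: realistic EM texture (organelles,
cytoskeleton, staining gradients), gap junctions, dense-core vesicles,
section artefacts (folds, contamination), or anisotropic pixel sizes.
Passing the recovery experiments therefore shows that the pipeline can
learn and explain the *designed* class structure end to end — not that
it would reach any particular accuracy on real tissue.

## Deduplication and splitting

Exact duplicates are removed by pixel hash (or identical centre + z when
images are absent).  Overlap is bounding-box IoU between same-section
patches; the greedy earliest-kept filter drops a patch whose IoU with a
kept patch exceeds 0.5 (configurable).  Greedy-by-index makes the
operation deterministic and idempotent.

Split fractions apply to (pre, post) cell-ID groups, not patches:
leakage prevention dominates class balance, and realised patch fractions
drift with group granularity.  Groups are sorted, shuffled under the
split seed, and allocated by largest-remainder rounding with every
non-zero split guaranteed at least one group.

## Classifier and training schedule

Both tasks (synapse/non-synapse, excitatory/inhibitory) use a
convolutional body → global average pooling → bias-free linear head
producing 2 logits.  Class indices: 0 = inhibitory/non-synapse,
1 = excitatory/synapse, defined in one table.

The default `small_cnn` body is three strided convolutions
(1→8, 7×7 s4; 8→16, 3×3 s2; 16→32, 3×3 s2, ReLU throughout), giving a
32-channel map at 1/16 resolution (8×8 on a 128-px input), implemented
in numpy with manual backpropagation.  A 33rd, constant-one channel is
appended to the feature map: the head's weight on it acts as a spatially
uniform offset, so the strictly bias-free head (required for the CAM
identity below) keeps the capacity of a logistic model with intercept.
Without it, held-out accuracy saturated well below what an intercepted
logistic fit achieves on the same frozen features, because the decision
boundary was pinned to the origin of a non-negative feature space.

Inputs are grayscale in [0, 1], resized to the configured input size
(128 default; the full-scale path uses 512, reconciling the 500-px crop
with a power-of-two input) and standardised by the fixed affine
(x − 0.5)/0.25.  Augmentation is horizontal/vertical flips only.

Training runs in two sessions: (1) body frozen, only the head fitted;
(2) everything unfrozen from the phase-1 best checkpoint at a lower
rate.  "Best" means maximum validation accuracy, earliest epoch on
ties, tracked across both phases; the returned model is that
checkpoint.  The training report records body-parameter checksums at
the start, the phase boundary and the end, making the freeze contract
auditable.

Optimizer: Adam (lr 0.1 for the convex head-only phase, 3e-3 for
fine-tuning, batch 8).  Plain momentum SGD at conventional rates is
available via config but does not converge within the short scaled-down
schedules used here (5 + 10 epochs); Adam's per-parameter scaling is
what makes those schedules workable.  At full scale the schedule is
100 + 200 epochs.

The `resnext50` backbone option (ImageNet-pretrained, 2048-feature head
input, grayscale replicated to 3 channels) requires the optional
`torch` extra and raises an informative error without it; every test
and experiment in this repository uses `small_cnn`.

## Voting and evaluation

Per-synapse call: majority over frame argmaxes; a tie goes to the class
with higher mean probability.  Per-neuron decision over synapse calls
(votes): conclusive iff total ≥ 3 and max > 1.5 × min, *strictly* — so
6 vs 4 is inconclusive.  Votes count synapses, not patches.

Precision is reported as TP/(TP+FP) and recall as TP/(TP+FN), the
standard definitions.  Inconclusive calls are excluded from the
confusion matrix and counted separately.

## CAM analysis

With GAP + bias-free head, projecting the head weights onto the feature
map, `CAM_c = Σ_k w_ck F_k`, satisfies mean(CAM_c) = logit_c exactly;
the implementation checks the head has no bias and the test suite
asserts the identity to 1e-4 relative tolerance (observed: machine
precision).  For region statistics the coarse map (16×16 at full scale)
is bilinearly upsampled to input resolution — a pixel-area threshold is
meaningless on the coarse grid.  Segmentation: Otsu threshold → connected
components of the suprathreshold mask as watershed seeds → watershed of
the negated map restricted to that mask.  Regions with area ≤ 5,000 px
(full scale) are discarded; at other input sizes the threshold scales as
`5000·(input/512)²`.  A constant map yields a single all-covering
region.  Region mean intensities are raw activation units; a normalised
view exists for rendering only.

## Embedding

Features are the penultimate (post-GAP) vectors — the 2-logit output
would make a 20-dim PCA meaningless — averaged over each synapse's
frames, one point per synapse.  PCA to min(20, n, d) components
(clipping recorded in the result), then t-SNE to 2-D with perplexity
min(30, (n−1)/3), PCA initialisation and a mandatory seed.

## Scaled-down study conditions

Tests and the acceptance script run 128-px (some 64-px) patches,
20-cell studies with 3–5 synapses per cell and 3–4 frames per synapse,
split 0.5/0.25/0.25, and the 5 + 10-epoch schedule.  Strong-effect
recovery uses vesicle-count means 10 vs 40 (sd 3) and PSD depths 0.15
vs 0.45; the null condition makes both classes identical, where test
accuracy must stay within the 99% binomial interval of chance.  These
sizes were chosen once as the smallest studies at which group-level
sampling variance does not dominate the class signal.

## Known limitations

- The numpy trainer is single-threaded BLAS-bound and meant for
  hundreds, not tens of thousands, of patches; the full-scale ResNeXt
  path needs the torch extra.
- Determinism is per-platform: fixed seeds give bit-identical reruns on
  one machine, but BLAS reduction order may differ across builds.
- Group-fraction splitting accepts class imbalance; no stratification.
- The inconclusive rule depends on how many of a neuron's synapses land
  in the evaluated split; neurons with < 3 held-out synapses can never
  be called.
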