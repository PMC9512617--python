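# Methods

## Input construction

A recording holds P tri-axial accelerometer streams (units of g), S optional
scalar channels and one label per timestamp.  Sliding windows of T samples
(default 24) advance by `step = round(T·(1 − overlap))`, clamped to a minimum
of 1 (default overlap 0.5 → step 12); the number of windows over n samples is
`floor((n − T)/step) + 1` for n ≥ T and 0 otherwise, and a window's label is
the label at its **last** timestamp — no majority voting, NULL kept as-is.
Indexing is 0-based and half-open throughout.  Recordings with missing (NaN)
samples are rejected rather than imputed.

Each window is re-indexed into three P × T axis pictures (row order = the
configured position order, recorded with every run's config) plus an S × T
scalar picture when S ≥ 1.  This is a bijective re-indexing: every picture
entry is a raw channel value, nothing is aggregated.

Channels are z-scored per channel before windowing, using statistics of the
training time block only; constant channels map to zero.  The raw signals
carry ±1 g gravity offsets that differ per position and pose, which would
otherwise dominate the early convolution layers, so scaling is applied even
though it is a preprocessing choice rather than part of the model proper.

## Network

Every picture is a 1-map image entering a stack of valid (no-padding)
convolutions, each followed by ReLU (σ′(0) := 0).  The pre-activation of
output map o at (i, j) with strides (h_s, w_s) is

    z[o,i,j] = Σ_c Σ_{u,v} a[c,o,u,v] · x[c, i·h_s+u, j·w_s+v] + b[o],

with output extent `floor((H − K_h)/h_s) + 1` per axis.  Backpropagation
follows the standard residual recursion: δ of a layer is pushed to its input
by full-boundary correlation with the 180°-rotated kernels (for stride 1;
general strides use the equivalent scatter), multiplied elementwise by σ′ of
the previous pre-activation; the weight gradient contracts input patches
with δ, and the bias gradient sums δ.  The full-correlation boundary choice
is the one under which central finite differences agree with the analytic
gradients, which the tests verify to ~1e−9 relative error (1e−5 asserted)
on 20 random shared networks; finite differences use ε = 1e−6 in double
precision, and the check is meaningful only where the perturbation does not
cross a ReLU kink — with continuous random pre-activations the crossing
probability at this ε is negligible, and none was observed.

Max pooling (disjoint tiles that must divide the map dims; first-index
argmax on ties, recorded for gradient routing) is implemented and tested but
not used in the reference architecture, whose four conv layers feed the
flatten step directly.

The flattened branch outputs are concatenated into a single fully connected
layer with softmax (max-subtraction stabilised).  The head is deliberately
minimal — one linear map to C logits — and its parameters are excluded from
the convolution-parameter accounting, which compares conv stacks.

**Sharing.**  In the shared variants the three axis branches resolve to the
same named parameter arrays: sharing is structural, so the branches cannot
drift apart and the shared gradient is automatically the sum (the literal
chain rule; a mean would only rescale the learning rate) of the three branch
contributions.  The scalar branch always owns its parameters — its picture
geometry differs from the axis pictures, so it cannot share theirs.

**Stacks.**  The reference stack is 3×3 (1→64), 3×3, 5×1, 5×1 (heights
first: 5×1 kernels span 5 rows/positions), giving the 640 / 36 928 / 20 544 /
20 544 per-layer counts and the 235 968 vs 78 656 totals.  That geometry
needs ≥ 13 picture rows; for the 4-position experiments the package uses a
compact stack with the same shape — two cross-position kernels then two
time-only kernels, widths (3, 3, 5, 5) — with kernel heights reduced to fit
the row budget ((3, 2) for P ≥ 4, down to (1, 1) at P = 1) and 8 feature
maps.  The 1-D baseline at matched depth applies the time-only stack to all
3P + S channels stacked as one picture.

## Training

Plain mini-batch SGD (no momentum) on mean categorical cross-entropy;
learning rate 0.01, batch size 32, He-scaled Gaussian initial weights
(sd = √(2/fan-in)) and zero biases from a seeded generator.  Training stops
when the largest absolute parameter change over an epoch falls below a
threshold (default 0: run the full epoch budget, default 40) and raises a
divergence error naming the epoch if the loss goes non-finite.  The history
is the per-epoch batch-size-weighted mean loss.

## Synthetic data

The generator emulates the structure of multi-position HAR corpora: P = 4
positions, 5 activity classes plus NULL, an imbalanced segment plan (NULL
most frequent, activity supports in ratio 5:4:3:3:2, segments of 160–480
samples), and 24 012 samples — 2 000 windows at the default windowing.  Per
activity and axis the shared oscillation has a class-specific base frequency
(0.040–0.190 cycles/sample) scaled per axis by (1.0, 1.37, 1.71) so the
three axes are mutually near-uncorrelated; the position-private term jitters
that frequency by a seeded factor in [0.75, 1.35].  Coupling κ = 0.8,
amplitude 0.4 g, noise sd 0.05 g; each class assigns a rotating gravity pose
per position; NULL is gravity + noise only.  Scalar channels are AR(1)
walks (coefficient 0.995) carrying no class signal.  g is represented as
1.0 — readings are in units of g.

These choices make the task *learnable but not trivial*: with zero noise a
nearest-centroid rule on raw windows that lie inside one segment classifies
perfectly (tested), so a near-1 model F1 demonstrates the pipeline works,
not that the problem is hard.  What the simulator does **not** emulate:
biomechanically realistic limb kinematics, gyroscope/magnetometer physics,
sensor drift or dropout, sampling-rate conversion, or label noise — so
passing results bound implementation correctness, not real-world accuracy,
and no real-dataset benchmark numbers are claimed anywhere in this package.

The measured correlation structure on the default recording is same-axis
mean |r| ≈ 0.28 vs cross-axis ≈ 0.07.  The same-axis value is far below the
within-segment coupling (≈ 0.9 at κ = 0.8) because the whole-recording
correlation mixes in between-segment gravity shifts that differ per
position; the analysis deliberately uses the whole recording, since that is
what a practitioner would compute on a raw corpus, and the group contrast —
same-axis ≫ cross-axis — is the premise being checked.

## Evaluation

Support-weighted F1 with P_i = column precision, R_i = row recall, 0/0
ratios defined as 0; Σ w_i = 1 over present classes.  NULL is included by
default (excludable via `exclude_labels`), and a uniform-weights switch is
provided.  The experiment split is by contiguous time blocks (70/30), not
shuffled windows — 50%-overlapping windows share half their samples, so a
shuffled split would leak test content into training.

## Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| window T / overlap | 24 / 50% | 48 also supported |
| positions P / classes | 4 / 5 + NULL | simulator default |
| recording length | 24 012 | ≈ 2 000 windows |
| feature maps (experiments) | 8 | reference accounting uses 64 |
| learning rate / batch | 0.01 / 32 | plain SGD |
| epochs (experiments) | 25–40 | loss plateaus by ~25 |
| gradient-check nets / geometries | 20 / 100 | vs finite differences / loops |

Training the shared 8-map model on ~1 400 windows takes a few seconds on one
CPU core; the full test-suite runs in well under a minute.

## Known limitations

* Valid convolution only — no padding, dilation, batch-norm or dropout; no
  automatic differentiation (gradients are hand-derived, which is the point).
* The dense head is a single layer; deeper heads were not needed on the
  synthetic task and are out of scope.
* The fixture container (HDF5) and checkpoint (NPZ) are runtime artifacts;
  the CSV dialect is the interchange format.
* Position subsets in the comparison experiment are order prefixes, a proxy
  for sensor-group selection on real hardware layouts.
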