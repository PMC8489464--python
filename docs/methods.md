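# Methods

## Problem and formulation

The package detects a fixed set of three anatomical landmarks per cardiac
view: the two mitral-valve-plane points and the apex on long-axis views
(CH2/CH3/CH4), and the anterior/posterior RV-insertion points plus the LV
center on short-axis (SAX) views. Detection is cast as semantic
segmentation over L+1 classes. A landmark at `x_k` is encoded as a Gaussian
spatial-probability map `g_k(x) = exp(−‖x − x_k‖²/2σ²)` with σ = 4 px by
default; the background channel is `clamp(1 − Σ_k g_k, 0, 1)` and the stack
is renormalized per pixel into a proper class distribution. This
clamp-then-normalize construction keeps each landmark channel's maximum at
the pixel nearest the annotation while making entropy-based losses
well-defined. Absent landmarks contribute an all-zero channel, so
landmark-free frames (which occur in basal/apical short-axis slices) encode
as pure background and are first-class citizens of training and decoding.

A caveat of the construction: where Gaussians of different landmarks
overlap enough that their sum exceeds 1, the per-pixel renormalization
distorts channel shapes and can shift peaks. With σ ≤ 6 px this is
negligible when landmark separations stay above ~3σ, which the cardiac
geometry satisfies at the 96×96 reference scale; it is the reason the
reference frame is not smaller.

## Network

The detector is a standard U-Net: `n_levels` resolution levels (default 4),
each a stack of `blocks_per_level` (default 2–3) blocks of 3×3 convolution
→ instance normalization → ReLU; 2×2 max-pool downsampling with channel
doubling; a decoder mirroring the encoder with nearest-neighbour upsampling,
a 3×3 channel-halving convolution, skip concatenation, and the same blocks;
and a final 1×1 convolution emitting per-pixel class scores. Weights are
He-initialized from a seeded generator. Instance norm was chosen over batch
norm so behaviour is independent of batch composition (batches mix views);
both the norm flavour (`instance`/`none`) and the architecture shape are
config fields.

The engine — convolution (im2col GEMM), pooling, normalization,
backpropagation, Adam — is implemented directly on NumPy arrays with a
configurable dtype: float32 for training throughput, float64 for the
finite-difference gradient verifications in the test suite. Analytic
gradients of every layer and of the full loss are covered by
finite-difference tests.

## Loss

Training minimizes `KL(p‖q) + (1 − soft-Dice(p, q))` between the truth
heatmap `p` and the softmax prediction `q`:

* KL term: mean over pixels of `Σ_c p_c log(p_c/q_c)` with `0·log 0 = 0`
  and `q` floored at 1e−12 only where it is exactly zero, so `KL(p, p)` is
  exactly 0.
* Dice term: `dice_c = 2 Σ p_c q_c / (Σ p_c + Σ q_c + 1e−8)` per landmark
  channel (background excluded, so the dominant background cannot wash out
  landmark gradients), averaged over channels and samples, entering the
  loss as `1 − mean dice`. The similarity ratio is negated into a loss
  because adding a similarity to a divergence would reward mismatch; the
  sum is then zero exactly at a perfect one-hot match. For smoothed
  (non-binary) truths the dice term retains its analytic self-overlap slack
  `1 − Σp² /Σp` even at `q = p`; the KL term is the part that vanishes.

Gradients with respect to the raw scores are analytic (KL reduces to
`(q − p)/N` through the softmax; the Dice part is chained through the
softmax Jacobian). The saliency map is the magnitude of the loss gradient
with respect to the input pixels, obtained by backpropagating one step
further.

## Training

Adam with lr 0.001, β = (0.9, 0.999), ε = 1e−8; the learning rate is
divided by 2 whenever the validation loss fails to improve by a relative
1e−3 for 5 consecutive epochs (the "plateau" rule made concrete); the
returned model is the minimum-validation-loss checkpoint. Splits are
patient-wise (90/10 by default): no patient contributes to both sets. The
long-axis model is multitask: CH2/CH3/CH4 samples are pooled and shuffled
so minibatches mix views at pooled proportions, with no rebalancing.
Fine-tuning for a new contrast starts from pretrained weights with lr
0.0005 for 10 epochs, all layers trainable (no freezing). One master seed
drives splitting, shuffling, augmentation and weight init, making runs
bit-reproducible.

Augmentation (optional, off in the reference runs, which randomize anatomy
instead): with probability 0.5 the as-acquired image is used, otherwise the
shading-corrected one; then joint image/landmark rotation ±30°, isotropic
scale ±10%, translation ±20 px, and intensity gamma 0.8–1.2. Mirror flips
are deliberately excluded: they swap anterior/posterior landmark semantics.
Landmarks transformed out of bounds are marked absent. Network inputs are
normalized per image to [0, 1] by the 1st–99th percentile window.

## Preprocessing

All geometry lives in a 0-based (row, col) pixel frame, pixel centers at
integer coordinates; millimetres are pixels × spacing. Images are resampled
to the target spacing (default 1 mm) with bilinear interpolation —
output size rounded half-to-even for determinism — then center-padded or
center-cropped to the detector grid (default 400×400; 96×96 in the
reference study), with the extra pixel going to / coming from the
high-index side. Both steps return composable coordinate maps so
annotations track the pixels exactly.

Surface-coil shading is modelled as a smooth multiplicative field.
`estimate_bias_field` fits a degree-3 polynomial surface to the log
intensities by iteratively reweighted least squares, downweighting pixels
far *above* the surface (bright anatomy is an outlier to the shading, not
part of it), and exponentiates, normalizes to max 1, and floors the result.
A projection in log space is idempotent: correcting a corrected image
changes nothing, and a pure multiplicative ramp is recovered essentially
exactly. Simple Gaussian-blur field estimates were rejected because, at
phantom scale, the anatomy contaminates the field enough to *increase*
background variability after division. `correct_inhomogeneity` divides the
field out and rescales to preserve the input mean. At inference the
correction is always applied (training samples it at p = 0.5); this is
exposed as a CLI flag.

## Decoding

Per landmark channel the global maximum is found (ties broken at the
smallest row-major index); the landmark is present iff the peak probability
is ≥ τ = 0.5 — the natural majority rule, and the reason uniform or
background-only predictions can never produce spurious detections.
Subpixel refinement fits a separable quadratic to the log probabilities of
the peak's immediate neighbours, which is exact for sampled Gaussians of
any width; a probability-weighted centroid over a ±2σ window is the
fallback when the log fit is unusable (border peaks, zero neighbours). The
centroid was originally the primary rule but biases wide-kernel peaks near
borders by more than a pixel; the log-parabolic fit has no such bias.

## Phantom generator

The generator emulates the statistical structure the detector relies on,
not MR physics:

* **Long-axis**: a bright bullet-shaped ventricle silhouette (quarter-ellipse
  width profile) with a darker myocardial rim, at a random position and
  orientation; valve points flank the base, apex at the pole, so the
  apex-to-midbase distance equals the sampled LV length exactly.
* **Short-axis**: bright LV blood pool inside a darker annulus, with a
  crescent-shaped RV cavity hugging the epicardium over a random angular
  sector on the anatomically consistent (left/anterior) side; insertion
  points at the sector ends, C-LV at the center. With probability
  `prob_no_landmark_frame` the frame is background only.
* **Cine**: a 30-phase cycle whose LV length follows
  `L_ED (1 − cf (1 − cos 2πt/n)/2)` — end-diastolic at phase 0, exactly
  `(1 − cf) L_ED` at mid-series, cyclic to within 1%.

Degradations: multiplicative shading (white noise smoothed at a quarter of
the image extent, rescaled to `[1 − amplitude, 1]`, default amplitude 0.3),
Rician-approximated noise (default SD 3% of dynamic range), and Gaussian
annotation jitter (default 0.5 px) emulating interreader variability.
Geometry ranges are millimetre quantities calibrated to the default 96×96 /
1 mm frame (LV length 45–65 mm, epicardial radius 14–22 mm, wall 5–9 mm)
and rescale proportionally via `PhantomConfig.scaled_to`. Every sample
records its sampled geometry so tests can verify ground-truth
self-consistency.

What the phantoms do **not** model: MR acquisition physics, pathology
(scar, amyloid), anatomical variability beyond affine pose/size, through-
plane effects, or realistic texture. Passing the phantom study therefore
demonstrates that the pipeline's machinery is correct and trainable — not
clinical-grade performance, which depends on real data diversity.

## Reference study and problem sizes

The package's reference experiment (`cardiomark.reference`) trains on 180
short-axis phantoms at 96×96 / 1 mm (split 90/10 patient-wise), a 4-level
base-8 U-Net with 2 blocks per level, 16 epochs with minibatches of 4, and
evaluates on 100 independently seeded phantoms. These sizes are the
package's CPU-scale defaults — each piece is configurable up to the
clinical-scale 400×400 setting with a wider net. At reference scale the
detector reaches a ~100% detection rate with no false positives and
sub-pixel mean error, is insensitive to the heatmap kernel within
σ ∈ {2, 4, 6} (mean errors within 1 px of each other), and fine-tuning on
contrast-inverted phantoms beats scratch training at an equal 10-epoch
budget. The minibatch of 4 was chosen because, at a fixed per-epoch wall
cost on one CPU core, more optimizer steps sharpen channel confidence
faster; larger batches need more epochs to push landmark peaks past the
presence threshold.

## Measurement conventions

* LV length: apex to the midpoint of the two valve points, invariant to
  valve order.
* RV-insertion angle: angle of the C-LV → A-RVI vector, counterclockwise
  from the +col axis with the row axis pointing down, in [0, 360). The
  zero direction is a convention (recorded in report metadata); any fixed
  frame supports comparisons between label sources.
* Shortening curve: baseline is phase 1 (end-diastole); phases with missing
  landmarks yield NaN gaps; curve undefined if phase 1 is incomplete.
* Detection rate: percentage of images with every truth-present landmark
  detected; spurious detections are counted separately; distances (mean ±
  SD, mm) pool successful detections only.

## Numerical choices and degenerate inputs

Round-half-to-even for resampled sizes; peak ties broken row-major;
`ε = 1e−8` in dice, `1e−12` KL floor applied only to true zeros; all-zero
images yield a flat bias field of ones; coincident A-RVI/C-LV or missing
landmarks raise an explicit undefined-measurement error rather than
returning numbers; checkpoint files embed the full model config plus a
format version.

## Known limitations

* The NumPy engine is single-device and unoptimized beyond GEMM batching;
  clinical-scale (400×400, base-32) training is possible but slow.
* The bias-field model is a global polynomial: it cannot represent
  multi-lobed coil patterns that genuinely need more spatial freedom.
* Decoding assumes one instance per landmark class per image.
* The σ-insensitivity of decoding degrades when landmark separations
  approach 2–3σ (see the encoding caveat above).
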