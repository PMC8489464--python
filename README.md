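# cardiomark

Automatic detection of anatomical landmarks on 2D cardiac-style MR images,
with the derived clinical measurements that depend on them.

Cardiac MR analysis hangs off a handful of anatomical points: on long-axis
views (two-, three-, four-chamber) the two mitral-valve-plane points and the
apex define the LV long axis; on short-axis views the anterior and posterior
RV-insertion points (A-RVI, P-RVI) anchor the AHA sector model and the LV
center (C-LV) fixes the myocardial ring. Locating them by hand is the slow,
operator-dependent step in otherwise automated pipelines. `cardiomark`
implements a heatmap-based detector for these landmarks together with a
synthetic cardiac phantom generator, so the complete pipeline — data,
training, detection, measurement — runs and is verifiable on a laptop CPU
with no clinical data.

## Method

Detection is reformulated as semantic segmentation. Each landmark annotation
is convolved with an isotropic Gaussian kernel (σ = 4 px by default),

```
g_k(x) = exp(−‖x − x_k‖² / 2σ²),
```

giving one spatial-probability channel per landmark plus a background
channel (`1 − Σ_k g_k`, clamped and normalized per pixel), so detecting L
landmarks is an (L+1)-class segmentation problem. A U-Net (4 resolution
levels, conv–norm–ReLU blocks, skip connections, 1×1 output head) predicts
per-pixel class scores; softmax probabilities `q` are trained against the
ground-truth heatmap `p` with a combined loss

```
L = KL(p ‖ q)  +  (1 − soft-Dice(p, q)),
soft-Dice_c = 2 Σ p_c q_c / (Σ p_c + Σ q_c + ε)   (landmark channels only),
```

optimized with Adam (lr 0.001, β = 0.9/0.999, ε = 1e−8), learning rate
divided by 2 on validation-loss plateaus, best-validation checkpoint kept,
with patient-wise 90/10 train/validation splitting. The three long-axis
views train jointly as one multitask model with views mixed within each
minibatch. Transfer to a new image contrast fine-tunes all layers at lr
0.0005 for 10 epochs. Decoding finds each channel's peak, declares the
landmark present when the peak probability reaches 0.5 (landmark-free frames
yield empty detections), and refines coordinates to subpixel precision with
a log-parabolic fit. Derived measurements: LV length (apex to mid-valve
plane), RV-insertion angle (C-LV → A-RVI, counterclockwise from the +col
axis), and the per-phase global longitudinal shortening ratio
`(L(1) − L(t)) / L(1)`.

The network engine (convolutions, instance norm, pooling, backpropagation,
Adam) is implemented directly on NumPy; no GPU or deep-learning framework is
required.

## Worked example

`examples/04_train_detector.py` trains a miniature detector on 60 synthetic
short-axis phantoms (48×48 px, ~1 min on one CPU core) and evaluates on 30
held-out phantoms:

```
validation loss: first 1.911 -> best 1.275 (epoch 7)
held-out detection rate: 100.0% (30 of 30 images), false positives: 0
mean landmark error: 1.22 mm
view  role  n  mean_mm    sd_mm
 SAX A-RVI 30 1.455900 0.657159
 SAX  C-LV 30 1.232955 0.518612
 SAX P-RVI 30 0.977607 0.397384
```

The detection rate is the fraction of images on which every present
landmark was found; distances are Euclidean errors (mean ± SD, mm) between
detected and reference landmarks over successful detections. The full
reference study (`cardiomark.reference.run_reference_training`, 180
phantoms at 96×96, 4-level U-Net, 16 epochs, a few minutes on CPU) reaches
a ~100% detection rate with sub-pixel mean error. Other examples cover
phantom generation, heatmap encode/decode, shading correction and cine
measurements:

```
$ python examples/05_cine_shortening.py
end-diastolic LV length 47.7 mm, end-systolic 37.1 mm
peak shortening ratio 0.222 at phase 17 (construction: 0.2 at mid-series)
A-RVI angle: 119.1 deg (frame: CCW from +col, row axis down)
```

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
cardiomark simulate --out data/ --n 100 --view SAX --seed 1
cardiomark train    --data data/ --out run/ --seed 1
cardiomark detect   --checkpoint run/model.npz --data data/ --out pred.csv
cardiomark evaluate --pred pred.csv --truth data/landmarks.csv --out-prefix eval
```

Every run records its configuration and master seed in a manifest, so a
`simulate → train → detect → evaluate` chain is exactly reproducible.
`detect` also reads DICOM/NIfTI/PNG/`.npy` images (with `--spacing` where
the container has no spacing metadata) and can dump per-image saliency maps
(`--saliency`), the gradient of the loss with respect to the input pixels.

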