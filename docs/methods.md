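# Methods

## The model

`mganet` implements a dual-branch convolutional framework for
benign/malignant lesion classification on grayscale ultrasound-style
images:

* **Classification branch** — a 34-layer residual network (7×7/2 stem
  with 3×3/2 max-pool, then stages of 3/4/6/3 basic blocks at widths
  64/128/256/512, global average pooling, two-way affine head).
* **Segmentation branch** — a UNet-shaped encoder–decoder whose encoder
  is an 18-layer residual network (2/2/2/2 blocks); the decoder
  upsamples bilinearly with skip connections from each encoder stage and
  ends in a 1-channel sigmoid head at input resolution, producing a
  per-pixel lesion probability map `mask`.

The two branches are coupled by **mask-guided attention (MGA)**. At an
insertion point with features F(C, H, W):

```
mask_resized = Resize(mask, H, W)                     (bilinear, half-pixel centers)
mask_norm    = (mask_resized − min) / (max − min + ε)  per image, ε = 1e−6
F_s = F ⊙ mask_norm                                    spatial branch
F_c = F ⊙ MLP(GAP(F ⊙ mask_norm))                      channel branch
F′  = F_s + F_c + F                                    parallel residual fusion
```

The channel MLP is squeeze-excitation shaped (C → max(C/r, 4) → C,
ReLU inside, sigmoid out; r = 16 by default).  Nothing on the mask path
is detached, so the classification loss back-propagates into the
segmentation branch — the property that makes the two tasks
co-adapt.  Ablation variants (`spatial_only`, `channel_only`,
`serial`, `none`) and placements (once per stage, or after every
residual block) are config options.

Insertion points are named L0 (stem output, after the first conv/pool)
through L4 (the four residual stages); the default enhances all five
scales, once after each stage's last block.  The single full-resolution
probability map is resized independently for each insertion point.

## Weak supervision

Segmentation ground truth is never required.  Each detection box
[x_min, y_min, x_max, y_max] becomes an elliptical pseudo-mask with
center ((x_min+x_max)/2, (y_min+y_max)/2) and semi-axes
((x_max−x_min)/2, (y_max−y_min)/2); `mask(i, j) = 1` iff the
inscribed-ellipse inequality holds at the integer pixel (boundary
included).  Centers and axes are kept as exact floats; masks are built
on the supervision grid (network resolution after preprocessing, or the
raw phantom grid when training on un-cropped phantoms) so prediction
and target share a lattice.

## Losses and metrics

* `L_total = L_cls + L_seg` (unweighted sum).
* `L_cls`: softmax cross-entropy.
* `L_seg = α·L_BCE + (1−α)·L_Dice`, α = 0.5.  BCE is the per-pixel
  mean (N = H·W) with probabilities clamped to [1e−7, 1−1e−7]; Dice is
  smoothed with ε_dice = 1.0 (config), computed per image and averaged
  over the batch.  The equation set reuses the symbol ε with no stated
  value for the Dice term; 1.0 is the common smoothing choice and is
  exposed in `LossConfig`.
* Metrics: accuracy; F1 = 2TP/(2TP+FP+FN) with malignant as the
  positive class (primary metric); rank-based Mann–Whitney AUC with
  ties counted half.  Repeated runs are summarised as mean ±
  t-interval (`t_{n−1,0.975}·s/√n`); the CI is across independent
  training runs, not a bootstrap over samples.

## Training schedule

Stage 1 pre-trains the segmentation branch alone against `L_seg`
(classification weights untouched — verified bit-identical in tests);
stage 2 optimises everything against `L_total`.  Adam with default
moments, initial learning rate 1e−4, no decay, batch size 32, 60 + 140
epochs at full scale.  Augmentation is horizontal flipping only, always
applied to image and pseudo-mask together.  The checkpoint with the
best validation F1 is kept; ties resolve to the later epoch (with equal
validation F1 the longer-trained weights have the lower training loss).
All randomness — weight init, batch order, flip draws — derives from
one integer seed; `run_experiment` repeats training with seeds
`seed+0 … seed+n_runs−1` (5 runs by default) and aggregates.

## Numerical substrate

No GPU framework is used.  The package carries a compact reverse-mode
automatic-differentiation engine over NumPy arrays (`mganet.autograd`)
with exactly the primitives the model needs — elementwise algebra with
broadcasting, reductions, matmul, im2col 2-D convolution, max pooling,
and bilinear resampling expressed as separable interpolation matrices —
plus a small layer/optimizer toolkit (`mganet.nn`).  Everything is
float64 on the CPU; gradients of every spatial primitive are verified
against central finite differences.  Bilinear resampling uses the
half-pixel-center convention with edge clamping (the same convention at
train and test time; the alternative corner-aligned convention differs
numerically).  Min/max reductions split gradients equally among ties.
Batch normalisation uses batch statistics during training and running
statistics (momentum 0.1) in eval mode, which makes eval-mode outputs
batch-order equivariant.

## Synthetic phantoms

Clinical ultrasound cannot be redistributed, so all experiments run on
generated phantoms that reproduce what the pipeline actually depends
on:

* a speckle-textured tissue field: slow multiplicative drift
  (amplitude 18 gray levels around 150) times a positive unit-mean
  noise field whose grains are spatially correlated (Gaussian
  correlation length 1 px), as in real speckle — per-pixel white noise
  would not survive the morphological pipeline and is not what scanners
  produce;
* a dark unscanned margin (0.12 of the frame on each side) and,
  optionally, a vendor-style text band or dark border that
  preprocessing must remove;
* one hypoechoic nodule per image (intensity drop 0.35–0.55).  Shape
  statistics encode the classic clinical cue: benign nodules are
  wider-than-tall smooth ellipses; malignant nodules are
  taller-than-wide (axis ratio 0.55–0.70) with a smooth radial
  boundary perturbation (amplitude 0.03–0.06) and 3–8 bright
  calcification specks.  Long semi-axes span 0.14–0.19 of the frame.

The ranges guarantee, with margin for pixel quantisation, that the
tight bounding box of a benign nodule is wider than tall and vice
versa, so the rule "malignant iff box taller than wide" is a 100%
oracle — the learning task is solvable at desk scale by construction.
What phantoms deliberately do **not** model: beam physics, attenuation
or shadowing, heterogeneous echotexture, multiple nodules, annotation
noise, or inter-scanner variation.  Passing the end-to-end tests
therefore demonstrates that the machinery (weak labels, attention,
staged optimisation, evaluation) works as specified — not that the
model reaches clinical performance on real data.

## Preprocessing

Adaptive thresholding marks a pixel foreground when it exceeds its
local mean by more than `offset` (default 5 gray levels); the
neighbourhood defaults to 51 px for full-size frames and scales down
with the image (twice the expected margin width).  The binary mask is
smoothed by 3×3 opening-then-closing (5×5 destroys speckle-scale
evidence; the kernel is a config parameter).  The largest 8-connected
component is taken as tissue; the bounding rectangle of its convex
hull (the hull repairs interior holes and boundary breaks) is the crop,
which is resized bilinearly to 224×224.  Lesion boxes are remapped with
outward rounding (floor minima, ceil maxima), so the back-projected box
always contains the original one.

## Desk-scale problem sizes

CPU-scale experiments in the tests and the acceptance script use
width-multiplier 1/8 models on 64×64 phantoms: a staged 2+4-epoch
experiment on 96 phantoms (64 train / 32 val, two runs, batch 8,
lr 2e−3 — small batches trade batch-statistics quality for more
optimisation steps at this scale), and a 3-seed comparison of parallel
MGA against the no-attention baseline on 200 phantoms (140/60, batch
16, 1+4 epochs).  Preprocessing checks run on 128-px decorated
phantoms, where the field-of-view pipeline is stable across hundreds of
seeds.  Class-activation maps are assessed at the two finest enhanced
scales (L1, L2; their normalised maps are averaged) because at 64-px
inputs the deeper maps are 4×4 and 2×2 and cannot resolve the nodule;
at full 224-px inputs `grad_cam` defaults to L4 (7×7), matching common
practice.

## Known limitations

* Float64 NumPy training is orders of magnitude slower than a GPU
  framework; the full 60+140-epoch schedule at 224 px is expressible
  but not practical here — all shipped experiments are the desk-scale
  configurations above.
* After only six total epochs, CAM localisation is noisy across seeds
  (hit rates vary by tens of percentage points between otherwise
  identical runs); the shipped experiments use fixed seeds and report
  what they measure.
* The no-attention baseline omits the segmentation branch entirely
  (the alternative — training it but ignoring its output — is
  constructible via `include_segmentation=True` with
  `attention_variant="none"`).
* `bbox_to_ellipse_mask` rejects degenerate boxes rather than emitting
  empty masks; callers must filter zero-area annotations.
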