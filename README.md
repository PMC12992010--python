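# mganet

Dual-branch, segmentation-guided classification of lesions in
ultrasound-style images, with weak supervision from bounding boxes.

Distinguishing benign from malignant thyroid nodules on ultrasound is
hard because most of the frame is diagnostically irrelevant: classifiers
fed whole images waste capacity on background texture and vendor
overlays.  `mganet` couples a 34-layer residual classification network
with an auxiliary UNet-style segmentation branch (18-layer residual
encoder) whose per-pixel lesion probability map steers the classifier's
intermediate features through **mask-guided attention (MGA)**: at each
scale the map is resized, min-max normalised, and applied through two
parallel branches fused residually,

    F_s = F ⊙ mask_norm
    F_c = F ⊙ MLP(GAP(F ⊙ mask_norm))
    F′  = F_s + F_c + F.

Pixel-level annotation is never needed — each lesion bounding box
becomes an elliptical pseudo-mask (the ellipse inscribed in the box)
that supervises the segmentation branch through a composite loss
`L_seg = α·L_BCE + (1−α)·L_Dice` with α = 0.5, alongside the
cross-entropy classification loss (`L_total = L_cls + L_seg`).
Training is staged: segmentation pre-training, then joint optimisation
in which the classification loss back-propagates through the attention
path into the segmentation branch.

Because clinical data are private, the package ships a seeded phantom
generator producing speckle-textured frames with one hypoechoic nodule
each — benign wider-than-tall and smooth, malignant taller-than-wide
with irregular margins and bright specks — plus optional text bands and
borders that the preprocessing stage (adaptive threshold, morphology,
largest-component convex hull, crop and resize to 224×224) removes.
Everything — including training, via a built-in NumPy autodiff engine —
runs on one CPU with no deep-learning framework.

This is aimed at researchers studying segmentation-guided attention and
weak supervision pipelines who need a fully reproducible, dependency-
light reference implementation, not a clinical tool.

## Worked example

Train the desk-scale configuration (width-⅛ model, 64-px phantoms,
2 pre-training + 4 joint epochs, two independent runs) and report
means with 95% confidence intervals:

```python
import numpy as np
from mganet import (ExperimentConfig, ModelConfig, TrainConfig,
                    PhantomArrayDataset, run_experiment)
from mganet.phantoms import generate_sample

rng = np.random.default_rng(123)
seeds = rng.integers(0, 2**31 - 1, 96)
samples = [generate_sample("benign" if i % 2 == 0 else "malignant", 64, int(s))
           for i, s in enumerate(seeds)]
train = PhantomArrayDataset.from_samples(samples[:64])
val = PhantomArrayDataset.from_samples(samples[64:])

config = ExperimentConfig(
    model=ModelConfig(width_multiplier=1/8, input_size=64),
    train=TrainConfig(lr=2e-3, batch_size=8, epochs_pretrain=2,
                      epochs_joint=4, seed=7, n_runs=2, tiny=True))
report = run_experiment(config, train, val)
for name, (mean, lo, hi) in (("accuracy", report.accuracy),
                             ("AUC", report.auc), ("F1", report.f1)):
    print(f"{name:9s} {mean:.4f}  (95% CI {lo:.4f}, {hi:.4f})")
print("confusion % (rows = true benign, malignant):")
print(np.round(report.confusion_percent, 1))
```

Output (about two minutes on one CPU):

```
accuracy  0.9844  (95% CI 0.7858, 1.1829)
AUC       1.0000  (95% CI 1.0000, 1.0000)
F1        0.9848  (95% CI 0.7923, 1.1774)
confusion % (rows = true benign, malignant):
[[ 96.9   3.1]
 [  0.  100. ]]
```

The model separates the two phantom classes almost perfectly (one
benign nodule in 32 validation images is misread as malignant); the
wide intervals reflect that they are t-intervals over only two runs.
Phantom classes are separable by construction, so these numbers
validate the machinery, not clinical performance.

The same workflow is available from the shell:

```sh
mganet make-phantoms --n 48 --size 64 --seed 123 --out data/
mganet train --config cfg.yaml --manifest data/manifest.csv --out model.npz
mganet eval --ckpt model.npz --manifest data/manifest.csv --out metrics.json
mganet cam --ckpt model.npz --image data/benign_0000.png --point L2 --out heat.png
```

plus `mganet preprocess` for frames that still carry text bands or
borders.

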