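"""Two-stage training, evaluation and class-activation mapping.

The schedule mirrors the staged joint regime: the segmentation branch
is first pre-trained alone against the elliptical pseudo-masks (60
epochs at full scale), then both branches are optimised jointly against
L_total = L_cls + L_seg (140 further epochs), Adam throughout with the
same initial learning rate and no decay.  Horizontal flips are the only
augmentation and are always applied to image and pseudo-mask together.
The best joint-stage checkpoint is selected by validation F1, the
primary metric.  Every stochastic choice — weight init, batch order,
flip draws — derives from one integer seed, so a run is exactly
repeatable.

``run_experiment`` repeats training ``n_runs`` times with seeds
``seed + 0 .. seed + n_runs - 1`` and aggregates the held-out metrics
into means with 95% confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor, interp_matrix
from .config import ExperimentConfig, LossConfig, ModelConfig, TrainConfig
from .losses_metrics import (MetricsReport, classification_metrics,
                             cross_entropy, seg_loss, total_loss)
from .networks import DualBranchModel, build_model
from .nn import Adam
from .phantoms import PhantomSample, load_manifest
from .weak_labels import BBox, bbox_to_ellipse_mask

__all__ = [
    "PhantomArrayDataset",
    "pretrain_segmentation",
    "joint_train",
    "train_staged",
    "evaluate",
    "run_experiment",
    "grad_cam",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class PhantomArrayDataset:
    """In-memory dataset: images in [0, 1], pseudo-masks, binary labels."""

    images: np.ndarray  # (N, 1, H, W) float64 in [0, 1]
    masks: np.ndarray  # (N, 1, H, W) float64 in {0, 1}
    labels: np.ndarray  # (N,) int
    bboxes: list

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_samples(cls, samples: list[PhantomSample]) -> "PhantomArrayDataset":
        images, masks, labels, bboxes = [], [], [], []
        for s in samples:
            h, w = s.image.shape
            images.append(s.image[None].astype(np.float64) / 255.0)
            masks.append(bbox_to_ellipse_mask(s.bbox, h, w)[None].astype(np.float64))
            labels.append(s.label)
            bboxes.append(s.bbox)
        return cls(np.stack(images), np.stack(masks), np.asarray(labels), bboxes)

    @classmethod
    def from_manifest(cls, manifest_path, split: str | None = None) -> "PhantomArrayDataset":
        from PIL import Image
        images, masks, labels, bboxes = [], [], [], []
        for rec in load_manifest(manifest_path):
            if split is not None and rec["split"] != split:
                continue
            arr = np.asarray(Image.open(rec["path"]).convert("L"), dtype=np.float64)
            h, w = arr.shape
            images.append(arr[None] / 255.0)
            masks.append(bbox_to_ellipse_mask(rec["bbox"], h, w)[None].astype(np.float64))
            labels.append(rec["label"])
            bboxes.append(rec["bbox"])
        if not images:
            raise ValueError(f"no records for split {split!r} in {manifest_path}")
        return cls(np.stack(images), np.stack(masks), np.asarray(labels), bboxes)


def _iter_batches(data: PhantomArrayDataset, batch_size: int,
                  rng: np.random.Generator, hflip_prob: float):
    """Shuffled minibatches; flips are applied to image and mask together."""
    order = rng.permutation(len(data))
    for start in range(0, len(data), batch_size):
        idx = order[start:start + batch_size]
        imgs = data.images[idx].copy()
        masks = data.masks[idx].copy()
        flips = rng.random(len(idx)) < hflip_prob
        imgs[flips] = imgs[flips, :, :, ::-1]
        masks[flips] = masks[flips, :, :, ::-1]
        yield imgs, masks, data.labels[idx]


def pretrain_segmentation(model: DualBranchModel, data: PhantomArrayDataset,
                          train_cfg: TrainConfig,
                          loss_cfg: LossConfig | None = None) -> list[float]:
    """Stage 1: optimise only the segmentation branch against L_seg."""
    if len(data) == 0:
        raise ValueError("empty training set")
    if model.segmentation is None:
        raise ValueError("model was built without a segmentation branch")
    loss_cfg = loss_cfg or LossConfig()
    rng = np.random.default_rng(train_cfg.seed)
    opt = Adam(model.segmentation.parameters(), lr=train_cfg.lr)
    model.train()
    history: list[float] = []
    for _ in range(train_cfg.epochs_pretrain):
        losses = []
        for imgs, masks, _labels in _iter_batches(data, train_cfg.batch_size,
                                                  rng, train_cfg.hflip_prob):
            opt.zero_grad()
            prob = model.segmentation(Tensor(imgs))
            loss = seg_loss(prob, masks, loss_cfg)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return history


def joint_train(model: DualBranchModel, train_data: PhantomArrayDataset,
                val_data: PhantomArrayDataset, train_cfg: TrainConfig,
                loss_cfg: LossConfig | None = None) -> dict:
    """Stage 2: optimise both branches against L_total; keep the best
    validation-F1 checkpoint."""
    if len(train_data) == 0:
        raise ValueError("empty training set")
    loss_cfg = loss_cfg or LossConfig()
    rng = np.random.default_rng(train_cfg.seed + 1_000_003)
    opt = Adam(model.parameters(), lr=train_cfg.lr)
    history = {"train_loss": [], "val_f1": []}
    best_f1, best_state = -1.0, None
    for _ in range(train_cfg.epochs_joint):
        model.train()
        losses = []
        for imgs, masks, labels in _iter_batches(train_data, train_cfg.batch_size,
                                                 rng, train_cfg.hflip_prob):
            opt.zero_grad()
            out = model(Tensor(imgs))
            cls = cross_entropy(out.class_logits, labels)
            if out.seg_prob is not None:
                loss = total_loss(cls, seg_loss(out.seg_prob, masks, loss_cfg))
            else:
                loss = cls
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["train_loss"].append(float(np.mean(losses)))
        metrics = evaluate(model, val_data, train_cfg.batch_size)
        history["val_f1"].append(metrics["f1"])
        # ties go to the later epoch: with equal validation F1 the longer-
        # trained weights have the lower training loss and sharper features
        if metrics["f1"] >= best_f1:
            best_f1 = metrics["f1"]
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    history["best_val_f1"] = best_f1
    return history


def train_staged(model: DualBranchModel, train_data: PhantomArrayDataset,
                 val_data: PhantomArrayDataset, train_cfg: TrainConfig,
                 loss_cfg: LossConfig | None = None) -> dict:
    """Full schedule: segmentation pre-training followed by joint training."""
    history = {}
    if model.segmentation is not None and train_cfg.epochs_pretrain > 0:
        history["pretrain_loss"] = pretrain_segmentation(model, train_data,
                                                         train_cfg, loss_cfg)
    history.update(joint_train(model, train_data, val_data, train_cfg, loss_cfg))
    return history


def _softmax_scores(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e[:, 1] / e.sum(axis=1)


def predict_scores(model: DualBranchModel, data: PhantomArrayDataset,
                   batch_size: int = 32) -> np.ndarray:
    """Malignant-class probabilities on a dataset (eval mode, no flips)."""
    model.eval()
    scores = []
    for start in range(0, len(data), batch_size):
        imgs = data.images[start:start + batch_size]
        out = model(Tensor(imgs))
        scores.append(_softmax_scores(out.class_logits.data))
    return np.concatenate(scores)


def evaluate(model: DualBranchModel, data: PhantomArrayDataset,
             batch_size: int = 32) -> dict:
    return classification_metrics(data.labels, predict_scores(model, data, batch_size))


def run_experiment(config: ExperimentConfig, train_data: PhantomArrayDataset,
                   val_data: PhantomArrayDataset) -> MetricsReport:
    """n_runs independent trainings (seeds seed+0..seed+n_runs-1), evaluated
    on the held-out split and aggregated with 95% CIs."""
    runs = []
    for i in range(config.train.n_runs):
        cfg_i = TrainConfig(**{**vars(config.train), "seed": config.train.seed + i})
        model = build_model(config.model, seed=cfg_i.seed)
        train_staged(model, train_data, val_data, cfg_i, config.loss)
        runs.append(evaluate(model, val_data, cfg_i.batch_size))
    return MetricsReport.from_runs(runs)


def grad_cam(model: DualBranchModel, image: np.ndarray, point: str = "L4",
             eps: float = 1e-8) -> np.ndarray:
    """Gradient-weighted class activation map at an insertion point.

    The gradient of the predicted-class logit w.r.t. the (enhanced)
    feature map is pooled per channel, used to weight the activations,
    rectified, upsampled bilinearly to the input size and min-max
    normalised to [0, 1].
    """
    model.eval()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[None, None]
    elif img.ndim == 3:
        img = img[None]
    out = model(Tensor(img))
    if point not in out.enhanced_features:
        raise ValueError(f"unknown insertion point {point!r}; "
                         f"available: {sorted(out.enhanced_features)}")
    feat = out.enhanced_features[point]
    pred = int(np.argmax(out.class_logits.data[0]))
    onehot = np.zeros_like(out.class_logits.data)
    onehot[0, pred] = 1.0
    (out.class_logits * onehot).sum().backward()
    grads = feat.grad if feat.grad is not None else np.zeros_like(feat.data)
    weights = grads.mean(axis=(2, 3))[0]  # (C,)
    cam = np.maximum((weights[:, None, None] * feat.data[0]).sum(axis=0), 0.0)
    size = img.shape[-1]
    cam = interp_matrix(cam.shape[0], size) @ cam @ interp_matrix(cam.shape[1], size).T
    lo, hi = cam.min(), cam.max()
    return (cam - lo) / (hi - lo + eps)


def save_checkpoint(model: DualBranchModel, config: ExperimentConfig, path) -> None:
    """Weights plus the full experiment config in one .npz archive."""
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(config.to_dict()),
             **{f"w/{k}": v for k, v in state.items()})


def load_checkpoint(path) -> tuple[DualBranchModel, ExperimentConfig]:
    archive = np.load(path, allow_pickle=False)
    config = ExperimentConfig.from_dict(json.loads(str(archive["__config__"])))
    model = build_model(config.model, seed=config.train.seed)
    model.load_state_dict({k[2:]: archive[k] for k in archive.files if k.startswith("w/")})
    return model, config
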