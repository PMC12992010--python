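"""Losses and evaluation metrics.

Training objective
------------------
The total loss is the unweighted sum of the classification and
segmentation terms,

    L_total = L_cls + L_seg,

where L_cls is the softmax cross-entropy of the two-way head and the
segmentation term blends pixel-wise binary cross-entropy with the Dice
loss against the elliptical pseudo-mask:

    L_seg  = alpha * L_BCE + (1 - alpha) * L_Dice
    L_BCE  = -(1/N) sum_ij [ m_ij log p_ij + (1 - m_ij) log(1 - p_ij) ]
    L_Dice = 1 - (2 sum_ij m_ij p_ij + eps) / (sum_ij m_ij + sum_ij p_ij + eps)

with N = H*W, probabilities clamped to [1e-7, 1 - 1e-7] before the
logarithms, Dice computed per image then averaged over the batch, and
alpha = 0.5 by default.

Evaluation
----------
F1 = 2TP / (2TP + FP + FN) (the primary metric, malignant = positive),
rank-based (Mann-Whitney) AUC with ties counted half, overall accuracy,
row-normalised percentage confusion matrices, and Student-t 95%
confidence intervals over repeated independent runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import autograd as ag
from .autograd import Tensor, as_tensor
from .config import LossConfig

__all__ = [
    "cross_entropy",
    "bce_loss",
    "dice_loss",
    "seg_loss",
    "total_loss",
    "f1_score",
    "auc_score",
    "run_ci",
    "confusion_percent",
    "MetricsReport",
    "classification_metrics",
]

PROB_CLAMP = 1e-7


# ---------------------------------------------------------------------
# losses (differentiable, Tensor in / Tensor out)
# ---------------------------------------------------------------------

def cross_entropy(class_logits: Tensor, labels) -> Tensor:
    """Mean negative log softmax probability of the true class."""
    logits = as_tensor(class_logits)
    if logits.ndim == 1:
        logits = logits.reshape(1, -1)
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    n, c = logits.shape
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c - 1}]")
    shift = logits.data.max(axis=1, keepdims=True)  # constant stabiliser
    z = logits - shift
    log_norm = ag.log(ag.exp(z).sum(axis=1, keepdims=True))
    log_probs = z - log_norm
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    return -(log_probs * onehot).sum() * (1.0 / n)


def bce_loss(seg_prob: Tensor, pseudo_mask) -> Tensor:
    """Pixel-mean binary cross-entropy; probabilities clamped before logs."""
    p = as_tensor(seg_prob)
    m = as_tensor(pseudo_mask)
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {m.shape}")
    p = ag.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    ll = m * ag.log(p) + (1.0 - m) * ag.log(1.0 - p)
    return -ll.mean()


def dice_loss(seg_prob: Tensor, pseudo_mask, eps_dice: float = 1.0) -> Tensor:
    """1 - smoothed Dice overlap, per image then batch-averaged.

    Arrays without a batch axis (H, W) are treated as a single image.
    """
    if eps_dice <= 0:
        raise ValueError("eps_dice must be positive")
    p = as_tensor(seg_prob)
    m = as_tensor(pseudo_mask)
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {m.shape}")
    if p.ndim <= 2:
        axes: tuple[int, ...] = tuple(range(p.ndim))
        batch = 1
    else:
        axes = tuple(range(1, p.ndim))
        batch = p.shape[0]
    inter = (p * m).sum(axis=axes)
    denom = p.sum(axis=axes) + m.sum(axis=axes)
    dice = (2.0 * inter + eps_dice) / (denom + eps_dice)
    return (1.0 - dice).sum() * (1.0 / batch)


def seg_loss(seg_prob: Tensor, pseudo_mask, loss_config: LossConfig) -> Tensor:
    a = loss_config.alpha
    if a == 1.0:
        return bce_loss(seg_prob, pseudo_mask)
    if a == 0.0:
        return dice_loss(seg_prob, pseudo_mask, loss_config.eps_dice)
    return a * bce_loss(seg_prob, pseudo_mask) + \
        (1.0 - a) * dice_loss(seg_prob, pseudo_mask, loss_config.eps_dice)


def total_loss(cls_loss: Tensor, seg_loss_val: Tensor) -> Tensor:
    return as_tensor(cls_loss) + as_tensor(seg_loss_val)


# ---------------------------------------------------------------------
# metrics (plain floats)
# ---------------------------------------------------------------------

def f1_score(tp: int, fp: int, fn: int) -> float:
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise ValueError("F1 undefined: no positives in labels or predictions")
    return 2.0 * tp / denom


def auc_score(scores_positive, scores_negative) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie), via the rank-sum statistic."""
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes need at least one score")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: len(pos)].sum()
    u = rank_sum - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def run_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a Student-t confidence interval over independent runs."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two runs for a confidence interval")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = stats.t.ppf(0.5 + level / 2.0, v.size - 1) * sd / np.sqrt(v.size)
    return mean, mean - half, mean + half


def confusion_percent(labels, predictions) -> np.ndarray:
    """2x2 row-normalised percentages; rows index the true class."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.size == 0 or y.shape != p.shape:
        raise ValueError("labels and predictions must be equal-length and nonempty")
    out = np.full((2, 2), np.nan)
    for c in (0, 1):
        sel = y == c
        if sel.sum() == 0:
            continue  # absent class row stays NaN (undefined)
        out[c, 0] = 100.0 * np.mean(p[sel] == 0)
        out[c, 1] = 100.0 * np.mean(p[sel] == 1)
    return out


def classification_metrics(labels, scores, threshold: float = 0.5) -> dict:
    """Accuracy / F1 / AUC of malignant-probability scores at a threshold."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return {
        "accuracy": float(np.mean(pred == y)),
        "f1": f1_score(tp, fp, fn),
        "auc": auc_score(s[y == 1], s[y == 0]),
        "confusion_percent": confusion_percent(y, pred),
    }


@dataclass
class MetricsReport:
    """Per-run metrics aggregated into means with 95% CIs."""

    accuracy: tuple[float, float, float]
    auc: tuple[float, float, float]
    f1: tuple[float, float, float]
    confusion_percent: np.ndarray  # mean over runs, rows sum to 100
    n_runs: int
    per_run: dict = field(default_factory=dict)

    @classmethod
    def from_runs(cls, runs: list[dict], level: float = 0.95) -> "MetricsReport":
        per_run = {k: [r[k] for r in runs] for k in ("accuracy", "auc", "f1")}
        conf = np.mean([r["confusion_percent"] for r in runs], axis=0)
        return cls(accuracy=run_ci(per_run["accuracy"], level),
                   auc=run_ci(per_run["auc"], level),
                   f1=run_ci(per_run["f1"], level),
                   confusion_percent=conf, n_runs=len(runs), per_run=per_run)

    def to_dict(self) -> dict:
        def triple(t):
            return {"mean": t[0], "ci_low": t[1], "ci_high": t[2]}
        return {"accuracy": triple(self.accuracy), "auc": triple(self.auc),
                "f1": triple(self.f1),
                "confusion_percent": np.asarray(self.confusion_percent).tolist(),
                "n_runs": self.n_runs, "per_run": self.per_run}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text
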