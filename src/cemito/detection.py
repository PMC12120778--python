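"""2D mitochondria detector: symmetric U-Net, thresholding, evaluation.

The reference architecture is a five-level symmetric U-Net (feature maps
16, 32, 64, 128, 256), three 3x3 non-strided same convolutions per step
with instance normalization and ReLU, 2x max pooling on the way down,
nearest-neighbor upsampling followed by a 2x2 convolution on the way up,
concatenation skips, and a 3x3 convolution + sigmoid head, applied to
576x576 sections at 8 nm. Probability maps are binarized at 128/255.

Training uses pixelwise binary cross-entropy with Adam (the reference
work names no loss or optimizer; these are the package defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._unet import UNet
from .core import ValidationError

THRESHOLD_128_255 = 128.0 / 255.0


@dataclass(frozen=True)
class DetectorConfig:
    depth: int = 5
    features: tuple[int, ...] = (16, 32, 64, 128, 256)
    convs_per_step: int = 3
    input_size: int = 576  # pixels at 8 nm; configurable for tests
    seed: int = 0

    def validate(self) -> None:
        if len(self.features) != self.depth:
            raise ValidationError("need one feature width per level")
        for a, b in zip(self.features, self.features[1:]):
            if b != 2 * a:
                raise ValidationError("features must double at every level")
        if self.depth < 2:
            raise ValidationError("depth must be >= 2")


def build_detector(config: DetectorConfig) -> UNet:
    """Build the U-Net; parameters are deterministic given ``config.seed``."""
    config.validate()
    return UNet(depth=config.depth, features=config.features,
                convs_per_step=config.convs_per_step, seed=config.seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _bce_with_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits.astype(np.float64)
    t = target.astype(np.float64)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    prob = 1.0 / (1.0 + np.exp(-z))
    grad = (prob - t) / z.size
    return float(loss.mean()), grad.astype(np.float32)


def train_detector(detector: UNet, pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                   epochs: int = 5, lr: float = 1e-3, seed: int = 0) -> list[float]:
    """Train on (image, mask) pairs; returns the per-step loss trace.

    Deterministic given ``seed`` (which only drives the epoch shuffling)
    and the pair order. Aborts with diagnostics on a non-finite loss.
    """
    if len(pairs) < 1:
        raise ValidationError("need at least one training pair")
    rng = np.random.default_rng(seed)
    opt = _Adam(detector.parameters(), lr=lr)
    trace: list[float] = []
    order = np.arange(len(pairs))
    for epoch in range(epochs):
        rng.shuffle(order)
        for idx in order:
            image, mask = pairs[idx]
            detector.zero_grad()
            logits = detector.forward_logits(image)
            loss, dlogits = _bce_with_logits(logits, np.asarray(mask, dtype=np.float32))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch}, pair {int(idx)}; "
                    f"logit range [{logits.min():.3g}, {logits.max():.3g}]")
            detector.backward(dlogits)
            opt.step(detector.gradients())
            trace.append(loss)
    return trace


# ---------------------------------------------------------------------------
# thresholding and evaluation
# ---------------------------------------------------------------------------

def binarize(prob_map: np.ndarray, threshold: float = THRESHOLD_128_255) -> np.ndarray:
    """Foreground iff probability >= threshold (default 128/255)."""
    prob_map = np.asarray(prob_map)
    if prob_map.size and (prob_map.min() < 0 or prob_map.max() > 1):
        raise ValidationError("probability map values must lie in [0, 1]")
    return prob_map >= threshold


@dataclass
class PixelEval:
    precision: float  # NaN (flagged) when nothing was predicted
    recall: float
    tp: int
    fp: int
    fn: int
    precision_defined: bool = True


def evaluate_pixels(pred_mask: np.ndarray, truth_mask: np.ndarray) -> PixelEval:
    """Pixelwise precision and recall of a thresholded prediction."""
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError("prediction and truth shapes differ")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    if tp + fp == 0:
        precision, defined = float("nan"), False
    else:
        precision, defined = tp / (tp + fp), True
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return PixelEval(precision=precision, recall=recall, tp=tp, fp=fp, fn=fn,
                     precision_defined=defined)


def pixel_f1(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    ev = evaluate_pixels(pred_mask, truth_mask)
    if not ev.precision_defined or not np.isfinite(ev.recall):
        return 0.0
    if ev.precision + ev.recall == 0:
        return 0.0
    return 2 * ev.precision * ev.recall / (ev.precision + ev.recall)


@dataclass
class ObjectEval:
    precision: float
    recall: float
    n_truth: int
    n_pred: int
    n_truth_detected: int
    n_pred_tp: int


def evaluate_objects(pred_labels: np.ndarray, truth_labels: np.ndarray,
                     overlap_frac: float = 0.5) -> ObjectEval:
    """Object-level detection metrics on two labeled volumes.

    A truth object counts as detected iff some single predicted object
    covers at least ``overlap_frac`` of its voxels; a predicted object is
    a true positive iff it detects at least one truth object this way.
    """
    pred = np.asarray(pred_labels).ravel()
    truth = np.asarray(truth_labels).ravel()
    if pred.shape != truth.shape:
        raise ValidationError("labeled volumes must share a grid")
    truth_ids, truth_sizes = np.unique(truth[truth > 0], return_counts=True)
    pred_ids = np.unique(pred[pred > 0])
    size_of = dict(zip(truth_ids.tolist(), truth_sizes.tolist()))
    both = (pred > 0) & (truth > 0)
    detected: set[int] = set()
    pred_tp: set[int] = set()
    if both.any():
        key = pred[both].astype(np.int64) * (int(truth.max()) + 1) + truth[both]
        uniq, counts = np.unique(key, return_counts=True)
        p_of = uniq // (int(truth.max()) + 1)
        t_of = uniq % (int(truth.max()) + 1)
        for p, t, n in zip(p_of, t_of, counts):
            if n >= overlap_frac * size_of[int(t)]:
                detected.add(int(t))
                pred_tp.add(int(p))
    n_truth, n_pred = len(truth_ids), len(pred_ids)
    recall = len(detected) / n_truth if n_truth else float("nan")
    precision = len(pred_tp) / n_pred if n_pred else float("nan")
    return ObjectEval(precision=precision, recall=recall, n_truth=n_truth,
                      n_pred=n_pred, n_truth_detected=len(detected),
                      n_pred_tp=len(pred_tp))


def predict_stack(detector: UNet, images: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Probability maps for a stack of sections."""
    return [detector.forward(img) for img in images]
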