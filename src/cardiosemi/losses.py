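"""Loss terms: supervised cross-entropy, confidence-weighted (robust)
pseudo-label loss, and their weighted combination.

The unlabeled-data loss weights each pixel by two confidence signals from
the teacher: the DPTM selection weight γ (the argmax probability where it
beats its dynamic threshold, else 0) and a temperature-softened maximum
probability p.  Two modes are provided:

``weighted_cross_entropy`` (default)
    −(1/HW) Σ γ·p·log ŝ(c*), where ŝ(c*) is the *student* probability at
    the teacher's argmax class — a pseudo-label cross-entropy whose
    per-pixel contribution is damped by teacher confidence.  This is the
    form used for training, since it couples the student to the
    pseudo-labels.
``literal_entropy``
    −(1/HW) Σ γ·p·log p, a pure teacher-confidence entropy with no student
    term; retained for analysis.

All functions accept plain NumPy arrays and return floats; the ``*_t``
variants take/return autodiff :class:`~cardiosemi.autodiff.Tensor` objects
(student maps as (B, C, H, W)) and are what the trainer differentiates.
Logarithms are stabilised as log(x + 1e-12).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .dptm import ConfidenceWeightMap, _as_prob_array, _stack_batch

__all__ = [
    "LOG_EPS",
    "LossWeights",
    "RobustLossConfig",
    "supervised_loss",
    "supervised_loss_t",
    "pseudo_confidence",
    "robust_unlabeled_loss",
    "robust_unlabeled_loss_t",
    "masked_pseudo_cross_entropy_t",
    "total_loss",
]

LOG_EPS = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Trade-off weights λ1 (unlabeled) and λ2 (contrastive) of the total
    objective L = L_l + λ1·L_u + λ2·L_con."""

    lambda_unlabeled: float = 1.0
    lambda_contrastive: float = 0.1

    def __post_init__(self):
        for name in ("lambda_unlabeled", "lambda_contrastive"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class RobustLossConfig:
    """Configuration of the robust unlabeled loss.

    temperature
        τ of the confidence softening softmax(ȳ/τ); smaller τ sharpens.
    mode
        ``weighted_cross_entropy`` or ``literal_entropy`` (see module doc).
    normalize_by
        ``all_pixels`` divides by H·W; ``selected_pixels`` by the number of
        pixels with γ > 0.
    confidence_from_logits
        When True the confidence softmax is applied to logits rather than
        to already-normalised probabilities.
    """

    temperature: float = 0.5
    mode: str = "weighted_cross_entropy"
    normalize_by: str = "all_pixels"
    confidence_from_logits: bool = False

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature τ must be > 0")
        if self.mode not in ("weighted_cross_entropy", "literal_entropy"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.normalize_by not in ("all_pixels", "selected_pixels"):
            raise ValueError(f"unknown normalize_by {self.normalize_by!r}")


# ---- supervised term ----------------------------------------------------


def _onehot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(
            f"labels must lie in [0, {num_classes - 1}], got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    return np.eye(num_classes, dtype=float)[labels]


def supervised_loss_t(student_probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean pixel-wise cross-entropy; ``student_probs`` is (B, C, H, W)."""
    b, c, h, w = student_probs.shape
    labels = np.asarray(labels)
    onehot = _onehot(labels, c).transpose(0, 3, 1, 2)  # (B, C, H, W)
    sel = (student_probs * Tensor(onehot.astype(student_probs.dtype))).sum(axis=1)
    return -((sel + LOG_EPS).log().sum()) / float(b * h * w)


def supervised_loss(student_maps, labels) -> float:
    """Batch-mean cross-entropy from (H, W, C) probability maps and integer
    label fields."""
    batch = _stack_batch(student_maps)
    labels = np.stack([np.asarray(l) for l in labels]) if not (
        isinstance(labels, np.ndarray) and labels.ndim == 3) else np.asarray(labels)
    if labels.shape != batch.shape[:3]:
        raise ValueError(f"label shape {labels.shape} != batch spatial shape {batch.shape[:3]}")
    probs = Tensor(batch.transpose(0, 3, 1, 2))
    return float(supervised_loss_t(probs, labels))


# ---- teacher confidence (temperature-softened max probability) ----------


def pseudo_confidence(pseudo_map, temperature: float,
                      from_logits: bool = False) -> np.ndarray:
    """Per-pixel confidence p = max_c softmax(ȳ/τ): the teacher's maximum
    class score after temperature softening.  Entries lie in (1/C, 1]."""
    if temperature <= 0:
        raise ValueError("temperature τ must be > 0")
    v = _as_prob_array(pseudo_map)
    z = v / temperature
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    sm = e / e.sum(axis=-1, keepdims=True)
    del from_logits  # the softmax form is identical; flag documents intent
    return sm.max(axis=-1)


# ---- robust unlabeled term ----------------------------------------------


def _gamma_array(gamma) -> np.ndarray:
    if isinstance(gamma, ConfidenceWeightMap):
        return gamma.weights
    return np.asarray(gamma, dtype=float)


def _normalizer(config: RobustLossConfig, gamma: np.ndarray, n_pixels_total: int) -> float:
    """Batch-level divisor: B·H·W as printed, or the γ>0 count."""
    if config.normalize_by == "selected_pixels":
        n_sel = int((gamma > 0).sum())
        return float(max(n_sel, 1))
    return float(n_pixels_total)


def robust_unlabeled_loss_t(student_probs: Tensor, pseudo_map, gamma,
                            config: RobustLossConfig = RobustLossConfig()) -> Tensor:
    """Differentiable robust loss for one batch.

    ``student_probs`` is (B, C, H, W); ``pseudo_map`` is (B, H, W, C) teacher
    probabilities (constants); ``gamma`` is (B, H, W).  Pixels with γ = 0
    contribute exactly 0 and receive no gradient.
    """
    pseudo = _stack_batch(pseudo_map) if not (
        isinstance(pseudo_map, np.ndarray) and pseudo_map.ndim == 4) else np.asarray(pseudo_map, dtype=float)
    gam = _gamma_array(gamma)
    if gam.ndim == 2:
        gam = gam[None]
    b, h, w, c = pseudo.shape
    p = pseudo_confidence(pseudo, config.temperature, config.confidence_from_logits)
    norm = _normalizer(config, gam, b * h * w)
    if config.mode == "literal_entropy":
        val = -(gam * p * np.log(p + LOG_EPS)).sum() / norm
        return Tensor(np.asarray(val))
    pred = pseudo.argmax(axis=-1)  # (B, H, W)
    onehot = _onehot(pred, c).transpose(0, 3, 1, 2)
    sel = (student_probs * Tensor(onehot.astype(student_probs.dtype))).sum(axis=1)  # (B, H, W)
    weights = (gam * p).astype(student_probs.dtype)
    return -((sel + LOG_EPS).log() * Tensor(weights)).sum() / norm


def robust_unlabeled_loss(student_map, pseudo_map, gamma,
                          config: RobustLossConfig = RobustLossConfig()) -> float:
    """Robust unlabeled loss for a single image (arrays shaped (H, W, C))."""
    student = _as_prob_array(student_map)
    pseudo = _as_prob_array(pseudo_map)
    if student.shape != pseudo.shape:
        raise ValueError(f"student shape {student.shape} != pseudo shape {pseudo.shape}")
    probs = Tensor(student[None].transpose(0, 3, 1, 2))
    gam = _gamma_array(gamma)
    return float(robust_unlabeled_loss_t(probs, pseudo[None], gam[None], config))


def masked_pseudo_cross_entropy_t(student_probs: Tensor, pseudo_map, mask) -> Tensor:
    """Plain pseudo-label cross-entropy on selected pixels: −(1/HW) Σ
    1[mask]·log ŝ(c*).  Used when robust confidence weighting is disabled."""
    pseudo = np.asarray(pseudo_map, dtype=float)
    m = np.asarray(mask, dtype=float)
    if m.ndim == 2:
        m = m[None]
    b, h, w, c = pseudo.shape
    pred = pseudo.argmax(axis=-1)
    onehot = _onehot(pred, c).transpose(0, 3, 1, 2)
    sel = (student_probs * Tensor(onehot.astype(student_probs.dtype))).sum(axis=1)
    binary = (m > 0).astype(student_probs.dtype)
    return -((sel + LOG_EPS).log() * Tensor(binary)).sum() / float(b * h * w)


# ---- total objective -----------------------------------------------------


def total_loss(l_sup, l_unl, l_con, weights: LossWeights):
    """L = L_l + λ1·L_u + λ2·L_con.  Accepts floats or Tensors; raises on a
    non-finite component (a training-divergence signal)."""
    parts = {"supervised": l_sup, "unlabeled": l_unl, "contrastive": l_con}
    for name, v in parts.items():
        val = v.data if isinstance(v, Tensor) else v
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(f"non-finite {name} loss component: {val}")
    total = l_sup + weights.lambda_unlabeled * l_unl + weights.lambda_contrastive * l_con
    return total
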