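"""Dynamic pseudo-label threshold map (DPTM).

Pseudo-labels produced by a teacher network are only useful where the
teacher is confident, and a single static confidence cutoff cannot follow
either the spatial structure of that confidence or its evolution over
training.  This module maintains a *spatial* threshold map that tracks the
batch-averaged maximum teacher confidence through an exponential moving
average, rescales it per class by the class's mean prediction confidence
(so small, hard structures are not starved of pseudo-labels), and converts
teacher probability maps into a confidence weighting map γ that selects and
weights the reliable pixels.

Conventions: probability maps are arrays of shape (H, W, C) (row-major,
0-based, class 0 = background); batches are lists of such maps or a single
(B, H, W, C) array.  Argmax ties break to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ProbabilityMap",
    "ThresholdMapState",
    "ClassScaling",
    "ConfidenceWeightMap",
    "batch_avg_confidence",
    "ema_update_threshold",
    "class_confidence",
    "class_scaling",
    "class_modulated_thresholds",
    "confidence_weight_map",
    "dptm_step",
    "save_threshold_state",
    "load_threshold_state",
]

DEFAULT_MOMENTUM = 0.99  # EMA momentum α for the threshold map
DEFAULT_STABILIZER = 1e-8  # ξ guarding the per-class pixel-count denominator


def _as_prob_array(m) -> np.ndarray:
    if isinstance(m, ProbabilityMap):
        return m.values
    return np.asarray(m, dtype=float)


def _stack_batch(pseudo_maps) -> np.ndarray:
    """Normalise input to a (B, H, W, C) array, validating shapes."""
    if isinstance(pseudo_maps, np.ndarray) and pseudo_maps.ndim == 4:
        batch = np.asarray(pseudo_maps, dtype=float)
    else:
        maps = [_as_prob_array(m) for m in pseudo_maps]
        if len(maps) == 0:
            raise ValueError("empty batch of pseudo-label maps")
        shape = maps[0].shape
        for m in maps[1:]:
            if m.shape != shape:
                raise ValueError(f"shape mismatch in batch: {m.shape} vs {shape}")
        batch = np.stack(maps)
    if batch.ndim != 4:
        raise ValueError(f"expected (B, H, W, C) maps, got shape {batch.shape}")
    if batch.shape[0] == 0:
        raise ValueError("empty batch of pseudo-label maps")
    return batch


@dataclass(frozen=True)
class ProbabilityMap:
    """A per-pixel class-probability field of shape (H, W, C)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"probability map must be (H, W, C), got {v.shape}")
        if v.min() < -1e-6 or v.max() > 1 + 1e-6:
            raise ValueError("probabilities outside [0, 1]")
        sums = v.sum(axis=-1)
        if np.abs(sums - 1.0).max() > 1e-5:
            raise ValueError("per-pixel class probabilities must sum to 1 within 1e-5")
        object.__setattr__(self, "values", v)

    @property
    def num_classes(self) -> int:
        return self.values.shape[-1]


@dataclass(frozen=True)
class ThresholdMapState:
    """The EMA-smoothed spatial threshold map M with batch/epoch bookkeeping.

    At construction every entry is 1/C (uniform uncertainty); after at least
    one update every entry lies in [1/C, 1] because the batch-averaged
    maximum confidence it tracks does.
    """

    map: np.ndarray
    num_classes: int
    momentum: float = DEFAULT_MOMENTUM
    epoch_index: int = 0
    batch_index: int = 0

    def __post_init__(self):
        m = np.asarray(self.map, dtype=float)
        if m.ndim != 2:
            raise ValueError(f"threshold map must be (H, W), got {m.shape}")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError(f"momentum α must be in [0, 1], got {self.momentum}")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        object.__setattr__(self, "map", m)

    @classmethod
    def initial(cls, height: int, width: int, num_classes: int,
                momentum: float = DEFAULT_MOMENTUM) -> "ThresholdMapState":
        """Uniform-uncertainty initial state M_{0,0} = 1/C everywhere."""
        return cls(
            map=np.full((height, width), 1.0 / num_classes),
            num_classes=num_classes,
            momentum=momentum,
        )

    def next_epoch(self, reset: bool = False) -> "ThresholdMapState":
        """Advance the epoch counter; optionally reset the map to 1/C."""
        m = np.full_like(self.map, 1.0 / self.num_classes) if reset else self.map
        return replace(self, map=m, epoch_index=self.epoch_index + 1, batch_index=0)


@dataclass(frozen=True)
class ClassScaling:
    """Per-class confidence scores ε and scaling factors η = ε / max ε."""

    confidence: np.ndarray
    scaling: np.ndarray
    stabilizer: float = DEFAULT_STABILIZER

    def __post_init__(self):
        object.__setattr__(self, "confidence", np.asarray(self.confidence, dtype=float))
        object.__setattr__(self, "scaling", np.asarray(self.scaling, dtype=float))


@dataclass(frozen=True)
class ConfidenceWeightMap:
    """γ field: per pixel, the predicted-class probability if it exceeds its
    class-modulated threshold, else 0; plus the argmax class c*."""

    weights: np.ndarray
    predicted_class: np.ndarray


def batch_avg_confidence(pseudo_maps) -> np.ndarray:
    """Batch-averaged maximum-confidence map M̄ (mean over images of the
    per-pixel max class probability).  Entries lie in [1/C, 1]."""
    batch = _stack_batch(pseudo_maps)
    return batch.max(axis=-1).mean(axis=0)


def ema_update_threshold(state: ThresholdMapState, batch_avg: np.ndarray) -> ThresholdMapState:
    """One EMA step of the spatial threshold map:
    M_k = α·M_{k-1} + (1-α)·M̄_k.  Returns a new state; the input state is
    left untouched."""
    batch_avg = np.asarray(batch_avg, dtype=float)
    if batch_avg.shape != state.map.shape:
        raise ValueError(f"batch average shape {batch_avg.shape} != map shape {state.map.shape}")
    a = state.momentum
    new_map = a * state.map + (1.0 - a) * batch_avg
    return replace(state, map=new_map, batch_index=state.batch_index + 1)


def class_confidence(pseudo_maps, stabilizer: float = DEFAULT_STABILIZER) -> np.ndarray:
    """Class-specific confidence scores ε_c: the mean max-probability over
    all pixels (across the batch) whose argmax class is c, with a small
    stabiliser ξ in the pixel-count denominator so empty classes give ≈0."""
    if stabilizer <= 0:
        raise ValueError("stabilizer ξ must be positive")
    batch = _stack_batch(pseudo_maps)
    c = batch.shape[-1]
    pred = batch.argmax(axis=-1)  # ties -> lowest class index
    conf = batch.max(axis=-1)
    eps = np.empty(c)
    for cls in range(c):
        mask = pred == cls
        eps[cls] = conf[mask].sum() / (mask.sum() + stabilizer)
    return eps


def class_scaling(confidence: np.ndarray) -> np.ndarray:
    """Class-wise scaling factors η_c = ε_c / max_c' ε_c'."""
    eps = np.asarray(confidence, dtype=float)
    top = eps.max()
    if top <= 0:
        raise ValueError("all class confidences are zero; degenerate batch")
    return eps / top


def class_modulated_thresholds(state: ThresholdMapState, scaling: np.ndarray) -> np.ndarray:
    """Class-adapted thresholds M_c(h,w) = η_c · M(h,w), shape (H, W, C)."""
    eta = np.asarray(scaling, dtype=float)
    if eta.shape != (state.num_classes,):
        raise ValueError(f"scaling must have length C={state.num_classes}, got {eta.shape}")
    return state.map[:, :, None] * eta[None, None, :]


def confidence_weight_map(pseudo_map, thresholds: np.ndarray) -> ConfidenceWeightMap:
    """Confidence weighting map γ for one image.

    At each pixel let c* be the argmax class of the teacher map; the weight
    is the probability at c* when it *strictly* exceeds the class-modulated
    threshold there, and 0 otherwise.
    """
    values = _as_prob_array(pseudo_map)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != values.shape:
        raise ValueError(f"thresholds shape {thresholds.shape} != map shape {values.shape}")
    pred = values.argmax(axis=-1)
    conf = np.take_along_axis(values, pred[:, :, None], axis=-1)[:, :, 0]
    thr = np.take_along_axis(thresholds, pred[:, :, None], axis=-1)[:, :, 0]
    weights = np.where(conf > thr, conf, 0.0)
    return ConfidenceWeightMap(weights=weights, predicted_class=pred)


def dptm_step(state: ThresholdMapState, pseudo_maps,
              stabilizer: float = DEFAULT_STABILIZER):
    """Run the full DPTM pipeline for one unlabeled batch.

    Returns ``(new_state, gamma, scaling)`` where ``gamma`` is the (B, H, W)
    stack of confidence weights and ``scaling`` the :class:`ClassScaling`
    diagnostics for the batch.
    """
    batch = _stack_batch(pseudo_maps)
    new_state = ema_update_threshold(state, batch_avg_confidence(batch))
    eps = class_confidence(batch, stabilizer)
    eta = class_scaling(eps)
    thr = class_modulated_thresholds(new_state, eta)
    gamma = np.stack([confidence_weight_map(m, thr).weights for m in batch])
    return new_state, gamma, ClassScaling(confidence=eps, scaling=eta, stabilizer=stabilizer)


def save_threshold_state(state: ThresholdMapState, path) -> None:
    """Serialise a threshold-map snapshot to a portable ``.npz`` container."""
    np.savez(
        Path(path),
        map=state.map,
        num_classes=state.num_classes,
        momentum=state.momentum,
        epoch_index=state.epoch_index,
        batch_index=state.batch_index,
    )


def load_threshold_state(path) -> ThresholdMapState:
    with np.load(Path(path)) as z:
        return ThresholdMapState(
            map=z["map"],
            num_classes=int(z["num_classes"]),
            momentum=float(z["momentum"]),
            epoch_index=int(z["epoch_index"]),
            batch_index=int(z["batch_index"]),
        )
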