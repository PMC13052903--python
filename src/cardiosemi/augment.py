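"""Data augmentation for single-channel 2-D images and label maps.

Two suites are provided, matching their roles in training:

* :func:`augment_pair` — the supervised/unlabeled training suite: random
  rotation (±30°), isotropic scaling (0.7–1.3), elastic deformation
  (Gaussian-smoothed displacement field, σ = 10 px), horizontal flipping
  (p = 0.5) and brightness scaling (0.7–1.3).  Geometric transforms are
  applied identically to image and label map (bilinear for the image,
  nearest-neighbour for the label, so no new label values can appear);
  photometric transforms touch the image only.
* :func:`contrastive_view` — the stronger photometric/occlusion suite for
  contrastive pairs: colour jitter (brightness/contrast/gamma on a
  grayscale image), random crop-and-resize, Gaussian noise injection and
  cutout (one zero-filled square, side 25% of the image side).

All randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = ["AugmentationConfig", "augment_pair", "augment_photometric",
           "strong_photometric_view", "contrastive_view"]


@dataclass(frozen=True)
class AugmentationConfig:
    rotation_degrees: float = 30.0
    scale_range: tuple = (0.7, 1.3)
    elastic_sigma: float = 10.0
    elastic_amplitude: float = 100.0
    flip_prob: float = 0.5
    brightness_range: tuple = (0.7, 1.3)
    contrastive_ops: tuple = ("color_jitter", "random_crop", "noise_injection", "cutout")
    noise_std: float = 0.05
    cutout_fraction: float = 0.25
    crop_scale_range: tuple = (0.6, 1.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("scale_range", "brightness_range", "crop_scale_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")


def _warp(image: np.ndarray, label: np.ndarray | None, angle_deg: float,
          scale: float, dx: np.ndarray | None, dy: np.ndarray | None):
    """One combined inverse-map warp: rotation + scaling about the centre,
    plus an optional elastic displacement field.  A single interpolation is
    used so labels are resampled exactly once (nearest-neighbour)."""
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # inverse map: rotate by -θ and divide by scale
    y0, x0 = yy - cy, xx - cx
    src_y = (cos_t * y0 + sin_t * x0) / scale + cy
    src_x = (-sin_t * y0 + cos_t * x0) / scale + cx
    if dy is not None:
        src_y = src_y + dy
        src_x = src_x + dx
    coords = np.stack([src_y, src_x])
    out_img = ndimage.map_coordinates(image, coords, order=1, mode="constant", cval=0.0)
    out_lab = None
    if label is not None:
        out_lab = ndimage.map_coordinates(label, coords, order=0, mode="constant", cval=0)
    return out_img, out_lab


def augment_pair(image: np.ndarray, label: np.ndarray | None,
                 config: AugmentationConfig, rng: np.random.Generator):
    """Geometric + photometric training augmentation of an image and its
    (optional) label map.  Output shapes equal input shapes."""
    image = np.asarray(image, dtype=float)
    if label is not None:
        label = np.asarray(label)
        if label.shape != image.shape:
            raise ValueError(f"label shape {label.shape} != image shape {image.shape}")

    angle = rng.uniform(-config.rotation_degrees, config.rotation_degrees)
    scale = rng.uniform(*config.scale_range)
    dx = dy = None
    if config.elastic_amplitude > 0:
        dy = ndimage.gaussian_filter(rng.uniform(-1, 1, image.shape),
                                     config.elastic_sigma) * config.elastic_amplitude
        dx = ndimage.gaussian_filter(rng.uniform(-1, 1, image.shape),
                                     config.elastic_sigma) * config.elastic_amplitude
    if angle != 0.0 or scale != 1.0 or dx is not None:
        image, label = _warp(image, label, angle, scale, dx, dy)

    if rng.uniform() < config.flip_prob:
        image = image[:, ::-1].copy()
        if label is not None:
            label = label[:, ::-1].copy()

    factor = rng.uniform(*config.brightness_range)
    if factor != 1.0:
        image = np.clip(image * factor, 0.0, 1.0)
    return image, label


def augment_photometric(image: np.ndarray, config: AugmentationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Geometry-preserving perturbation (brightness + noise) used for the
    student's view of unlabeled images, so pseudo-labels computed on the
    original geometry stay pixel-aligned."""
    image = np.asarray(image, dtype=float)
    factor = rng.uniform(*config.brightness_range)
    out = image * factor
    if config.noise_std > 0:
        out = out + rng.normal(0.0, config.noise_std, image.shape)
    return np.clip(out, 0.0, 1.0)


def strong_photometric_view(image: np.ndarray, config: AugmentationConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Strong geometry-preserving view for consistency training: brightness/
    contrast/gamma jitter, Gaussian noise and cutout.  Pseudo-labels remain
    pixel-aligned; the occluded square forces the student to predict the
    covered structure from context."""
    out = np.asarray(image, dtype=float).copy()
    h, w = out.shape
    out = np.clip(out * rng.uniform(*config.brightness_range), 0.0, 1.0)
    mean = out.mean()
    out = np.clip((out - mean) * rng.uniform(0.7, 1.3) + mean, 0.0, 1.0)
    out = out ** rng.uniform(0.7, 1.3)
    if config.noise_std > 0:
        out = np.clip(out + rng.normal(0.0, config.noise_std, out.shape), 0.0, 1.0)
    side = max(1, int(round(config.cutout_fraction * min(h, w))))
    top = rng.integers(0, h - side + 1)
    left = rng.integers(0, w - side + 1)
    out[top:top + side, left:left + side] = 0.0
    return out


def contrastive_view(image: np.ndarray, config: AugmentationConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Stochastic composition of the contrastive augmentation ops; output
    spatial shape always equals the input shape (crops are resized back)."""
    out = np.asarray(image, dtype=float).copy()
    h, w = out.shape
    ops = config.contrastive_ops

    if "color_jitter" in ops and rng.uniform() < 0.8:
        out = np.clip(out * rng.uniform(0.7, 1.3), 0.0, 1.0)       # brightness
        mean = out.mean()
        out = np.clip((out - mean) * rng.uniform(0.7, 1.3) + mean, 0.0, 1.0)  # contrast
        out = np.clip(out, 0.0, 1.0) ** rng.uniform(0.7, 1.3)       # gamma

    if "random_crop" in ops and rng.uniform() < 0.8:
        s = rng.uniform(*config.crop_scale_range)
        ch, cw = max(2, int(round(s * h))), max(2, int(round(s * w)))
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        out = resize(out[top:top + ch, left:left + cw], (h, w),
                     order=1, mode="edge", anti_aliasing=False)

    if "noise_injection" in ops and rng.uniform() < 0.5 and config.noise_std > 0:
        out = np.clip(out + rng.normal(0.0, config.noise_std, out.shape), 0.0, 1.0)

    if "cutout" in ops and rng.uniform() < 0.5:
        side = max(1, int(round(config.cutout_fraction * min(h, w))))
        top = rng.integers(0, h - side + 1)
        left = rng.integers(0, w - side + 1)
        out[top:top + side, left:left + side] = 0.0

    return np.clip(out, 0.0, 1.0)
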