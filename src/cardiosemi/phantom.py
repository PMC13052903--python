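"""Synthetic cardiac-like 2-D phantoms with ground-truth labels.

Each phantom emulates the four-class structure of a short-axis cardiac MRI
slice: background (0), an RV-like crescent (1), a Myo-like ring (2) and an
LV-like disk (3) strictly inside the ring.  The image is piecewise-constant
class intensity (bright blood pools, darker myocardium), corrupted by a
smooth multiplicative bias field and additive Gaussian noise, clipped to
[0, 1].  Geometry is an idealisation sufficient to exercise every training
and evaluation path — it is not an anatomical simulation.

Every sample is fully determined by ``(config.seed, index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "make_split",
    "load_nifti_slices",
]

NUM_CLASSES = 4
CLASS_NAMES = ("background", "RV", "Myo", "LV")


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 64
    center_jitter: float = 0.04           # fraction of image side
    lv_radius_range: tuple = (0.10, 0.15)  # fractions of image side
    myo_outer_range: tuple = (0.17, 0.24)
    rv_radius_range: tuple = (0.09, 0.14)
    intensity_means: tuple = (0.15, 0.65, 0.35, 0.80)  # bg, RV, Myo, LV
    noise_std: float = 0.08
    bias_field_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("lv_radius_range", "myo_outer_range", "rv_radius_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be ordered positive, got ({lo}, {hi})")
        if self.lv_radius_range[1] >= self.myo_outer_range[0]:
            raise ValueError("LV disk must fit strictly inside the Myo ring: "
                             "lv_radius_range max must be < myo_outer_range min")
        if len(self.intensity_means) != NUM_CLASSES:
            raise ValueError(f"need {NUM_CLASSES} intensity means")
        # worst-case RV crescent must stay inside the image
        s = self.image_size
        reach = (self.center_jitter + self.myo_outer_range[1]
                 + 1.5 * self.rv_radius_range[1]) * s
        if reach >= s / 2:
            raise ValueError("infeasible radius ranges: RV crescent can leave the image")


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray           # (H, W) float in [0, 1]
    label: np.ndarray           # (H, W) int in {0, 1, 2, 3}
    seed: int
    index: int
    params_used: dict = field(default_factory=dict)


def generate_phantom(config: PhantomConfig, index: int) -> PhantomSample:
    """Deterministically generate the ``index``-th phantom of a config."""
    rng = np.random.default_rng([config.seed, index])
    s = config.image_size
    cy = s / 2 + rng.uniform(-config.center_jitter, config.center_jitter) * s
    cx = s / 2 + rng.uniform(-config.center_jitter, config.center_jitter) * s
    r_lv = rng.uniform(*config.lv_radius_range) * s
    r_myo = rng.uniform(*config.myo_outer_range) * s
    r_rv = rng.uniform(*config.rv_radius_range) * s
    # the RV disk centre sits left of the ring so that its part outside the
    # ring forms a crescent hugging the myocardium
    d_rv = r_myo + 0.5 * r_rv
    rv_cy, rv_cx = cy, cx - d_rv

    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    r_main = np.hypot(yy - cy, xx - cx)
    r_sat = np.hypot(yy - rv_cy, xx - rv_cx)

    label = np.zeros((s, s), dtype=np.int64)
    label[(r_sat <= r_rv) & (r_main > r_myo)] = 1   # RV crescent
    label[(r_main <= r_myo) & (r_main > r_lv)] = 2  # Myo ring
    label[r_main <= r_lv] = 3                        # LV disk

    image = np.asarray(config.intensity_means, dtype=float)[label]
    if config.bias_field_amplitude > 0:
        raw = rng.normal(size=(s, s))
        smooth = ndimage.gaussian_filter(raw, sigma=s / 4)
        span = np.abs(smooth).max()
        if span > 0:
            image = image * (1.0 + config.bias_field_amplitude * smooth / span)
    if config.noise_std > 0:
        image = image + rng.normal(0.0, config.noise_std, (s, s))
    image = np.clip(image, 0.0, 1.0)

    params = {"cy": cy, "cx": cx, "r_lv": r_lv, "r_myo": r_myo,
              "r_rv": r_rv, "rv_cx": rv_cx}
    return PhantomSample(image=image, label=label, seed=config.seed,
                         index=index, params_used=params)


def generate_dataset(config: PhantomConfig, n: int,
                     start_index: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stack ``n`` consecutive phantoms into (N, H, W) image/label arrays."""
    samples = [generate_phantom(config, start_index + i) for i in range(n)]
    return (np.stack([s.image for s in samples]),
            np.stack([s.label for s in samples]))


def make_split(config: PhantomConfig, n_total: int, labeled_fraction: float,
               seed: int, test_fraction: float = 0.2):
    """Partition phantom indices into disjoint labeled / unlabeled / test sets.

    The train pool is split so that ``labeled count = max(1,
    round(labeled_fraction · n_train))``, mirroring the labeled-data-ratio
    protocol of semi-supervised benchmarks.
    """
    if not 0 < labeled_fraction <= 1:
        raise ValueError("labeled_fraction must be in (0, 1]")
    n_test = int(round(test_fraction * n_total))
    n_train = n_total - n_test
    if n_train < 1 or (n_test < 1 and test_fraction > 0):
        raise ValueError(f"n_total={n_total} too small for test_fraction={test_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_total)
    test = np.sort(perm[:n_test])
    train = perm[n_test:]
    n_labeled = max(1, int(round(labeled_fraction * n_train)))
    labeled = np.sort(train[:n_labeled])
    unlabeled = np.sort(train[n_labeled:])
    return labeled, unlabeled, test


def load_nifti_slices(image_path, label_path, axis: int = 2):
    """Read a NIfTI image/label volume pair as a list of 2-D samples.

    Intensities are min–max normalised per volume to [0, 1]; labels are cast
    to integers.  This adapter lets real short-axis slices flow through the
    same sample interface as phantoms.
    """
    import nibabel as nib

    img = np.asarray(nib.load(str(image_path)).get_fdata(), dtype=float)
    lab = np.asarray(nib.load(str(label_path)).get_fdata()).astype(np.int64)
    if img.shape != lab.shape:
        raise ValueError(f"image shape {img.shape} != label shape {lab.shape}")
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    samples = []
    for i in range(img.shape[axis]):
        sl_img = np.take(img, i, axis=axis)
        sl_lab = np.take(lab, i, axis=axis)
        samples.append(PhantomSample(image=sl_img, label=sl_lab, seed=-1,
                                     index=i, params_used={"source": "nifti"}))
    return samples
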