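"""Mean-teacher training: EMA parameter coupling, the per-step procedure,
and the SGD + cosine schedule.

One training step runs, in order: (1) teacher forward (evaluation mode, no
gradients) on the unlabeled batch to obtain pseudo-label probability maps;
(2) the DPTM pipeline turning those maps into the confidence weighting map
γ; (3) student forwards on the labeled batch, the unlabeled batch and (for
contrastive consistency) augmented views; (4) the combined objective
L = L_l + λ1·L_u + λ2·L_con; (5) an SGD step on the student; (6) the EMA
update of the teacher.  Component toggles independently disable DPTM (γ
falls back to a fixed 0.5 confidence cutoff), robust weighting (plain
pseudo-label cross-entropy on the selected pixels) and contrastive
consistency.  With DPTM *and* REM both off the pseudo-label branch is
inactive altogether, so the all-off configuration is exactly the
supervised-only baseline.

Pseudo-labels are data: the teacher never receives gradients, and the
student's view of each unlabeled image is a geometry-preserving photometric
perturbation so that γ and the pseudo-labels stay pixel-aligned.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import SGD, Tensor
from .augment import (AugmentationConfig, augment_pair, augment_photometric,
                      contrastive_view, strong_photometric_view)
from .backbone import NetworkConfig, UNet
from .contrastive import nt_xent_t
from .dptm import ThresholdMapState, dptm_step
from .losses import (LossWeights, RobustLossConfig, masked_pseudo_cross_entropy_t,
                     robust_unlabeled_loss_t, supervised_loss_t, total_loss)

__all__ = [
    "ScheduleConfig",
    "ComponentToggles",
    "TeacherStudentState",
    "ema_update_params",
    "cosine_lr",
    "train_step",
    "Trainer",
]

FIXED_FALLBACK_THRESHOLD = 0.5  # confidence cutoff when DPTM is disabled


@dataclass(frozen=True)
class ScheduleConfig:
    """SGD optimiser and cosine learning-rate schedule settings."""

    initial_lr: float = 1e-2
    final_lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 16
    total_epochs: int = 10
    rampup_fraction: float = 0.3

    def __post_init__(self):
        if not (self.initial_lr >= self.final_lr > 0):
            raise ValueError("require initial_lr >= final_lr > 0")
        if not 0.0 <= self.rampup_fraction <= 1.0:
            raise ValueError("rampup_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ComponentToggles:
    dptm: bool = True
    rem: bool = True
    cc: bool = True


@dataclass
class TeacherStudentState:
    """Paired student/teacher networks with EMA coefficient β and step count.

    The teacher starts as a copy of the student and is only ever moved by
    :func:`ema_update_params`; it receives no gradients.
    """

    student: UNet
    teacher: UNet
    ema_coefficient: float = 0.99
    step: int = 0

    @classmethod
    def initialize(cls, student: UNet, ema_coefficient: float = 0.99) -> "TeacherStudentState":
        if not 0.0 <= ema_coefficient <= 1.0:
            raise ValueError(f"β must be in [0, 1], got {ema_coefficient}")
        return cls(student=student, teacher=student.copy(),
                   ema_coefficient=ema_coefficient)


def ema_update_params(state: TeacherStudentState,
                      beta: float | None = None) -> TeacherStudentState:
    """θ̂ ← β·θ̂ + (1−β)·θ̄ for every parameter; normalisation buffers are
    copied from the student.  Increments the step counter.

    ``beta`` overrides the state's coefficient for one update (used by the
    warmup schedule β_t = min(β, 1 − 1/(t+1)), under which the teacher is
    the plain average of all students early in training)."""
    beta = state.ema_coefficient if beta is None else beta
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"β must be in [0, 1], got {beta}")
    s_params = state.student.parameters()
    for name, t_param in state.teacher.parameters().items():
        t_param.data *= beta
        t_param.data += (1.0 - beta) * s_params[name].data
    s_buffers = state.student.buffers()
    state.teacher.load_arrays({}, {k: v.copy() for k, v in s_buffers.items()})
    state.step += 1
    return state


def cosine_lr(step: int, total_steps: int, schedule: ScheduleConfig) -> float:
    """η_f + ½(η_i − η_f)(1 + cos(π·step/total_steps))."""
    if total_steps == 0:
        raise ValueError("total_steps must be positive")
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    ei, ef = schedule.initial_lr, schedule.final_lr
    return ef + 0.5 * (ei - ef) * (1.0 + math.cos(math.pi * step / total_steps))


def sigmoid_rampup(step: int, rampup_steps: int) -> float:
    """exp(−5(1−t)²) ramp of the unlabeled/consistency weights.

    The teacher's pseudo-labels are close to random early in training;
    feeding them to the student at full weight locks in a degenerate
    solution (confirmation bias).  The standard mean-teacher ramp grows the
    weight smoothly from ≈0 to 1 over ``rampup_steps``."""
    if rampup_steps <= 0:
        return 1.0
    t = min(step, rampup_steps) / rampup_steps
    return float(np.exp(-5.0 * (1.0 - t) ** 2))


def _pool_t(feats: Tensor) -> Tensor:
    """(B, d, h', w') -> (B, d) global average."""
    return feats.mean(axis=(2, 3))


def train_step(
    labeled_images: np.ndarray,
    labeled_labels: np.ndarray,
    unlabeled_images: np.ndarray | None,
    state: TeacherStudentState,
    threshold_state: ThresholdMapState,
    optimizer: SGD,
    lr: float,
    weights: LossWeights,
    toggles: ComponentToggles,
    robust_config: RobustLossConfig,
    aug_config: AugmentationConfig,
    rng: np.random.Generator,
    contrastive_temperature: float = 0.1,
    simclr_denominator: bool = False,
    dptm_stabilizer: float = 1e-8,
    augment_labeled: bool = True,
    student_unlabeled_view: str = "augmented",
    unlabeled_view_count: int = 1,
    projection: "ProjectionHead | None" = None,
    rng_unlabeled: np.random.Generator | None = None,
    rng_views: np.random.Generator | None = None,
):
    """One semi-supervised training step.

    Returns ``(threshold_state, breakdown)``; the teacher/student state is
    updated in place.  Raises :class:`FloatingPointError` with the loss
    breakdown attached if the total loss is non-finite.

    Randomness is split into three streams — labeled augmentation (``rng``),
    unlabeled photometric views (``rng_unlabeled``) and contrastive views
    (``rng_views``) — so that configurations differing only in component
    toggles draw identical labeled batches/augmentations (common random
    numbers; ablation differences then reflect the components, not RNG
    divergence).  Missing streams fall back to ``rng``.
    """
    rng_unlabeled = rng_unlabeled if rng_unlabeled is not None else rng
    rng_views = rng_views if rng_views is not None else rng
    if len(labeled_images) == 0:
        raise ValueError("labeled batch must be nonempty")
    student = state.student

    # labeled branch -------------------------------------------------------
    if augment_labeled:
        imgs, labs = [], []
        for im, lb in zip(labeled_images, labeled_labels):
            ai, al = augment_pair(im, lb, aug_config, rng)
            imgs.append(ai)
            labs.append(al)
        lab_x = np.stack(imgs).astype(np.float32)
        lab_y = np.stack(labs)
    else:
        lab_x = np.asarray(labeled_images, dtype=np.float32)
        lab_y = np.asarray(labeled_labels)

    has_unlabeled = unlabeled_images is not None and len(unlabeled_images) > 0
    pseudo_branch = has_unlabeled and (toggles.dptm or toggles.rem) and weights.lambda_unlabeled > 0
    cc_branch = has_unlabeled and toggles.cc and weights.lambda_contrastive > 0 \
        and len(unlabeled_images) >= 2

    l_unl = Tensor(np.asarray(0.0))
    l_con = Tensor(np.asarray(0.0))
    n_selected = 0
    pseudo = gamma = None

    if pseudo_branch:
        # (1) teacher pseudo-labels on the original geometry
        with ad.no_grad():
            t_probs, _ = state.teacher.forward(
                np.asarray(unlabeled_images, dtype=np.float32), training=False)
        pseudo = t_probs.data.transpose(0, 2, 3, 1).astype(float)  # (B, H, W, C)

        # (2) confidence weighting map
        if toggles.dptm:
            threshold_state, gamma, _ = dptm_step(threshold_state, pseudo,
                                                  stabilizer=dptm_stabilizer)
        else:
            conf = pseudo.max(axis=-1)
            gamma = (conf > FIXED_FALLBACK_THRESHOLD).astype(float)
        n_selected = int((gamma > 0).sum())

        # (3) student forwards: labeled batch and the (photometric) view of
        # the unlabeled batch run separately, so the supervised branch's
        # batch-normalisation statistics are not perturbed by the unlabeled
        # stream
        view_fn = {"strong": strong_photometric_view,
                   "augmented": augment_photometric}.get(student_unlabeled_view)
        n_views = max(1, unlabeled_view_count) if view_fn is not None else 1
        if view_fn is not None:
            u_view = np.stack([view_fn(im, aug_config, rng_unlabeled)
                               for _ in range(n_views)
                               for im in unlabeled_images]).astype(np.float32)
        else:
            u_view = np.asarray(unlabeled_images, dtype=np.float32)
        probs_l, _ = student.forward(lab_x, training=True)
        l_sup = supervised_loss_t(probs_l, lab_y)
        # all views pass through one forward (one stream, one BN batch);
        # the pseudo-labels and γ apply to every view unchanged
        probs_u, feats_u = student.forward(u_view, training=True)
        pseudo_rep = np.concatenate([pseudo] * n_views) if n_views > 1 else pseudo
        gamma_rep = np.concatenate([gamma] * n_views) if n_views > 1 else gamma
        if n_views > 1:
            feats_u = feats_u[:len(unlabeled_images)]

        # (4) robust or plain pseudo-label loss
        if toggles.rem:
            l_unl = robust_unlabeled_loss_t(probs_u, pseudo_rep, gamma_rep, robust_config)
        else:
            l_unl = masked_pseudo_cross_entropy_t(probs_u, pseudo_rep, gamma_rep)
    else:
        probs_l, _ = student.forward(lab_x, training=True)
        l_sup = supervised_loss_t(probs_l, lab_y)
        feats_u = None

    if cc_branch:
        views = np.stack([contrastive_view(im, aug_config, rng_views)
                          for im in unlabeled_images]).astype(np.float32)
        if feats_u is None:
            feats_u = student.encode(
                np.asarray(unlabeled_images, dtype=np.float32), training=True)
        feats_aug = student.encode(views, training=True)
        h = _pool_t(feats_u)
        h_aug = _pool_t(feats_aug)
        if projection is not None:
            h, h_aug = projection(h), projection(h_aug)
        l_con = nt_xent_t(h, h_aug, contrastive_temperature, simclr_denominator)

    breakdown = {
        "l_sup": float(l_sup), "l_unl": float(l_unl), "l_con": float(l_con),
        "lr": lr, "n_selected": n_selected,
    }
    try:
        total = total_loss(l_sup, l_unl, l_con, weights)
    except FloatingPointError as exc:
        raise FloatingPointError(f"{exc}; breakdown={breakdown}") from exc
    breakdown["total"] = float(total)

    # (5) student gradient step
    optimizer.zero_grad()
    total.backward()
    optimizer.step(lr=lr)

    # (6) teacher EMA with warmup: early teachers average all students
    eff_beta = min(state.ema_coefficient, 1.0 - 1.0 / (state.step + 1))
    ema_update_params(state, beta=eff_beta)
    return threshold_state, breakdown


class ProjectionHead:
    """Optional 2-layer MLP applied to pooled embeddings before NT-Xent."""

    def __init__(self, dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / dim)
        self.w1 = ad.Parameter(rng.normal(0, scale, (dim, dim)).astype(np.float32))
        self.b1 = ad.Parameter(np.zeros(dim, dtype=np.float32))
        self.w2 = ad.Parameter(rng.normal(0, scale, (dim, dim)).astype(np.float32))
        self.b2 = ad.Parameter(np.zeros(dim, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ((x @ self.w1) + self.b1).relu() @ self.w2 + self.b2

    def parameters(self) -> list:
        return [self.w1, self.b1, self.w2, self.b2]


class Trainer:
    """Runs the full semi-supervised loop on in-memory image stacks.

    Epochs iterate over the unlabeled stream (or the labeled one when no
    unlabeled data is given); labeled batches cycle independently with their
    own shuffling, as the two streams are sampled independently each step.
    """

    def __init__(
        self,
        network: NetworkConfig,
        schedule: ScheduleConfig,
        weights: LossWeights = LossWeights(),
        toggles: ComponentToggles = ComponentToggles(),
        robust_config: RobustLossConfig = RobustLossConfig(),
        aug_config: AugmentationConfig = AugmentationConfig(),
        ema_coefficient: float = 0.99,
        dptm_momentum: float = 0.99,
        dptm_stabilizer: float = 1e-8,
        dptm_reset_each_epoch: bool = False,
        contrastive_temperature: float = 0.1,
        simclr_denominator: bool = False,
        projection_head: bool = False,
        student_unlabeled_view: str = "augmented",
        unlabeled_view_count: int = 1,
        seed: int = 0,
    ):
        self.network_config = network
        self.schedule = schedule
        self.weights = weights
        self.toggles = toggles
        self.robust_config = robust_config
        self.aug_config = aug_config
        self.dptm_stabilizer = dptm_stabilizer
        self.dptm_momentum = dptm_momentum
        self.dptm_reset_each_epoch = dptm_reset_each_epoch
        self.contrastive_temperature = contrastive_temperature
        self.simclr_denominator = simclr_denominator
        self.student_unlabeled_view = student_unlabeled_view
        self.unlabeled_view_count = unlabeled_view_count
        self.seed = seed

        # independent streams: labeled sampling/augmentation, unlabeled
        # views, contrastive views (common-random-numbers across toggle
        # configurations sharing a seed)
        self.rng = np.random.default_rng([seed, 0])
        self.rng_unlabeled = np.random.default_rng([seed, 1])
        self.rng_views = np.random.default_rng([seed, 2])
        student = UNet(NetworkConfig(**{**network.__dict__, "seed": network.seed + seed}))
        self.state = TeacherStudentState.initialize(student, ema_coefficient)
        self.projection = None
        if projection_head:
            dim = network.base_width * 2 ** (network.depth - 1)
            # dedicated stream: adding the head must not shift the labeled
            # augmentation sequence shared across toggle configurations
            self.projection = ProjectionHead(dim, np.random.default_rng([seed, 3]))
        params = list(student.parameters().values())
        if self.projection is not None:
            params += self.projection.parameters()
        self.optimizer = SGD(params, lr=schedule.initial_lr,
                             momentum=schedule.momentum,
                             weight_decay=schedule.weight_decay)
        self.threshold_state: ThresholdMapState | None = None
        self.history: list[dict] = []

    # ------------------------------------------------------------------

    def _init_threshold(self, h: int, w: int) -> None:
        self.threshold_state = ThresholdMapState.initial(
            h, w, self.network_config.num_classes, momentum=self.dptm_momentum)

    def fit(self, labeled_images, labeled_labels, unlabeled_images=None,
            log_path=None) -> list[dict]:
        """Train for ``schedule.total_epochs``; returns the per-step history."""
        labeled_images = np.asarray(labeled_images, dtype=float)
        labeled_labels = np.asarray(labeled_labels)
        nl = len(labeled_images)
        has_u = unlabeled_images is not None and len(unlabeled_images) > 0
        if has_u:
            unlabeled_images = np.asarray(unlabeled_images, dtype=float)
        h, w = labeled_images.shape[1:3]
        self._init_threshold(h, w)

        bs = self.schedule.batch_size
        nu = len(unlabeled_images) if has_u else 0
        steps_per_epoch = math.ceil((nu if has_u else nl) / bs)
        total_steps = self.schedule.total_epochs * steps_per_epoch

        log_file = open(log_path, "w") if log_path else None
        step = 0
        lab_order = self.rng.permutation(nl)
        lab_pos = 0
        try:
            for epoch in range(self.schedule.total_epochs):
                if epoch > 0 and self.threshold_state is not None:
                    self.threshold_state = self.threshold_state.next_epoch(
                        reset=self.dptm_reset_each_epoch)
                u_order = self.rng_unlabeled.permutation(nu) if has_u else None
                for k in range(steps_per_epoch):
                    # labeled batch: independent cycling sampler
                    idx = []
                    for _ in range(min(bs, nl)):
                        if lab_pos == nl:
                            lab_order = self.rng.permutation(nl)
                            lab_pos = 0
                        idx.append(lab_order[lab_pos])
                        lab_pos += 1
                    lx, ly = labeled_images[idx], labeled_labels[idx]
                    ux = None
                    if has_u:
                        u_idx = u_order[k * bs:(k + 1) * bs]
                        if len(u_idx) == 0:
                            u_idx = u_order[-min(bs, nu):]
                        ux = unlabeled_images[u_idx]
                    lr = cosine_lr(step, total_steps, self.schedule)
                    ramp = sigmoid_rampup(
                        step, int(self.schedule.rampup_fraction * total_steps))
                    eff_weights = LossWeights(
                        lambda_unlabeled=self.weights.lambda_unlabeled * ramp,
                        lambda_contrastive=self.weights.lambda_contrastive * ramp)
                    self.threshold_state, breakdown = train_step(
                        lx, ly, ux, self.state, self.threshold_state,
                        self.optimizer, lr, eff_weights, self.toggles,
                        self.robust_config, self.aug_config, self.rng,
                        rng_unlabeled=self.rng_unlabeled,
                        rng_views=self.rng_views,
                        contrastive_temperature=self.contrastive_temperature,
                        simclr_denominator=self.simclr_denominator,
                        dptm_stabilizer=self.dptm_stabilizer,
                        student_unlabeled_view=self.student_unlabeled_view,
                        unlabeled_view_count=self.unlabeled_view_count,
                        projection=self.projection,
                    )
                    breakdown.update(step=step, epoch=epoch, batch=k)
                    self.history.append(breakdown)
                    if log_file:
                        log_file.write(json.dumps(breakdown) + "\n")
                    step += 1
        finally:
            if log_file:
                log_file.close()
        return self.history

    # ------------------------------------------------------------------

    def predict_labels(self, images, model: str = "student") -> np.ndarray:
        net = self.state.student if model == "student" else self.state.teacher
        out = []
        for start in range(0, len(images), self.schedule.batch_size):
            probs, _ = net.predict_proba(
                np.asarray(images[start:start + self.schedule.batch_size], dtype=np.float32))
            out.append(probs.argmax(axis=-1))
        return np.concatenate(out)

    def save_checkpoint(self, directory) -> None:
        """Write student/teacher parameters, threshold map, optimizer and RNG
        state into a run directory."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.state.student.save(d / "student.npz")
        self.state.teacher.save(d / "teacher.npz")
        if self.threshold_state is not None:
            from .dptm import save_threshold_state
            save_threshold_state(self.threshold_state, d / "threshold_map.npz")
        np.savez(d / "optimizer.npz", *self.optimizer.state_dict()["velocity"])
        meta = {
            "step": self.state.step,
            "ema_coefficient": self.state.ema_coefficient,
            "rng_state": self.rng.bit_generator.state,
            "rng_unlabeled_state": self.rng_unlabeled.bit_generator.state,
            "rng_views_state": self.rng_views.bit_generator.state,
            "seed": self.seed,
        }
        (d / "trainer_state.json").write_text(json.dumps(meta, default=str, indent=1))
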