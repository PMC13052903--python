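"""Run configuration: one nested, YAML-round-trippable record tying the
phantom generator, augmentation, network, optimiser schedule, loss weights
and component toggles into a reproducible run."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentationConfig
from .backbone import NetworkConfig
from .losses import LossWeights, RobustLossConfig
from .mean_teacher import ComponentToggles, ScheduleConfig
from .phantom import PhantomConfig

__all__ = ["DataSettings", "DPTMSettings", "ContrastiveSettings", "RunConfig",
           "load_config", "save_config", "desk_scale_config"]


@dataclass(frozen=True)
class DataSettings:
    n_total: int = 250
    labeled_fraction: float = 0.1
    test_fraction: float = 0.2
    split_seed: int = 0


@dataclass(frozen=True)
class DPTMSettings:
    momentum: float = 0.99        # EMA α of the threshold map
    stabilizer: float = 1e-8      # ξ
    reset_each_epoch: bool = False


@dataclass(frozen=True)
class ContrastiveSettings:
    temperature: float = 0.1
    simclr_denominator: bool = False
    projection_head: bool = False


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    robust: RobustLossConfig = field(default_factory=RobustLossConfig)
    dptm: DPTMSettings = field(default_factory=DPTMSettings)
    contrastive: ContrastiveSettings = field(default_factory=ContrastiveSettings)
    toggles: ComponentToggles = field(default_factory=ComponentToggles)
    data: DataSettings = field(default_factory=DataSettings)
    ema_coefficient: float = 0.99
    student_unlabeled_view: str = "augmented"
    unlabeled_view_count: int = 1
    seed: int = 0
    output_dir: str = "runs/run"


_SECTIONS = {f.name: f for f in dataclasses.fields(RunConfig)}


def _build(cls, data: dict):
    """Instantiate a (frozen) dataclass from a plain dict, restoring tuples
    and rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        default = fields[name].default
        if isinstance(value, list) and (isinstance(default, tuple)
                                        or fields[name].type.startswith("tuple")):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[name] = value
    return cls(**kwargs)


def config_to_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(data: dict) -> RunConfig:
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections/keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = _SECTIONS[name]
        if isinstance(value, dict):
            if f.default_factory is dataclasses.MISSING:
                raise ValueError(f"config key {name!r} does not take a mapping")
            kwargs[name] = _build(type(f.default_factory()), value)
        else:
            kwargs[name] = value
    return RunConfig(**kwargs)


def desk_scale_config() -> RunConfig:
    """The built-in CPU-scale study configuration.

    Trains on 16 labeled + 144 unlabeled 64×64 phantoms and evaluates on 50
    held-out phantoms with a small U-Net (depth 3, base width 8).  Schedule
    parameters are matched to the few-hundred-step budget: batch 8, a
    threshold-map EMA horizon of tens of batches (α = 0.9), the mean-teacher
    warmup β_t = min(0.99, 1 − 1/(t+1)), a sigmoid ramp of the unlabeled
    and contrastive weights over the first half of training, a reduced
    unlabeled weight (λ1 = 0.3) as appropriate for a very small labeled
    set, a strong (occluding) student view of unlabeled images, and a
    softer contrastive temperature (0.5) because phantom embeddings are far
    more homogeneous than real slices.  See docs/methods.md.
    """
    from .backbone import NetworkConfig
    from .losses import LossWeights
    from .mean_teacher import ScheduleConfig

    return RunConfig(
        network=NetworkConfig(base_width=8, depth=3, seed=0),
        schedule=ScheduleConfig(total_epochs=15, batch_size=8,
                                rampup_fraction=0.5),
        data=DataSettings(n_total=210, labeled_fraction=0.1,
                          test_fraction=50 / 210),
        dptm=DPTMSettings(momentum=0.9),
        contrastive=ContrastiveSettings(temperature=0.5),
        ema_coefficient=0.99,
        student_unlabeled_view="strong",
        loss_weights=LossWeights(lambda_unlabeled=0.3, lambda_contrastive=0.1),
    )


def load_config(path) -> RunConfig:
    """Read a (possibly partial) YAML config; unspecified fields take their
    defaults and are present in the resolved dump."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    """Dump the fully-resolved config (every defaulted field included)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
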