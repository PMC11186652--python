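"""Run configuration: YAML schema, validation, and seed fan-out.

A single global seed deterministically derives named sub-seeds (cohort
sampling, model initialisation, training shuffle/augmentation) via a stable
CRC-based hash, so one flag reproduces the whole pipeline.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelConfig
from .synthetic import CohortConfig, RenderConfig
from .training import AugmentConfig, TrainConfig

__all__ = ["RunConfig", "load_config", "save_config", "derive_seed"]


def derive_seed(global_seed: int, name: str) -> int:
    """Stable named sub-seed, below 2^31."""
    return int((int(global_seed) * 0x9E3779B1 + zlib.crc32(name.encode())) % (2**31))


@dataclass
class RunConfig:
    """Merged cohort + render + model + training configuration."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        # fan the global seed out to the sub-configs
        self.cohort = dataclasses.replace(
            self.cohort, seed=derive_seed(self.seed, "cohort")
        )
        self.train = dataclasses.replace(
            self.train, seed=derive_seed(self.seed, "train")
        )

    @property
    def model_seed(self) -> int:
        return derive_seed(self.seed, "model-init")

    def seeds(self) -> dict[str, int]:
        return {
            "global": self.seed,
            "cohort": self.cohort.seed,
            "train": self.train.seed,
            "model-init": self.model_seed,
        }


_SECTION_TYPES = {
    "cohort": CohortConfig,
    "render": RenderConfig,
    "model": ModelConfig,
    "train": TrainConfig,
}


def _build_section(cls, data: dict, path: str, errors: list[str]):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    errors.extend(f"{path}.{k}: unknown key" for k in sorted(unknown))
    kwargs = {k: v for k, v in data.items() if k in known}
    for key in ("sc_conv_channels", "sc_fc_widths", "grade_distribution",
                "lesion_radius_range", "scale_jitter_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if cls is TrainConfig and isinstance(kwargs.get("augment_cfg"), dict):
        kwargs["augment_cfg"] = _build_section(
            AugmentConfig, kwargs["augment_cfg"], f"{path}.augment_cfg", errors
        )
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"{path}: {exc}")
        return None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing sections take their defaults; unknown keys are rejected, and all
    schema violations are reported together.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    unknown = set(raw) - set(_SECTION_TYPES) - {"seed"}
    errors.extend(f"{k}: unknown top-level key" for k in sorted(unknown))
    sections = {}
    for name, cls in _SECTION_TYPES.items():
        data = raw.get(name, {})
        if not isinstance(data, dict):
            errors.append(f"{name}: must be a mapping")
            data = {}
        sections[name] = _build_section(cls, data, name, errors)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(seed=int(raw.get("seed", 0)), **sections)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    payload = {
        "seed": cfg.seed,
        "cohort": clean(cfg.cohort),
        "render": clean(cfg.render),
        "model": clean(cfg.model),
        "train": clean(cfg.train),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
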