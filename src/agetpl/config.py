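"""Run configuration: a single YAML-serializable object with every tolerance."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

BACKENDS = ("demons",)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    root_seed: int = 0
    out_dir: str = "agetpl_run"
    # cohort
    age_groups: list[str] = field(default_factory=lambda: ["20-24", "70-74"])
    n_per_group: int = 3
    grid_shape: list[int] = field(default_factory=lambda: [48, 48, 48])
    voxel_size: float = 2.0
    noise_sigma: float = 15.0
    bias_amplitude: float = 0.0
    shape_jitter: float = 1.0
    phantom_overrides: dict = field(default_factory=dict)  # extra PhantomSpec fields
    # registration
    backend: str = "demons"
    schedule_plan: list[str] = field(
        default_factory=lambda: ["8x0x0", "8x4x0", "8x4x2"]
    )
    inv_tol_voxels: float = 0.2
    # template
    rms_tol: float = 0.05
    template_max_iter: int = 3
    # segmentation
    seg_tol: float = 1e-6
    seg_max_iter: int = 200
    mrf_beta: float = 0.0
    # evaluation
    schemes: list[str] = field(default_factory=lambda: ["five_year", "ten_year"])

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ConfigError(
                f"unknown registration backend {self.backend!r}; choose from {BACKENDS}"
            )
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(self.to_yaml())
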