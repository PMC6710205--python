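"""Pipeline configuration: defaults, YAML/JSON loading, validation.

One config object drives every stage so a run is reproducible from a
single file.  Unknown keys are rejected rather than ignored — a typo in
a threshold name should fail loudly, not silently fall back to the
default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PreprocessConfig:
    dt: float = 1.0                 # s, uniform grid step (~1 beat at rest)
    refractory_s: float = 0.3       # s, min inter-beat interval
    breath_min_sep_s: float = 1.5   # s, min separation of end-tidal maxima
    artifact_sd: float = 4.0        # SD threshold for beat rejection
    max_reject_frac: float = 0.2    # above this the recording is unusable


@dataclass
class ModelConfig:
    M: int = 50                     # kernel memory, samples
    alpha_grid: list = field(default_factory=lambda: [0.2, 0.3, 0.4, 0.5,
                                                      0.6, 0.7, 0.8])
    L_grid: list = field(default_factory=lambda: [2, 3, 4])
    ridge: float = 0.0
    # pinning all four fixes the structure and skips the grid search
    alpha_p: float | None = None
    alpha_c: float | None = None
    L_p: int | None = None
    L_c: int | None = None
    nonlinear: bool = False         # reserved extension point; must stay False

    def fixed_structure(self) -> bool:
        return None not in (self.alpha_p, self.alpha_c, self.L_p, self.L_c)


@dataclass
class PulseConfig:
    duration_s: float = 5.0         # s, ETCO2 pulse length
    amplitude: float = 1.0          # mmHg
    window_s: float = 5.0           # s, averaging window from pulse onset
    normalized: bool = False        # report DVR as % baseline CBFV per mmHg


@dataclass
class StatsConfig:
    covariates: list = field(default_factory=lambda: ["age", "gender",
                                                      "education"])
    alpha: float = 0.05


@dataclass
class VoxelwiseConfig:
    alpha: float = 0.05
    method: str = "uncorrected"     # or "bh_fdr"
    use_adjusted_dvr: bool = False


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    pulse: PulseConfig = field(default_factory=PulseConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    voxelwise: VoxelwiseConfig = field(default_factory=VoxelwiseConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, val in d.items():
            if key not in sections:
                raise ValueError(f"unknown config section {key!r}")
            f = sections[key]
            if key == "seed":
                kwargs[key] = int(val)
                continue
            sub_cls = f.default_factory
            sub_fields = {sf.name for sf in dataclasses.fields(sub_cls)}
            unknown = set(val) - sub_fields
            if unknown:
                raise ValueError(
                    f"unknown keys in config section {key!r}: {sorted(unknown)}")
            kwargs[key] = sub_cls(**val)
        cfg = cls(**kwargs)
        if cfg.model.nonlinear:
            raise ValueError("nonlinear model extension is reserved, not "
                             "implemented; set model.nonlinear = false")
        if cfg.voxelwise.method not in ("uncorrected", "bh_fdr"):
            raise ValueError(f"unknown voxelwise method "
                             f"{cfg.voxelwise.method!r}")
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = (json.loads(text) if str(path).endswith(".json")
             else yaml.safe_load(text)) or {}
        return cls.from_dict(d)
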