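"""Pipeline configuration: a YAML file mapping onto :class:`PipelineConfig`.

The config names the input files, filtering thresholds (in percent, as
they are conventionally quoted), the dominant-taxon list omitted from
abundance analyses, the model and MCMC blocks, seeds and the output
directory. A stable hash of the canonicalised config travels into every
output manifest so a run can be reproduced from its artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import McmcSchedule, ModelSpec, Priors, RandomLevel
from .preprocess import DEFAULT_DOMINANTS

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    counts: "str | None" = None
    samples: "str | None" = None
    traits: "str | None" = None
    blank: "str | None" = None
    out_dir: str = "honeyjsdm_out"
    cell_threshold_pct: float = 0.001
    mean_threshold_pct: float = 0.01
    min_prevalence_pct: float = 5.0
    dominant_ids: list = field(default_factory=lambda: list(DEFAULT_DOMINANTS))
    seed: int = 0
    simulate: "dict | None" = None          # synthgen settings when simulating
    model: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)

    def schedule(self) -> McmcSchedule:
        return McmcSchedule(**self.mcmc)

    def model_spec(self) -> ModelSpec:
        kwargs = dict(self.model)
        if "random_levels" in kwargs:
            kwargs["random_levels"] = [RandomLevel(**rl) for rl in kwargs["random_levels"]]
        if "priors" in kwargs:
            kwargs["priors"] = Priors(**kwargs["priors"])
        return ModelSpec(**kwargs)

    def validate(self, require_inputs: bool = True) -> None:
        for pct in (self.cell_threshold_pct, self.mean_threshold_pct,
                    self.min_prevalence_pct):
            if not 0 <= pct <= 100:
                raise ValueError(f"threshold {pct} outside [0, 100]%")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be integral")
        self.schedule().validate()
        self.model_spec()
        if require_inputs and self.simulate is None:
            for name in ("counts", "samples", "traits"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config missing required input path: {name}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")
            if self.blank is not None and not Path(self.blank).exists():
                raise FileNotFoundError(f"blank file not found: {self.blank}")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
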