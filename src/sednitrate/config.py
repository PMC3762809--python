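"""Pipeline configuration: YAML loading and fail-fast validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .metrics import DEFAULT_FUCO_THRESHOLD, RateParams, default_rate_params
from .partition import DEFAULT_POREWATER_DENSITY
from .simulate import SimulationParams


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, resolved before any computation."""

    slice_csv: str | None = None
    pigment_csv: str | None = None
    environment_csv: str | None = None
    mat_csv: str | None = None
    otu_table: str | None = None
    out_dir: str = "out"
    seed: int = 0
    porewater_density: float = DEFAULT_POREWATER_DENSITY
    threshold: float = DEFAULT_FUCO_THRESHOLD
    naive_v2: bool = False
    n_perm: int = 9999
    max_depth: float | None = None  # None: integrate each core's full profile
    allow_gaps: bool = False
    rate_params: RateParams = field(default_factory=default_rate_params)
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def validate(self) -> None:
        for attr in ("slice_csv", "pigment_csv", "environment_csv", "mat_csv", "otu_table"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{attr}: file not found: {path}")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        self.simulation.validate()

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from an optional YAML file plus overrides.

    Unknown keys in the file or the overrides are rejected by name.
    """
    raw: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {', '.join(sorted(unknown))}")

    if isinstance(raw.get("rate_params"), dict):
        sub = raw["rate_params"]
        allowed = {"fuco_per_cell", "cell_rate_low", "cell_rate_high"}
        bad = set(sub) - allowed
        if bad:
            raise ValidationError(f"unknown rate_params key(s): {', '.join(sorted(bad))}")
        base = dataclasses.asdict(default_rate_params())
        base.update(sub)
        raw["rate_params"] = RateParams(**base)
    sim_seed_explicit = False
    if isinstance(raw.get("simulation"), dict):
        sub = raw["simulation"]
        allowed = {f.name for f in dataclasses.fields(SimulationParams)}
        bad = set(sub) - allowed
        if bad:
            raise ValidationError(f"unknown simulation key(s): {', '.join(sorted(bad))}")
        sim_seed_explicit = "seed" in sub
        raw["simulation"] = SimulationParams(**sub)

    cfg = PipelineConfig(**raw)
    if not sim_seed_explicit:
        cfg.simulation = cfg.simulation.replace(seed=int(cfg.seed))
    cfg.validate()
    return cfg
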