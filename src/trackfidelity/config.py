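"""Pipeline configuration: schema-validated parameters with field defaults
matching the analysis conventions used throughout the package (150 km/h
speed ceiling, DBSCAN 3/4000 m/10 d with a 5/8000 m/20 d alternative, 90%
utilization level, 15-minute interpolation, 500-point mean route, 1°
latitudinal bands from 8°N to 73°N)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .clustering import ClusterParams
from .synthetic import SimConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    vmax_kmh: float = 150.0
    distance_method: str = "ellipsoidal"      # or "haversine"
    cluster: ClusterParams = field(default_factory=ClusterParams)
    cluster_overrides: dict = field(default_factory=dict)   # bird_id -> ClusterParams kwargs
    min_tenure_d: float = 1.0
    ud_level: float = 0.90
    ud_cell_m: float = 250.0
    interp_dt_min: float = 15.0
    interp_mode: str = "kalman"               # or "linear"
    n_route_points: int = 500
    n_boot: int = 1000
    min_ind_per_band: int = 2
    d_north_km: float = 100.0
    sim: SimConfig = field(default_factory=SimConfig)

    def cluster_params_for(self, bird_id: str) -> ClusterParams:
        if bird_id in self.cluster_overrides:
            return ClusterParams(**{**dataclasses.asdict(self.cluster),
                                    **self.cluster_overrides[bird_id]})
        return self.cluster


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected with a message."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "cluster" in kwargs and isinstance(kwargs["cluster"], dict):
        kwargs["cluster"] = ClusterParams(**kwargs["cluster"])
    if "sim" in kwargs and isinstance(kwargs["sim"], dict):
        sim_known = {f.name for f in fields(SimConfig)}
        sim_unknown = set(kwargs["sim"]) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
        kwargs["sim"] = SimConfig(**{k: _delist(v) for k, v in kwargs["sim"].items()})
    return PipelineConfig(**kwargs)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def _delist(v):
    return tuple(v) if isinstance(v, list) else v
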