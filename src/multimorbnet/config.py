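"""Pipeline configuration: all tunable constants in one serializable object."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .synthetic import SyntheticSpec


class ConfigError(ValueError):
    """Raised when a configuration value is outside its documented range."""


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis.

    Thresholds default to the study constants: 1% prevalence filter, t-screen
    at 2.58 (two-sided p < 0.01), burst growth >= 6, top-10 PageRank hubs with
    damping 0.85, 1%/3%/5% edge removal x3, temporal baseline 2015 through
    2021. The master seed fans out deterministically to every stochastic
    stage.
    """

    # inputs / outputs
    events_path: str | None = None
    patients_path: str | None = None
    catalog_path: str | None = None
    output_dir: str = "results"
    # cohort rules
    t2dm_codes: tuple[str, ...] = ("E11",)
    min_prevalence: float = 0.01
    require_chronic_anchor: bool = True
    exempt_partial_years: bool = False
    # network construction
    t_critical: float = 2.58
    min_stratum_size: int = 30
    # crucial diseases
    top_k_hubs: int = 10
    pagerank_damping: float = 0.85
    louvain_restarts: int = 20
    louvain_resolution: float = 1.0
    burst_threshold: int = 6
    # perturbation
    perturb_levels: tuple[float, ...] = (0.01, 0.03, 0.05)
    perturb_reps: int = 3
    # temporal trends
    temporal_start_year: int = 2013
    temporal_baseline_year: int = 2015
    temporal_end_year: int = 2021
    # randomness
    seed: int = 0
    # optional synthetic-data stage
    synthetic: SyntheticSpec | None = None

    def validate(self) -> None:
        if not 0 < self.min_prevalence <= 1:
            raise ConfigError(
                f"min_prevalence={self.min_prevalence} must be a fraction in (0, 1] "
                "(use 0.01 for 1%, not a percentage)"
            )
        if not 0 < self.pagerank_damping < 1:
            raise ConfigError("pagerank_damping must lie in (0, 1)")
        if self.t_critical <= 0:
            raise ConfigError("t_critical must be positive")
        if self.burst_threshold < 1:
            raise ConfigError("burst_threshold must be >= 1")
        if self.top_k_hubs < 1:
            raise ConfigError("top_k_hubs must be >= 1")
        if any(not 0 <= lv < 1 for lv in self.perturb_levels):
            raise ConfigError("perturb_levels must be fractions in [0, 1)")
        if self.perturb_reps < 1:
            raise ConfigError("perturb_reps must be >= 1")
        if not (self.temporal_start_year <= self.temporal_baseline_year <= self.temporal_end_year):
            raise ConfigError("temporal years must satisfy start <= baseline <= end")
        if self.louvain_restarts < 1:
            raise ConfigError("louvain_restarts must be >= 1")
        if self.synthetic is not None:
            self.synthetic.validate()

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        if syn is not None:
            for key in ("baseline_prevalence_range", "hub_conditions", "years", "age_range"):
                if key in syn and syn[key] is not None:
                    syn[key] = tuple(syn[key])
            syn = SyntheticSpec(**syn)
        for key in ("t2dm_codes", "perturb_levels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(synthetic=syn, **d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_tuples_to_lists(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the full configuration (for the run manifest)."""
        payload = json.dumps(_tuples_to_lists(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj
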