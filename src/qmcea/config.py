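"""Run configuration: one structured object tying all stages together.

A ``RunConfig`` nests the cohort spec, generating parameters, imputation
settings, decision-model switches and PSA settings, and round-trips to YAML
so a full analysis is reproducible from a single text file plus a master
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .params import ConfigurationError
from .synthetic import CohortSpec, TrajectoryParams
from .imputation import ImputationSpec
from .markov import ModelConfig

#: Scenario menu: base case, secondary state definition, NICE values and the
#: one-way sensitivity toggles (no mortality, undiscounted, no post-trial
#: non-hospital costs).
SCENARIOS = {
    "base": {},
    "any_hosp": {"rsh_definition": "any"},
    "nice": {"value_source": "nice"},
    "no_mortality": {"include_mortality": False},
    "discount_0": {"discount_rate": 0.0},
    "no_posttrial_nonhosp": {"include_post_trial_nonhosp": False},
}


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    prune_alpha: float = 0.05
    working_correlation: str = "independence"
    n_sims: int = 10000
    scenarios: list = field(default_factory=lambda: list(SCENARIOS))

    def __post_init__(self):
        self.cohort.seed = self.seed
        self.imputation.seed = self.seed

    def validate(self) -> None:
        self.cohort.validate()
        self.trajectory.validate(self.cohort.n_cycles)
        self.imputation.validate()
        self.model.validate()
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ConfigurationError(f"unknown scenario '{s}'; choose from {sorted(SCENARIOS)}")
        if self.n_sims < 1:
            raise ConfigurationError("n_sims must be >= 1")

    def scenario_model(self, name: str) -> ModelConfig:
        overrides = SCENARIOS[name]
        return dataclasses.replace(self.model, **overrides)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d.pop(f.name)
            if f.name == "cohort":
                kw[f.name] = _from_plain(CohortSpec, v)
            elif f.name == "trajectory":
                kw[f.name] = _from_plain(TrajectoryParams, v)
            elif f.name == "imputation":
                kw[f.name] = _from_plain(ImputationSpec, v)
            elif f.name == "model":
                kw[f.name] = _from_plain(ModelConfig, v)
            else:
                kw[f.name] = v
        if d:
            raise ConfigurationError(f"unknown config keys: {sorted(d)}")
        cfg = cls(**kw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _from_plain(cls, d):
    if dataclasses.is_dataclass(d):
        return d
    kw = {}
    array_fields = {"p_nonsh_given_sh", "p_nonsh_given_nosh", "dropout_hazard",
                    "censor_cycle_pmf", "wtp_grid"}
    dict_of_array = {"p_sh", "sh_cost_mean", "nonsh_cost_mean",
                     "p_nonhosp_given_sh", "p_nonhosp_given_nosh", "death_hazard"}
    names = {f.name for f in dataclasses.fields(cls)}
    for k, v in d.items():
        if k not in names:
            raise ConfigurationError(f"unknown {cls.__name__} key '{k}'")
        if k in array_fields and v is not None:
            v = np.asarray(v, dtype=float)
        elif k in dict_of_array and isinstance(v, dict):
            v = {a: np.asarray(x, dtype=float) for a, x in v.items()}
        kw[k] = v
    return cls(**kw)
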