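"""Run configuration (JSON-serializable, schema-validated).

Defaults follow the standard study conditions: batch size 256 with 128
oracle calls per epoch in one inner loop (AL/RL ratio 0.5); the optimized
configuration uses 512/64/2 with zero-surrogate weights and UCB acquisition
for a ratio of 0.125. Unknown keys fail fast.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .acquisition import AcquisitionSpec
from .oracles import Oracle, make_oracle
from .rl import RLParams, WeightScheme
from .scoring import (ScoreComponentSpec, TransformSpec, docking_transform,
                      rocs_transform)

__all__ = ["RunConfig", "default_components"]


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TransformConfig(_Base):
    kind: Literal["identity", "sigmoid", "reverse_sigmoid", "double_sigmoid"] = "identity"
    low: float = 0.0
    high: float = 1.0
    k: float = 1.0
    coef_div: float = 1.0
    coef_steep: float = 1.0

    def to_spec(self) -> TransformSpec:
        return TransformSpec(kind=self.kind, low=self.low, high=self.high,
                             k=self.k, coef_div=self.coef_div,
                             coef_steep=self.coef_steep)


class ComponentConfig(_Base):
    name: str
    evaluator: Literal["qed", "mol_weight", "hbd_count", "custom_alerts",
                       "oracle", "surrogate"]
    is_penalty: bool = False
    weight: float = Field(1.0, ge=0.0, le=1.0)
    transform: TransformConfig = TransformConfig()
    params: Optional[list[str]] = None

    def to_spec(self) -> ScoreComponentSpec:
        return ScoreComponentSpec(name=self.name, evaluator=self.evaluator,
                                  is_penalty=self.is_penalty, weight=self.weight,
                                  transform=self.transform.to_spec(),
                                  params=(None if self.params is None
                                          else tuple(self.params)))


class OracleConfig(_Base):
    name: Literal["pseudo_rocs", "pseudo_dock"] = "pseudo_rocs"
    noise_sd: float = Field(0.0, ge=0.0)
    include_hidden: bool = False


class AcquisitionConfig(_Base):
    strategy: Literal["random", "greedy", "ucb", "mpo_greedy", "mpo_ucb"] = "ucb"
    beta: float = Field(1.0, ge=0.0)


class SurrogateConfig(_Base):
    window: int = Field(1000, ge=2)
    selection_mode: Literal["recent", "adaptive"] = "recent"
    n_trees: int = Field(200, ge=1)
    max_depth: int = Field(30, ge=1)
    min_samples_split: int = Field(2, ge=2)
    adaptive_cycles: int = Field(3, ge=1)


class WeightConfig(_Base):
    kind: Literal["full_belief", "constant", "uncertainty_gate",
                  "zero_surrogate"] = "full_belief"
    constant_value: float = Field(0.5, ge=0.0, le=1.0)
    uncertainty_threshold: float = Field(0.05, ge=0.0)

    def to_scheme(self) -> WeightScheme:
        return WeightScheme(kind=self.kind, constant_value=self.constant_value,
                            uncertainty_threshold=self.uncertainty_threshold)


class RLConfig(_Base):
    alpha: float = Field(128.0, gt=0.0)
    learning_rate: float = Field(1e-4, gt=0.0)
    difference: Literal["agent", "prior"] = "agent"

    def to_params(self) -> RLParams:
        return RLParams(alpha=self.alpha, learning_rate=self.learning_rate,
                        difference=self.difference)


class DiversityConfig(_Base):
    enabled: bool = True
    bucket_size: int = Field(100, ge=1)
    min_score: float = Field(0.2, ge=0.0, le=1.0)


class ReplayConfig(_Base):
    enabled: bool = True
    capacity: int = Field(100, ge=1)
    sample_size: int = Field(10, ge=1)


class RunConfig(_Base):
    """Full experiment parameterization."""

    mode: Literal["rl", "rl-al", "vs-al"] = "rl-al"
    n_batch: int = Field(256, ge=1)
    n_acquired: int = Field(128, ge=1)
    n_loops: int = Field(1, ge=1)
    epochs: Optional[int] = Field(None, ge=1)
    oracle_budget: Optional[int] = Field(2000, ge=1)
    stop_at_hit_scaffolds: Optional[int] = Field(None, ge=1)
    mc_samples: int = Field(1000, ge=1)
    descriptor_set: Literal["fast", "full", "oracle"] = "fast"
    max_len: int = Field(128, ge=4)
    seed: int = 0
    weight_scheme: WeightConfig = WeightConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    oracle: OracleConfig = OracleConfig()
    surrogate: SurrogateConfig = SurrogateConfig()
    rl: RLConfig = RLConfig()
    diversity_filter: DiversityConfig = DiversityConfig()
    replay: ReplayConfig = ReplayConfig()
    components: Optional[list[ComponentConfig]] = None

    @model_validator(mode="after")
    def _check(self):
        if self.n_acquired > self.n_batch:
            raise ValueError("n_acquired must not exceed n_batch")
        if self.n_acquired % self.n_loops:
            raise ValueError("n_acquired must be divisible by n_loops")
        if self.epochs is None and self.oracle_budget is None:
            raise ValueError("either epochs or oracle_budget must be set")
        return self

    @property
    def al_rl_ratio(self) -> float:
        return self.n_acquired / self.n_batch

    # -- runtime object factories -----------------------------------------
    def build_oracle(self) -> Oracle:
        return make_oracle(self.oracle.name, noise_sd=self.oracle.noise_sd,
                           noise_seed=(self.seed * 7919 + 13) % (2 ** 31),
                           **({"include_hidden": True}
                              if (self.oracle.include_hidden
                                  and self.oracle.name == "pseudo_rocs") else {}))

    def component_specs(self) -> list[ScoreComponentSpec]:
        if self.components is not None:
            return [c.to_spec() for c in self.components]
        return default_components(self.oracle.name)

    def acquisition_spec(self) -> AcquisitionSpec:
        direction = "minimize" if self.oracle.name == "pseudo_dock" else "maximize"
        return AcquisitionSpec(strategy=self.acquisition.strategy,
                               beta=self.acquisition.beta, direction=direction)

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return cls.model_validate(json.loads(path.read_text()))

    def with_overrides(self, overrides: dict[str, object]) -> "RunConfig":
        """Apply dotted-path overrides, e.g. {"surrogate.n_trees": 100}."""
        data = self.model_dump()
        for key, value in overrides.items():
            node = data
            parts = key.split(".")
            for p in parts[:-1]:
                if p not in node:
                    raise KeyError(f"unknown config key {key!r}")
                node = node[p]
            if parts[-1] not in node:
                raise KeyError(f"unknown config key {key!r}")
            node[parts[-1]] = value
        return RunConfig.model_validate(data)


def default_components(oracle_name: str) -> list[ScoreComponentSpec]:
    """The standard five-component MPO panel.

    QED (untransformed), molecular weight (double sigmoid 200/550, divisor
    550, steepness 20), HBD count (reverse sigmoid 2/6, k=0.5), custom
    structural alerts (multiplicative penalty), and the oracle score mapped
    through its printed sigmoid.
    """
    oracle_tf = docking_transform() if oracle_name == "pseudo_dock" else rocs_transform()
    return [
        ScoreComponentSpec(name="qed", evaluator="qed",
                           transform=TransformSpec(kind="identity")),
        ScoreComponentSpec(name="mol_weight", evaluator="mol_weight",
                           transform=TransformSpec(kind="double_sigmoid",
                                                   low=200.0, high=550.0,
                                                   coef_div=550.0, coef_steep=20.0)),
        ScoreComponentSpec(name="hbd", evaluator="hbd_count",
                           transform=TransformSpec(kind="reverse_sigmoid",
                                                   low=2.0, high=6.0, k=0.5)),
        ScoreComponentSpec(name="custom_alerts", evaluator="custom_alerts",
                           is_penalty=True),
        ScoreComponentSpec(name="oracle", evaluator="oracle", transform=oracle_tf),
    ]
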