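"""Run configuration.

A single validated, serialisable object drives the whole pipeline; every
stage reads only from it.  Unknown keys are rejected so a typo in a YAML
file fails loudly instead of silently falling back to a default.
"""

from __future__ import annotations

import hashlib
import zlib

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "CohortConfig", "SustainConfig", "AssociationConfig",
           "substream_seed"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PlantedEdgeConfig(_Strict):
    i: int
    j: int
    rho: float
    subtype: int = 0


class CohortConfig(_Strict):
    n_controls: int = 224
    n_patients: int = 85
    n_subtypes: int = 2
    fractions: list[float] | None = None
    volume_noise_sd: float = 0.25       # z-units on top of the planted trajectory
    n_regions: int = 96                 # connectivity atlas size
    edge_noise_sd: float = 0.15         # Fisher-z units
    opposed_sequences: bool = False     # plant maximally separated subtype orderings
    planted_edges: list[PlantedEdgeConfig] = Field(default_factory=list)
    clinical_slopes: dict[str, list[float]] | None = None
    score_noise_sd: float = 2.0
    split_bilateral: bool = True
    asymmetry_sd: float = 50.0          # mm^3 hemispheric offset on bilateral markers


class SustainConfig(_Strict):
    z_thresholds: list[float] = Field(default_factory=lambda: [1.0, 2.0, 3.0])
    max_subtypes: int = 2
    n_restarts: int = 25
    em_iters: int = 30
    split_restarts: int | None = None
    sigma: float = 1.0
    z_max: float = 5.0
    bic_param_count: str = "events+fractions"

    @model_validator(mode="after")
    def _check(self):
        if sorted(self.z_thresholds) != self.z_thresholds or \
                len(set(self.z_thresholds)) != len(self.z_thresholds):
            raise ValueError("z_thresholds must be strictly increasing")
        if self.z_max <= max(self.z_thresholds):
            raise ValueError("z_max must exceed the top threshold")
        return self


class AssociationConfig(_Strict):
    n_permutations: int = 20_000
    volume_covariates: list[str] = Field(
        default_factory=lambda: ["age", "sex", "handedness", "tiv"])
    edge_covariates: list[str] = Field(
        default_factory=lambda: ["age", "sex", "handedness", "scanner"])
    alpha: float = 0.05
    fdr_q: float = 0.05
    min_subtype_n: int = 10


class RunConfig(_Strict):
    seed: int = 0
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    sustain: SustainConfig = Field(default_factory=SustainConfig)
    association: AssociationConfig = Field(default_factory=AssociationConfig)
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    def digest(self) -> str:
        # output_dir is not a scientific parameter; two runs of the same
        # analysis into different directories share a digest
        blob = yaml.safe_dump(self.model_dump(exclude={"output_dir"}),
                              sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic named sub-seed of a root seed (stable across runs)."""
    import numpy as np

    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))
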