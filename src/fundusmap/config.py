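"""Run configuration: the end-to-end pipeline's documented parameter set.

A configuration is a flat YAML (or JSON) mapping; unknown keys are errors.
Every field has a default, and the config used for a run is serialized next
to its outputs so any run can be reproduced from the output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from fundusmap.linkage import MODELS, PedigreeConfig
from fundusmap.phenotype import PhenotypeModel


@dataclass
class RunConfig:
    """All tunables of one simulate -> score -> map -> call run."""

    # pedigree
    n_sites: int = 60
    n_g2_dams: int = 5
    n_g3_per_dam: int = 8
    effect_class_probs: tuple[float, float, float, float] = (0.10, 0.25, 0.25, 0.40)
    min_var_carriers: int = 2
    # phenotype model
    baseline_mean: float = 1.0
    effect_size: float = 40.0
    inheritance: str = "recessive"
    age_slope: float = 0.0
    dispersion: float = 10.0
    causal: bool = True
    # scoring
    quadrant_involvement_threshold: int = 3
    # mapping
    models: tuple[str, ...] = MODELS
    alpha: float = 0.05
    bonferroni_count_models: bool = True
    dichotomize_cut: int = 6
    # bookkeeping
    seed: int = 0
    out_dir: str = "fundusmap_run"

    def pedigree_config(self) -> PedigreeConfig:
        return PedigreeConfig(
            n_sites=self.n_sites,
            n_g2_dams=self.n_g2_dams,
            n_g3_per_dam=self.n_g3_per_dam,
            effect_class_probs=tuple(self.effect_class_probs),
            min_var_carriers=self.min_var_carriers if self.causal else 0,
        )

    def phenotype_model(self) -> PhenotypeModel:
        return PhenotypeModel(
            baseline_mean=self.baseline_mean,
            effect_size=self.effect_size if self.causal else 0.0,
            inheritance=self.inheritance,
            age_slope=self.age_slope,
            dispersion=self.dispersion,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_class_probs"] = list(self.effect_class_probs)
        d["models"] = list(self.models)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "effect_class_probs" in data:
            data["effect_class_probs"] = tuple(data["effect_class_probs"])
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
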