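"""Pipeline configuration: one dataclass, YAML round-trip, stable hash."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import yaml

from .errors import ValidationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All knobs of the fingerprint pipeline, with survey-scale defaults."""

    ranks: tuple = ("order", "family", "genus")
    q_values: tuple = (0.5, 2.0)
    anova_replicates: int = 5000
    permutations: int = 2000
    subsample_size: int = 18
    fdr: float = 0.01
    tukey_alpha: float = 0.01
    rf_trees: int = 1000
    rf_vars_per_split: int = 10
    ensemble_folds: int = 2
    ensemble_iterations: int = 100
    ensemble_components: tuple = (
        "lda", "knn", "cart", "svm_linear", "rf", "plr",
    )
    network_target_nodes: int = 10
    network_tolerance: int = 1
    min_sample_total: int = 1           # per-sample QC: minimum total count
    normalize_per_city: bool = True
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for name in ("anova_replicates", "permutations", "subsample_size",
                     "rf_trees", "rf_vars_per_split", "ensemble_folds",
                     "ensemble_iterations", "network_target_nodes"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        for name in ("fdr", "tukey_alpha"):
            v = float(getattr(self, name))
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        for q in self.q_values:
            if q <= 0 or q == 1:
                raise ValidationError("q values must be positive and != 1")
        if self.network_tolerance < 0:
            raise ValidationError("network_tolerance must be >= 0")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ranks"] = list(self.ranks)
        d["q_values"] = list(self.q_values)
        d["ensemble_components"] = list(self.ensemble_components)
        return d

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        kwargs = dict(payload)
        for key in ("ranks", "q_values", "ensemble_components"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
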