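"""Pipeline configuration: one YAML file covering every stage.

Defaults are the published analysis settings (QC thresholds, the rare-damaging
filter cutoffs, the two-variant gene-inclusion rule and q < 0.20 significance).
Any override is echoed into each output's provenance header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .damaging import FilterThresholds
from .qc import QCThresholds


@dataclass(frozen=True)
class BurdenSettings:
    min_variants: int = 2
    q_threshold: float = 0.20
    subgroup_sidedness: str = "two"


@dataclass(frozen=True)
class PCASettings:
    k: int = 2
    maf_min: float = 0.05
    n_permutations: int = 999


@dataclass(frozen=True)
class PermanovaSettings:
    n_permutations: int = 9999
    distance: str = "euclidean"


@dataclass(frozen=True)
class NetworkSettings:
    threshold: float = 0.8
    signed: bool = True
    inflation: float = 2.0
    heart_fold: float = 2.0


@dataclass(frozen=True)
class PipelineConfig:
    vcf: str | None = None
    annotations: str | None = None
    phenotypes: str | None = None
    expression_panel: str | None = None
    expression_matrix: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    filter: FilterThresholds = field(default_factory=FilterThresholds)
    burden: BurdenSettings = field(default_factory=BurdenSettings)
    pca: PCASettings = field(default_factory=PCASettings)
    permanova: PermanovaSettings = field(default_factory=PermanovaSettings)
    network: NetworkSettings = field(default_factory=NetworkSettings)
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self, stage: str) -> dict[str, object]:
        return {"stage": stage, "config_hash": self.config_hash(), "seed": self.seed}


_SECTIONS = {
    "qc": QCThresholds,
    "filter": FilterThresholds,
    "burden": BurdenSettings,
    "pca": PCASettings,
    "permanova": PermanovaSettings,
    "network": NetworkSettings,
}


def load_config(path: str | Path | None = None, **overrides: object) -> PipelineConfig:
    """Build a config from YAML (optional) plus keyword overrides.

    Unknown keys raise with the offending key named.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides)

    cfg = PipelineConfig()
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            valid = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
            bad = set(value) - valid
            if bad:
                raise ValueError(f"unknown key(s) in config section {key!r}: {sorted(bad)}")
            kwargs[key] = cls(**value)
        elif key in PipelineConfig.__dataclass_fields__:
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config key: {key!r}")
    return replace(cfg, **kwargs)
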