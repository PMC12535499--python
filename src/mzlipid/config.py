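"""Run configuration: one YAML/JSON file drives a reproducible run.

Every default is documented in the generated template (``mzlipid init``).
The configuration hash recorded in run manifests is the SHA-256 of the
canonical JSON dump of the fully-resolved configuration, so two runs with
byte-different files but identical resolved settings share a hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .gradient import GradientProgram

__all__ = ["RunConfig", "ConfigError", "load_config", "template_yaml"]


class ConfigError(ValueError):
    """The configuration is structurally invalid or references missing inputs."""


@dataclass
class RunConfig:
    seed: int = 0
    # paths
    discovery: Optional[str] = None
    validation: Optional[str] = None
    taxonomy: Optional[str] = None
    output_dir: str = "mzlipid_out"
    # gradient program
    a_start: float = 20.0
    a_end: float = 80.0
    ramp_minutes: float = 13.0
    t_delay: float = 0.0
    # curation
    rt_low: float = 1.0
    rt_high: float = 14.0
    preferred_polarity: str = "negative"
    lipid_class: str = "Lipids and lipid-like molecules"
    # learning
    test_fraction: float = 0.25
    n_folds: int = 10
    k_neighbors: int = 5
    reduce_threshold: float = 0.9
    families: Optional[list[str]] = None
    conditions: Optional[list[str]] = None
    grids: dict = field(default_factory=dict)
    # evaluation
    top_k: int = 4
    report_precision: int = 3

    def program(self) -> GradientProgram:
        return GradientProgram(
            a_start=self.a_start,
            a_end=self.a_end,
            ramp_minutes=self.ramp_minutes,
            t_delay=self.t_delay,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    def validate_paths(self, require_discovery: bool = True) -> None:
        if require_discovery:
            if not self.discovery:
                raise ConfigError("config must set 'discovery' (feature table path)")
            if not self.taxonomy:
                raise ConfigError("config must set 'taxonomy' (taxonomy table path)")
        for label, p in (
            ("discovery", self.discovery),
            ("validation", self.validation),
            ("taxonomy", self.taxonomy),
        ):
            if p and not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")


_SECTION_KEYS = {
    "paths": {"discovery", "validation", "taxonomy", "output_dir"},
    "gradient": {"a_start", "a_end", "ramp_minutes", "t_delay"},
    "curation": {"rt_low", "rt_high", "preferred_polarity", "lipid_class"},
    "learning": {
        "test_fraction",
        "n_folds",
        "k_neighbors",
        "reduce_threshold",
        "families",
        "conditions",
        "grids",
    },
    "evaluation": {"top_k", "report_precision"},
}


def load_config(path) -> RunConfig:
    """Load a sectioned YAML/JSON config file into a flat RunConfig."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    flat: dict = {}
    for key, value in raw.items():
        if key in _SECTION_KEYS:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            unknown = set(value) - _SECTION_KEYS[key]
            if unknown:
                raise ConfigError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            flat.update(value)
        elif key == "seed":
            flat["seed"] = value
        else:
            raise ConfigError(f"unknown top-level config key {key!r}")
    try:
        return RunConfig(**flat)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def template_yaml() -> str:
    """The annotated config template written by ``mzlipid init``."""
    return """\
# mzlipid run configuration (all values shown are the defaults)
seed: 0

paths:
  discovery: discovery_features.tsv   # required by `run`
  validation: null                    # optional second table, same dialect
  taxonomy: taxonomy.tsv              # hmdb_id -> super_class extract
  output_dir: mzlipid_out

gradient:                             # single linear ramp, %A over time
  a_start: 20.0
  a_end: 80.0
  ramp_minutes: 13.0
  t_delay: 0.0                        # dead-volume delay, minutes

curation:
  rt_low: 1.0                         # RT <= rt_low excluded
  rt_high: 14.0                       # RT >= rt_high excluded
  preferred_polarity: negative        # kept side of dual-polarity IDs
  lipid_class: Lipids and lipid-like molecules

learning:
  test_fraction: 0.25                 # stratified hold-out share
  n_folds: 10                         # stratified CV folds
  k_neighbors: 5                      # balancing: nearest-neighbor count
  reduce_threshold: 0.9               # |r| at which a predictor is dropped
  families: null                      # null = all 10 model families
  conditions: null                    # null = canonical 12 conditions
  grids: {}                           # per-family hyperparameter overrides

evaluation:
  top_k: 4                            # models carried to validation
  report_precision: 3                 # decimals in written tables
"""
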