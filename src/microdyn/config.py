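"""Run configuration: defaults, YAML/JSON loading, validation.

Every analysis threshold defaults to the method's canonical value:
prevalence filter at 20 samples, clipping at 5 robust SDs, central 90%
standardization window, 5 candidate PCs at 5% explained variance, alpha
0.05, 20K comparable positions at depth >= 3 with a 1/20K dissimilarity
floor and a lower-5% replacement quantile, 500 bootstrap resamples with
seed 42 for mediation, and a 0.05 training-R^2 stratification threshold.

Cohort/panel/pileup sizes default to a desk-scale synthetic study so a full
pipeline run completes in well under a minute on one CPU; the generator
specs themselves (see :mod:`microdyn.synthetic`) default to the full panel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

from .exceptions import ConfigError


@dataclass
class RunConfig:
    # reproducibility: every stage's RNG derives from this one seed
    seed: int = 0

    # synthetic-study scale (desk scale; see module docstring)
    n_per_arm: int = 25
    n_days: int = 28

    # panel overrides passed to PanelSpec (desk-scale defaults)
    panel: dict = field(default_factory=lambda: {
        "n_gut_species": 60, "n_oral_species": 34, "n_gut_pathways": 38,
        "n_oral_pathways": 31, "n_metabolites": 110, "n_cytokines": 8,
    })
    effect: dict = field(default_factory=dict)
    pileups: dict = field(default_factory=lambda: {
        "n_species": 4, "n_positions": 22_000, "depth_mean": 12.0,
    })

    # preprocessing thresholds
    min_samples: int = 20
    clip_k: float = 5.0
    central_fraction: float = 0.90
    pc_count: int = 5
    pc_var: float = 0.05

    # testing
    alpha: float = 0.05
    method: str = "bonferroni"
    min_unique: int = 20

    # strain analysis
    min_positions: int = 20_000
    min_depth: int = 3
    clip: float = 1.0 / 20_000
    presence_fraction: float = 0.10
    q: float = 0.05
    min_inter_pairs: int = 10
    top_k: int = 10
    min_participants: int = 50

    # mediation
    n_boot: int = 500
    mediation_seed: int = 42

    # delta evaluation
    r2_threshold: float = 0.05

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON) config; unspecified fields take the defaults.

    Unknown keys raise :class:`ConfigError` listing the valid keys; parse
    errors propagate with the parser's location information attached.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    base = RunConfig()
    for key, value in data.items():
        default = getattr(base, key)
        if isinstance(default, dict) and isinstance(value, dict):
            merged = dict(default)
            merged.update(value)
            value = merged
        setattr(base, key, value)
    return base


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=1)
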