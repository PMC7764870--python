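"""Run configuration: one structured YAML file drives a whole analysis run.

Every threshold the analysis depends on (peak prominence, squeeze-out,
stationarity, kinetics tolerance) is explicit here and echoed into the run
manifest, so a report is always auditable against the settings that produced
it.  CLI flags override config values; defaults are filled on load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    """Inputs plus every tunable of a pipeline run.

    ``relaxation_inputs`` is a list of {path, strain, pi0?} mappings;
    ``isotherm_pairs`` a list of {ref, test} path pairs; ``kinetics_inputs``
    a list of {path, pi0?} mappings.
    """

    relaxation_inputs: list = field(default_factory=list)
    isotherm_pairs: list = field(default_factory=list)
    kinetics_inputs: list = field(default_factory=list)
    # parsing
    sep: str = ","
    decimal: str = "."
    # analysis
    strain: float = 0.05
    fmin: float = 1e-4
    fmax: float = 1.0
    n_components: object = "auto"
    peak_prominence: float = 0.05
    squeeze_out_threshold: float = 0.5
    stationarity_tol: float | None = None
    kinetics_tol: float = 0.5
    classification_band: tuple = (1e-4, 1e-3)
    seed: int = 0
    out_dir: str = "filmrheo_out"

    def validate(self) -> "RunConfig":
        for name in ("peak_prominence", "squeeze_out_threshold", "kinetics_tol"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.stationarity_tol is not None and self.stationarity_tol <= 0:
            raise ConfigError("stationarity_tol must be positive")
        if not (0 < self.fmin < self.fmax):
            raise ConfigError("need 0 < fmin < fmax")
        if not (0 < self.strain <= 0.2):
            raise ConfigError("strain must lie in (0, 0.2]")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classification_band"] = list(self.classification_band)
        return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "classification_band" in raw:
        raw["classification_band"] = tuple(raw["classification_band"])
    return RunConfig(**raw).validate()


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, for output tagging."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
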