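"""Run configuration: YAML round-trip of model parameters and stage settings.

The shipped default configuration equals the package's reference parameter
set (see :class:`mtxhcy.population.PKParameters` /
:class:`~mtxhcy.population.PDParameters`); unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .population import PDParameters, PKParameters, params_from_dict, params_to_dict

__all__ = ["RunConfig", "load_config", "save_config", "default_config"]

_KNOWN_KEYS = {"seed", "n_subjects", "n_patients", "n_sim", "n_bootstrap",
               "horizon", "grid_step", "maxfev", "pk", "pd"}


@dataclass
class RunConfig:
    """Seed plus stage parameters and model-parameter overrides."""

    seed: int
    n_subjects: int = 150
    n_patients: int = 1000
    n_sim: int = 1000
    n_bootstrap: int = 200
    horizon: float = 168.0
    grid_step: float = 0.1
    maxfev: int = 4000
    pk: PKParameters = field(default_factory=PKParameters)
    pd: PDParameters = field(default_factory=PDParameters)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pk"] = params_to_dict(self.pk)
        d["pd"] = params_to_dict(self.pd)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def default_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raise ValueError(f"empty config file {path}")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    pk = params_from_dict(PKParameters, raw.pop("pk", {}))
    pdp = params_from_dict(PDParameters, raw.pop("pd", {}))
    return RunConfig(pk=pk, pd=pdp, **raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
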