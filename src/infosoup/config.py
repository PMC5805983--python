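"""Run configuration, validation, serialization and manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

import yaml

__all__ = [
    "SimConfig",
    "ConfigError",
    "RESTRICTED_INFLUX_SET",
    "load_config",
    "save_config",
    "config_hash",
    "RunManifest",
]

#: the type-restricted influx subset used for the Phi' protocol: the types
#: most frequently depleted from (or extinct in) zero-influx niches.
RESTRICTED_INFLUX_SET: Tuple[int, ...] = (6, 7, 9, 11, 13, 14)


class ConfigError(ValueError):
    """A configuration field is out of range or unknown."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one lattice simulation.

    Parameters
    ----------
    n : lattice side; the population size is N = n^2 (default 300, N = 90 000).
    c : mixing swap events per production step (0 <= c <= N).
    v : variance of the zero-mean Gaussian displacement of a swap (0 <= v <= n).
    phi : per-step probability that the chosen occupant is replaced by an
        influx draw instead of a composition product (0 <= phi <= 1).
    influx_set : type ids drawn from on influx (uniformly); all 15 by
        default, or a restricted subset for the Phi' protocol.
    iterations : production time-step budget.
    seed : RNG seed; (config, seed) fully determines every output.
    record_every : sampling stride of the frequency series.
    """

    n: int = 300
    c: int = 0
    v: float = 0.0
    phi: float = 0.0
    influx_set: Tuple[int, ...] = tuple(range(1, 16))
    iterations: int = 1_000_000
    seed: int = 0
    record_every: int = 1000

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ConfigError(f"n: lattice side must be >= 4, got {self.n}")
        if not 0 <= self.c <= self.n * self.n:
            raise ConfigError(f"c: must satisfy 0 <= c <= N = n^2, got {self.c}")
        if not 0 <= self.v <= self.n:
            raise ConfigError(f"v: must satisfy 0 <= v <= n, got {self.v}")
        if not 0.0 <= self.phi <= 1.0:
            raise ConfigError(f"phi: must be in [0, 1], got {self.phi}")
        ids = tuple(int(t) for t in self.influx_set)
        if self.phi > 0 and not ids:
            raise ConfigError("influx_set: must be non-empty when phi > 0")
        if any(not 1 <= t <= 15 for t in ids):
            raise ConfigError(f"influx_set: type ids must be in 1..15, got {ids}")
        object.__setattr__(self, "influx_set", ids)
        if self.iterations < 0:
            raise ConfigError(f"iterations: must be >= 0, got {self.iterations}")
        if self.record_every < 1:
            raise ConfigError(f"record_every: must be >= 1, got {self.record_every}")

    @property
    def population(self) -> int:
        return self.n * self.n

    def replace(self, **overrides: Any) -> "SimConfig":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        d["influx_set"] = list(d["influx_set"])
        return d


#: a perturbation schedule: list of (step, field overrides) applied in order
Schedule = List[Tuple[int, Dict[str, Any]]]

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def _build_config(data: Dict[str, Any]) -> Tuple[SimConfig, Schedule]:
    unknown = set(data) - _CONFIG_FIELDS - {"schedule"}
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    raw_schedule = data.pop("schedule", [])
    schedule: Schedule = []
    for entry in raw_schedule:
        step = int(entry["step"])
        overrides = {k: v for k, v in entry.items() if k != "step"}
        bad = set(overrides) - _CONFIG_FIELDS
        if bad:
            raise ConfigError(f"unknown schedule override keys: {sorted(bad)}")
        schedule.append((step, overrides))
    if "influx_set" in data:
        data["influx_set"] = tuple(data["influx_set"])
    return SimConfig(**data), sorted(schedule, key=lambda e: e[0])


def load_config(path) -> Tuple[SimConfig, Schedule]:
    """Read a YAML/JSON run configuration; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"configuration file {path} must hold a mapping")
    return _build_config(dict(data))


def save_config(config: SimConfig, path, schedule: Optional[Schedule] = None) -> None:
    data = config.to_dict()
    if schedule:
        data["schedule"] = [{"step": s, **o} for s, o in schedule]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(config: SimConfig, schedule: Optional[Schedule] = None) -> str:
    payload = {"config": config.to_dict(), "schedule": schedule or []}
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record written next to every output set."""

    config: Dict[str, Any]
    schedule: List[Dict[str, Any]]
    seed: int
    config_hash: str
    version: str
    start_step: int
    end_step: int
    outputs: List[str] = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
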