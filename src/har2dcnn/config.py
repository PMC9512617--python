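"""Structured run configuration with a YAML round trip.

A :class:`RunConfig` fixes every knob of a run — simulator, windowing,
position subset, model variant and training — plus the master seed, so that
any artifact on disk is reproducible from the resolved config written next
to it.  ``load(dump(cfg)) == cfg`` is an identity, property-tested.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from .errors import ParameterError


@dataclass
class SimulatorConfig:
    n_positions: int = 4
    n_classes: int = 5
    n_scalar: int = 0
    total_length: int = 24012


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 40
    batch_size: int = 32
    threshold: float = 0.0


@dataclass
class RunConfig:
    seed: int = 0
    window: int = 24
    overlap: float = 0.5
    variant: str = "ts2dcnn"
    maps: int = 8
    train_fraction: float = 0.7
    positions_subset: list[str] = field(default_factory=list)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    training: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "simulator" in d:
            d["simulator"] = SimulatorConfig(**d["simulator"])
        if "training" in d:
            d["training"] = TrainConfig(**d["training"])
        return cls(**d)

    def dump(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def load(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path) -> None:
        with open(path, "w") as f:
            f.write(self.dump())

    @classmethod
    def read(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.load(f.read())

    @property
    def config_hash(self) -> str:
        """Stable short hash of the resolved configuration, for provenance
        logging."""
        return hashlib.sha256(self.dump().encode()).hexdigest()[:12]
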