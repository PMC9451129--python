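"""Experiment configuration: one serializable object for the whole pipeline.

Every output file carries ``ExperimentConfig.digest()`` so results can
be traced to the exact configuration (including the master seed) that
produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .cohort import DEFAULT_STATION_BIASES, CohortConfig, StationSpec, default_stations
from .feedback import TimingConfig


@dataclass(frozen=True)
class AgentConfig:
    """Population distribution of agent parameters.

    Per-participant decodability (snr) and compliance (learning rate)
    are drawn uniformly from these ranges, emulating the wide
    inter-participant variation in decoding accuracy seen in practice.
    """

    snr_range: tuple[float, float] = (0.2, 2.0)
    learning_rate_range: tuple[float, float] = (0.05, 0.4)
    probe_temperature: float = 0.5
    initial_theta: float = 0.0


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to run the simulated experiment end to end."""

    seed: int = 0
    n_features: int = 100
    separation: float = 2.0
    station_biases: tuple[float, ...] = DEFAULT_STATION_BIASES
    training: CohortConfig = field(
        default_factory=lambda: CohortConfig(n_participants=20, n_runs=2)
    )
    pilot: CohortConfig = field(
        default_factory=lambda: CohortConfig(n_participants=10, n_runs=4)
    )
    n_participants: int = 20
    n_runs: int = 4
    agent: AgentConfig = field(default_factory=AgentConfig)
    timing: TimingConfig = field(default_factory=TimingConfig)
    regularization_c: float = 1.0
    reward_cap: float = 20.0
    sd_mode: str = "population"
    mode: str = "live"

    def __post_init__(self) -> None:
        if self.mode not in ("live", "yoked"):
            raise ValueError("mode must be 'live' or 'yoked'")
        if len(self.station_biases) != 7:
            raise ValueError("station_biases must have 7 entries")

    def stations(self) -> list[StationSpec]:
        return default_stations(tuple(self.station_biases))

    def training_cohort(self) -> CohortConfig:
        """Training cohort with feature dimension and seed tied to this config."""
        return replace(
            self.training, n_features=self.n_features, seed=(self.seed * 3 + 1) % 2**31
        )

    def pilot_cohort(self) -> CohortConfig:
        """Pilot cohort with feature dimension and seed tied to this config."""
        return replace(
            self.pilot, n_features=self.n_features, seed=(self.seed * 3 + 2) % 2**31
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["station_biases"] = list(self.station_biases)
        d["agent"]["snr_range"] = list(self.agent.snr_range)
        d["agent"]["learning_rate_range"] = list(self.agent.learning_rate_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "training" in d:
            t = dict(d["training"])
            if t.get("group_assignment"):
                t["group_assignment"] = tuple(t["group_assignment"])
            d["training"] = CohortConfig(**t)
        if "pilot" in d:
            p = dict(d["pilot"])
            if p.get("group_assignment"):
                p["group_assignment"] = tuple(p["group_assignment"])
            d["pilot"] = CohortConfig(**p)
        if "agent" in d:
            a = dict(d["agent"])
            for k in ("snr_range", "learning_rate_range"):
                if k in a:
                    a[k] = tuple(a[k])
            d["agent"] = AgentConfig(**a)
        if "timing" in d:
            d["timing"] = TimingConfig(**d["timing"])
        if "station_biases" in d:
            d["station_biases"] = tuple(d["station_biases"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def digest(self) -> str:
        """Short provenance hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(self, seed=seed)
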