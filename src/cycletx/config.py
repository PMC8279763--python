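"""Run configuration: one flat document describing a whole simulation.

A config can come from a YAML/JSON file or be assembled from CLI flags
(flags override file values). Exactly one of ``divisions`` / ``total_time``
must be set, and a seed is mandatory for any stochastic run so every result
is replayable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from .genome import Genome, TranscriptionParams, make_uniform_genome
from .lineage import SCENARIOS, CycleRule

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    # genome: either explicit lengths or a uniform range recipe
    genome_lengths: list[float] | None = None
    genome_count: int | None = None
    genome_min_len: float | None = None
    genome_max_len: float | None = None
    ploidy: int = 1

    # transcription
    rate: float = 1.0
    reinit_spacing: float = 0.25
    serial_mode: bool = False
    parental_retention: float = 0.0

    # cycle rule
    rule_kind: str = "inherit"
    delta_mean: float = 0.1
    sigma: float = 0.06
    gamma_min: float | None = None

    # run shape
    gamma: float | None = None          # founder cycle duration (hr)
    gamma1: float | None = None         # scenario founders
    gamma2: float | None = None
    scenario: str | None = None
    founders: int = 1
    divisions: int | None = None
    total_time: float | None = None
    iterations: int = 1
    seed: int | None = None
    out_dir: str = "out"

    def __post_init__(self) -> None:
        if (self.divisions is None) == (self.total_time is None):
            raise ValueError("exactly one of divisions / total_time must be set")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.genome_lengths is None and self.genome_count is None:
            raise ValueError("genome_lengths or genome_count/min/max must be given")

    # -- object builders -----------------------------------------------------
    def build_genome(self) -> Genome:
        if self.genome_lengths is not None:
            return Genome.from_lengths(self.genome_lengths, ploidy=self.ploidy)
        return make_uniform_genome(
            self.genome_count, self.genome_min_len, self.genome_max_len, self.ploidy
        )

    def build_params(self) -> TranscriptionParams:
        return TranscriptionParams(
            rate=self.rate,
            reinit_spacing=self.reinit_spacing,
            serial_mode=self.serial_mode,
            parental_retention=self.parental_retention,
        )

    def build_rule(self) -> CycleRule:
        kwargs: dict[str, Any] = {
            "kind": self.rule_kind,
            "delta_mean": self.delta_mean,
            "sigma": self.sigma,
            "gamma_min": self.gamma_min,
        }
        if self.rule_kind == "asymmetric":
            kwargs["fast_gamma"] = self.gamma1
            kwargs["slow_gamma"] = self.gamma2
        return CycleRule(**kwargs)

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load from a YAML (or JSON — a YAML subset) file; kwargs override."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)
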