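"""Run configuration: declarative YAML with CLI overrides.

Thresholds default to the analysis constants used throughout: coverage
gate 10 reads at >= 2 CpG sites, 40-220 bp fragment size range, alpha
0.05 with Bonferroni correction, 25% methylation difference, 500 bp
probe-matching window, 2 kb CpG island shores, promoter -2000..+500
around the TSS.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class Thresholds:
    cov_min: int = 10
    min_cpgs: int = 2
    size_min: int = 40
    size_max: int = 220
    alpha: float = 0.05
    delta_min: float = 0.25
    window: int = 500
    shore_width: int = 2000
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    gene_distance_cap: int = 50_000

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigError(f"threshold {f.name} must be positive")
        if self.size_min > self.size_max:
            raise ConfigError("size_min must be <= size_max")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    seed: int = 0
    output_dir: str = "epidriver_run"
    genome_fasta: str | None = None
    sample_sheet: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    tracks: dict = field(default_factory=dict)  # genes / cgi / repeats / features
    cohort: dict = field(default_factory=dict)  # probes / betas / groups
    simulate: dict | None = None  # simulator parameters, see simulate module

    def __post_init__(self) -> None:
        if self.simulate is None and (
            self.genome_fasta is None or self.sample_sheet is None
        ):
            raise ConfigError(
                "config needs either a simulate section or both "
                "genome_fasta and sample_sheet"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        thr = raw.pop("thresholds", {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(thresholds=Thresholds(**thr), **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        """Hash over thresholds, parameters and referenced file contents."""
        payload = self.to_dict()
        digest = hashlib.sha256()
        digest.update(json.dumps(payload, sort_keys=True).encode())
        for p in self._referenced_paths():
            if Path(p).exists():
                digest.update(Path(p).read_bytes())
        return digest.hexdigest()[:16]

    def _referenced_paths(self) -> list[str]:
        paths = [p for p in (self.genome_fasta, self.sample_sheet) if p]
        paths += [v for v in self.tracks.values() if isinstance(v, str)]
        paths += [v for v in self.cohort.values() if isinstance(v, str)]
        return sorted(paths)
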