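"""Run configuration: schema, defaults, validation, YAML/JSON round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .harmonics import FREQUENCY_MODES
from .dissimilarity import GEO_MODES, MEASURE_COLUMNS
from .synthetic import SyntheticConfig
from .transfer import RFConfig

__all__ = [
    "HarmonicConfig",
    "DissimilarityConfig",
    "TransferConfig",
    "RunConfig",
    "load_config",
    "dump_config",
]


def _from_dict(cls, data: dict, section: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config section {section!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}"
        )
    return cls(**data)


@dataclass
class HarmonicConfig:
    J: int = 2
    frequency_mode: str = "per-year-multiples"
    phase_average: str = "arithmetic"

    def validate(self) -> None:
        if self.J < 1:
            raise ValueError("harmonic.J must be >= 1")
        if self.frequency_mode not in FREQUENCY_MODES:
            raise ValueError(f"harmonic.frequency_mode must be one of {FREQUENCY_MODES}")
        if self.phase_average not in ("arithmetic", "circular"):
            raise ValueError("harmonic.phase_average must be arithmetic or circular")


@dataclass
class DissimilarityConfig:
    min_plots: int = 100
    geo_mode: str = "equirectangular"
    zscore_mode: str = "pooled-plots"
    amplitude_scaling: str = "per-variable"

    def validate(self) -> None:
        if self.min_plots < 1:
            raise ValueError("dissimilarity.min_plots must be >= 1")
        if self.geo_mode not in GEO_MODES:
            raise ValueError(f"dissimilarity.geo_mode must be one of {GEO_MODES}")
        if self.zscore_mode not in ("pooled-plots", "centroids"):
            raise ValueError(
                "dissimilarity.zscore_mode must be pooled-plots or centroids"
            )
        if self.amplitude_scaling not in ("per-variable", "per-variable-harmonic"):
            raise ValueError(
                "dissimilarity.amplitude_scaling must be per-variable or "
                "per-variable-harmonic"
            )


@dataclass
class TransferConfig:
    rf: RFConfig = field(default_factory=RFConfig)
    indicators: list[str] = field(default_factory=lambda: ["TFC"])
    measures: list[str] = field(
        default_factory=lambda: ["geoDist", "ecoDisIS", "ecoDisRS"]
    )

    def validate(self) -> None:
        if not self.indicators:
            raise ValueError("transfer.indicators must not be empty")
        bad = [m for m in self.measures if m not in MEASURE_COLUMNS]
        if bad:
            raise ValueError(
                f"transfer.measures contains unknown measure(s) {bad}; "
                f"valid: {sorted(MEASURE_COLUMNS)}"
            )
        if self.rf.n_trees < 1:
            raise ValueError("transfer.rf.n_trees must be >= 1")


@dataclass
class RunConfig:
    """Full pipeline configuration with one master seed."""

    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    harmonic: HarmonicConfig = field(default_factory=HarmonicConfig)
    dissimilarity: DissimilarityConfig = field(default_factory=DissimilarityConfig)
    transfer: TransferConfig = field(default_factory=TransferConfig)

    def validate(self) -> None:
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        self.synthetic.seed = int(self.seed)
        self.synthetic.validate()
        self.harmonic.validate()
        self.dissimilarity.validate()
        self.transfer.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        transfer_data = dict(data.get("transfer") or {})
        rf_data = transfer_data.pop("rf", None)
        transfer = _from_dict(TransferConfig, transfer_data, "transfer")
        if rf_data is not None:
            transfer.rf = _from_dict(RFConfig, rf_data, "transfer.rf")
        cfg = cls(
            seed=data.get("seed", 0),
            synthetic=_from_dict(SyntheticConfig, data.get("synthetic"), "synthetic"),
            harmonic=_from_dict(HarmonicConfig, data.get("harmonic"), "harmonic"),
            dissimilarity=_from_dict(
                DissimilarityConfig, data.get("dissimilarity"), "dissimilarity"
            ),
            transfer=transfer,
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)  # JSON is a YAML subset
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> Path:
    """Write the effective configuration as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path
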