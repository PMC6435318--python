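"""Run configuration and reproducibility helpers."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import yaml

from .periphery import FilterbankConfig


def child_seed(global_seed: int, label: str) -> int:
    """Stable per-component seed derived from a single global seed.

    Uses a CRC of the label so that partial pipelines reproduce bit-for-bit
    regardless of which other components ran.  Result is < 2**31.
    """
    return (int(global_seed) * 2654435761 + zlib.crc32(label.encode())) % (2**31)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    species: tuple[str, ...] = ("human", "ferret")
    filterbank: FilterbankConfig = field(default_factory=FilterbankConfig)
    f0: float = 500.0
    band_lo: float = 1000.0
    band_hi: float = 10000.0
    level_db_spl: float = 70.0
    duration_s: float = 0.3
    window: tuple[float, float] = (0.05, 0.2)
    seed: int = 0
    log_level: str = "INFO"


def load_run_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; missing keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fb = FilterbankConfig(**raw.pop("filterbank", {}))
    if "species" in raw:
        raw["species"] = tuple(raw["species"])
    if "window" in raw:
        raw["window"] = tuple(raw["window"])
    return RunConfig(filterbank=fb, **raw)
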