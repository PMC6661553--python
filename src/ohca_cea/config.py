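"""Run configuration: a single source of truth for model defaults.

A run is described by a small flat YAML/JSON document.  Every key is optional;
the defaults are the model's reference settings (1000 PSA iterations, start
age 65, 3.5% annual discounting after post-discharge year 1, £20 000/QALY
willingness-to-pay, the built-in parameter registry and synthetic life table).
Unknown keys are rejected by name so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .life_tables import LifeTable, read_life_table, synthesize_life_table
from .parameters import ParameterSpec, default_specs, load_specs
from .pathway import CohortConfig

__all__ = ["ConfigError", "RunConfig", "load_config", "DEFAULT_SEED"]

DEFAULT_SEED = 2019


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings with defaults filled in."""

    n_iterations: int = 1000
    seed: int = DEFAULT_SEED
    start_age: int = 65
    discount_rate: float = 0.035
    max_age: int = 110
    wtp: float = 20_000.0
    #: Optional path to a YAML parameter registry replacing the built-in one.
    parameters: str | None = None
    #: Optional path to a CSV life table replacing the synthetic default.
    life_table: str | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ConfigError(f"discount_rate {self.discount_rate} outside [0, 1)")
        if not 0 <= self.start_age < self.max_age:
            raise ConfigError(
                f"start_age {self.start_age} must lie in [0, max_age={self.max_age})"
            )
        if self.wtp < 0:
            raise ConfigError(f"wtp must be non-negative, got {self.wtp}")
        for key in ("parameters", "life_table"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{key}: file not found: {path}")

    def cohort(self) -> CohortConfig:
        return CohortConfig(
            start_age=self.start_age,
            discount_rate=self.discount_rate,
            max_age=self.max_age,
            wtp_default=self.wtp,
        )

    def specs(self) -> list[ParameterSpec]:
        if self.parameters is not None:
            return load_specs(self.parameters)
        return default_specs()

    def table(self) -> LifeTable:
        if self.life_table is not None:
            return read_life_table(self.life_table)
        return synthesize_life_table(max_age=self.max_age)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file, applying defaults.

    ``overrides`` (e.g. a ``--seed`` given on the command line) take
    precedence over the file.  ``path=None`` or an empty file yields the
    defaults.  Unknown keys raise :class:`ConfigError` naming the key.
    """
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        doc = loaded
    doc.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(doc) - valid
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}"
        )
    try:
        return RunConfig(**doc)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a configuration, for output manifests."""
    import hashlib

    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
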