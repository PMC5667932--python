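"""Run configuration: validated defaults for every tunable of the pipeline."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .abn import DEFAULT_ENUMERATION_LIMIT
from .boolean import RULES

log = logging.getLogger("commitnet")


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run.

    ``alpha`` is the edge-call significance threshold; ``reference_scope``
    selects the discretisation averaging set (``sample`` = the table's own
    genes); ``rule_catalogue`` lists the regulation rules the solver may
    assign; ``enumeration_limit`` bounds explicit concrete-network search;
    ``noise_sd`` is a convention — the study does not report its
    measurement noise magnitude.
    """

    alpha: float = 0.05
    reference_scope: str = "sample"
    rule_catalogue: tuple[str, ...] = ("default",)
    enumeration_limit: int = DEFAULT_ENUMERATION_LIMIT
    seed: int = 0
    noise_sd: float = 0.2
    knockdown_efficiency: float = 0.2
    n_replicates: int = 3
    log_level: str = "INFO"
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.reference_scope not in ("sample", "external"):
            raise ConfigError("reference_scope must be 'sample' or 'external'")
        unknown = [r for r in self.rule_catalogue if r not in RULES]
        if unknown:
            raise ConfigError(f"unknown rules {unknown}; known: {sorted(RULES)}")
        if self.enumeration_limit < 1:
            raise ConfigError("enumeration_limit must be >= 1")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"unknown log level {self.log_level!r}")
        self.rule_catalogue = tuple(self.rule_catalogue)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        return cls(**data)

    def announce(self) -> None:
        """Log the fully resolved configuration (every run records its seed)."""
        logging.basicConfig(level=self.log_level.upper())
        log.info("resolved config: %s", asdict(self))
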