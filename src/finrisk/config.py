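"""Structured run configuration, loadable from YAML."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .catastrophic import CheThreshold

__all__ = ["RunConfig", "load_config", "parse_threshold"]


def parse_threshold(spec: str, inequality: str = "strict") -> CheThreshold:
    """Parse ``"0.10:total"`` / ``"0.40:nonfood"`` into a :class:`CheThreshold`."""
    try:
        z_str, kind = spec.split(":")
        z = float(z_str)
    except ValueError as exc:
        raise ValueError(f"bad threshold spec {spec!r}; expected 'Z:total|nonfood'") from exc
    denom = {"total": "total_expenditure", "nonfood": "nonfood_expenditure"}.get(kind)
    if denom is None:
        raise ValueError(f"bad threshold denominator {kind!r}; expected total|nonfood")
    return CheThreshold(z, denom, inequality)


class RunConfig(BaseModel):
    """Run-wide settings shared by the CLI subcommands."""

    currency: str = "USD"
    exchange_rate_etb_per_usd: float = Field(default=28.574, gt=0)
    che_thresholds: list[str] = Field(
        default_factory=lambda: ["0.10:total", "0.25:total", "0.40:nonfood"]
    )
    che_inequality: str = "strict"
    poverty_line_ppp_per_day: float = Field(default=1.90, gt=0)
    ppp_factor: float | None = None
    equivalence_exponent: float = 1.0
    seed: int = 0

    def thresholds(self) -> tuple[CheThreshold, ...]:
        return tuple(parse_threshold(s, self.che_inequality) for s in self.che_thresholds)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
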