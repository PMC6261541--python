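"""Pipeline configuration: defaults, YAML loading and validation.

Defaults reproduce the study settings: learning rate 0.1, sports PEs lagged
one day, sunshine PEs same-day, the 100-tweet / 80%-of-days county coverage
filter, the 15,000 adult-resident postal floor, and 10,000 mediation draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    data_dir: str = "data"
    alpha: float = 0.1
    sports_lag: int = 1
    sunshine_lag: int = 0
    min_tweets: int = 100
    min_frac: float = 0.80
    min_pop: int = 15_000
    log_eps: float = 1e-6
    n_sims: int = 10_000
    seed: int = 17
    reml: bool = True
    pooled_holidays: bool = False
    hurricane_window: list | None = None    # [start, end] ISO dates or null
    use_weather_flags: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")
        if self.n_sims < 1000:
            raise ValueError("n_sims must be at least 1000")
        if self.hurricane_window is not None and len(self.hurricane_window) != 2:
            raise ValueError("hurricane_window must be [start, end] or null")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys, then apply overrides."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
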