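"""Run configuration: defaults, YAML loading, and domain validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "validate_config", "load_config"]


@dataclass
class RunConfig:
    """Per-stage parameters with the pipeline's documented defaults."""

    seed: int = 0
    # LTR dating
    rate: float = 1.3e-8
    bin_mya: float = 0.25
    # 4DTv
    min_4d_sites: int = 10
    bin_4dtv: float = 0.02
    # centromere scan
    window: int = 300_000
    min_fraction: float = 0.05
    min_monomer_identity: float = 0.80
    period_min: int = 50
    period_max: int = 500
    # gene-family screen
    max_evalue: float = 1e-5
    min_identity: float = 50.0
    min_coverage: float = 50.0
    lea_max_evalue: float = 0.01
    max_gap_bp: int = 100_000
    max_intervening: int = 5
    # expression
    pseudocount: float = 1.0


def validate_config(cfg: Mapping[str, Any] | RunConfig) -> RunConfig:
    """Fill defaults and reject unknown keys or out-of-domain values,
    naming the offending key."""
    if isinstance(cfg, RunConfig):
        data = asdict(cfg)
    else:
        data = dict(cfg)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = RunConfig(**data)
    positive = [
        "rate", "bin_mya", "bin_4dtv", "window", "pseudocount",
        "period_min", "period_max", "min_4d_sites",
    ]
    for key in positive:
        if getattr(out, key) <= 0:
            raise ValueError(f"config key {key!r} must be positive")
    for key in ("max_evalue", "lea_max_evalue", "max_gap_bp", "max_intervening"):
        if getattr(out, key) < 0:
            raise ValueError(f"config key {key!r} must be non-negative")
    for key in ("min_fraction", "min_monomer_identity"):
        if not 0 <= getattr(out, key) <= 1:
            raise ValueError(f"config key {key!r} must be within [0, 1]")
    for key in ("min_identity", "min_coverage"):
        if not 0 <= getattr(out, key) <= 100:
            raise ValueError(f"config key {key!r} must be within [0, 100]")
    if out.period_min > out.period_max:
        raise ValueError("config key 'period_min' exceeds 'period_max'")
    return out


def load_config(path: str | Path | None, **overrides: Any) -> RunConfig:
    """Load a YAML config (optional) and apply explicit overrides on top."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return validate_config(data)
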