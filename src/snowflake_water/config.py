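"""Run configuration: one file/mapping resolving to a complete run.

A run configuration names a preset, optional parameter overrides, a state
point, and the growth settings.  Unknown keys are rejected so typos fail
loudly.  ``dump(resolve(cfg))`` is idempotent.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

from .params import ModelParams, StatePoint, load_preset
from .snowflake import GrowthConfig

__all__ = ["RunConfig", "resolve_config", "dump_config"]

_TOP_KEYS = {
    "preset", "overrides", "T", "p",
    "max_shells", "n_replicas", "max_attempts", "overlap_margin", "seed",
}


@dataclass(frozen=True)
class RunConfig:
    preset: str
    params: ModelParams
    state_point: StatePoint
    growth: GrowthConfig


def resolve_config(source: Mapping[str, Any] | str | Path) -> RunConfig:
    """Resolve a mapping or TOML file into a complete :class:`RunConfig`."""
    if not isinstance(source, Mapping):
        source = tomllib.loads(Path(source).read_text())
    unknown = set(source) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    for key in ("T", "p"):
        if key not in source:
            raise ValueError(f"run config is missing required key {key!r}")
    preset = source.get("preset", "MB-rose")
    params = load_preset(preset, **source.get("overrides", {}))
    sp = StatePoint(T=float(source["T"]), p=float(source["p"]))
    growth = GrowthConfig(
        max_shells=int(source.get("max_shells", 9)),
        n_replicas=int(source.get("n_replicas", 100_000)),
        max_attempts=int(source.get("max_attempts", 10)),
        overlap_margin=float(source.get("overlap_margin", 0.05)),
        seed=source.get("seed"),
    )
    return RunConfig(preset=preset, params=params, state_point=sp, growth=growth)


def dump_config(cfg: RunConfig) -> dict[str, Any]:
    """Serialize a resolved config back to a plain mapping."""
    return {
        "preset": cfg.preset,
        "overrides": asdict(cfg.params),
        "T": cfg.state_point.T,
        "p": cfg.state_point.p,
        "max_shells": cfg.growth.max_shells,
        "n_replicas": cfg.growth.n_replicas,
        "max_attempts": cfg.growth.max_attempts,
        "overlap_margin": cfg.growth.overlap_margin,
        "seed": cfg.growth.seed,
    }
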