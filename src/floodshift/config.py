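"""Run configuration shared across the pipeline stages.

A :class:`RunConfig` collects every tunable the pipeline exposes: the two
stage-level season thresholds that delimit the flood-pulse phases, the STARS
significance/window settings, the common-species CPUE cut-off and the
missing-value sweep increment.  Values can be loaded from a YAML file and
overridden field-by-field (the CLI layers its flags on top of the file).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide parameters.

    Parameters
    ----------
    season_low_threshold
        Stage level (m) below which a day belongs to the dry season and at
        whose upward crossing a flood-pulse cycle begins.
    season_high_threshold
        Stage level (m) above which a day belongs to the flood season.
    stars_significance
        Two-sided significance level for the STARS sequential t-test.
    stars_window
        STARS cut-off length ``l`` in years (window used for the regime
        variance, the critical difference and the RSI confirmation span).
    prewhiten
        Whether annual series are passed through the AR(1) white-noise filter
        before STARS.
    common_species_cpue_threshold
        CPUE (individuals per m^2) above which a species counts as common;
        the criterion is the maximum CPUE over cycles.
    sweep_increment
        Grid step for the missing-value robustness sweep, in the units of the
        swept series.
    max_gap_fraction
        Largest tolerated fraction of missing days inside a flood-pulse cycle
        before the cycle is flagged unusable.
    random_seed
        Seed for every stochastic component (simulators, multi-starts).
    """

    season_low_threshold: float = 20.0
    season_high_threshold: float = 26.0
    stars_significance: float = 0.05
    stars_window: int = 10
    prewhiten: bool = True
    common_species_cpue_threshold: float = 0.01
    sweep_increment: float = 0.001
    max_gap_fraction: float = 0.05
    random_seed: int = 20170110

    def __post_init__(self) -> None:
        if not self.season_low_threshold < self.season_high_threshold:
            raise ValueError(
                "season_low_threshold must be below season_high_threshold "
                f"(got {self.season_low_threshold} >= {self.season_high_threshold})"
            )
        if not 0.0 < self.stars_significance < 1.0:
            raise ValueError("stars_significance must lie in (0, 1)")
        if self.stars_window < 3:
            raise ValueError("stars_window must be at least 3 years")
        if self.sweep_increment <= 0:
            raise ValueError("sweep_increment must be positive")
        if not 0.0 <= self.max_gap_fraction < 1.0:
            raise ValueError("max_gap_fraction must lie in [0, 1)")

    def override(self, **kwargs: Any) -> "RunConfig":
        """Return a copy with the given fields replaced (None values ignored)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates) if updates else self


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    YAML keys mirror the field names.  Unknown keys raise ``ValueError`` so a
    typo in a config file cannot silently fall back to a default.  Overrides
    (e.g. CLI flags) win over the file.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        data.update(loaded)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    if overrides:
        cfg = cfg.override(**overrides)
    return cfg
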