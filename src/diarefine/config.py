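"""Structured configuration for the quantification pipeline.

All tunables referenced across the toolkit live here with their defaults.
TOML files are accepted; unknown keys are rejected so a typo cannot
silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass
class QuantConfig:
    """Peak refinement and quantification tunables.

    rt_extraction_halfwidth_s : half-width of the RT extraction window
        around the expected apex (the 300 s full extraction window).
    shape_good_threshold : minimum Pearson correlation of a fragment trace
        against the peak-group consensus to count as "good peak shape".
    snr_threshold : minimum apex signal-to-noise (apex intensity over the
        median intensity outside the peak boundaries) for a good fragment.
    resample_step_s : grid step for shape-score resampling and consensus.
    boundary_cap_s : maximum distance a peak boundary may walk from the apex.
    boundary_baseline_frac : boundary stop threshold as a fraction of the
        apex intensity.
    apex_search_halfwidth_s : apex re-centering search radius around the
        seeded retention time.
    min_good_fragments : precursors with fewer good fragments are excluded.
    """

    rt_extraction_halfwidth_s: float = 150.0
    shape_good_threshold: float = 0.8
    snr_threshold: float = 3.0
    resample_step_s: float = 1.0
    boundary_cap_s: float = 60.0
    boundary_baseline_frac: float = 0.05
    apex_search_halfwidth_s: float = 15.0
    min_good_fragments: int = 4


@dataclass
class NormalizeConfig:
    """Normalization and replicate-filter tunables.

    tech_fc_threshold : technical duplicates whose max/min ratio is >= this
        are discarded ("fold-change equal or higher than two").
    normalize_before_filter : apply per-window TIC normalization before the
        technical-replicate filter (the filter then compares normalized
        values).
    """

    tech_fc_threshold: float = 2.0
    normalize_before_filter: bool = True


@dataclass
class StatsConfig:
    """Differential-analysis thresholds (volcano rule)."""

    fc_threshold: float = 2.0
    alpha: float = 0.05
    benjamini_hochberg: bool = False


@dataclass
class WindowConfig:
    """Isolation-window designer settings."""

    n_windows: int = 48
    overlap_margin: float = 0.5
    mode: str = "intensity"  # or "count"


@dataclass
class PipelineConfig:
    """Top-level pipeline configuration (CLI `run-all`)."""

    quant: QuantConfig = field(default_factory=QuantConfig)
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    windows: WindowConfig = field(default_factory=WindowConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


_SECTIONS = {
    "quant": QuantConfig,
    "normalize": NormalizeConfig,
    "stats": StatsConfig,
    "windows": WindowConfig,
}
_TOP_LEVEL_SCALARS = {"seed", "log_level"}


def _build_section(cls, data: dict, section: str):
    known = {f.name: f.type for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) in [{section}]: {', '.join(sorted(unknown))}"
        )
    return cls(**data)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a TOML pipeline config; unknown keys raise :class:`ConfigError`."""
    if path is None:
        return PipelineConfig()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    unknown = set(data) - set(_SECTIONS) - _TOP_LEVEL_SCALARS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"config section [{name}] must be a table")
        kwargs[name] = _build_section(cls, section, name)
    return PipelineConfig(
        seed=int(data.get("seed", 0)),
        log_level=str(data.get("log_level", "INFO")),
        **kwargs,
    )
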