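"""Run configuration: QC thresholds, reduction options, statistics options.

Configuration files are flat ``key: value`` YAML; keys are routed to the
matching dataclass field.  All QC thresholds default to the acceptance limits
used during method validation (43.5/44 interference 1e-5, 10% intensity match,
0.1 mass-bias-factor spread, 0.1‰ mass-dependence deviation).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import constants
from .errors import ConfigError


@dataclass
class ReductionConfig:
    """Options controlling the cycle-level reduction and its QC filters."""

    #: reject when the blank-corrected 43.5/44 ratio exceeds this (Sr²⁺ screen)
    interference_threshold: float = 1e-5
    #: reject when |sample I44 / bracketing-standard I44 − 1| exceeds this
    intensity_threshold: float = 0.10
    #: reject when 2·sd of the three mass-bias factors exceeds this
    massbias_spread_threshold: float = 0.1
    #: reject when the mass-dependence statistic exceeds this (‰)
    massdep_threshold: float = 0.1
    #: slope linking the 43/42 and 44/42 delta scales in the QC statistic
    massdep_coef: float = constants.MASS_DEPENDENCE_COEF
    #: 'analysis' → |coef·δ44 − δ43|; 'cycle' → 2·sd of per-cycle paired values
    massdep_mode: str = "analysis"
    #: 'mean' (arithmetic mean of bracketing standards) or 'linear'
    #: (linear-in-run-index interpolation)
    bracketing: str = "mean"
    #: optional per-block cycle trimming at this many sd of the 44/42 ratio
    trim_cycles: bool = False
    trim_sd: float = 2.5
    #: reference ("true") ratios for mass-bias factors
    r44_42_reference: float = constants.R44_42_REFERENCE
    r43_42_reference: float = constants.R43_42_REFERENCE
    #: mass-bias law; only the exponential (kinetic) law is implemented
    mass_bias_law: str = "exponential"

    def validate(self) -> None:
        for name in (
            "interference_threshold",
            "intensity_threshold",
            "massbias_spread_threshold",
            "massdep_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.massdep_mode not in ("analysis", "cycle"):
            raise ConfigError(f"unknown massdep_mode {self.massdep_mode!r}")
        if self.bracketing not in ("mean", "linear"):
            raise ConfigError(f"unknown bracketing mode {self.bracketing!r}")
        if self.mass_bias_law != "exponential":
            raise ConfigError(f"unsupported mass-bias law {self.mass_bias_law!r}")


@dataclass
class StatsConfig:
    """Options for the cohort statistics."""

    alpha: float = 0.05
    log_base: float = 10.0
    #: variables treated as normal (ANOVA); everything else → Kruskal–Wallis.
    #: Defaults mirror mean±SD versus median[IQR] reporting conventions.
    normal_vars: tuple[str, ...] = (
        "egfr",
        "po4",
        "albumin",
        "vitd",
        "ba_pwv_cm_s",
        "urine_ca_ug_g",
        "urine_delta44_42",
        "serum_delta44_42",
        "fgf23_log10",
    )
    #: univariable screening p-value for stepwise candidate entry
    screen_p: float = 0.2


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    session_csv: str | None = None
    cohort_csv: str | None = None
    scale: str = "SRM915a"
    seed: int = 0
    out_dir: str = "caiso_out"
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)


def _route(cfg: RunConfig, key: str, value) -> None:
    red_fields = {f.name for f in dataclasses.fields(ReductionConfig)}
    stat_fields = {f.name for f in dataclasses.fields(StatsConfig)}
    top_fields = {f.name for f in dataclasses.fields(RunConfig)} - {"reduction", "stats"}
    k = key.split(".")[-1]
    if k in red_fields:
        setattr(cfg.reduction, k, value)
    elif k in stat_fields:
        if k == "normal_vars" and isinstance(value, (list, tuple)):
            cfg.stats.normal_vars = tuple(value)
        else:
            setattr(cfg.stats, k, value)
    elif k in top_fields:
        setattr(cfg, k, value)
    else:
        raise ConfigError(f"unknown configuration key {key!r}")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a flat key-value YAML file into a :class:`RunConfig`."""
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration file {path} is not a key-value mapping")
    for key, value in raw.items():
        _route(cfg, str(key), value)
    cfg.reduction.validate()
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective configuration as flat YAML (for run provenance)."""
    flat: dict = {}
    for f in dataclasses.fields(RunConfig):
        if f.name in ("reduction", "stats"):
            continue
        flat[f.name] = getattr(cfg, f.name)
    for sub, obj in (("reduction", cfg.reduction), ("stats", cfg.stats)):
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            flat[f"{sub}.{f.name}"] = list(v) if isinstance(v, tuple) else v
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True)
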