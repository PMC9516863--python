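"""Run configuration for the end-to-end pipeline.

A run is described either by a YAML file or by CLI flags (flags override the
file).  Countries with any missing year in the configured study span are
rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "validate_config", "load_config"]

# Countries dropped by default from ingested data when present (low-quality
# registration in the source archive).
DEFAULT_EXCLUDE = ("BGR",)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    stmf_path: str | None = None
    archive_deaths_path: str | None = None
    archive_population_path: str | None = None
    dataset_path: str | None = None        # canonical CSV, already ingested
    synthetic: bool = False                # use the packaged synthetic cohort
    include: tuple[str, ...] = ()          # empty = all available
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE
    baseline_span: tuple[int, int] = (2009, 2019)
    study_span: tuple[int, int] = (2009, 2021)
    widths: tuple[int, ...] = (1, 2, 3, 4)
    composites: dict[str, tuple[str, ...]] = field(default_factory=dict)
    out_dir: str = "multimort_out"
    seed: int = 20090923

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError([f"unknown config keys: {sorted(unknown)}"])
        kwargs = dict(mapping)
        for key in ("baseline_span", "study_span", "widths", "include", "exclude"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "composites" in kwargs and kwargs["composites"] is not None:
            kwargs["composites"] = {str(k): tuple(v)
                                    for k, v in dict(kwargs["composites"]).items()}
        return cls(**kwargs)


def validate_config(config: RunConfig) -> RunConfig:
    """Normalise and check a configuration; raises :class:`ConfigError`
    listing every violation."""
    violations: list[str] = []
    cfg = replace(config,
                  widths=tuple(sorted(set(config.widths))),
                  include=tuple(config.include),
                  exclude=tuple(config.exclude))

    sources = [cfg.synthetic, cfg.dataset_path is not None,
               cfg.stmf_path is not None or cfg.archive_deaths_path is not None]
    if not any(sources):
        violations.append("no input source: set synthetic, dataset_path, or "
                          "stmf/archive paths")
    if (cfg.archive_deaths_path is None) != (cfg.archive_population_path is None):
        violations.append("archive input needs both deaths and population paths")

    b0, b1 = cfg.baseline_span
    s0, s1 = cfg.study_span
    if b0 > b1:
        violations.append(f"reversed baseline span {cfg.baseline_span}")
    if s0 > s1:
        violations.append(f"reversed study span {cfg.study_span}")
    if not (s0 <= b0 and b1 <= s1):
        violations.append(f"baseline span {cfg.baseline_span} not inside "
                          f"study span {cfg.study_span}")
    if not cfg.widths or not set(cfg.widths) <= {1, 2, 3, 4}:
        violations.append(f"widths {cfg.widths} must be a nonempty subset of 1..4")
    if cfg.include and set(cfg.include) <= set(cfg.exclude):
        violations.append("include/exclude lists remove every country")
    for name, members in cfg.composites.items():
        if not members:
            violations.append(f"composite {name!r} has no members")
        if cfg.include and not set(members) <= set(cfg.include):
            absent = sorted(set(members) - set(cfg.include))
            violations.append(f"composite {name!r} names countries outside the "
                              f"include list: {absent}")
    if violations:
        raise ConfigError(violations)
    return cfg


def load_config(path) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig` (not yet validated)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError([f"config file {path} is not a mapping"])
    return RunConfig.from_mapping(raw)
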