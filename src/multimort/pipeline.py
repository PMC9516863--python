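"""End-to-end pipeline: ingest -> multiverse grid -> summary tables.

Outputs (CSV, written to the configured directory):

* ``grid.csv``               — the full multiverse grid (long format)
* ``table1_summary.csv``     — per-country p% spread for the final two-year window
* ``table2_ranks.csv``       — country x rank counts across baselines
* ``table3_attenuation.csv`` — 1-to-4-year projected-window attenuation
* ``fig1_patterns.csv``      — per-country, per-window average/min/max (width 2)
* ``worst_periods.csv``      — windows ranked by baseline-averaged p%
* ``moments.csv``            — cross-country mean/SD per recent window and the
  correlations of the per-country average with max/min/SD/range

Runs are deterministic: identical config and inputs give byte-identical CSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig, validate_config
from .data import (MortalityDataset, aggregate_composite, merge_sources,
                   read_annual_archive, read_dataset_csv, read_stmf,
                   write_dataset_csv)
from .errors import ValidationError
from .model import ExcessMortalityMultiverse
from .multiverse import ProjectedWindow
from .simulate import default_cohort
from . import summaries as _summ

__all__ = ["run_pipeline", "load_input_dataset"]

log = logging.getLogger("multimort")


def load_input_dataset(cfg: RunConfig) -> MortalityDataset:
    """Assemble the annual dataset from the configured sources.

    When both the annual archive and an STMF file are given, the archive is
    treated as the older source and overwritten by the STMF data wherever
    they overlap.
    """
    if cfg.synthetic:
        log.info("generating packaged synthetic cohort (seed=%d)", cfg.seed)
        dataset, _ = default_cohort(seed=cfg.seed)
        return dataset
    if cfg.dataset_path:
        return read_dataset_csv(cfg.dataset_path)
    old = new = None
    if cfg.archive_deaths_path:
        old = read_annual_archive(cfg.archive_deaths_path, cfg.archive_population_path)
    if cfg.stmf_path:
        new = read_stmf(cfg.stmf_path)
    if old is None and new is None:
        raise ValidationError("no input source configured")
    if old is None:
        return new
    return merge_sources(old, new)


def _select_countries(dataset: MortalityDataset, cfg: RunConfig) -> list[str]:
    available = set(dataset.countries)
    wanted = set(cfg.include) if cfg.include else available
    missing = wanted - available
    if missing:
        raise ValidationError(f"requested countries absent from data: {sorted(missing)}")
    wanted -= set(cfg.exclude)
    # keep only countries covering the full study span
    s0, s1 = cfg.study_span
    covered = {c for c in wanted
               if all((c, y) in dataset for y in range(s0, s1 + 1))}
    dropped = sorted(wanted - covered)
    if dropped:
        log.warning("dropping countries with incomplete study span: %s", dropped)
    if not covered:
        raise ValidationError("no countries cover the configured study span")
    return sorted(covered)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute a full run and return the paths of the emitted tables."""
    cfg = validate_config(config)
    dataset = load_input_dataset(cfg)
    for name, members in cfg.composites.items():
        dataset = aggregate_composite(dataset, list(members), name)
    countries = _select_countries(dataset, cfg)

    model = ExcessMortalityMultiverse(dataset, baseline_span=cfg.baseline_span,
                                      widths=cfg.widths, countries=countries)
    log.info("fitting multiverse: %d countries, baseline %s, widths %s",
             len(countries), cfg.baseline_span, cfg.widths)
    res = model.fit()
    log.info("grid: %d estimates (%d baselines)", len(res.grid), res.n_baselines)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        frame.to_csv(path, index=index)
        paths[name] = path
        log.info("wrote %s (%d rows)", path, len(frame))

    write_dataset_csv(dataset.subset(countries), out / "dataset.csv")
    paths["dataset.csv"] = out / "dataset.csv"
    emit("grid.csv", res.grid)

    pair = res._default_projected()
    emit("table1_summary.csv", res.summary_table(pair))
    if len(countries) > 1:
        emit("table2_ranks.csv", res.rank_table(pair), index=True)

    s0, s1 = cfg.study_span
    if s1 - 3 >= s0 and max(cfg.widths) >= 4:
        emit("table3_attenuation.csv", res.attenuation())

    pattern_width = 2 if 2 in cfg.widths else cfg.widths[0]
    patterns = pd.concat(
        [res.year_patterns(c, pattern_width).assign(country=c) for c in countries],
        ignore_index=True,
    )[["country", "proj_start", "proj_end", "average", "minimum", "maximum"]]
    emit("fig1_patterns.csv", patterns)

    worst = pd.concat(
        [res.worst_periods(c, cfg.widths[0]).assign(country=c) for c in countries],
        ignore_index=True,
    )[["country", "proj_start", "proj_end", "average", "minimum", "maximum"]]
    emit("worst_periods.csv", worst)

    if len(countries) > 2:
        rows = []
        for width in cfg.widths:
            if s1 - width + 1 < s0:
                continue
            win = ProjectedWindow(s1 - width + 1, s1)
            summaries = res.summaries(win)
            mean, sd = _summ.cross_country_moments(summaries)
            corr = _summ.summary_correlations(summaries)
            rows.append({"proj_start": win.start_year, "proj_end": win.end_year,
                         "mean": mean, "sd": sd,
                         "corr_avg_max": corr["maximum"],
                         "corr_avg_min": corr["minimum"],
                         "corr_avg_sd": corr["sd"],
                         "corr_avg_range": corr["range"]})
        emit("moments.csv", pd.DataFrame(rows))
    return paths
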