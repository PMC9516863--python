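"""Summary products of the multiverse grid.

These mirror the descriptive outputs of a multiverse excess-death study:

* per-country spread of p% across all baselines (average, SD, min, max,
  range) for a fixed projected window;
* distribution of country ranks across baselines (rank 1 = highest excess);
* attenuation of the single-year pandemic peak as the projected window
  widens from 1 to 4 years;
* per-year time patterns (average and min-max envelope across baselines);
* cross-country moments and correlations of the per-country summaries.

Summary statistics use the sample (n-1) standard deviation.  Values are
carried at full precision; rounding to one decimal (two for correlations)
is left to the reporting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import MortalityDataset
from .errors import ValidationError
from .multiverse import (ExcessEstimate, ProjectedWindow, multiverse_grid)

__all__ = [
    "MultiverseSummary",
    "summarize_multiverse",
    "summary_table",
    "rank_distribution",
    "attenuation_table",
    "year_patterns",
    "worst_periods",
    "cross_country_moments",
    "summary_correlations",
]


@dataclass(frozen=True)
class MultiverseSummary:
    """Spread of relative excess p% across all enumerated baselines for one
    country and projected window."""

    country_code: str
    projected: ProjectedWindow
    average: float
    sd: float
    minimum: float
    maximum: float

    @property
    def range(self) -> float:
        return self.maximum - self.minimum


def summarize_multiverse(estimates: Sequence[ExcessEstimate]) -> MultiverseSummary:
    """Average, sample SD, min, max of p% across a country's baselines.

    All estimates must share one country and one projected window.
    """
    if not estimates:
        raise ValueError("cannot summarize an empty list of estimates")
    country = estimates[0].country_code
    projected = estimates[0].projected
    if any(e.country_code != country or e.projected != projected for e in estimates):
        raise ValueError("estimates mix countries or projected windows")
    p = np.array([e.p_pct for e in estimates])
    sd = float(np.std(p, ddof=1)) if len(p) > 1 else 0.0
    return MultiverseSummary(country, projected, float(p.mean()), sd,
                             float(p.min()), float(p.max()))


def _grid_window(grid: pd.DataFrame, projected: ProjectedWindow) -> pd.DataFrame:
    sub = grid[(grid["proj_start"] == projected.start_year)
               & (grid["proj_end"] == projected.end_year)]
    if sub.empty:
        raise ValidationError(f"projected window {projected} not present in grid")
    return sub


def summary_table(grid: pd.DataFrame, projected: ProjectedWindow) -> pd.DataFrame:
    """Per-country summary of p% across baselines for one projected window.

    Columns: country, average, sd, minimum, maximum, range (percent).
    """
    sub = _grid_window(grid, projected)
    out = (sub.groupby("country")["p_pct"]
           .agg(average="mean",
                sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
                minimum="min", maximum="max")
           .reset_index())
    out["range"] = out["maximum"] - out["minimum"]
    return out.sort_values("country", ignore_index=True)


def rank_distribution(grid: pd.DataFrame, projected: ProjectedWindow) -> pd.DataFrame:
    """Counts of each rank attained by each country across baselines.

    For every baseline, countries are ranked by p% descending (rank 1 =
    highest excess), ties broken by country code ascending.  Returned as a
    country x rank DataFrame whose rows each sum to the number of baselines.
    """
    sub = _grid_window(grid, projected)
    pivot = sub.pivot_table(index=["ref_start", "ref_end"], columns="country",
                            values="p_pct")
    if pivot.isna().any().any():
        bad = pivot.columns[pivot.isna().any()].tolist()
        raise ValidationError(f"ragged grid: countries missing baselines: {bad}")
    countries = sorted(pivot.columns)
    n_ranks = len(countries)
    counts = pd.DataFrame(0, index=countries,
                          columns=pd.RangeIndex(1, n_ranks + 1, name="rank"))
    for _, row in pivot.iterrows():
        order = sorted(countries, key=lambda c: (-row[c], c))
        for rank, country in enumerate(order, start=1):
            counts.at[country, rank] += 1
    counts.index.name = "country"
    return counts


def attenuation_table(dataset: MortalityDataset, countries: Sequence[str] | None,
                      baseline_span: tuple[int, int],
                      end_year: int | None = None,
                      grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Peak attenuation when widening the projected window from 1 to 4 years.

    For a final year Y (2021 in the default study), the five windows are
    {Y-1}, {Y}, {Y-1,Y}, {Y-2..Y}, {Y-3..Y}.  Each entry is the mean across
    all enumerated baselines of the pooled p%, and the drops are

        drop_k = max(p_{Y-1}, p_Y) - p_{k-year window},  k = 2, 3, 4,

    in percentage points, computed from unrounded values.
    """
    if end_year is None:
        end_year = dataset.study_span[1]
    if countries is None:
        countries = dataset.countries
    windows = {
        f"p_{end_year - 1}": ProjectedWindow(end_year - 1, end_year - 1),
        f"p_{end_year}": ProjectedWindow(end_year, end_year),
        "p_2y": ProjectedWindow(end_year - 1, end_year),
        "p_3y": ProjectedWindow(end_year - 2, end_year),
        "p_4y": ProjectedWindow(end_year - 3, end_year),
    }
    first_needed = end_year - 3
    for c in countries:
        missing = [y for y in range(first_needed, end_year + 1)
                   if (c, y) not in dataset]
        if missing:
            raise ValidationError(f"{c}: years {missing} needed for attenuation")
    if grid is None:
        grid = multiverse_grid(dataset, baseline_span, countries=countries,
                               study_span=(first_needed, end_year))
    rows = []
    for c in countries:
        entry = {"country": c}
        for name, win in windows.items():
            sub = _grid_window(grid, win)
            entry[name] = float(sub.loc[sub["country"] == c, "p_pct"].mean())
        peak = max(entry[f"p_{end_year - 1}"], entry[f"p_{end_year}"])
        entry["drop_2y"] = peak - entry["p_2y"]
        entry["drop_3y"] = peak - entry["p_3y"]
        entry["drop_4y"] = peak - entry["p_4y"]
        rows.append(entry)
    return pd.DataFrame(rows)


def year_patterns(dataset: MortalityDataset, country: str, width: int,
                  baseline_span: tuple[int, int],
                  study_span: tuple[int, int] | None = None,
                  grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Average and min-max envelope of p% across baselines for every
    width-year projected window in the study span.

    Columns: proj_start, proj_end, average, minimum, maximum.
    """
    if study_span is None:
        study_span = (dataset.years(country)[0], dataset.years(country)[-1])
    if grid is None:
        grid = multiverse_grid(dataset, baseline_span, countries=[country],
                               widths=(width,), study_span=study_span)
    sub = grid[(grid["country"] == country)
               & (grid["proj_end"] - grid["proj_start"] == width - 1)]
    if sub.empty:
        raise ValidationError(f"no width-{width} windows for {country} in grid")
    out = (sub.groupby(["proj_start", "proj_end"])["p_pct"]
           .agg(average="mean", minimum="min", maximum="max")
           .reset_index())
    return out.sort_values("proj_start", ignore_index=True)


def worst_periods(dataset: MortalityDataset, country: str, width: int,
                  baseline_span: tuple[int, int],
                  study_span: tuple[int, int] | None = None,
                  grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Projected windows of the given width ordered by baseline-averaged p%
    descending; ties broken by earlier start year."""
    pattern = year_patterns(dataset, country, width, baseline_span,
                            study_span=study_span, grid=grid)
    return pattern.sort_values(["average", "proj_start"],
                               ascending=[False, True],
                               kind="mergesort", ignore_index=True)


def cross_country_moments(summaries: Sequence[MultiverseSummary]) -> tuple[float, float]:
    """Mean and sample SD, across countries, of the per-country averages."""
    if not summaries:
        raise ValueError("no summaries given")
    projected = summaries[0].projected
    if any(s.projected != projected for s in summaries):
        raise ValueError("summaries mix projected windows")
    averages = np.array([s.average for s in summaries])
    sd = float(np.std(averages, ddof=1)) if len(averages) > 1 else 0.0
    return float(averages.mean()), sd


def summary_correlations(summaries: Sequence[MultiverseSummary]) -> dict[str, float]:
    """Pearson correlations, across countries, of the per-country average
    with maximum, minimum, sd and range.

    A zero-variance vector makes the coefficient undefined; it is reported
    as NaN with a warning.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 countries for correlations")
    avg = np.array([s.average for s in summaries])
    others = {
        "maximum": np.array([s.maximum for s in summaries]),
        "minimum": np.array([s.minimum for s in summaries]),
        "sd": np.array([s.sd for s in summaries]),
        "range": np.array([s.range for s in summaries]),
    }
    out = {}
    for name, vec in others.items():
        if np.std(avg) == 0 or np.std(vec) == 0:
            warnings.warn(f"correlation(average, {name}) undefined: zero variance")
            out[name] = float("nan")
        else:
            out[name] = float(np.corrcoef(avg, vec)[0, 1])
    return out
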