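"""Model/Results interface over the multiverse computation.

`ExcessMortalityMultiverse` is constructed from a :class:`MortalityDataset`
(or a long-format DataFrame) together with the analytic universe — baseline
span and projected-window widths.  `fit()` evaluates the full grid once and
returns a :class:`MultiverseResults` from which all the summary products
(per-country spread tables, rank distributions, attenuation, year patterns)
are derived without recomputation.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .data import MortalityDataset
from .errors import ValidationError
from .multiverse import (ProjectedWindow, enumerate_reference_windows,
                         multiverse_grid)
from . import summaries as _summ

__all__ = ["ExcessMortalityMultiverse", "MultiverseResults"]

_DEFAULT_BASELINE = (2009, 2019)


class ExcessMortalityMultiverse:
    """Multiverse excess-death analysis of an annual five-band dataset.

    Parameters
    ----------
    dataset : MortalityDataset
        Annual deaths and populations in the five standard age bands.
    baseline_span : (int, int), optional
        First and last year eligible as reference baseline.  Defaults to
        2009-2019 when the data cover it, otherwise to the study span.
    widths : sequence of int in 1..4
        Projected-window widths to evaluate.
    countries : sequence of str, optional
        Restrict the analysis; defaults to every country in the dataset.

    Examples
    --------
    >>> from multimort.simulate import default_cohort
    >>> dataset, _ = default_cohort(seed=1)
    >>> res = ExcessMortalityMultiverse(dataset).fit()
    >>> res.n_baselines
    66
    """

    def __init__(self, dataset: MortalityDataset,
                 baseline_span: tuple[int, int] | None = None,
                 widths: Sequence[int] = (1, 2, 3, 4),
                 countries: Sequence[str] | None = None):
        self.dataset = dataset
        start, end = dataset.study_span
        if baseline_span is None:
            if start <= _DEFAULT_BASELINE[0] and end >= _DEFAULT_BASELINE[1]:
                baseline_span = _DEFAULT_BASELINE
            else:
                baseline_span = (start, end)
        if not (start <= baseline_span[0] <= baseline_span[1] <= end):
            raise ValidationError(
                f"baseline span {baseline_span} outside study span {(start, end)}")
        self.baseline_span = tuple(baseline_span)
        self.widths = tuple(sorted(set(widths)))
        if not self.widths or not set(self.widths) <= {1, 2, 3, 4}:
            raise ValidationError(f"widths must be within 1..4, got {widths}")
        self.countries = list(countries) if countries is not None else dataset.countries
        if not self.countries:
            raise ValidationError("no countries selected")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "ExcessMortalityMultiverse":
        """Build from a long-format frame (country, year, band, deaths,
        population)."""
        return cls(MortalityDataset.from_frame(frame), **kwargs)

    def fit(self) -> "MultiverseResults":
        """Evaluate p% on the full (country x baseline x projected) grid."""
        grid = multiverse_grid(self.dataset, self.baseline_span,
                               countries=self.countries, widths=self.widths)
        return MultiverseResults(self, grid)


class MultiverseResults:
    """Fitted multiverse grid plus derived summary products."""

    def __init__(self, model: ExcessMortalityMultiverse, grid: pd.DataFrame):
        self.model = model
        self.grid = grid
        self.n_baselines = len(enumerate_reference_windows(*model.baseline_span))

    # -- defaults ------------------------------------------------------

    def _default_projected(self) -> ProjectedWindow:
        """The pandemic-style pair: the last two study years (last year if
        only width 1 was requested)."""
        end = self.model.dataset.study_span[1]
        if 2 in self.model.widths:
            return ProjectedWindow(end - 1, end)
        return ProjectedWindow(end, end)

    # -- summary products ----------------------------------------------

    def summary_table(self, projected: ProjectedWindow | None = None) -> pd.DataFrame:
        """Per-country average / SD / min / max / range of p% across baselines."""
        projected = projected or self._default_projected()
        return _summ.summary_table(self.grid, projected)

    def summaries(self, projected: ProjectedWindow | None = None) -> list[_summ.MultiverseSummary]:
        projected = projected or self._default_projected()
        table = self.summary_table(projected)
        return [_summ.MultiverseSummary(r.country, projected, r.average, r.sd,
                                        r.minimum, r.maximum)
                for r in table.itertuples(index=False)]

    def rank_table(self, projected: ProjectedWindow | None = None) -> pd.DataFrame:
        projected = projected or self._default_projected()
        return _summ.rank_distribution(self.grid, projected)

    def attenuation(self, end_year: int | None = None) -> pd.DataFrame:
        return _summ.attenuation_table(self.model.dataset, self.model.countries,
                                       self.model.baseline_span, end_year=end_year)

    def year_patterns(self, country: str, width: int = 2) -> pd.DataFrame:
        if width in self.model.widths:
            return _summ.year_patterns(self.model.dataset, country, width,
                                       self.model.baseline_span, grid=self.grid)
        return _summ.year_patterns(self.model.dataset, country, width,
                                   self.model.baseline_span)

    def worst_periods(self, country: str, width: int = 1) -> pd.DataFrame:
        grid = self.grid if width in self.model.widths else None
        return _summ.worst_periods(self.model.dataset, country, width,
                                   self.model.baseline_span, grid=grid)

    def cross_country_moments(self, projected: ProjectedWindow | None = None
                              ) -> tuple[float, float]:
        return _summ.cross_country_moments(self.summaries(projected))

    def correlations(self, projected: ProjectedWindow | None = None) -> dict[str, float]:
        return _summ.summary_correlations(self.summaries(projected))

    # -- presentation ---------------------------------------------------

    def summary(self, projected: ProjectedWindow | None = None) -> str:
        """Human-readable report for one projected window."""
        projected = projected or self._default_projected()
        table = self.summary_table(projected).copy()
        for col in ("average", "sd", "minimum", "maximum", "range"):
            table[col] = table[col].round(1)
        lines = [
            "Excess-death multiverse analysis",
            f"  countries: {len(self.model.countries)}   "
            f"baselines: {self.n_baselines} "
            f"({self.model.baseline_span[0]}-{self.model.baseline_span[1]})   "
            f"widths: {self.model.widths}",
            f"  projected window: {projected}",
            "",
            "Relative excess deaths p% across baselines (percent):",
            table.to_string(index=False),
        ]
        if len(self.model.countries) > 1:
            mean, sd = self.cross_country_moments(projected)
            lines.append("")
            lines.append(f"Cross-country mean {mean:.2f}%  SD {sd:.2f}%")
        return "\n".join(lines)

    def plot_year_pattern(self, country: str, width: int = 2, ax=None):
        """Line-and-band plot of the baseline-averaged p% per year with the
        min-max envelope (requires matplotlib)."""
        import matplotlib.pyplot as plt

        pattern = self.year_patterns(country, width)
        if ax is None:
            _, ax = plt.subplots()
        x = pattern["proj_end"]
        ax.fill_between(x, pattern["minimum"], pattern["maximum"],
                        alpha=0.3, label="baseline min-max")
        ax.plot(x, pattern["average"], color="black", label="baseline average")
        ax.axhline(0.0, lw=0.5, color="grey")
        ax.set_xlabel("final year of projected window")
        ax.set_ylabel("relative excess deaths p%")
        ax.set_title(f"{country}, {width}-year projected windows")
        ax.legend()
        return ax
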