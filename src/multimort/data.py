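"""Reading, validating, merging and writing annual five-band mortality data.

Two input dialects are supported:

* the STMF weekly dialect — one row per (country, ISO year, week, sex) with
  death counts and death rates in the five standard age bands;
* the annual archive dialect — deaths and populations by 1-year age, which
  are collapsed onto the five bands.

Both are normalised to the package's canonical in-memory container,
:class:`MortalityDataset`: per (country, calendar year), death counts and
person-years of exposure in the five bands, validated to be gap-free over
each country's span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .bands import AGE_BANDS, N_BANDS, STMF_SUFFIXES, band_of_age
from .errors import FormatError, ValidationError

__all__ = [
    "CountryYearData",
    "MortalityDataset",
    "WeeklyRow",
    "read_stmf",
    "read_annual_archive",
    "annual_to_weekly",
    "weekly_to_annual",
    "merge_sources",
    "aggregate_composite",
    "read_dataset_csv",
    "write_dataset_csv",
    "write_stmf",
]

_SEX_ALIASES = {
    "b": "both", "both": "both", "t": "both", "total": "both",
    "m": "male", "male": "male",
    "f": "female", "female": "female",
}

STMF_DEATH_COLUMNS = tuple(f"D{s}" for s in STMF_SUFFIXES)
STMF_RATE_COLUMNS = tuple(f"R{s}" for s in STMF_SUFFIXES)
STMF_REQUIRED = ("CountryCode", "Year", "Week", "Sex") + STMF_DEATH_COLUMNS + STMF_RATE_COLUMNS


@dataclass(frozen=True)
class CountryYearData:
    """Deaths and person-years of exposure in the five age bands for one
    country and calendar year.

    ``deaths`` and ``population`` are length-5 arrays ordered as
    :data:`~multimort.bands.AGE_BANDS`.  Deaths may be fractional (annual
    counts rebuilt from 52 equal weeks are); populations must be strictly
    positive.
    """

    country_code: str
    year: int
    deaths: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        deaths = np.asarray(self.deaths, dtype=float)
        population = np.asarray(self.population, dtype=float)
        object.__setattr__(self, "deaths", deaths)
        object.__setattr__(self, "population", population)
        if deaths.shape != (N_BANDS,) or population.shape != (N_BANDS,):
            raise ValidationError(
                f"{self.country_code}/{self.year}: expected {N_BANDS} bands, "
                f"got deaths {deaths.shape}, population {population.shape}"
            )
        if np.any(deaths < 0) or not np.all(np.isfinite(deaths)):
            raise ValidationError(f"{self.country_code}/{self.year}: negative or non-finite deaths")
        if np.any(population <= 0) or not np.all(np.isfinite(population)):
            raise ValidationError(f"{self.country_code}/{self.year}: non-positive population")

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())

    @property
    def band_rates(self) -> np.ndarray:
        """Band mortality rates, deaths per person-year."""
        return self.deaths / self.population

    def scaled(self, factor: float) -> "CountryYearData":
        """Deaths and populations multiplied by a common positive factor."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return CountryYearData(self.country_code, self.year,
                               self.deaths * factor, self.population * factor)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountryYearData):
            return NotImplemented
        return (self.country_code == other.country_code
                and self.year == other.year
                and np.array_equal(self.deaths, other.deaths)
                and np.array_equal(self.population, other.population))

    def __hash__(self) -> int:
        return hash((self.country_code, self.year))


@dataclass(frozen=True)
class WeeklyRow:
    """One STMF-dialect row: deaths and rates per band for one ISO week."""

    country_code: str
    iso_year: int
    week: int
    sex: str
    deaths: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        if not 1 <= self.week <= 53:
            raise ValidationError(f"week {self.week} outside 1..53")
        if np.any(np.asarray(self.rates) < 0):
            raise ValidationError("negative rate in weekly row")


class MortalityDataset:
    """A validated collection of :class:`CountryYearData`.

    For every included country, every year of that country's span is present
    (no gaps) and there are no duplicate (country, year) keys.  ``study_span``
    is the overall (first, last) year across all countries.
    """

    def __init__(self, records: Iterable[CountryYearData]):
        self._records: dict[tuple[str, int], CountryYearData] = {}
        for rec in records:
            key = (rec.country_code, rec.year)
            if key in self._records:
                raise ValidationError(f"duplicate record for {key}")
            self._records[key] = rec
        if not self._records:
            raise ValidationError("empty dataset: no (country, year) records")
        self._validate_spans()

    def _validate_spans(self) -> None:
        for country in self.countries:
            years = sorted(y for (c, y) in self._records if c == country)
            missing = sorted(set(range(years[0], years[-1] + 1)) - set(years))
            if missing:
                raise ValidationError(
                    f"{country}: gap in year span {years[0]}-{years[-1]}, "
                    f"missing years {missing}"
                )

    # -- access ---------------------------------------------------------

    @property
    def countries(self) -> list[str]:
        return sorted({c for (c, _) in self._records})

    @property
    def study_span(self) -> tuple[int, int]:
        years = [y for (_, y) in self._records]
        return min(years), max(years)

    def years(self, country: str) -> list[int]:
        ys = sorted(y for (c, y) in self._records if c == country)
        if not ys:
            raise KeyError(f"no records for country {country!r}")
        return ys

    def get(self, country: str, year: int) -> CountryYearData:
        try:
            return self._records[(country, year)]
        except KeyError:
            raise KeyError(f"no record for ({country!r}, {year})") from None

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._records

    def __iter__(self) -> Iterator[CountryYearData]:
        return iter(sorted(self._records.values(), key=lambda r: (r.country_code, r.year)))

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MortalityDataset):
            return NotImplemented
        return (set(self._records) == set(other._records)
                and all(self._records[k] == other._records[k] for k in self._records))

    # -- conversion -----------------------------------------------------

    def subset(self, countries: Sequence[str]) -> "MortalityDataset":
        wanted = set(countries)
        unknown = wanted - set(self.countries)
        if unknown:
            raise KeyError(f"countries not in dataset: {sorted(unknown)}")
        return MortalityDataset(r for r in self if r.country_code in wanted)

    def to_frame(self) -> pd.DataFrame:
        """Long format: country, year, band, deaths, population."""
        rows = []
        for rec in self:
            for i, band in enumerate(AGE_BANDS):
                rows.append((rec.country_code, rec.year, band,
                             rec.deaths[i], rec.population[i]))
        return pd.DataFrame(rows, columns=["country", "year", "band", "deaths", "population"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MortalityDataset":
        required = {"country", "year", "band", "deaths", "population"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"dataset frame missing columns: {sorted(missing)}")
        records = []
        for (country, year), grp in frame.groupby(["country", "year"], sort=True):
            by_band = grp.set_index("band")
            try:
                deaths = np.array([by_band.at[b, "deaths"] for b in AGE_BANDS], dtype=float)
                pop = np.array([by_band.at[b, "population"] for b in AGE_BANDS], dtype=float)
            except KeyError as exc:
                raise ValidationError(f"{country}/{year}: missing band {exc}") from None
            records.append(CountryYearData(str(country), int(year), deaths, pop))
        return cls(records)


# ---------------------------------------------------------------------------
# STMF weekly dialect
# ---------------------------------------------------------------------------

def read_stmf(path, sex_filter: str = "both") -> MortalityDataset:
    """Read an STMF-dialect weekly CSV into an annual five-band dataset.

    Weekly deaths are summed within each ISO year per band.  Band exposure
    (person-years) is recovered from the rate columns as the summed weekly
    person-time, ``sum_w(deaths_w / rate_w)``, which equals annual deaths
    divided by the death-weighted annual rate and is exact when weekly rates
    are uniform.  Rows with sex categories other than ``sex_filter`` are
    dropped.
    """
    sex_filter = _SEX_ALIASES.get(str(sex_filter).lower())
    if sex_filter is None:
        raise ValueError(f"unknown sex category {sex_filter!r}")
    frame = pd.read_csv(path)
    for col in STMF_REQUIRED:
        if col not in frame.columns:
            raise FormatError(f"STMF file missing required column {col!r}")
    sex = frame["Sex"].astype(str).str.lower().map(_SEX_ALIASES)
    frame = frame.loc[sex == sex_filter]
    if frame.empty:
        raise ValidationError(f"no rows remain after filtering to sex={sex_filter!r}")

    records = []
    for (country, year), grp in frame.groupby(["CountryCode", "Year"], sort=True):
        deaths = np.zeros(N_BANDS)
        person_time = np.zeros(N_BANDS)
        for i, suffix in enumerate(STMF_SUFFIXES):
            d = grp[f"D{suffix}"].to_numpy(dtype=float)
            r = grp[f"R{suffix}"].to_numpy(dtype=float)
            if np.any((d > 0) & (r <= 0)):
                raise ValidationError(
                    f"{country}/{year}: band {AGE_BANDS[i]} has deaths with "
                    "zero rate; exposure cannot be recovered"
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                pt = np.where(d > 0, d / np.where(r > 0, r, np.nan), 0.0)
            deaths[i] = d.sum()
            person_time[i] = np.nansum(pt)
        if person_time.sum() <= 0:
            raise ValidationError(
                f"{country}/{year}: zero total population derived from rates"
            )
        if np.any(person_time <= 0):
            bad = [AGE_BANDS[i] for i in range(N_BANDS) if person_time[i] <= 0]
            raise ValidationError(
                f"{country}/{year}: bands {bad} have no deaths, so band "
                "population cannot be derived from rates"
            )
        records.append(CountryYearData(str(country), int(year), deaths, person_time))
    return MortalityDataset(records)


def annual_to_weekly(record: CountryYearData) -> list[WeeklyRow]:
    """Expand an annual record into 52 equal weeks.

    Each week carries band deaths ``annual/52`` (fractional) and the annual
    band rate ``deaths/population``; re-aggregating the 52 rows reproduces
    the record exactly.
    """
    weekly_deaths = record.deaths / 52.0
    rates = record.band_rates
    return [
        WeeklyRow(record.country_code, record.year, week, "both",
                  weekly_deaths.copy(), rates.copy())
        for week in range(1, 53)
    ]


def weekly_to_annual(rows: Sequence[WeeklyRow]) -> CountryYearData:
    """Aggregate weekly rows of one (country, year) back to an annual record.

    Inverse of :func:`annual_to_weekly`; exposure is recovered as summed
    weekly person-time, matching :func:`read_stmf`.
    """
    if not rows:
        raise ValidationError("no weekly rows to aggregate")
    country = rows[0].country_code
    year = rows[0].iso_year
    if any(r.country_code != country or r.iso_year != year for r in rows):
        raise ValidationError("weekly rows mix countries or years")
    deaths = np.sum([r.deaths for r in rows], axis=0)
    person_time = np.zeros(N_BANDS)
    for r in rows:
        d = np.asarray(r.deaths, dtype=float)
        rate = np.asarray(r.rates, dtype=float)
        if np.any((d > 0) & (rate <= 0)):
            raise ValidationError(f"{country}/{year}: deaths with zero rate")
        person_time += np.where(d > 0, d / np.where(rate > 0, rate, np.nan), 0.0)
    return CountryYearData(country, year, deaths, person_time)


def write_stmf(dataset: MortalityDataset, path) -> None:
    """Emit a dataset in the STMF weekly dialect (52 equal weeks per year)."""
    rows = []
    for rec in dataset:
        for wr in annual_to_weekly(rec):
            row = {"CountryCode": wr.country_code, "Year": wr.iso_year,
                   "Week": wr.week, "Sex": "b"}
            for i, suffix in enumerate(STMF_SUFFIXES):
                row[f"D{suffix}"] = wr.deaths[i]
                row[f"R{suffix}"] = wr.rates[i]
            row["DTotal"] = wr.deaths.sum()
            # death-weighted all-age rate implied by the band rows
            row["RTotal"] = wr.deaths.sum() / np.sum(wr.deaths / wr.rates)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Annual archive dialect (1-year ages)
# ---------------------------------------------------------------------------

def _parse_age(value) -> int:
    text = str(value).strip()
    match = re.fullmatch(r"(\d+)\+?", text)
    if not match:
        raise FormatError(f"unparseable age value {value!r}")
    return int(match.group(1))


def _collapse_archive(frame: pd.DataFrame, what: str) -> pd.DataFrame:
    for col in ("CountryCode", "Year", "Age", "Value"):
        if col not in frame.columns:
            raise FormatError(f"annual archive {what} file missing column {col!r}")
    frame = frame.copy()
    frame["age"] = frame["Age"].map(_parse_age)
    for (country, year), grp in frame.groupby(["CountryCode", "Year"]):
        ages = set(grp["age"])
        if min(ages) > 0 or max(ages) < 85:
            raise ValidationError(
                f"{country}/{year}: 1-year ages cover {min(ages)}..{max(ages)}, "
                "not the full 0..85+ range"
            )
    frame["band"] = frame["age"].map(band_of_age)
    out = (frame.groupby(["CountryCode", "Year", "band"])["Value"]
           .sum().rename(what).reset_index())
    return out


def read_annual_archive(deaths_path, population_path) -> MortalityDataset:
    """Read archive-style 1-year-age deaths and populations and collapse
    them onto the five standard bands."""
    deaths = _collapse_archive(pd.read_csv(deaths_path), "deaths")
    pop = _collapse_archive(pd.read_csv(population_path), "population")
    merged = deaths.merge(pop, on=["CountryCode", "Year", "band"], how="outer")
    if merged[["deaths", "population"]].isna().any().any():
        missing = merged[merged.isna().any(axis=1)][["CountryCode", "Year"]]
        raise ValidationError(
            f"deaths/population country-years do not match: {missing.drop_duplicates().to_dict('records')}"
        )
    merged = merged.rename(columns={"CountryCode": "country", "Year": "year"})
    return MortalityDataset.from_frame(merged)


# ---------------------------------------------------------------------------
# Merging, composites, canonical CSV
# ---------------------------------------------------------------------------

def merge_sources(old: MortalityDataset, new: MortalityDataset | None) -> MortalityDataset:
    """Overlay ``new`` on ``old``: for any (country, year) in both, the
    newer record wins; otherwise the union is taken.  The result is
    revalidated, so a merge that leaves a gap in a country's span fails."""
    if new is None or len(new) == 0:
        return MortalityDataset(iter(old))
    combined = {(r.country_code, r.year): r for r in old}
    combined.update({(r.country_code, r.year): r for r in new})
    return MortalityDataset(combined.values())


def aggregate_composite(dataset: MortalityDataset, members: Sequence[str],
                        composite_code: str) -> MortalityDataset:
    """Append a pseudo-country whose band deaths and populations are the
    member-wise sums per year, over the members' common span."""
    if not members:
        raise ValidationError("composite needs at least one member")
    unknown = set(members) - set(dataset.countries)
    if unknown:
        raise ValidationError(f"composite members not in dataset: {sorted(unknown)}")
    if composite_code in dataset.countries:
        raise ValidationError(f"composite code {composite_code!r} already present")
    start = max(dataset.years(m)[0] for m in members)
    end = min(dataset.years(m)[-1] for m in members)
    if start > end:
        raise ValidationError("composite members share no common years")
    missing = [(m, y) for m in members for y in range(start, end + 1)
               if (m, y) not in dataset]
    if missing:  # pragma: no cover - spans are gap-free by construction
        raise ValidationError(f"missing member-years for composite: {missing}")
    records = list(dataset)
    for year in range(start, end + 1):
        deaths = np.sum([dataset.get(m, year).deaths for m in members], axis=0)
        pop = np.sum([dataset.get(m, year).population for m in members], axis=0)
        records.append(CountryYearData(composite_code, year, deaths, pop))
    return MortalityDataset(records)


def write_dataset_csv(dataset: MortalityDataset, path) -> None:
    """Write the canonical exchange format: country, year, band, deaths,
    population.  Floats use shortest round-trip formatting, so write->read
    is the identity."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_dataset_csv(path) -> MortalityDataset:
    return MortalityDataset.from_frame(
        pd.read_csv(path, float_precision="round_trip"))
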