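"""Synthetic national mortality series with known ground truth.

Each country is defined by per-band initial mortality rates, a
multiplicative secular rate trend, per-band initial populations with
geometric growth, and a map of shock years to multiplicative rate shocks.
For year index t (t = 0 at the first generated year) and band b:

    population_b(t) = pop0_b * growth_b^t
    mu_b(t)         = population_b(t) * rate0_b * trend_b^t * shock_b(t)

Deaths are exactly mu (noise="none") or a seeded Poisson draw with mean mu
(noise="poisson").  Bands are independent; there is no migration or cohort
aging between bands — the generator exercises the data shapes and the
expected-death arithmetic, not demography.

With a band-uniform shock s in a year and trend 1, any pre-shock baseline
recovers a relative excess of exactly 100*(s-1) percent in the noiseless
case, which is what the recovery tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import AGE_BANDS, N_BANDS
from .data import CountryYearData, MortalityDataset

__all__ = [
    "CountrySpec",
    "generate_country",
    "generate_cohort",
    "default_cohort_specs",
    "default_cohort",
    "DEFAULT_SEED",
    "DEFAULT_BASE_RATES",
    "DEFAULT_BASE_POPULATION",
]

DEFAULT_SEED = 20090923

# Plausible five-band annual death rates (per person-year) and populations
# for a mid-sized high-income country (~19M inhabitants, ~180k deaths/year).
DEFAULT_BASE_RATES = np.array([0.0005, 0.002, 0.015, 0.045, 0.13])
DEFAULT_BASE_POPULATION = np.array([3.0e6, 13.0e6, 1.5e6, 1.0e6, 0.4e6])


def _as_band_array(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(N_BANDS, float(arr))
    if arr.shape != (N_BANDS,):
        raise ValueError(f"{name} must be scalar or length-{N_BANDS}, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class CountrySpec:
    """Ground-truth parameters of one synthetic country.

    ``shock_map`` maps calendar year to a multiplicative rate shock, either
    a scalar applied to all bands or a per-band length-5 array; 1.10 means
    mortality elevated by 10% in that year.
    """

    country_code: str
    base_rates: np.ndarray = field(default_factory=lambda: DEFAULT_BASE_RATES.copy())
    rate_trend: np.ndarray = 1.0
    base_population: np.ndarray = field(
        default_factory=lambda: DEFAULT_BASE_POPULATION.copy())
    pop_growth: np.ndarray = 1.0
    shock_map: Mapping[int, float | np.ndarray] = field(default_factory=dict)
    noise: str = "none"
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_rates", _as_band_array(self.base_rates, "base_rates"))
        object.__setattr__(self, "rate_trend", _as_band_array(self.rate_trend, "rate_trend"))
        object.__setattr__(self, "base_population",
                           _as_band_array(self.base_population, "base_population"))
        object.__setattr__(self, "pop_growth", _as_band_array(self.pop_growth, "pop_growth"))
        if np.any(self.base_rates <= 0):
            raise ValueError("base rates must be > 0")
        if np.any(self.base_population <= 0):
            raise ValueError("base populations must be > 0")
        if np.any(self.rate_trend <= 0) or np.any(self.pop_growth <= 0):
            raise ValueError("trend and growth factors must be > 0")
        shocks = {int(y): _as_band_array(f, f"shock[{y}]")
                  for y, f in dict(self.shock_map).items()}
        if any(np.any(f <= 0) for f in shocks.values()):
            raise ValueError("shock factors must be > 0")
        object.__setattr__(self, "shock_map", shocks)
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    def shock(self, year: int) -> np.ndarray:
        return self.shock_map.get(year, np.ones(N_BANDS))

    def expected_band_deaths(self, year: int, first_year: int) -> np.ndarray:
        """Noiseless band death counts mu_b(t) for a calendar year."""
        t = year - first_year
        pop = self.base_population * self.pop_growth ** t
        return pop * self.base_rates * self.rate_trend ** t * self.shock(year)


def generate_country(spec: CountrySpec, years: tuple[int, int]) -> list[CountryYearData]:
    """Generate the annual five-band series for one country over an
    inclusive span of calendar years."""
    start, end = years
    if start > end:
        raise ValueError(f"reversed span {start}..{end}")
    rng = np.random.default_rng(spec.seed)
    out = []
    for year in range(start, end + 1):
        t = year - start
        pop = spec.base_population * spec.pop_growth ** t
        mu = spec.expected_band_deaths(year, start)
        if spec.noise == "poisson":
            deaths = rng.poisson(mu).astype(float)
        else:
            deaths = mu
        out.append(CountryYearData(spec.country_code, year, deaths, pop))
    return out


def generate_cohort(specs: Sequence[CountrySpec],
                    years: tuple[int, int]) -> tuple[MortalityDataset, pd.DataFrame]:
    """Assemble a multi-country dataset plus a machine-readable truth table.

    The truth table has one row per (country, shock year, band) with the
    injected shock factor, for parameter-recovery tests.
    """
    if not specs:
        raise ValueError("empty list of country specs")
    codes = [s.country_code for s in specs]
    if len(set(codes)) != len(codes):
        raise ValueError(f"duplicate country codes in specs: {codes}")
    records = []
    truth_rows = []
    for spec in specs:
        records.extend(generate_country(spec, years))
        for year, factors in sorted(spec.shock_map.items()):
            for i, band in enumerate(AGE_BANDS):
                truth_rows.append((spec.country_code, year, band, factors[i]))
    truth = pd.DataFrame(truth_rows,
                         columns=["country", "year", "band", "shock_factor"])
    return MortalityDataset(records), truth


def default_cohort_specs(seed: int = DEFAULT_SEED, noise: str = "poisson") -> list[CountrySpec]:
    """The packaged five-country fixture: shocks of 0/5/10/15/20% applied in
    both 2020 and 2021, mildly declining mortality, growing populations."""
    shock_sizes = [0.00, 0.05, 0.10, 0.15, 0.20]
    specs = []
    for i, s in enumerate(shock_sizes):
        factor = 1.0 + s
        specs.append(CountrySpec(
            country_code=f"SY{chr(ord('A') + i)}",
            base_rates=DEFAULT_BASE_RATES * (1.0 + 0.05 * i),
            rate_trend=0.995,
            base_population=DEFAULT_BASE_POPULATION * (0.5 + 0.25 * i),
            pop_growth=1.003,
            shock_map={2020: factor, 2021: factor} if s > 0 else {},
            noise=noise,
            seed=seed + i,
        ))
    return specs


def default_cohort(seed: int = DEFAULT_SEED, noise: str = "poisson",
                   years: tuple[int, int] = (2009, 2021)
                   ) -> tuple[MortalityDataset, pd.DataFrame]:
    """Generate the packaged fixture cohort (5 countries x 13 years)."""
    return generate_cohort(default_cohort_specs(seed=seed, noise=noise), years)
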