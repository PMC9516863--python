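import numpy as np
import pytest

from multimort.data import CountryYearData, MortalityDataset
from multimort.simulate import CountrySpec, default_cohort_specs, generate_cohort


def naive_p_pct(dataset, country, ref_years, proj_years):
    """Plain-Python reference implementation of the relative excess p%.

    Mean band rates over the reference years, expected deaths from each
    projected year's own band populations, pooled D and E.  Kept free of
    numpy so it cannot share code paths with the package.
    """
    n_bands = len(dataset.get(country, ref_years[0]).deaths)
    rates = []
    for b in range(n_bands):
        acc = 0.0
        for y in ref_years:
            rec = dataset.get(country, y)
            acc += rec.deaths[b] / rec.population[b]
        rates.append(acc / len(ref_years))
    D = 0.0
    E = 0.0
    for y in proj_years:
        rec = dataset.get(country, y)
        D += sum(float(d) for d in rec.deaths)
        for b in range(n_bands):
            E += rates[b] * rec.population[b]
    return 100.0 * (D - E) / E


def make_record(country="AAA", year=2009, deaths=(10, 200, 300, 450, 520),
                population=(1e5, 1e6, 2e5, 1e5, 4e4)):
    return CountryYearData(country, year,
                           np.asarray(deaths, float), np.asarray(population, float))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Packaged 5-country fixture, deterministic (no noise)."""
    dataset, truth = generate_cohort(default_cohort_specs(noise="none"), (2009, 2021))
    return dataset, truth


@pytest.fixture(scope="session")
def poisson_cohort():
    dataset, truth = generate_cohort(default_cohort_specs(noise="poisson"), (2009, 2021))
    return dataset, truth


@pytest.fixture
def flat_shock_spec():
    """Constant rates and a band-uniform +10% shock in 2020 and 2021."""
    return CountrySpec("FLT", rate_trend=1.0, pop_growth=1.003,
                       shock_map={2020: 1.10, 2021: 1.10}, noise="none")


@pytest.fixture
def two_country_flat():
    """Two structurally identical flat countries (for composite/rank checks)."""
    specs = [CountrySpec(code, rate_trend=1.0, pop_growth=1.0, noise="none")
             for code in ("AAA", "BBB")]
    dataset, _ = generate_cohort(specs, (2009, 2015))
    return dataset
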