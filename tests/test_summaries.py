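import numpy as np
import pandas as pd
import pytest

import multimort as mm
from multimort.multiverse import ProjectedWindow
from multimort.simulate import CountrySpec, generate_country
from multimort.summaries import MultiverseSummary


def make_estimates(p_values, country="AAA", projected=ProjectedWindow(2020, 2021)):
    refs = mm.enumerate_reference_windows(2009, 2009 + len(p_values) - 1)
    return [mm.ExcessEstimate(country, refs[i], projected, 100 + p, 100.0, p)
            for i, p in enumerate(p_values)]


class TestSummarize:
    def test_constant_estimates(self):
        s = mm.summarize_multiverse(make_estimates([5.0, 5.0, 5.0]))
        assert (s.average, s.sd, s.range) == (5.0, 0.0, 0.0)

    def test_two_point_sample(self):
        s = mm.summarize_multiverse(make_estimates([0.0, 10.0]))
        assert s.average == pytest.approx(5.0)
        assert s.sd == pytest.approx(np.sqrt(50.0))      # sample (n-1) form
        assert s.minimum == 0.0 and s.maximum == 10.0 and s.range == 10.0

    def test_empty_or_mixed_inputs_rejected(self):
        with pytest.raises(ValueError):
            mm.summarize_multiverse([])
        mixed = make_estimates([1.0]) + make_estimates([2.0], country="BBB")
        with pytest.raises(ValueError, match="mix"):
            mm.summarize_multiverse(mixed)

    def test_extrema_attained_by_some_baseline(self, noiseless_cohort):
        dataset, _ = noiseless_cohort
        ests = mm.multiverse(dataset, "SYE", ProjectedWindow(2020, 2021),
                             (2009, 2019))
        s = mm.summarize_multiverse(ests)
        ps = [e.p_pct for e in ests]
        assert s.minimum in ps and s.maximum in ps
        assert s.minimum <= s.average <= s.maximum


class TestRankDistribution:
    def test_separated_countries_hold_constant_ranks(self, noiseless_cohort):
        # fixture shocks 0/5/10/15/20% keep the country order the same under
        # every baseline
        dataset, _ = noiseless_cohort
        grid = mm.multiverse_grid(dataset, (2009, 2019), widths=(2,))
        counts = mm.rank_distribution(grid, ProjectedWindow(2020, 2021))
        assert counts.at["SYE", 1] == 66
        assert counts.at["SYA", 5] == 66

    def test_row_and_column_sums_equal_baseline_count(self, poisson_cohort):
        dataset, _ = poisson_cohort
        grid = mm.multiverse_grid(dataset, (2009, 2019), widths=(1,))
        counts = mm.rank_distribution(grid, ProjectedWindow(2015, 2015))
        assert (counts.sum(axis=1) == 66).all()
        assert (counts.sum(axis=0) == 66).all()

    def test_single_country(self, noiseless_cohort):
        dataset, _ = noiseless_cohort
        grid = mm.multiverse_grid(dataset, (2009, 2019), countries=["SYA"],
                                  widths=(1,))
        counts = mm.rank_distribution(grid, ProjectedWindow(2020, 2020))
        assert counts.shape == (1, 1) and counts.at["SYA", 1] == 66

    def test_matches_brute_force_sort(self, poisson_cohort):
        dataset, _ = poisson_cohort
        grid = mm.multiverse_grid(dataset, (2009, 2019), widths=(1,))
        proj = ProjectedWindow(2021, 2021)
        counts = mm.rank_distribution(grid, proj)
        sub = grid[(grid.proj_start == 2021) & (grid.proj_end == 2021)]
        expected = {c: {r: 0 for r in range(1, 6)} for c in dataset.countries}
        for _, baseline in sub.groupby(["ref_start", "ref_end"]):
            ordered = sorted(baseline.itertuples(),
                             key=lambda t: (-t.p_pct, t.country))
            for rank, t in enumerate(ordered, start=1):
                expected[t.country][rank] += 1
        for country in dataset.countries:
            for rank in range(1, 6):
                assert counts.at[country, rank] == expected[country][rank]

    def test_ties_break_alphabetically(self):
        grid = pd.DataFrame({
            "country": ["AAA", "BBB"], "ref_start": 2009, "ref_end": 2009,
            "proj_start": 2020, "proj_end": 2020,
            "D": 100.0, "E": 100.0, "p_pct": [3.0, 3.0],
        })
        counts = mm.rank_distribution(grid, ProjectedWindow(2020, 2020))
        assert counts.at["AAA", 1] == 1 and counts.at["BBB", 2] == 1

    def test_ragged_grid_rejected(self, poisson_cohort):
        dataset, _ = poisson_cohort
        grid = mm.multiverse_grid(dataset, (2009, 2019), widths=(1,))
        ragged = grid.drop(grid[(grid.country == "SYB")
                                & (grid.ref_start == 2009)
                                & (grid.ref_end == 2009)].index)
        with pytest.raises(mm.ValidationError, match="SYB"):
            mm.rank_distribution(ragged, ProjectedWindow(2020, 2020))


def flat_single_shock_dataset(s=0.15, shock_year=2021):
    spec = CountrySpec("SHK", rate_trend=1.0, pop_growth=1.004,
                       shock_map={shock_year: 1.0 + s}, noise="none")
    return mm.MortalityDataset(generate_country(spec, (2009, 2021))), spec


class TestAttenuation:
    def test_single_shock_closed_form(self):
        s = 0.15
        ds, spec = flat_single_shock_dataset(s)
        table = mm.attenuation_table(ds, ["SHK"], (2009, 2019))
        row = table.iloc[0]
        # expected deaths per year from the known constant rates
        E = {y: float(spec.expected_band_deaths(y, 2009).sum()
                      / (spec.shock(y)[0]))
             for y in range(2018, 2022)}
        assert row["p_2021"] == pytest.approx(100 * s, abs=1e-9)
        assert row["p_2020"] == pytest.approx(0.0, abs=1e-9)
        e_frac_2y = E[2021] / (E[2020] + E[2021])
        assert row["p_2y"] == pytest.approx(100 * s * e_frac_2y, abs=1e-9)
        assert row["drop_2y"] == pytest.approx(100 * s * (1 - e_frac_2y), abs=1e-9)
        # pooled peak shrinks monotonically with window width
        assert row["p_2021"] > row["p_2y"] > row["p_3y"] > row["p_4y"]
        assert 0 < row["drop_2y"] < row["drop_3y"] < row["drop_4y"]

    def test_flat_country_all_zero(self):
        spec = CountrySpec("CST", rate_trend=1.0, pop_growth=1.0, noise="none")
        ds = mm.MortalityDataset(generate_country(spec, (2009, 2021)))
        row = mm.attenuation_table(ds, ["CST"], (2009, 2019)).iloc[0]
        for col in ("p_2020", "p_2021", "p_2y", "p_3y", "p_4y",
                    "drop_2y", "drop_3y", "drop_4y"):
            assert row[col] == pytest.approx(0.0, abs=1e-9)

    def test_missing_years_rejected(self):
        ds, _ = flat_single_shock_dataset()
        short = mm.MortalityDataset(r for r in ds if r.year <= 2019)
        with pytest.raises(mm.ValidationError):
            mm.attenuation_table(short, ["SHK"], (2009, 2019), end_year=2021)


class TestYearPatterns:
    def test_degenerate_identical_years(self):
        spec = CountrySpec("CST", rate_trend=1.0, pop_growth=1.0, noise="none")
        ds = mm.MortalityDataset(generate_country(spec, (2009, 2021)))
        pattern = mm.year_patterns(ds, "CST", 1, (2009, 2019))
        assert pattern["average"].abs().max() < 1e-9
        assert pattern["minimum"].abs().max() < 1e-9
        assert pattern["maximum"].abs().max() < 1e-9

    def test_single_baseline_collapses_envelope(self, noiseless_cohort):
        dataset, _ = noiseless_cohort
        pattern = mm.year_patterns(dataset, "SYD", 2, (2012, 2012))
        np.testing.assert_allclose(pattern["average"], pattern["minimum"])
        np.testing.assert_allclose(pattern["average"], pattern["maximum"])

    def test_agrees_with_grid_recomputation(self, poisson_cohort):
        dataset, _ = poisson_cohort
        grid = mm.multiverse_grid(dataset, (2009, 2019), widths=(2,))
        pattern = mm.year_patterns(dataset, "SYC", 2, (2009, 2019), grid=grid)
        sub = grid[(grid.country == "SYC") & (grid.proj_start == 2019)
                   & (grid.proj_end == 2020)]
        row = pattern[pattern.proj_start == 2019].iloc[0]
        assert row["average"] == pytest.approx(sub["p_pct"].mean(), rel=1e-12)
        assert row["minimum"] == pytest.approx(sub["p_pct"].min(), rel=1e-12)
        assert row["maximum"] == pytest.approx(sub["p_pct"].max(), rel=1e-12)

    def test_envelope_ordering(self, poisson_cohort):
        dataset, _ = poisson_cohort
        pattern = mm.year_patterns(dataset, "SYB", 3, (2009, 2019))
        assert (pattern["minimum"] <= pattern["average"]).all()
        assert (pattern["average"] <= pattern["maximum"]).all()


class TestWorstPeriods:
    def test_injected_shock_ranks_first(self):
        ds, _ = flat_single_shock_dataset(s=0.2, shock_year=2021)
        worst = mm.worst_periods(ds, "SHK", 1, (2009, 2019))
        assert worst.iloc[0]["proj_start"] == 2021

    def test_flat_country_ties_break_to_earliest(self):
        spec = CountrySpec("CST", rate_trend=1.0, pop_growth=1.0, noise="none")
        ds = mm.MortalityDataset(generate_country(spec, (2009, 2021)))
        worst = mm.worst_periods(ds, "CST", 1, (2009, 2019))
        assert worst.iloc[0]["proj_start"] == 2009
        assert list(worst["proj_start"]) == sorted(worst["proj_start"])

    def test_two_shocks_ordered_by_size(self):
        spec = CountrySpec("TWO", rate_trend=1.0, pop_growth=1.0,
                           shock_map={2015: 1.08, 2020: 1.20}, noise="none")
        ds = mm.MortalityDataset(generate_country(spec, (2009, 2021)))
        worst = mm.worst_periods(ds, "TWO", 1, (2009, 2019))
        ordered = worst.sort_values(["average", "proj_start"],
                                    ascending=[False, True], kind="mergesort")
        pd.testing.assert_frame_equal(worst, ordered.reset_index(drop=True))
        assert worst.iloc[0]["proj_start"] == 2020
        assert worst.iloc[1]["proj_start"] == 2015


class TestCrossCountry:
    def make_summaries(self, averages, sds=None, projected=ProjectedWindow(2021, 2021)):
        sds = sds or [1.0] * len(averages)
        return [MultiverseSummary(f"C{i:02d}", projected, a, sd, a - 2, a + 2)
                for i, (a, sd) in enumerate(zip(averages, sds))]

    def test_two_symmetric_countries(self):
        mean, sd = mm.cross_country_moments(self.make_summaries([10.0, -10.0]))
        assert mean == pytest.approx(0.0)
        assert sd == pytest.approx(np.sqrt(200.0))

    def test_identical_countries_have_zero_sd(self):
        mean, sd = mm.cross_country_moments(self.make_summaries([3.0, 3.0, 3.0]))
        assert (mean, sd) == (3.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mm.cross_country_moments([])

    def test_affine_max_gives_unit_correlation(self):
        summaries = self.make_summaries([1.0, 4.0, 9.0, 16.0])
        corr = mm.summary_correlations(summaries)
        assert corr["maximum"] == pytest.approx(1.0)
        assert corr["minimum"] == pytest.approx(1.0)

    def test_zero_variance_yields_nan_with_warning(self):
        summaries = self.make_summaries([1.0, 2.0, 3.0], sds=[2.0, 2.0, 2.0])
        with pytest.warns(UserWarning, match="zero variance"):
            corr = mm.summary_correlations(summaries)
        assert np.isnan(corr["sd"])

    def test_independent_random_summaries_nearly_uncorrelated(self):
        rng = np.random.default_rng(123)
        proj = ProjectedWindow(2021, 2021)
        avgs = rng.normal(size=2000)
        sds = rng.uniform(0.5, 1.5, size=2000)
        summaries = [MultiverseSummary(f"C{i:04d}", proj, a, s, a - 2, a + 2)
                     for i, (a, s) in enumerate(zip(avgs, sds))]
        corr = mm.summary_correlations(summaries)
        assert abs(corr["sd"]) < 0.1


class TestOffsetShift:
    def test_constant_offset_shifts_summary_statistics(self, poisson_cohort):
        # a baseline change that adds a constant to every estimate moves
        # average/min/max by that constant and leaves the spread alone
        dataset, _ = poisson_cohort
        ests = mm.multiverse(dataset, "SYC", ProjectedWindow(2020, 2021),
                             (2009, 2019))
        shifted = [mm.ExcessEstimate(e.country_code, e.reference, e.projected,
                                     e.D, e.E, e.p_pct + 4.2) for e in ests]
        s0 = mm.summarize_multiverse(ests)
        s1 = mm.summarize_multiverse(shifted)
        assert s1.average == pytest.approx(s0.average + 4.2)
        assert s1.minimum == pytest.approx(s0.minimum + 4.2)
        assert s1.maximum == pytest.approx(s0.maximum + 4.2)
        assert s1.sd == pytest.approx(s0.sd)
        assert s1.range == pytest.approx(s0.range)
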