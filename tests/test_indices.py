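"""Trapezoid indices, effort covariates, and inclusion filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lepitrend import indices as idx

counts_series = st.lists(st.floats(0, 1000), min_size=2, max_size=40)


class TestTrapezoidIndex:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([0, 2, 4, 2, 0], 8.0),
            ([0, 0, 0, 0], 0.0),
            ([3, 3, 3, 3, 3], 3 * 4),  # constant c over w weeks -> c * (w-1)
        ],
    )
    def test_hand_examples(self, series, expected):
        assert idx.trapezoid_index(series) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "series, msg",
        [
            ([5.0], ">= 2"),
            ([1.0, np.nan], "missing"),
            ([1.0, -0.5], "negative"),
        ],
    )
    def test_contract_violations(self, series, msg):
        with pytest.raises(ValueError, match=msg):
            idx.trapezoid_index(series)

    @given(a=counts_series, b=counts_series)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_additive_in_the_series(self, a, b):
        # underpins total-abundance aggregation: sum of indices = index of sums
        m = min(len(a), len(b))
        a, b = np.array(a[:m]), np.array(b[:m])
        assert idx.trapezoid_index(a + b) == pytest.approx(
            idx.trapezoid_index(a) + idx.trapezoid_index(b), rel=1e-9, abs=1e-9
        )

    @given(a=counts_series)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_by_max_count(self, a):
        v = idx.trapezoid_index(a)
        assert 0.0 <= v <= max(a) * (len(a) - 1) + 1e-9


class TestEffortCovariates:
    def test_mean_list_length_examples(self):
        counts = pd.DataFrame(
            {
                "week": [1] * 3 + [2] * 5 + [3] * 4,
                "species_id": [f"s{i}" for i in range(3)]
                + [f"s{i}" for i in range(5)]
                + [f"s{i}" for i in range(4)],
                "count": 1,
            }
        )
        assert idx.mean_list_length(counts, [1, 2, 3]) == pytest.approx(4.0)

    def test_list_length_counts_empty_surveys_as_zero(self):
        counts = pd.DataFrame({"week": [1] * 7, "species_id": [f"s{i}" for i in range(7)],
                               "count": 1})
        assert idx.mean_list_length(counts, [1]) == pytest.approx(7.0)
        assert idx.mean_list_length(counts.assign(count=0), [1, 2]) == 0.0

    def test_list_length_requires_surveyed_weeks(self):
        with pytest.raises(ValueError, match="undefined"):
            idx.mean_list_length(pd.DataFrame({"week": [], "species_id": [],
                                               "count": []}), [])

    @pytest.mark.parametrize(
        "durations, weeks, expected",
        [
            ([85.0] * 23, 30, 2550.0),
            ([60.0], 30, 1800.0),
            ([30.0, 90.0], 30, 1800.0),
        ],
    )
    def test_projected_duration(self, durations, weeks, expected):
        assert idx.projected_duration(durations, weeks) == pytest.approx(expected)

    def test_projected_duration_contracts(self):
        with pytest.raises(ValueError, match="no surveyed"):
            idx.projected_duration([])
        with pytest.raises(ValueError, match="missing"):
            idx.projected_duration([60.0, np.nan])


def _toy_tables():
    """6 sites; C and D have only 2 qualifying years; F's years lack surveys."""
    rows = []
    surveys = []
    for site, years, n_surv in [
        ("A", [2000, 2001, 2002, 2003], 12),
        ("B", [2000, 2001, 2002], 15),
        ("C", [2000, 2001], 12),
        ("D", [2001, 2002], 20),
        ("E", [2000, 2001, 2002, 2003, 2004], 10),
        ("F", [2000, 2001, 2002], 8),  # under 10 surveys: years never qualify
    ]:
        for y in years:
            for sp in ["sp1", "sp2"]:
                rows.append((site, y, sp, 5.0, 3.0, 2550.0, n_surv))
            for w in range(1, n_surv + 1):
                surveys.append((site, y, w, True))
    indices = pd.DataFrame(
        rows,
        columns=["site_id", "year", "species_id", "index", "mean_list_length",
                 "projected_duration_minutes", "n_surveys"],
    )
    surveys = pd.DataFrame(surveys, columns=["site_id", "year", "week", "surveyed"])
    return indices, surveys


class TestTrendFilters:
    def test_matches_brute_force_enumeration(self):
        indices, surveys = _toy_tables()
        filtered, elig = idx.apply_trend_filters(indices, surveys)
        # brute force: qualifying site-years then sites with >= 3 of them
        nsv = surveys.groupby(["site_id", "year"])["week"].size()
        qual = {(s, y) for (s, y), n in nsv.items() if n >= 10}
        sites_ok = {
            s for s in indices.site_id.unique()
            if sum(1 for (s2, _) in qual if s2 == s) >= 3
        }
        expected = {
            (r.site_id, r.year)
            for r in indices.itertuples()
            if (r.site_id, r.year) in qual and r.site_id in sites_ok
        }
        got = set(map(tuple, filtered[["site_id", "year"]].drop_duplicates().to_numpy()))
        assert got == expected
        assert sites_ok == {"A", "B", "E"}

    def test_species_eligibility_thresholds(self):
        indices, surveys = _toy_tables()
        # sp2 present at only 4 sites: ineligible but still in the table
        indices.loc[(indices.species_id == "sp2") & (indices.site_id == "E"),
                    "index"] = 0.0
        filtered, elig = idx.apply_trend_filters(
            indices, surveys, min_sites_species=3, min_years_species=3
        )
        assert elig["sp1"]
        assert not elig["sp2"]
        assert "sp2" in set(filtered.species_id)

    def test_filters_are_idempotent(self):
        indices, surveys = _toy_tables()
        once, elig1 = idx.apply_trend_filters(indices, surveys)
        twice, elig2 = idx.apply_trend_filters(once, surveys)
        pd.testing.assert_frame_equal(once, twice)
        assert elig1 == elig2

    def test_empty_input(self):
        indices, surveys = _toy_tables()
        out, elig = idx.apply_trend_filters(indices.iloc[:0], surveys)
        assert out.empty and elig == {}


class TestTotalAbundance:
    def test_sums_species_and_carries_covariates(self):
        indices, _ = _toy_tables()
        df = indices[indices.site_id == "A"].copy()
        df.loc[df.species_id == "sp1", "index"] = 3.5
        df.loc[df.species_id == "sp2", "index"] = 6.5
        out = idx.total_abundance_indices(df)
        assert (out["index"] == 10.0).all()
        assert (out["mean_list_length"] == 3.0).all()
        assert (out["species_id"] == "total").all()

    def test_single_species_passthrough(self):
        indices, _ = _toy_tables()
        one = indices[indices.species_id == "sp1"]
        out = idx.total_abundance_indices(one)
        assert np.allclose(out["index"], one["index"].to_numpy())

    def test_zero_total_rows_are_retained(self):
        indices, _ = _toy_tables()
        df = indices[indices.site_id == "A"].copy()
        df["index"] = 0.0
        out = idx.total_abundance_indices(df)
        assert len(out) == df.year.nunique()
        assert (out["index"] == 0.0).all()

    def test_conflicting_covariates_raise(self):
        indices, _ = _toy_tables()
        df = indices[indices.site_id == "A"].copy()
        df.loc[df.index[0], "mean_list_length"] = 99.0
        with pytest.raises(ValueError, match="conflicting"):
            idx.total_abundance_indices(df)


class TestSpeciesRows:
    def test_restricted_to_sites_where_species_recorded(self):
        indices, _ = _toy_tables()
        indices.loc[(indices.species_id == "sp1") & (indices.site_id == "A"),
                    "index"] = 0.0
        rows = idx.species_trend_rows(indices, "sp1")
        assert "A" not in set(rows.site_id)
        # zero rows at sites where the species was ever recorded stay
        indices.loc[
            (indices.species_id == "sp1") & (indices.site_id == "B")
            & (indices.year == 2000), "index"] = 0.0
        rows = idx.species_trend_rows(indices, "sp1")
        assert ((rows.site_id == "B") & (rows["index"] == 0)).any()
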