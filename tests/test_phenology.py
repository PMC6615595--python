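"""Degree-day arithmetic, eligibility filtering, flight curves, imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lepitrend import phenology as phen
from lepitrend import simdata


class TestDegreeDays:
    @pytest.mark.parametrize(
        "tmin, tmax, expected",
        [
            ([10, 10, 10], [20, 20, 20], [10, 20, 30]),
            ([-5], [3], [0]),  # increment floored at zero
            ([0, 10], [4, 30], [0, 15]),
        ],
    )
    def test_accumulation_examples(self, tmin, tmax, expected):
        np.testing.assert_allclose(
            phen.accumulate_degree_days(tmin, tmax, base=5.0), expected
        )

    def test_rejects_tmax_below_tmin(self):
        with pytest.raises(ValueError, match="tmax"):
            phen.accumulate_degree_days([10.0], [5.0])
        with pytest.raises(ValueError, match="equal length"):
            phen.accumulate_degree_days([1.0, 2.0], [3.0])

    @given(
        tmean=st.lists(st.floats(-20, 40), min_size=2, max_size=40),
        split=st.integers(1, 39),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_accumulation_is_chunk_associative(self, tmean, split):
        # accumulating a full series equals accumulating chunks and offsetting
        tmean = np.asarray(tmean)
        tmin, tmax = tmean - 5, tmean + 5
        split = min(split, len(tmean) - 1)
        full = phen.accumulate_degree_days(tmin, tmax)
        a = phen.accumulate_degree_days(tmin[:split], tmax[:split])
        b = phen.accumulate_degree_days(tmin[split:], tmax[split:]) + a[-1]
        np.testing.assert_allclose(np.concatenate([a, b]), full, rtol=1e-12)

    def test_table_accumulates_within_site_year(self):
        temps = pd.DataFrame(
            {
                "site_id": ["A"] * 4,
                "year": [2000, 2000, 2001, 2001],
                "doy": [1, 2, 1, 2],
                "tmin": [10.0] * 4,
                "tmax": [20.0] * 4,
            }
        )
        out = phen.degree_day_table(temps)
        np.testing.assert_allclose(out["gdd"], [10, 20, 10, 20])


class TestEligibility:
    def _surveys(self, n_surveyed):
        weeks = np.arange(1, 31)
        return pd.DataFrame(
            {
                "site_id": "A",
                "year": 2000,
                "week": weeks,
                "surveyed": weeks <= n_surveyed,
            }
        )

    def test_threshold_is_inclusive_at_five(self):
        assert len(phen.eligible_for_phenology(self._surveys(5))) == 30
        assert len(phen.eligible_for_phenology(self._surveys(4))) == 0

    def test_empty_table_passes_through(self):
        empty = self._surveys(5).iloc[:0]
        assert phen.eligible_for_phenology(empty).empty

    def test_retained_rows_unchanged(self):
        s = self._surveys(10)
        out = phen.eligible_for_phenology(s)
        pd.testing.assert_frame_equal(out, s)


def _training_frame(sim):
    surveys = phen.eligible_for_phenology(sim.surveys)
    gdd = phen.degree_day_table(sim.temperatures)
    sched = surveys.merge(gdd, on=["site_id", "year", "doy"], how="left")
    sched = sched.merge(sim.sites, on="site_id", how="left")
    grid = sched.merge(
        sim.counts[["site_id", "year", "week", "count"]],
        on=["site_id", "year", "week"], how="left",
    )
    grid.loc[grid["surveyed"] & grid["count"].isna(), "count"] = 0.0
    return grid


class TestFlightCurve:
    def test_refuses_all_zero_counts(self):
        df = pd.DataFrame(
            {
                "site_id": ["A", "B"] * 15,
                "count": 0.0,
                "gdd": np.linspace(100, 2000, 30),
                "latitude": 40.0,
                "longitude": -83.0,
                "year": 2000,
            }
        )
        with pytest.raises(ValueError, match="no phenology signal"):
            phen.fit_flight_curve(df)

    def test_refuses_sparse_training_data(self):
        df = pd.DataFrame(
            {
                "site_id": "A",
                "count": [1.0] * 10,
                "gdd": np.linspace(100, 2000, 10),
                "latitude": 40.0,
                "longitude": -83.0,
                "year": 2000,
            }
        )
        with pytest.raises(ValueError, match="nonzero-count"):
            phen.fit_flight_curve(df)

    def test_flat_truth_gives_flat_curve(self):
        # counts with no phenology structure: fitted curve ratio stays < 1.2
        rng = np.random.default_rng(0)
        n = 4000
        df = pd.DataFrame(
            {
                "site_id": rng.choice(list("ABCDEFGH"), n),
                "count": rng.poisson(5.0, n).astype(float),
                "gdd": rng.uniform(150, 2500, n),
                "latitude": rng.uniform(39, 41, n),
                "longitude": rng.uniform(-84, -82, n),
                "year": rng.choice([2000, 2001, 2002], n),
            }
        )
        model = phen.fit_flight_curve(df)
        gg = np.linspace(200, 2400, 200)
        mu, _ = model.predict(gg, 40.0, -83.0, 2000)
        assert mu.max() / mu.min() < 1.2

    def test_bivoltine_truth_recovers_two_peaks(self):
        spec = simdata.SpeciesSpec("bi", "bivoltine", [450.0, 1000.0], 80.0,
                                   np.log(300.0))
        cfg = simdata.SimConfig(
            species_specs=[spec], n_sites=25, n_years=4,
            sd_site=0.2, sd_year=0.1, sd_obs=0.2, seed=6,
        )
        sim = simdata.simulate_monitoring(cfg)
        grid = _training_frame(sim)
        model = phen.fit_flight_curve(grid[grid["surveyed"]], species_id="bi")
        gg = np.linspace(*model.gdd_range, 2000)
        mu, _ = model.predict(
            gg, sim.sites["latitude"].median(), sim.sites["longitude"].median(),
            model.year_levels[0],
        )
        from scipy.signal import argrelmax

        peaks = gg[argrelmax(mu, order=60)[0]]
        assert any(abs(p - 450.0) <= 50 for p in peaks)
        assert any(abs(p - 1000.0) <= 50 for p in peaks)

    def test_prediction_invariant_to_row_order(self, tiny_pipeline):
        sim = tiny_pipeline["sim"]
        grid = _training_frame(sim)
        sp = sorted(sim.counts["species_id"].unique())[0]
        spc = sim.counts[sim.counts["species_id"] == sp]
        g = _training_frame(sim)
        train = g[g["surveyed"]]
        m1 = phen.fit_flight_curve(train, species_id=sp)
        shuffled = train.sample(frac=1.0, random_state=0)
        m2 = phen.fit_flight_curve(shuffled, species_id=sp)
        gg = np.linspace(*m1.gdd_range, 50)
        mu1, _ = m1.predict(gg, 40.0, -83.0, m1.year_levels[0])
        mu2, _ = m2.predict(gg, 40.0, -83.0, m2.year_levels[0])
        np.testing.assert_allclose(mu1, mu2, rtol=1e-6)


class TestImputation:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted():
        spec = simdata.SpeciesSpec("uni", "univoltine", [700.0], 120.0, np.log(250.0))
        cfg = simdata.SimConfig(
            species_specs=[spec], n_sites=15, n_years=3,
            sd_site=0.2, sd_year=0.1, sd_obs=0.2, seed=17,
        )
        sim = simdata.simulate_monitoring(cfg)
        grid = _training_frame(sim)
        model = phen.fit_flight_curve(grid[grid["surveyed"]], species_id="uni")
        return model, grid

    def test_no_missing_weeks_is_identity(self, fitted):
        model, grid = fitted
        full = grid[grid["surveyed"]].copy()
        out = phen.impute_missing_counts(model, full)
        assert not out["imputed"].any()
        pd.testing.assert_frame_equal(out.drop(columns="imputed"), full)

    def test_observed_counts_pass_through_bit_exact(self, fitted):
        model, grid = fitted
        out = phen.impute_missing_counts(model, grid)
        obs = grid["count"].notna()
        assert (out.loc[obs, "count"] == grid.loc[obs, "count"]).all()
        assert out["count"].notna().all()
        assert (out.loc[~obs, "count"] >= 0).all()
        assert out.loc[~obs, "imputed"].all()

    def test_peak_week_imputes_more_than_tail_week(self, fitted):
        model, grid = fitted
        one = grid[(grid["site_id"] == grid["site_id"].iloc[0])
                   & (grid["year"] == grid["year"].iloc[0])].copy()
        one["count"] = np.nan  # all weeks missing: full predicted curve
        out = phen.impute_missing_counts(model, one)
        assert out["imputed"].all()
        by_week = out.set_index("week")["count"]
        peak_week = (np.abs(one.set_index("week")["gdd"] - 700.0)).idxmin()
        tail_week = one["week"].max()
        assert by_week[peak_week] > by_week[tail_week]

    def test_unknown_year_left_unfilled_with_warning(self, fitted):
        model, grid = fitted
        one = grid.head(5).copy()
        one["year"] = 1900
        one["count"] = np.nan
        with pytest.warns(UserWarning, match="outside model support"):
            out = phen.impute_missing_counts(model, one)
        assert out["count"].isna().all()
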