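"""The synthetic monitoring generator: construction contracts and marginals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lepitrend import simdata


def _two_site_table():
    return pd.DataFrame(
        {"site_id": ["A", "B"], "latitude": [39.0, 41.0], "longitude": [-83.0, -83.0]}
    )


class TestTemperatures:
    def test_latitude_gradient_sets_mean_difference(self):
        # zero day-noise: two sites 2 degrees apart differ by 2 x gradient
        temps = simdata.simulate_temperatures(
            _two_site_table(), years=1, seed=0, noise_sd_c=0.0,
            temp_gradient_per_degree_lat=-2.5,
        )
        means = temps.assign(tmean=(temps.tmin + temps.tmax) / 2).groupby("site_id")[
            "tmean"
        ].mean()
        assert means["A"] - means["B"] == pytest.approx(2 * 2.5, abs=1e-9)

    def test_same_seed_reproduces_series(self):
        a = simdata.simulate_temperatures(_two_site_table(), years=2, seed=42)
        b = simdata.simulate_temperatures(_two_site_table(), years=2, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_gives_exact_diurnal_range(self):
        temps = simdata.simulate_temperatures(
            _two_site_table(), years=1, seed=0, noise_sd_c=0.0, diurnal_range_c=10.0
        )
        assert np.allclose(temps.tmax - temps.tmin, 10.0)

    def test_tmax_never_below_tmin(self):
        temps = simdata.simulate_temperatures(_two_site_table(), years=3, seed=7,
                                              noise_sd_c=5.0)
        assert (temps.tmax >= temps.tmin).all()

    def test_nonfinite_latitude_rejected(self):
        bad = _two_site_table().assign(latitude=[39.0, np.nan])
        with pytest.raises(ValueError, match="latitude"):
            simdata.simulate_temperatures(bad, years=1)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sd_site": -0.1},
            {"missing_week_prob": 1.0},
            {"weeks_per_season": 1},
            {"n_sites": 0},
            {"n_years": 1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        spec = simdata.SpeciesSpec("s1", "univoltine", [800.0], 100.0, 3.0)
        with pytest.raises(ValueError):
            simdata.SimConfig(species_specs=[spec], **kwargs)

    def test_brood_count_must_match_voltinism(self):
        with pytest.raises(ValueError, match="brood"):
            simdata.SpeciesSpec("s1", "bivoltine", [500.0], 100.0, 3.0)
        with pytest.raises(ValueError, match="brood"):
            simdata.SpeciesSpec("s1", "multivoltine", [300.0, 900.0], 100.0, 3.0)


class TestMonitoring:
    def test_same_config_gives_identical_tables(self):
        spec = simdata.SpeciesSpec("s1", "univoltine", [800.0], 100.0, 4.0)
        cfg = simdata.SimConfig(species_specs=[spec], n_sites=4, n_years=3, seed=99)
        a = simdata.simulate_monitoring(cfg)
        b = simdata.simulate_monitoring(cfg)
        pd.testing.assert_frame_equal(a.surveys, b.surveys)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.temperatures, b.temperatures)

    def test_counts_only_for_surveyed_weeks(self, tiny_sim):
        surveyed = tiny_sim.surveys[tiny_sim.surveys.surveyed]
        keys_counts = set(map(tuple, tiny_sim.counts[["site_id", "year", "week"]]
                              .drop_duplicates().to_numpy()))
        keys_surveyed = set(map(tuple, surveyed[["site_id", "year", "week"]].to_numpy()))
        assert keys_counts <= keys_surveyed
        assert surveyed["duration_min"].gt(0).all()
        # at most one record per site x year x week x species
        assert not tiny_sim.counts.duplicated(
            ["site_id", "year", "week", "species_id"]
        ).any()

    def test_missing_fraction_matches_binomial(self):
        spec = simdata.SpeciesSpec("s1", "univoltine", [800.0], 100.0, 2.0)
        cfg = simdata.SimConfig(
            species_specs=[spec], n_sites=25, n_years=10,
            missing_week_prob=0.23, seed=5,
        )
        sim = simdata.simulate_monitoring(cfg)
        n = len(sim.surveys)
        frac = 1.0 - sim.surveys["surveyed"].mean()
        mc_se = np.sqrt(0.23 * 0.77 / n)
        assert abs(frac - 0.23) < 4 * mc_se

    def test_zero_sd_weekly_means_match_analytic_expectation(self):
        # all random effects off, no trend, full coverage, fixed duration:
        # weekly counts are iid Poisson with mean exp(b0) * flight-curve mass
        b0, peak, bsd = np.log(150.0), 800.0, 120.0
        spec = simdata.SpeciesSpec("s1", "univoltine", [peak], bsd, b0)
        cfg = simdata.SimConfig(
            species_specs=[spec], n_sites=1, n_years=30,
            sd_site=0.0, sd_year=0.0, sd_obs=0.0,
            missing_week_prob=0.0, duration_sd_minutes=0.0, seed=11,
        )
        sim = simdata.simulate_monitoring(cfg)
        from lepitrend.phenology import degree_day_table

        gdd = degree_day_table(sim.temperatures)
        merged = sim.counts.merge(sim.surveys, on=["site_id", "year", "week"])
        # independent analytic weekly mass: mixture CDF difference at week bounds
        realized, expected, ses = [], [], []
        for (year, week), grp in merged.groupby(["year", "week"]):
            g = gdd[gdd.year == year].set_index("doy")["gdd"]
            lo = np.interp(91 + 7 * (week - 1), g.index, g.to_numpy())
            hi = np.interp(91 + 7 * week, g.index, g.to_numpy())
            mass = stats.norm.cdf(hi, peak, bsd) - stats.norm.cdf(lo, peak, bsd)
            expected.append(np.exp(b0) * mass)
            realized.append(grp["count"].mean())
            ses.append(np.sqrt(np.exp(b0) * mass / len(grp)))
        realized, expected, ses = map(np.array, (realized, expected, ses))
        grand_se = np.sqrt(np.sum(ses**2)) / len(ses)
        assert abs(realized.mean() - expected.mean()) < 3 * grand_se

    def test_missingness_independent_of_latent_abundance(self):
        spec = simdata.SpeciesSpec("s1", "univoltine", [800.0], 100.0, 3.0)
        cfg = simdata.SimConfig(
            species_specs=[spec], n_sites=40, n_years=15, seed=21,
        )
        sim = simdata.simulate_monitoring(cfg)
        obs_eff = pd.Series(sim.truth["obs_effects"])
        frac = (
            sim.surveys.groupby(["site_id", "year"])["surveyed"].mean()
        )
        frac.index = pd.MultiIndex.from_tuples(
            [(s, int(y)) for s, y in frac.index]
        )
        joined = pd.concat([frac, obs_eff], axis=1, join="inner")
        r = np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1]
        assert abs(r) < 0.1

    def test_degenerate_flight_curve_warns_and_zeroes(self):
        spec = simdata.SpeciesSpec("s1", "univoltine", [90000.0], 50.0, 5.0)
        cfg = simdata.SimConfig(species_specs=[spec], n_sites=2, n_years=2, seed=3)
        with pytest.warns(UserWarning, match="no mass"):
            sim = simdata.simulate_monitoring(cfg)
        assert (sim.counts["count"] == 0).all()


class TestSerialization:
    def test_yaml_config_round_trip(self, tmp_path):
        spec = simdata.SpeciesSpec("s1", "bivoltine", [400.0, 1100.0], 90.0, 3.5,
                                   annual_trend=-0.02, migratory=True)
        cfg = simdata.SimConfig(species_specs=[spec], n_sites=3, n_years=4, seed=8)
        path = tmp_path / "config.yaml"
        simdata.config_to_yaml(cfg, path)
        back = simdata.config_from_yaml(path)
        assert back == cfg

    def test_survey_csv_and_truth_json(self, tiny_sim, tmp_path):
        simdata.write_survey_csv(tiny_sim, tmp_path / "surveys.csv")
        simdata.write_truth_json(tiny_sim, tmp_path / "truth.json")
        df = pd.read_csv(tmp_path / "surveys.csv")
        assert {"site_id", "year", "week", "date", "duration_min",
                "species_id", "count"} <= set(df.columns)
        assert len(df) == len(tiny_sim.counts)
        import json

        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth["species"]) == {s.species_id
                                         for s in tiny_sim.truth["config"].species_specs}
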