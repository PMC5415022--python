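"""Synthetic generator: configuration guards, statistical targets, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, spearmanr

from porpoisepam import detection, simulate


def _flat_config(**kw):
    base = dict(
        site_ids=("X",),
        start_date="2015-01-01",
        end_date="2016-03-01",
        seasonal_amplitude=0.0,
        diel_amplitude=(0.0,),
        diel_peak_hours=(0.0,),
        garma_phi=0.0,
        overdispersion_sigma=0.0,
        gap_schedule=[],
        seed=1,
    )
    base.update(kw)
    return simulate.SimulationConfig(**base)


class TestConfigValidation:
    def test_quality_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="simplex"):
            _flat_config(quality_class_probs=(0.5, 0.3, 0.3))

    def test_buzz_range_must_stay_below_threshold(self):
        with pytest.raises(ValueError, match="10,000"):
            _flat_config(buzz_ici_range=(2_000, 12_000))

    def test_travel_range_must_exceed_threshold(self):
        with pytest.raises(ValueError, match="exceed"):
            _flat_config(travel_ici_range=(8_000, 60_000))

    def test_dates_must_be_ordered(self):
        with pytest.raises(ValueError, match="end_date"):
            _flat_config(start_date="2016-01-01", end_date="2015-01-01")

    def test_mean_above_sixty_rejected(self):
        cfg = _flat_config(baseline_rate=30.0, seasonal_amplitude=1.5)
        with pytest.raises(ValueError, match="60"):
            simulate.simulate_occupancy(cfg)


class TestOccupancy:
    def test_homogeneous_poisson_mean(self):
        cfg = _flat_config(baseline_rate=3.0, end_date="2016-02-22")  # > 10,000 h
        truth = simulate.simulate_occupancy(cfg)
        y = truth.hours["minutes"].to_numpy()
        n = len(y)
        assert n >= 10_000
        tol = 4.0 * np.sqrt(3.0 / n)
        assert abs(np.mean(y) - 3.0) <= tol

    def test_zero_inflated_with_zero_baseline_emits_nothing(self):
        cfg = _flat_config(baseline_rate=1e-9, zero_inflation_pi=0.5)
        truth = simulate.simulate_occupancy(cfg)
        assert (truth.hours["minutes"] == 0).all()

    def test_pig_variance_matches_moment_formula(self):
        cfg = _flat_config(baseline_rate=5.0, overdispersion_sigma=0.5,
                           end_date="2017-05-01")  # > 20,000 h
        y = simulate.simulate_occupancy(cfg).hours["minutes"].to_numpy()
        assert len(y) >= 20_000
        assert np.var(y) == pytest.approx(5.0 * (1 + 0.5 * 5.0), rel=0.10)

    def test_minutes_bounded_and_mu_positive(self, small_truth):
        h = small_truth.hours
        assert h["minutes"].between(0, 60).all()
        assert (h["mu"] > 0).all()


class TestClickTrains:
    def test_foraging_hours_contain_buzz(self, small_truth, small_trains):
        t = small_trains.copy()
        t["hour_start"] = t["start"].dt.floor("h")
        min_ici = t.groupby(["site", "hour_start"])["icis"].apply(
            lambda g: np.min(np.concatenate(list(g)))
        )
        truth_hours = small_truth.hours.set_index(["site", "hour_start"])
        for key, mi in min_ici.items():
            row = truth_hours.loc[key]
            if row["foraging"]:
                assert mi <= 10_000
            else:
                assert mi > 10_000

    def test_every_train_has_at_least_five_clicks(self, small_trains):
        assert all(len(i) >= 4 for i in small_trains["icis"])

    def test_hours_with_zero_minutes_have_no_trains(self, small_truth, small_trains):
        t = small_trains.copy()
        t["hour_start"] = t["start"].dt.floor("h")
        with_trains = set(zip(t["site"], t["hour_start"]))
        zero = small_truth.hours.query("minutes == 0")
        assert not with_trains & set(zip(zero["site"], zero["hour_start"]))

    def test_no_trains_during_gaps(self, small_trains):
        b = small_trains[small_trains["site"] == "B"]
        gap = (b["start"] >= pd.Timestamp("2015-03-10")) & (
            b["start"] < pd.Timestamp("2015-03-20")
        )
        assert not gap.any()

    def test_quality_frequencies_within_binomial_bounds(self, small_trains):
        """Class counts fall inside exact 99% binomial intervals."""
        counts = small_trains["quality"].value_counts()
        n = len(small_trains)
        assert n > 1000
        for cls, p in zip(("Hi", "Med", "Low"), (0.5, 0.3, 0.2)):
            lo, hi = binom.ppf([0.005, 0.995], n, p)
            assert lo <= counts.get(cls, 0) <= hi, cls


class TestEnvironment:
    def test_constant_sst_when_amplitude_zero(self):
        cfg = _flat_config()
        cfg.env_params["sst_amplitude_c"] = 0.0
        env = simulate.simulate_environment(cfg)
        assert (env["sst_c"] == cfg.env_params["sst_mean_c"]).all()

    def test_moon_peak_spacing_matches_period(self):
        env = simulate.simulate_environment(_flat_config())
        m = env["moon_frac"].to_numpy()
        peaks = [i for i in range(1, len(m) - 1) if m[i] >= m[i - 1] and m[i] >= m[i + 1] and m[i] > 0.99]
        gaps = np.diff(peaks)
        assert set(gaps) <= {29, 30}

    def test_midsummer_chlorophyll_at_baseline(self):
        env = simulate.simulate_environment(_flat_config())
        july = env[pd.DatetimeIndex(env["date"]).month == 7]
        assert np.allclose(july["chla_mg_m3"], 0.8)

    def test_moon_fraction_in_unit_interval(self):
        env = simulate.simulate_environment(_flat_config())
        assert env["moon_frac"].between(0, 1).all()


class TestDensityPredictions:
    def test_noise_free_rank_order_matches_truth(self, small_truth):
        dens = simulate.simulate_density_predictions(small_truth, noise_sd=0.0)
        occ = simulate.true_monthly_occupancy(small_truth)
        merged = dens.merge(occ, on=["site", "month"])
        for _, grp in merged.groupby("site"):
            rho = spearmanr(grp["density_per_100km2"], grp["mean_minutes"]).statistic
            assert rho == pytest.approx(1.0)

    def test_twelve_or_fewer_rows_per_site_nonnegative(self, small_truth):
        dens = simulate.simulate_density_predictions(small_truth)
        assert (dens["density_per_100km2"] >= 0).all()
        assert dens.groupby("site").size().le(12).all()

    def test_noisy_density_rank_agrees_with_monte_carlo_oracle(self):
        """Mean Spearman under noise matches a direct simulation oracle."""
        cfg = _flat_config(baseline_rate=0.5, seasonal_amplitude=1.0,
                           end_date="2016-01-01", density_noise_sd=0.4)
        truth = simulate.simulate_occupancy(cfg)
        occ = simulate.true_monthly_occupancy(truth)
        x = occ["mean_minutes"].to_numpy()
        rng = np.random.default_rng(99)
        # package path: repeated noisy density tables
        rhos = []
        for _ in range(200):
            d = simulate.simulate_density_predictions(truth, rng=rng)
            m = d.merge(occ, on=["site", "month"])
            rhos.append(spearmanr(m["density_per_100km2"], m["mean_minutes"]).statistic)
        # oracle: direct Monte-Carlo of rank corr between x and x * lognormal noise
        rng2 = np.random.default_rng(7)
        oracle = np.mean(
            [
                spearmanr(x, x * np.exp(rng2.normal(0, 0.4, len(x)))).statistic
                for _ in range(4000)
            ]
        )
        assert np.mean(rhos) == pytest.approx(oracle, abs=0.1)


class TestDeterminism:
    def test_identical_seed_byte_identical_tables(self, tmp_path):
        cfg = simulate.SimulationConfig(
            site_ids=("A",), start_date="2015-01-01", end_date="2015-03-01",
            baseline_rate=0.1, seed=5,
        )
        a = simulate.write_all(cfg, tmp_path / "a")
        b = simulate.write_all(cfg, tmp_path / "b")
        for name in ("trains", "effort", "environment", "density"):
            fa = (tmp_path / "a" / f"{name}.csv").read_bytes()
            fb = (tmp_path / "b" / f"{name}.csv").read_bytes()
            assert fa == fb, name

    def test_different_seed_changes_counts(self):
        cfg1 = _flat_config(baseline_rate=1.0, seed=1, end_date="2015-02-01")
        cfg2 = _flat_config(baseline_rate=1.0, seed=2, end_date="2015-02-01")
        y1 = simulate.simulate_occupancy(cfg1).hours["minutes"]
        y2 = simulate.simulate_occupancy(cfg2).hours["minutes"]
        assert not (y1 == y2).all()
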