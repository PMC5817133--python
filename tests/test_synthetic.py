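import numpy as np
import pandas as pd
import pytest

from ttherm import Individual, SyntheticConfig
from ttherm.errors import ParameterError
from ttherm.synthetic import (
    activity_window,
    generate_trial,
    heat_exchange_rate,
    simulate_activity,
    simulate_core_temperature,
    simulate_environment,
    simulate_surface_temperatures,
    sinusoid_response,
)
from ttherm.response import daily_summaries
from ttherm.rhythms import Cosinor, acrophase_lag


class TestEnvironment:
    def test_noiseless_sinusoid_hits_closed_form_extremes(self):
        cfg = SyntheticConfig(
            days=3, noise_sd=0, day_effect_sd=0, shade_mesor=25, shade_amplitude=5
        )
        shade, _ = simulate_environment(cfg)
        daily = daily_summaries(shade)
        assert daily["min"].to_numpy() == pytest.approx(20.0, abs=0.01)
        assert daily["max"].to_numpy() == pytest.approx(30.0, abs=0.01)
        assert daily["range"].to_numpy() == pytest.approx(10.0, abs=0.02)

    def test_zero_sun_excess_makes_sun_identical_to_shade(self):
        cfg = SyntheticConfig(days=3, sun_excess_peak=0.0, seed=5)
        shade, sun = simulate_environment(cfg)
        assert np.array_equal(shade.data.to_numpy(), sun.data.to_numpy())

    def test_same_seed_reproduces_different_seed_varies(self):
        cfg = SyntheticConfig(days=3, seed=7)
        a1, _ = simulate_environment(cfg)
        a2, _ = simulate_environment(cfg)
        b, _ = simulate_environment(cfg, seed=8)
        assert np.array_equal(a1.data.to_numpy(), a2.data.to_numpy())
        assert not np.array_equal(a1.data.to_numpy(), b.data.to_numpy())

    def test_sun_never_below_shade_and_equal_at_night(self, small_env):
        shade, sun = small_env
        diff = sun.data - shade.data
        assert (diff >= -1e-9).all()
        hours = shade.data.index.hour
        night = (hours < 6) | (hours >= 18)
        assert np.allclose(diff[night], 0.0)


class TestActivity:
    def test_bimodal_profile_with_higher_morning_mode(self):
        cfg = SyntheticConfig(
            days=20,
            seed=2,
            noise_sd=0,
            day_effect_sd=0,
            shade_mesor=28.5,
            shade_amplitude=0.0,  # temperature always inside the window
        )
        shade, _ = simulate_environment(cfg)
        states, _ = simulate_activity(shade, cfg)
        hourly = states.groupby(states.index.hour).mean()
        morning = hourly.loc[7:10].max()
        afternoon = hourly.loc[15:19].max()
        trough = hourly.loc[12:14].min()
        assert morning > afternoon > trough
        assert morning > 0.5

    def test_flat_drive_and_optimal_temperature_gives_full_daytime_activity(self):
        cfg = SyntheticConfig(
            days=3, noise_sd=0, day_effect_sd=0, shade_mesor=28.5, shade_amplitude=0.0
        )
        shade, _ = simulate_environment(cfg)
        states, _ = simulate_activity(shade, cfg, drive=lambda h: np.ones_like(h))
        day = states[states.index.hour >= 6]
        assert (day == 1).all()

    def test_window_taper_suppresses_activity_10C_above_preference(self):
        w = activity_window(np.array([41.0]), 26.0, 31.0, scale=1.0)
        assert w[0] < 0.05

    def test_no_activity_between_midnight_and_6am(self, small_trial):
        states = small_trial["states"]
        night = states[states.index.hour < 6]
        assert (night == 0).all()

    def test_burst_frame_covers_recording_hours_only(self, small_trial):
        bursts = small_trial["bursts"]
        assert (bursts.index.hour >= 6).all()
        assert bursts.shape[1] == 36


class TestCoreTemperature:
    def test_fast_equilibration_tracks_forcing(self, quiet_config):
        shade, sun = simulate_environment(quiet_config)
        cfg = SyntheticConfig(**{**quiet_config.__dict__, "k0": 1000.0})
        core = simulate_core_temperature(shade, sun, None, Individual("x", 1.0), cfg)
        # k*dt = 250 >> 20: core equals the step-midpoint forcing
        mid = 0.5 * (shade.data.to_numpy()[:-1] + shade.data.to_numpy()[1:])
        assert np.allclose(core.data.to_numpy()[1:], mid, atol=1e-6)

    def test_zero_rate_keeps_initial_temperature(self, quiet_config):
        shade, sun = simulate_environment(quiet_config)
        cfg = SyntheticConfig(**{**quiet_config.__dict__, "k0": 1e-12})
        core = simulate_core_temperature(shade, sun, None, Individual("x", 1.0), cfg, t0=30.0)
        assert np.allclose(core.data.to_numpy(), 30.0, atol=1e-6)

    @pytest.mark.parametrize("mass", [10.0, 70.0, 250.0])
    def test_sinusoid_steady_state_matches_first_order_closed_form(
        self, quiet_config, mass
    ):
        shade, sun = simulate_environment(quiet_config)
        core = simulate_core_temperature(shade, sun, None, Individual("x", mass), quiet_config)
        warm = core.data.index >= core.data.index[0] + pd.Timedelta(days=3)
        fit_c = Cosinor(core.data[warm]).fit()
        fit_e = Cosinor(shade.data[warm]).fit()
        k = heat_exchange_rate(mass, quiet_config.k0, quiet_config.mass_exponent)
        ratio, lag = sinusoid_response(k)
        assert fit_c.amplitude / fit_e.amplitude == pytest.approx(ratio, rel=0.01)
        assert acrophase_lag(fit_c, fit_e) == pytest.approx(lag, abs=0.1)

    def test_daily_core_range_strictly_decreases_with_mass(self, quiet_config):
        shade, sun = simulate_environment(quiet_config)
        ranges = []
        for mass in (40.0, 80.0, 160.0):
            core = simulate_core_temperature(shade, sun, None, Individual("x", mass), quiet_config)
            ranges.append(daily_summaries(core)["range"].mean())
        assert ranges[0] > ranges[1] > ranges[2]

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ParameterError):
            Individual("x", 0.0)


class TestSurface:
    def test_region_daily_ranges_strictly_ordered(self, small_trial, fast_config):
        surf = simulate_surface_temperatures(
            small_trial["shade"], small_trial["sun"], small_trial["core"], fast_config
        )
        ranges = {}
        for group in ("carapace", "extremity", "skinfold"):
            sub = surf[surf["region"].str.startswith(group)]
            mean_ts = sub.groupby("timestamp")["temperature_c"].mean()
            daily = mean_ts.groupby(mean_ts.index.normalize()).agg(["min", "max", "count"])
            daily = daily[daily["count"] >= 8]
            ranges[group] = (daily["max"] - daily["min"]).mean()
        core_daily = daily_summaries(small_trial["core"])["range"].mean()
        assert ranges["carapace"] > ranges["extremity"] > ranges["skinfold"] > 0
        assert ranges["skinfold"] > core_daily or ranges["skinfold"] == pytest.approx(
            core_daily, rel=0.3
        )

    def test_weight_extremes_reduce_to_core_or_environment(self, small_trial):
        cfg = SyntheticConfig(days=4, seed=11, surface_weights=(1.0, 0.5, 0.0), surface_noise_sd=0.0)
        surf = simulate_surface_temperatures(
            small_trial["shade"], small_trial["sun"], small_trial["core"], cfg
        )
        core = small_trial["core"].data
        skin = surf[surf["region"] == "skinfold_1"].set_index("timestamp")["temperature_c"]
        matched = core.reindex(skin.index).dropna()
        assert np.allclose(skin[matched.index], matched, atol=0.01)


class TestGenerateTrial:
    def test_trial_dimensions_and_determinism(self, tmp_path):
        cfg = SyntheticConfig(days=10, masses_kg=(40.0, 160.0), seed=3)
        t1 = generate_trial(cfg, outdir=tmp_path / "a")
        assert len(t1.core) == 2
        assert all(len(c) == 960 for c in t1.core)  # 10 d x 96 samples
        t2 = generate_trial(cfg, outdir=tmp_path / "b")
        m1 = (tmp_path / "a" / "manifest.yaml").read_text()
        m2 = (tmp_path / "b" / "manifest.yaml").read_text()
        assert m1 == m2  # identical digests => byte-identical files

    def test_single_day_config_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticConfig(days=1).validate()
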