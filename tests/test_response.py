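import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ttherm.io_core import BodyCoreSeries
from ttherm.response import (
    daily_summaries,
    heating_cooling_rates,
    kendall_tau,
    range_quotient,
    rank_sum_test,
    surface_gradient_profile,
    ta_mean_series,
    trial_summary_table,
)
from ttherm.synthetic import SyntheticConfig, simulate_surface_temperatures

from conftest import make_series


def kendall_oracle(x, y):
    """O(n^2) pair-counting tau-b with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom > 0 else np.nan


class TestDailySummaries:
    def test_constant_day(self):
        s = make_series(np.full(96, 25.0))
        d = daily_summaries(s)
        assert len(d) == 1
        assert d["range"].iloc[0] == 0.0
        assert d["mean"].iloc[0] == 25.0

    def test_sinusoid_daily_range_is_twice_amplitude(self):
        idx = pd.date_range("2014-04-01", periods=192, freq="15min")
        t = (idx - idx[0]).total_seconds().to_numpy() / 3600.0
        s = pd.Series(25 + 5 * np.cos(2 * np.pi * (t - 14) / 24), index=idx)
        d = daily_summaries(s)
        assert d["range"].to_numpy() == pytest.approx(10.0, abs=0.02)

    def test_matches_bruteforce_loop(self, rng):
        vals = rng.uniform(15, 40, 96 * 3)
        s = make_series(vals)
        d = daily_summaries(s)
        for date, row in d.iterrows():
            day_vals = s[s.index.normalize() == date]
            assert row["min"] == day_vals.min()
            assert row["max"] == day_vals.max()
            assert row["mean"] == pytest.approx(day_vals.mean())
            assert row["range"] == row["max"] - row["min"]

    def test_partial_days_skipped_by_coverage(self):
        s = make_series(np.arange(96 + 30, dtype=float))  # day 2 has 30/96 samples
        d = daily_summaries(s, coverage_threshold=0.75)
        assert len(d) == 1

    def test_translation_and_scaling_of_range(self, rng):
        vals = rng.uniform(15, 40, 96)
        s = make_series(vals)
        base = daily_summaries(s)["range"].iloc[0]
        assert daily_summaries(s + 7.0)["range"].iloc[0] == pytest.approx(base)
        assert daily_summaries(s * 3.0)["range"].iloc[0] == pytest.approx(3 * base)


class TestRangeQuotient:
    def _daily(self, ranges):
        dates = pd.date_range("2014-04-01", periods=len(ranges))
        return pd.DataFrame({"range": ranges}, index=dates)

    def test_representative_trial_values(self):
        out = range_quotient(self._daily([3.7]), self._daily([6.5]))
        assert out["quotient"].iloc[0] == pytest.approx(0.569, abs=5e-4)

    def test_equal_ranges_give_one(self):
        out = range_quotient(self._daily([4.0]), self._daily([4.0]))
        assert out["quotient"].iloc[0] == 1.0
        assert not out["exceeds_one"].iloc[0]

    def test_zero_air_range_flagged_undefined(self):
        out = range_quotient(self._daily([2.0]), self._daily([0.0]))
        assert out["undefined"].iloc[0]
        assert np.isnan(out["quotient"].iloc[0])

    def test_quotient_above_one_flagged_kept(self):
        out = range_quotient(self._daily([8.0]), self._daily([5.0]))
        assert out["exceeds_one"].iloc[0]
        assert out["quotient"].iloc[0] == pytest.approx(1.6)


class TestHeatingCoolingRates:
    def test_linear_ramp_recovers_slope(self):
        idx = pd.date_range("2014-04-01 06:00", periods=33, freq="15min")  # to 14:00
        t = (idx - idx[0]).total_seconds().to_numpy() / 3600.0
        s = pd.Series(20 + 0.5 * t, index=idx)
        rates = heating_cooling_rates(s)
        assert rates["heating_rate"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_constant_series_zero_rate(self):
        idx = pd.date_range("2014-04-01 00:00", periods=96, freq="15min")
        rates = heating_cooling_rates(pd.Series(25.0, index=idx))
        assert rates["heating_rate"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples_flagged_nan(self):
        idx = pd.date_range("2014-04-01 06:00", periods=3, freq="15min")
        rates = heating_cooling_rates(pd.Series([20.0, 21.0, 22.0], index=idx))
        assert np.isnan(rates["heating_rate"].iloc[0])

    def test_cooling_magnitude_decreases_with_mass(self, quiet_config):
        from ttherm import Individual
        from ttherm.synthetic import simulate_core_temperature, simulate_environment

        shade, sun = simulate_environment(quiet_config)
        mags = []
        for m in (40.0, 80.0, 160.0):
            core = simulate_core_temperature(shade, sun, None, Individual("x", m), quiet_config)
            rates = heating_cooling_rates(core.data)
            mags.append(abs(rates["cooling_rate"].dropna().mean()))
        assert mags[0] > mags[1] > mags[2]


class TestKendallTau:
    def test_perfectly_concordant(self):
        r = kendall_tau([1, 2, 3, 4], [2, 4, 6, 8])
        assert r.tau == pytest.approx(1.0)

    def test_perfectly_discordant(self):
        r = kendall_tau([1, 2, 3, 4], [8, 6, 4, 2])
        assert r.tau == pytest.approx(-1.0)

    def test_all_tied_flagged_undefined(self):
        r = kendall_tau([1, 1, 1], [1, 2, 3])
        assert not r.defined

    def test_small_sample_with_ties_matches_oracle_and_scipy(self, rng):
        x = rng.integers(0, 5, 8).astype(float)
        y = rng.integers(0, 5, 8).astype(float)
        r = kendall_tau(x, y)
        assert r.tau == pytest.approx(kendall_oracle(x, y), abs=1e-12)
        sp = stats.kendalltau(x, y)
        assert r.tau == pytest.approx(sp.statistic, abs=1e-12)
        assert r.p == pytest.approx(
            stats.kendalltau(x, y, method="asymptotic").pvalue, abs=1e-9
        )

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(3, 50),
        seed=st.integers(0, 10_000),
        tie_prob=st.sampled_from([0.0, 0.5]),
    )
    def test_matches_pair_counting_oracle(self, n, seed, tie_prob):
        rng = np.random.default_rng(seed)
        if tie_prob:
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, n).astype(float)
        else:
            x = rng.normal(size=n)
            y = rng.normal(size=n)
        expected = kendall_oracle(x, y)
        r = kendall_tau(x, y)
        if np.isnan(expected):
            assert not r.defined
        else:
            assert r.tau == pytest.approx(expected, abs=1e-12)


class TestRankSum:
    def test_identical_samples_give_large_p(self):
        r = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.p >= 0.9

    def test_extreme_separation_exact_p(self):
        r = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert r.method == "exact"
        assert r.p == pytest.approx(0.1)  # 2 extreme of C(6,3)=20 assignments

    def test_exact_enumeration_matches_scipy_without_ties(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(1, 1, 6)
        r = rank_sum_test(a, b)
        sp = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert r.method == "exact"
        assert r.p == pytest.approx(sp.pvalue, abs=1e-12)

    def test_large_sample_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1, 15)
        b = rng.normal(0.8, 1, 15)
        r = rank_sum_test(a, b)
        assert r.method == "normal"
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        obs = abs(ranks[:15].sum() - 15 * 31 / 2)
        count = 0
        n_perm = 20000
        for _ in range(n_perm):
            rng.shuffle(ranks)
            if abs(ranks[:15].sum() - 15 * 31 / 2) >= obs - 1e-9:
                count += 1
        assert r.p == pytest.approx(count / n_perm, abs=0.01)


class TestSurfaceGradient:
    def test_generator_regions_ordered_and_correlated(self, small_trial, fast_config):
        surf = simulate_surface_temperatures(
            small_trial["shade"], small_trial["sun"], small_trial["core"], fast_config
        )
        env = ta_mean_series(small_trial["shade"], small_trial["sun"])
        prof = surface_gradient_profile(surf, small_trial["core"], env=env)
        dr = prof.daily_ranges["daily_range"]
        assert dr["carapace"] > dr["extremity"] > dr["skinfold"] > dr["core"]
        assert all(r.tau > 0.5 for r in prof.correlations.values())
        # turning points: environment leads, core trails
        acro = prof.acrophases
        assert acro["environment"] < acro["carapace"] < acro["extremity"]
        assert acro["extremity"] < acro["skinfold"] < acro["core"]

    def test_surface_identical_to_core_gives_tau_one(self, small_trial):
        core = small_trial["core"]
        sub = core.data.iloc[::8]
        rows = []
        for region in ("carapace_scute_1", "extremity_1", "skinfold_1"):
            rows.append(
                pd.DataFrame(
                    {
                        "individual_id": core.individual_id,
                        "timestamp": sub.index,
                        "region": region,
                        "temperature_c": sub.to_numpy(),
                    }
                )
            )
        surf = pd.concat(rows, ignore_index=True)
        prof = surface_gradient_profile(surf, core)
        for r in prof.correlations.values():
            assert r.tau == pytest.approx(1.0)
        for t in prof.level_tests.values():
            assert t.p >= 0.9


class TestTrialSummary:
    def test_table_contains_all_series_with_expected_columns(self, small_trial):
        table = trial_summary_table(
            {"air_shade": small_trial["shade"], "core": small_trial["core"]}
        )
        assert set(table.index) == {"air_shade", "core"}
        assert {"mean", "sd", "min", "max", "daily_range", "acrophase_h"} <= set(table.columns)
        assert (table["max"] >= table["min"]).all()
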