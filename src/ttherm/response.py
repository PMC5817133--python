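"""Daily thermal statistics and the rank statistics used throughout.

Covers per-calendar-day min/max/mean/range summaries, the daily core-range
to air-range quotient (a thermal-lability index normalised by
environmental forcing), heating/cooling rates, the tie-corrected Kendall
tau-b with its z statistic, the Wilcoxon rank-sum test (exact by
enumeration at small n), and the surface-versus-core gradient profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, InsufficientDataError, ParameterError
from .io_core import BodyCoreSeries, LoggerSeries, REGION_GROUPS, align_series
from .rhythms import Cosinor

EXPECTED_PER_DAY = 96  # 15-min cadence


def _as_series(series) -> tuple[str, pd.Series]:
    if isinstance(series, LoggerSeries):
        return f"{series.placement}", series.data
    if isinstance(series, BodyCoreSeries):
        return series.individual_id, series.data
    return getattr(series, "name", "series") or "series", series


def daily_summaries(
    series,
    coverage_threshold: float = 0.75,
    expected_per_day: int = EXPECTED_PER_DAY,
) -> pd.DataFrame:
    """Per-calendar-day mean/min/max/range with coverage gating.

    Days with fewer than ``coverage_threshold * expected_per_day`` samples
    are skipped (partial days bias the min/max).  Returns a frame indexed
    by date with columns ``series_id, mean, min, max, range, n``.
    """
    series_id, data = _as_series(series)
    if len(data) == 0:
        raise EmptyInputError("daily_summaries: empty series")
    grouped = data.groupby(data.index.normalize())
    rows = []
    for date, vals in grouped:
        n = len(vals)
        if n < coverage_threshold * expected_per_day:
            continue
        rows.append(
            {
                "date": date,
                "series_id": series_id,
                "mean": vals.mean(),
                "min": vals.min(),
                "max": vals.max(),
                "range": vals.max() - vals.min(),
                "n": n,
            }
        )
    return pd.DataFrame(rows).set_index("date") if rows else pd.DataFrame(
        columns=["series_id", "mean", "min", "max", "range", "n"]
    )


def ta_mean_series(shade: LoggerSeries, sun: LoggerSeries) -> pd.Series:
    """Per-timestamp mean of the shade and sun loggers (the T_a mean envelope)."""
    sun_vals = sun.data.reindex(shade.data.index)
    return ((shade.data + sun_vals) / 2.0).dropna().rename("ta_mean")


def trial_summary_table(named_series: dict[str, object], coverage: float = 0.75) -> pd.DataFrame:
    """Study-period summary per series: overall mean/SD/min/max, mean daily
    range, and acrophase — the layout of the trial summary table."""
    rows = []
    for name, series in named_series.items():
        _, data = _as_series(series)
        daily = daily_summaries(series, coverage_threshold=coverage)
        fit = Cosinor(data).fit()
        rows.append(
            {
                "series": name,
                "mean": data.mean(),
                "sd": data.std(ddof=1),
                "min": data.min(),
                "max": data.max(),
                "daily_range": daily["range"].mean() if len(daily) else np.nan,
                "acrophase_h": fit.acrophase,
            }
        )
    return pd.DataFrame(rows).set_index("series")


def range_quotient(bc_daily: pd.DataFrame, air_daily: pd.DataFrame) -> pd.DataFrame:
    """Per-day ratio of core range to air range, matched by date.

    Ratios above 1 are legitimate (the shade logger can under-represent the
    envelope the animal actually occupied) and are flagged, not dropped;
    days with zero air range get an undefined flag.
    """
    merged = bc_daily[["range"]].join(
        air_daily[["range"]], how="inner", lsuffix="_bc", rsuffix="_air"
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = merged["range_bc"] / merged["range_air"]
    out = pd.DataFrame(
        {
            "range_bc": merged["range_bc"],
            "range_air": merged["range_air"],
            "quotient": ratio.where(merged["range_air"] > 0),
            "undefined": merged["range_air"] <= 0,
        }
    )
    out["exceeds_one"] = out["quotient"] > 1
    return out


def heating_cooling_rates(
    series: BodyCoreSeries | pd.Series,
    heating_window: tuple[str, str] = ("06:00", "14:00"),
    cooling_window: tuple[str, str] = ("19:00", "07:00"),
    min_samples: int = 4,
) -> pd.DataFrame:
    """Per-day least-squares heating and cooling slopes (degC/h).

    The heating window spans the morning rise; the cooling window crosses
    midnight (evening into next morning) and the rate is attributed to the
    evening's date.  Windows with fewer than ``min_samples`` points yield
    NaN.
    """
    _, data = _as_series(series)
    t_h = data.index.view("int64") / 3600e9

    def _slope(mask_vals: pd.Series) -> float:
        if len(mask_vals) < min_samples:
            return float("nan")
        t = mask_vals.index.view("int64") / 3600e9
        return float(np.polyfit(t - t[0], mask_vals.to_numpy(), 1)[0])

    del t_h
    minutes = np.asarray(data.index.hour) * 60 + np.asarray(data.index.minute)
    h0, h1 = (_cm(c) for c in heating_window)
    c0, c1 = (_cm(c) for c in cooling_window)
    dates = data.index.normalize()
    rows = []
    for date in pd.unique(dates):
        day_mask = dates == date
        heat = data[day_mask & (minutes >= h0) & (minutes <= h1)]
        # cooling crosses midnight: evening of `date` + morning of the next day
        next_day = dates == (date + pd.Timedelta(days=1))
        cool = pd.concat(
            [data[day_mask & (minutes >= c0)], data[next_day & (minutes <= c1)]]
        )
        rows.append(
            {
                "date": date,
                "heating_rate": _slope(heat),
                "cooling_rate": _slope(cool),
            }
        )
    return pd.DataFrame(rows).set_index("date")


def _cm(clock: str) -> int:
    h, m = clock.split(":")
    return int(h) * 60 + int(m)


# ---------------------------------------------------------------------------
# rank statistics


@dataclass
class KendallResult:
    tau: float
    z: float
    p: float
    n: int
    defined: bool = True


def kendall_tau(x, y) -> KendallResult:
    """Kendall tau-b with tie correction, normal-approximation z and two-sided p.

    tau-b = S / sqrt((n0 - n1)(n0 - n2)) with S the concordant-discordant
    excess; var(S) uses the tie-adjusted formula, giving z = S/sqrt(var(S)).
    All-tied input in either variable yields an undefined flag.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ParameterError("kendall_tau: unequal lengths")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("kendall_tau needs n >= 3")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    S = float(np.sum(np.triu(sx * sy, k=1)))
    n0 = n * (n - 1) / 2.0

    def tie_sizes(v: np.ndarray) -> np.ndarray:
        _, counts = np.unique(v, return_counts=True)
        return counts[counts > 1].astype(float)

    tx, ty = tie_sizes(x), tie_sizes(y)
    n1 = float(np.sum(tx * (tx - 1) / 2.0))
    n2 = float(np.sum(ty * (ty - 1) / 2.0))
    if n1 == n0 or n2 == n0:
        return KendallResult(float("nan"), float("nan"), float("nan"), n, defined=False)
    tau = S / np.sqrt((n0 - n1) * (n0 - n2))
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(tx * (tx - 1) * (2 * tx + 5)))
    vu = float(np.sum(ty * (ty - 1) * (2 * ty + 5)))
    v1 = float(np.sum(tx * (tx - 1)) * np.sum(ty * (ty - 1))) / (2.0 * n * (n - 1))
    v2 = (
        float(np.sum(tx * (tx - 1) * (tx - 2)) * np.sum(ty * (ty - 1) * (ty - 2)))
        / (9.0 * n * (n - 1) * (n - 2))
    )
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        return KendallResult(float(tau), float("nan"), float("nan"), n, defined=False)
    z = S / np.sqrt(var_s)
    p = 2.0 * stats.norm.sf(abs(z))
    return KendallResult(float(tau), float(z), float(p), n)


@dataclass
class RankSumResult:
    statistic: float  # rank sum of the first sample (midranks)
    p: float
    method: str  # "exact" or "normal"
    n_a: int
    n_b: int


def rank_sum_test(a, b, exact_max_n: int = 12) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    For combined n <= ``exact_max_n`` the null distribution of the rank sum
    is enumerated over all C(n, n_a) assignments (midranks, so ties are
    handled exactly); otherwise the normal approximation with continuity
    and tie correction is used.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise EmptyInputError("rank_sum_test: empty sample")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    w = float(ranks[:n_a].sum())
    mean_w = n_a * (n + 1) / 2.0
    if n <= exact_max_n:
        obs_dev = abs(w - mean_w)
        count = 0
        total = comb(n, n_a)
        for idx in combinations(range(n), n_a):
            if abs(ranks[list(idx)].sum() - mean_w) >= obs_dev - 1e-9:
                count += 1
        return RankSumResult(w, count / total, "exact", n_a, n_b)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return RankSumResult(w, 1.0, "normal", n_a, n_b)
    z = (abs(w - mean_w) - 0.5) / np.sqrt(var_w)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return RankSumResult(w, p, "normal", n_a, n_b)


# ---------------------------------------------------------------------------
# surface-vs-core gradients


@dataclass
class GradientProfile:
    """Region-level thermal gradients relative to the core."""

    daily_ranges: pd.DataFrame  # index: region, column: mean daily range
    correlations: dict[str, KendallResult]
    level_tests: dict[str, RankSumResult]
    acrophases: pd.Series  # region -> acrophase hours

    def summary(self) -> str:
        lines = ["Surface-vs-core gradient profile"]
        for region, row in self.daily_ranges.iterrows():
            tau = self.correlations.get(region)
            tau_s = f"tau={tau.tau:.2f} (p={tau.p:.3g})" if tau else ""
            lines.append(
                f"  {region:<10} daily range {row['daily_range']:5.2f} degC  {tau_s}"
            )
        order = self.acrophases.sort_values()
        lines.append("  acrophase order: " + " -> ".join(order.index))
        return "\n".join(lines)


def surface_gradient_profile(
    surface: pd.DataFrame,
    core: BodyCoreSeries,
    env: pd.Series | None = None,
    max_gap_min: float = 30.0,
) -> GradientProfile:
    """Aggregate the 21-site spot readings into region gradients vs the core.

    Carapace = mean of the 13 scutes per timestamp; extremities and skin
    folds = means of their 4 sites.  For each region: mean daily range,
    Kendall tau against the time-matched core, a rank-sum comparison of
    levels, and a cosinor acrophase (turning-point timing).
    """
    df = surface[surface["individual_id"] == core.individual_id]
    if len(df) == 0:
        df = surface
    region_series: dict[str, pd.Series] = {}
    for group, members in REGION_GROUPS.items():
        sub = df[df["region"].isin(members)]
        if len(sub) == 0:
            continue
        region_series[group] = sub.groupby("timestamp")["temperature_c"].mean()
    if not region_series:
        raise EmptyInputError("no surface readings in any region")
    daily_rows = {}
    correlations: dict[str, KendallResult] = {}
    level_tests: dict[str, RankSumResult] = {}
    acroph = {}
    series_for_phase: dict[str, pd.Series] = dict(region_series)
    series_for_phase["core"] = core.data
    if env is not None:
        series_for_phase["environment"] = env
    for name, s in series_for_phase.items():
        expected = max(4, int(round(len(s) / max(1, len(np.unique(s.index.normalize()))))))
        daily = daily_summaries(s.rename(name), expected_per_day=expected)
        daily_rows[name] = daily["range"].mean() if len(daily) else np.nan
        fit = Cosinor(s).fit()
        acroph[name] = fit.acrophase
    for name, s in region_series.items():
        paired = align_series(s, core.data, rule="nearest", max_gap_min=max_gap_min)
        if len(paired) >= 3:
            correlations[name] = kendall_tau(paired["value_a"], paired["value_b"])
            level_tests[name] = rank_sum_test(paired["value_a"], paired["value_b"])
    return GradientProfile(
        daily_ranges=pd.DataFrame.from_dict(
            daily_rows, orient="index", columns=["daily_range"]
        ),
        correlations=correlations,
        level_tests=level_tests,
        acrophases=pd.Series(acroph, name="acrophase_h"),
    )
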