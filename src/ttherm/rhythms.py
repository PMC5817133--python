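"""Cosinor (circular-linear) analysis of 24-h temperature rhythms.

A fixed-period cosine ``y = M + A cos(2 pi (t - phi) / P)`` is fitted by
ordinary least squares on the linear basis {1, cos, sin}: the mesor M is
the rhythm-adjusted mean, the amplitude A half the peak-to-trough swing,
and the acrophase phi the clock time of the fitted peak.  Acrophase lags
between series (e.g. core temperature behind air temperature) are circular
signed differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError

TWO_PI = 2.0 * np.pi


def _times_hours(obj, times=None) -> tuple[np.ndarray, np.ndarray]:
    """Extract (t_hours, y) from a pandas series or explicit arrays."""
    if isinstance(obj, pd.Series) and isinstance(obj.index, pd.DatetimeIndex):
        t0 = obj.index[0].normalize()
        t = (obj.index - t0).total_seconds().to_numpy() / 3600.0
        return t, obj.to_numpy(float)
    y = np.asarray(obj, float)
    if times is None:
        raise ParameterError("times= required when endog has no DatetimeIndex")
    return np.asarray(times, float), y


class Cosinor:
    """Single-component cosinor model with fixed period (default 24 h)."""

    def __init__(self, endog, times=None, period: float = 24.0):
        self.t, self.y = _times_hours(endog, times)
        if len(self.t) < 3 or len(np.unique(self.t)) < 3:
            raise InsufficientDataError("cosinor needs >= 3 distinct time points")
        if not period > 0:
            raise ParameterError("period must be > 0")
        self.period = period
        self.span_warning = (self.t.max() - self.t.min()) < period

    def fit(self) -> "CosinorResults":
        w = TWO_PI / self.period
        X = np.column_stack([np.ones_like(self.t), np.cos(w * self.t), np.sin(w * self.t)])
        beta, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        mesor, bc, bs = beta
        amplitude = float(np.hypot(bc, bs))
        resid = self.y - X @ beta
        rss = float(resid @ resid)
        scale = max(1.0, float(np.abs(self.y).max()))
        if amplitude < 1e-10 * scale:
            acrophase, defined = float("nan"), False
            amplitude = 0.0
        else:
            acrophase = float((np.arctan2(bs, bc) / w) % self.period)
            defined = True
        return CosinorResults(
            model=self,
            mesor=float(mesor),
            amplitude=amplitude,
            acrophase=acrophase,
            acrophase_defined=defined,
            period=self.period,
            rss=rss,
            n=len(self.y),
        )


@dataclass
class CosinorResults:
    model: Cosinor
    mesor: float
    amplitude: float
    acrophase: float  # hours in [0, period); NaN when undefined
    acrophase_defined: bool
    period: float
    rss: float
    n: int

    def predict(self, t_hours) -> np.ndarray:
        w = TWO_PI / self.period
        phi = 0.0 if not self.acrophase_defined else self.acrophase
        return self.mesor + self.amplitude * np.cos(w * (np.asarray(t_hours, float) - phi))

    def summary(self) -> str:
        acro = f"{self.acrophase:5.2f} h" if self.acrophase_defined else "undefined"
        return (
            "Cosinor fit (period {p:.0f} h, n={n})\n"
            "  mesor     : {m:7.3f} degC\n"
            "  amplitude : {a:7.3f} degC\n"
            "  acrophase : {acro}\n"
            "  RSS       : {rss:.3f}".format(
                p=self.period, n=self.n, m=self.mesor, a=self.amplitude, acro=acro, rss=self.rss
            )
        )

    def plot(self, ax=None):  # pragma: no cover - thin plotting shim
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.t, self.model.y, ".", ms=2, alpha=0.5, label="data")
        tt = np.linspace(self.model.t.min(), self.model.t.max(), 500)
        ax.plot(tt, self.predict(tt), "r-", label="cosinor")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("temperature (degC)")
        ax.legend()
        return ax


def cosinor_fit(series, times=None, period: float = 24.0) -> CosinorResults:
    """Convenience wrapper: ``Cosinor(series).fit()``."""
    return Cosinor(series, times=times, period=period).fit()


def acrophase_lag(a: CosinorResults, b: CosinorResults) -> float:
    """Circular signed acrophase difference a - b, mapped to (-12, +12] h.

    Positive means ``a`` peaks after ``b`` (e.g. core temperature lagging
    air temperature).  NaN when either acrophase is undefined.
    """
    if not (a.acrophase_defined and b.acrophase_defined):
        return float("nan")
    half = a.period / 2.0
    lag = (a.acrophase - b.acrophase) % a.period
    return float(lag - a.period) if lag > half else float(lag)


# ---------------------------------------------------------------------------
# discretised day periods


@dataclass(frozen=True)
class PeriodScheme:
    """Ordered, non-overlapping clock intervals labelling parts of the day."""

    boundaries: tuple[tuple[str, str, str], ...]  # (start, end, label)

    def __post_init__(self) -> None:
        mins = [(_clock_min(s), _clock_min(e), lab) for s, e, lab in self.boundaries]
        for s, e, lab in mins:
            if not 0 <= s <= e <= 24 * 60:
                raise ParameterError(f"period {lab}: interval outside 00:00-24:00")
        for (s1, e1, l1), (s2, e2, l2) in zip(mins, mins[1:]):
            if s2 < e1:
                raise ParameterError(f"periods {l1} and {l2} overlap")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for _, _, lab in self.boundaries)


def _clock_min(clock: str) -> int:
    h, m = clock.split(":")
    return int(h) * 60 + int(m)


#: Four activity periods following the activity turning points through the day.
ACTIVITY_PERIODS = PeriodScheme(
    (
        ("06:00", "08:00", "I"),
        ("08:15", "13:30", "II"),
        ("13:45", "17:30", "III"),
        ("17:45", "20:00", "IV"),
    )
)


def discretise_day(timestamps: pd.DatetimeIndex, scheme: PeriodScheme) -> pd.Series:
    """Label each timestamp with its containing period.

    Interval ends are inclusive at the labelled grid times; a timestamp in
    the short seam between one period's end and the next one's start (the
    15-min gaps of the activity scheme) belongs to the earlier period.
    Timestamps before the first start or after the last end are labelled
    ``"excluded"``.
    """
    ts = pd.DatetimeIndex(timestamps)
    minute = np.asarray(ts.hour) * 60 + np.asarray(ts.minute)
    bounds = [(_clock_min(s), _clock_min(e), lab) for s, e, lab in scheme.boundaries]
    labels = np.full(len(ts), "excluded", dtype=object)
    first_start = bounds[0][0]
    last_end = bounds[-1][1]
    in_span = (minute >= first_start) & (minute <= last_end)
    starts = np.array([s for s, _, _ in bounds])
    pos = np.searchsorted(starts, minute, side="right") - 1
    pos = np.clip(pos, 0, len(bounds) - 1)
    lab_arr = np.array([lab for _, _, lab in bounds], dtype=object)
    labels[in_span] = lab_arr[pos[in_span]]
    return pd.Series(labels, index=ts, name="period")


def thermoregulation_periods(
    core_series: list[pd.Series] | pd.Series, smooth_hours: float = 2.0
) -> PeriodScheme:
    """Trial-specific three-period scheme from the grand-mean core curve.

    The mean daily core-temperature curve (all individuals pooled) is
    smoothed with a moving mean of ``smooth_hours``; its minimum marks the
    end of the overnight cooling period (I) and the start of the heating
    period (II), and its maximum the start of the evening cooling period
    (III).  This is an approximation: the original trial-specific turning
    points are not published.
    """
    series = [core_series] if isinstance(core_series, pd.Series) else list(core_series)
    frames = []
    for s in series:
        minute = s.index.hour * 60 + s.index.minute
        frames.append(pd.DataFrame({"minute": np.asarray(minute), "y": s.to_numpy()}))
    prof = pd.concat(frames).groupby("minute")["y"].mean()
    step = int(np.median(np.diff(prof.index))) or 15
    win = max(1, int(round(smooth_hours * 60 / step)))
    smooth = prof.rolling(win, center=True, min_periods=1).mean()
    t_min = int(smooth.idxmin())
    t_max = int(smooth.idxmax())
    if t_min >= t_max:  # degenerate: fall back to a sensible morning/afternoon split
        t_min, t_max = 6 * 60, 16 * 60
    fmt = lambda m: f"{m // 60:02d}:{m % 60:02d}"
    return PeriodScheme(
        (
            ("00:00", fmt(t_min), "I"),
            (fmt(t_min + step), fmt(t_max), "II"),
            (fmt(t_max + step), "24:00", "III"),
        )
    )
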