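"""Data model and I/O for temperature-logger and accelerometer files.

All timestamps are naive local clock times (one site per trial; loggers
export local time).  Temperatures are stored at 0.01 degC resolution, which
exceeds the 0.05-0.06 degC accuracy of the field loggers.  The CSV dialect
is comma-separated UTF-8 with a header row and ISO-8601 ``YYYY-MM-DD HH:MM``
timestamps.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateTimestampError,
    EmptyInputError,
    MalformedBurstError,
    ParameterError,
    RowError,
    SchemaError,
)

#: Nominal logger cadence for environmental and core series.
ENV_CADENCE_MIN = 15
#: Nominal accelerometer burst cadence.
ACC_CADENCE_MIN = 5
#: Readings per accelerometer burst (5 s at 7.2 Hz).
BURST_LEN = 36
#: Plausibility bounds for ingested-logger core temperature, degC.
CORE_BOUNDS = (5.0, 50.0)

ACC_COLUMNS = [f"r{i:02d}" for i in range(1, BURST_LEN + 1)]


@dataclass
class GapReport:
    """Sampling-gap summary for a nominally regular series."""

    n_gaps: int
    longest_min: float
    cadence_min: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.n_gaps} gap(s), longest {self.longest_min:.0f} min"


def _gap_report(index: pd.DatetimeIndex, cadence_min: float) -> GapReport:
    if len(index) < 2:
        return GapReport(0, 0.0, cadence_min)
    steps = np.diff(index.view("int64")) / 60e9
    gaps = steps[steps > cadence_min + 1e-9]
    longest = float(steps.max()) if len(index) > 1 else 0.0
    return GapReport(int(gaps.size), longest, cadence_min)


def _validated_series(
    timestamps: pd.DatetimeIndex, values: np.ndarray, what: str
) -> pd.Series:
    if len(timestamps) == 0:
        raise EmptyInputError(f"{what}: no rows")
    order = np.argsort(timestamps.values, kind="stable")
    timestamps, values = timestamps[order], np.asarray(values, float)[order]
    if timestamps.duplicated().any():
        dup = timestamps[timestamps.duplicated()][0]
        raise DuplicateTimestampError(f"{what}: duplicate timestamp {dup}")
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise RowError(f"{what}: non-finite temperature", row=bad)
    # values kept at full precision in memory; the writers format at 0.01 degC
    return pd.Series(values, index=timestamps, name="temperature_c")


@dataclass
class LoggerSeries:
    """Environmental temperature from one logger placement (shade or sun)."""

    site: str
    placement: Literal["shade", "sun"]
    data: pd.Series  # DatetimeIndex -> degC
    gap_report: GapReport = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.placement not in ("shade", "sun"):
            raise ParameterError(f"placement must be shade|sun, got {self.placement!r}")
        self.data = _validated_series(
            pd.DatetimeIndex(self.data.index), self.data.to_numpy(), "LoggerSeries"
        )
        if self.gap_report is None:
            self.gap_report = _gap_report(self.data.index, ENV_CADENCE_MIN)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class BodyCoreSeries:
    """Ingested-logger core (gut) temperature for one individual."""

    individual_id: str
    data: pd.Series
    gap_report: GapReport = field(default=None)  # type: ignore[assignment]
    flagged: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = _validated_series(
            pd.DatetimeIndex(self.data.index), self.data.to_numpy(), "BodyCoreSeries"
        )
        if self.gap_report is None:
            self.gap_report = _gap_report(self.data.index, ENV_CADENCE_MIN)
        lo, hi = CORE_BOUNDS
        if self.flagged is None:
            self.flagged = (self.data < lo) | (self.data > hi)

    def __len__(self) -> int:
        return len(self.data)


SURFACE_REGIONS = (
    tuple(f"carapace_scute_{i}" for i in range(1, 14))
    + tuple(f"extremity_{i}" for i in range(1, 5))
    + tuple(f"skinfold_{i}" for i in range(1, 5))
)

REGION_GROUPS = {
    "carapace": tuple(r for r in SURFACE_REGIONS if r.startswith("carapace")),
    "extremity": tuple(r for r in SURFACE_REGIONS if r.startswith("extremity")),
    "skinfold": tuple(r for r in SURFACE_REGIONS if r.startswith("skinfold")),
}


@dataclass(frozen=True)
class Individual:
    id: str
    mass_kg: float
    trial: str = ""

    def __post_init__(self) -> None:
        if not self.mass_kg > 0:
            raise ParameterError(f"mass must be > 0 kg, got {self.mass_kg}")


@dataclass
class Trial:
    """One study period: environment pair, individuals, and their series."""

    label: str
    season: Literal["wet", "dry", "na"]
    env_shade: LoggerSeries
    env_sun: LoggerSeries
    individuals: list[Individual]
    core: list[BodyCoreSeries]
    surface: pd.DataFrame | None = None  # columns: individual_id, timestamp, region, temperature_c
    activity: dict[str, pd.DataFrame] | None = None  # individual_id -> states frame

    def __post_init__(self) -> None:
        span_a = self.env_shade.data.index
        span_b = self.env_sun.data.index
        if abs(span_a[0] - span_b[0]) > pd.Timedelta(days=1) or abs(
            span_a[-1] - span_b[-1]
        ) > pd.Timedelta(days=1):
            raise ParameterError("shade and sun series must cover the same span (+-1 day)")
        ids = {ind.id for ind in self.individuals}
        for series in self.core:
            if series.individual_id not in ids:
                raise ParameterError(
                    f"core series {series.individual_id!r} has no matching individual"
                )


# ---------------------------------------------------------------------------
# readers / writers


def read_temperature_series(
    path: str | Path,
    timestamp_col: str = "timestamp",
    temp_col: str = "temperature_c",
    placement: str | None = None,
    site: str = "",
    individual_id: str | None = None,
) -> LoggerSeries | BodyCoreSeries:
    """Read a 15-min temperature logger CSV.

    With ``placement`` given returns a :class:`LoggerSeries`; with
    ``individual_id`` given returns a :class:`BodyCoreSeries`.  Duplicate
    timestamps are rejected; a gap report (count and longest gap) is
    attached to the result.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    for col in (timestamp_col, temp_col):
        if col not in raw.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    try:
        ts = pd.DatetimeIndex(pd.to_datetime(raw[timestamp_col], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path.name}: unparseable timestamps: {exc}") from exc
    vals = pd.to_numeric(raw[temp_col], errors="coerce").to_numpy()
    if np.isnan(vals).any():
        bad = int(np.flatnonzero(np.isnan(vals))[0])
        raise RowError(f"{path.name}: unparseable temperature", row=bad + 2)
    data = pd.Series(vals, index=ts)
    if individual_id is not None:
        return BodyCoreSeries(individual_id=individual_id, data=data)
    if placement is None:
        raise ParameterError("give either placement= (env logger) or individual_id= (core)")
    return LoggerSeries(site=site, placement=placement, data=data)  # type: ignore[arg-type]


def write_temperature_series(series: LoggerSeries | BodyCoreSeries, path: str | Path) -> None:
    """Write a series in the package CSV dialect (0.01 degC resolution)."""
    df = pd.DataFrame(
        {
            "timestamp": series.data.index.strftime("%Y-%m-%d %H:%M"),
            "temperature_c": [f"{v:.2f}" for v in series.data.to_numpy()],
        }
    )
    df.to_csv(path, index=False)


def read_acc_series(path: str | Path) -> pd.DataFrame:
    """Read accelerometer bursts: ``timestamp,r01..r36`` per record.

    Returns a frame indexed by timestamp with the 36 reading columns,
    ordered in time.  A record with a missing or non-numeric reading raises
    :class:`MalformedBurstError` naming the record.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    if "timestamp" not in raw.columns:
        raise SchemaError(f"{path.name}: missing column 'timestamp'")
    missing = [c for c in ACC_COLUMNS if c not in raw.columns]
    extra = [c for c in raw.columns if c.startswith("r") and c not in ACC_COLUMNS]
    if missing or extra:
        raise MalformedBurstError(
            f"{path.name}: expected exactly columns r01..r36 "
            f"(missing {missing[:3]}, unexpected {extra[:3]})"
        )
    ts = pd.DatetimeIndex(pd.to_datetime(raw["timestamp"], format="ISO8601"))
    readings = raw[ACC_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad_rows = readings.isna().any(axis=1) | ~np.isfinite(readings.to_numpy()).all(axis=1)
    if bad_rows.any():
        row = int(np.flatnonzero(bad_rows.to_numpy())[0])
        raise MalformedBurstError("burst has a missing/non-finite reading", row=row + 2)
    if ts.duplicated().any():
        raise DuplicateTimestampError(f"{path.name}: duplicate burst timestamp")
    frame = readings.set_axis(ts, axis=0).sort_index()
    return frame


def write_acc_series(bursts: pd.DataFrame, path: str | Path) -> None:
    out = bursts.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%d %H:%M"))
    out.to_csv(path, index=False, float_format="%.3f")


def read_surface_table(path: str | Path) -> pd.DataFrame:
    """Read spot surface-temperature readings.

    Schema: ``individual_id,timestamp,region,temperature_c`` with region in
    the 21-site scheme (13 carapace scutes, 4 extremities, 4 skin folds).
    """
    raw = pd.read_csv(path)
    need = {"individual_id", "timestamp", "region", "temperature_c"}
    if not need <= set(raw.columns):
        raise SchemaError(f"surface table: missing {sorted(need - set(raw.columns))}")
    bad = ~raw["region"].isin(SURFACE_REGIONS)
    if bad.any():
        raise RowError(
            f"unknown region {raw.loc[bad, 'region'].iloc[0]!r}",
            row=int(np.flatnonzero(bad.to_numpy())[0]) + 2,
        )
    out = raw.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], format="ISO8601")
    out["temperature_c"] = pd.to_numeric(out["temperature_c"])
    return out.sort_values(["individual_id", "timestamp", "region"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# alignment between cadences


def align_series(
    a: pd.Series,
    b: pd.Series,
    rule: Literal["nearest", "previous", "interpolate"] = "nearest",
    max_gap_min: float = 8.0,
) -> pd.DataFrame:
    """Pair every sample of ``a`` with a partner from ``b`` within ``max_gap_min``.

    The 5-min activity epochs are coupled to the 15-min weather-station
    series this way; the default gap of 8 min is half the coarser cadence
    plus slack.  Returns a frame with columns ``value_a, value_b,
    pairing_gap_min`` indexed by the timestamps of ``a``; unmatched rows are
    dropped and counted in ``result.attrs["n_dropped"]``.
    """
    if len(a) == 0 or len(b) == 0:
        raise EmptyInputError("align_series: empty input series")
    if not max_gap_min > 0:
        raise ParameterError(f"max_gap_min must be > 0, got {max_gap_min}")
    a = a.sort_index()
    b = b.sort_index()
    ta = a.index.view("int64") / 60e9  # minutes
    tb = b.index.view("int64") / 60e9
    if rule in ("nearest", "previous"):
        pos = np.searchsorted(tb, ta, side="right") - 1
        if rule == "nearest":
            lo = np.clip(pos, 0, len(tb) - 1)
            hi = np.clip(pos + 1, 0, len(tb) - 1)
            pick = np.where(np.abs(tb[hi] - ta) < np.abs(ta - tb[lo]), hi, lo)
        else:
            pick = pos
        valid = pick >= 0
        gap = np.full(len(ta), np.inf)
        gap[valid] = np.abs(ta[valid] - tb[pick[valid]])
        vb = np.full(len(ta), np.nan)
        vb[valid] = b.to_numpy()[pick[valid]]
    elif rule == "interpolate":
        vb = np.interp(ta, tb, b.to_numpy(), left=np.nan, right=np.nan)
        # gap = distance to the nearest original sample of b
        pos = np.clip(np.searchsorted(tb, ta), 1, len(tb) - 1)
        gap = np.minimum(np.abs(ta - tb[pos - 1]), np.abs(tb[pos] - ta))
        inside = (ta >= tb[0]) & (ta <= tb[-1])
        gap[~inside] = np.inf
    else:
        raise ParameterError(f"unknown rule {rule!r}")
    keep = np.isfinite(vb) & (gap <= max_gap_min + 1e-9)
    out = pd.DataFrame(
        {"value_a": a.to_numpy()[keep], "value_b": vb[keep], "pairing_gap_min": gap[keep]},
        index=a.index[keep],
    )
    out.attrs["n_dropped"] = int((~keep).sum())
    out.attrs["rule"] = rule
    return out


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for run logs and manifests."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
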