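"""Accelerometer burst classification into binary active/inactive states.

A burst is 36 voltage readings taken over 5 s, one burst per 5-min epoch.
Behavioural state is assigned from a rolling mean of the per-burst standard
error: epochs whose rolling SE reaches the threshold are active.  Overnight
epochs (00:00-06:00) are assumed inactive by design of the field protocol.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .errors import EmptyInputError, MalformedBurstError, ParameterError
from .io_core import ACC_COLUMNS, BURST_LEN

#: Default classification threshold on the rolling-average burst SE, in the
#: logger's raw voltage units.  Fully configurable: the voltage scale of a
#: different logger model will need a different value.
DEFAULT_THRESHOLD = 5.0
#: Default rolling-window length in bursts (centered, edge-truncated).
DEFAULT_WINDOW = 3
#: Epochs from midnight up to (excluding) this hour are forced inactive.
QUIET_END_HOUR = 6
#: Epoch range retained for activity modelling (inclusive clock hours).
MODEL_HOURS = (6.0, 20.0)


def burst_dispersion(readings: np.ndarray) -> float:
    """Standard error of one burst: sample SD of the 36 readings / sqrt(36).

    The per-burst "SE" is the dispersion statistic the classifier
    thresholds; whether the literal SD would serve equally is a matter of
    scale only (factor 6), absorbed by the threshold.
    """
    arr = np.asarray(readings, float)
    if arr.shape[-1] != BURST_LEN:
        raise MalformedBurstError(f"burst must hold {BURST_LEN} readings, got {arr.shape[-1]}")
    if not np.all(np.isfinite(arr)):
        raise MalformedBurstError("burst contains a non-finite reading")
    return float(np.std(arr, ddof=1) / np.sqrt(BURST_LEN))


def _burst_se_vector(bursts: pd.DataFrame) -> np.ndarray:
    arr = bursts[ACC_COLUMNS].to_numpy(float) if set(ACC_COLUMNS) <= set(bursts.columns) else bursts.to_numpy(float)
    if arr.shape[1] != BURST_LEN:
        raise MalformedBurstError(f"expected {BURST_LEN} reading columns, got {arr.shape[1]}")
    if not np.all(np.isfinite(arr)):
        row = int(np.flatnonzero(~np.isfinite(arr).all(axis=1))[0])
        raise MalformedBurstError("burst contains a non-finite reading", row=row)
    return np.std(arr, axis=1, ddof=1) / np.sqrt(BURST_LEN)


def classify_states(
    bursts: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Binary activity states from a time-ordered burst frame.

    ``rolling_se`` is the centered moving average (window in bursts,
    truncated at the edges) of the per-burst SE; ``state`` is 1 where
    ``rolling_se >= threshold`` (ties resolve to active).  Epochs between
    00:00 and 06:00 are forced inactive regardless of dispersion.

    Returns a frame indexed by epoch timestamp with columns
    ``rolling_se`` and ``state``.
    """
    if len(bursts) == 0:
        raise EmptyInputError("classify_states: no bursts")
    if window < 1:
        raise ParameterError("window must be >= 1")
    if not threshold > 0:
        raise ParameterError("threshold must be > 0")
    bursts = bursts.sort_index()
    se = _burst_se_vector(bursts)
    rolling = (
        pd.Series(se, index=bursts.index)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
    )
    state = (rolling.to_numpy() >= threshold).astype(int)
    hours = bursts.index.hour + bursts.index.minute / 60.0
    state[np.asarray(hours) < QUIET_END_HOUR] = 0
    return pd.DataFrame({"rolling_se": rolling.to_numpy(), "state": state}, index=bursts.index)


def restrict_to_model_hours(states: pd.DataFrame) -> pd.DataFrame:
    """Keep only epochs in the modelling window (06:00-20:00 inclusive)."""
    hours = states.index.hour + states.index.minute / 60.0
    lo, hi = MODEL_HOURS
    keep = (np.asarray(hours) >= lo) & (np.asarray(hours) <= hi)
    return states.loc[keep]


def activity_profile(
    states: pd.DataFrame | pd.Series,
    by: Literal["hour", "temperature_bin"] = "hour",
    aligned_env: pd.DataFrame | None = None,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Per-bin activity probability (mean state) with bin counts.

    ``by="hour"`` covers all 24 clock hours; empty bins are reported with
    count 0 and probability NaN (flagged, never fabricated).
    ``by="temperature_bin"`` requires an aligned table pairing each epoch
    with a temperature (``value_b`` column).
    """
    st = states["state"] if isinstance(states, pd.DataFrame) else states
    if len(st) == 0:
        raise EmptyInputError("activity_profile: no states")
    if by == "hour":
        keys = pd.Series(st.index.hour, index=st.index, name="hour")
        grouped = st.groupby(keys)
        out = pd.DataFrame(
            {"n": grouped.size(), "probability": grouped.mean()}
        ).reindex(range(24))
        out.index.name = "hour"
        out["n"] = out["n"].fillna(0).astype(int)
        out.loc[out["n"] == 0, "probability"] = np.nan
        return out
    if by == "temperature_bin":
        if aligned_env is None:
            raise ParameterError("temperature_bin profile needs an aligned env table")
        joined = pd.DataFrame({"state": st}).join(aligned_env[["value_b"]], how="inner")
        edges = np.arange(
            np.floor(joined["value_b"].min() / bin_width) * bin_width,
            joined["value_b"].max() + bin_width,
            bin_width,
        )
        keys = pd.cut(joined["value_b"], edges, include_lowest=True)
        grouped = joined["state"].groupby(keys, observed=True)
        out = pd.DataFrame({"n": grouped.size(), "probability": grouped.mean()})
        out.index.name = "temperature_bin"
        return out
    raise ParameterError(f"unknown profile axis {by!r}")
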