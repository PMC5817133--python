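"""Optimal air-temperature range for activity from state-conditional KDEs.

The activity epochs, each paired with a shade air temperature, are
partitioned by behavioural state.  A Gaussian kernel density is estimated
for each state on a common temperature grid; each density integrates to
one.  The optimum range T_a-opt is the longest contiguous run of grid
temperatures where the active-state density exceeds the inactive-state
density, and the active-state temperatures themselves yield the mean/SD
and quartile summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError

GRID_STEP = 0.1  # degC; matches the 0.1 degC precision of reported endpoints


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    x = np.asarray(x, float)
    n = len(x)
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread == 0.0:
        return GRID_STEP  # degenerate sample: fall back to the grid scale
    return 0.9 * spread * n ** (-0.2)


def gaussian_kde_on_grid(x: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Plain Gaussian kernel sum: mean over points of phi((g - x_i)/h)/h."""
    z = (grid[:, None] - np.asarray(x, float)[None, :]) / bandwidth
    return np.exp(-0.5 * z**2).sum(axis=1) / (len(x) * bandwidth * np.sqrt(2 * np.pi))


@dataclass
class StateDensities:
    """State-conditional kernel densities on a shared temperature grid."""

    grid: np.ndarray
    active_density: np.ndarray
    inactive_density: np.ndarray
    bandwidth: float
    n_active: int
    n_inactive: int


@dataclass
class OptimumRange:
    """T_a-opt interval plus active-state temperature summaries."""

    low: float
    high: float
    defined: bool
    mean_active: float
    sd_active: float
    q25: float
    q75: float
    bandwidth: float = float("nan")
    secondary_runs: list[tuple[float, float]] = field(default_factory=list)


class ThermalOptimum:
    """Model object: activity states paired with air temperature.

    Parameters
    ----------
    temperature, state
        Equal-length arrays: shade air temperature (degC) per epoch and the
        binary state (1 active).
    bandwidth
        Kernel bandwidth in degC, or ``"auto"`` for the larger of the two
        per-state Silverman values (a common bandwidth, so density
        crossings reflect the data rather than bandwidth asymmetry).
    min_per_state
        Minimum observations required in each state.
    """

    def __init__(
        self,
        temperature,
        state,
        bandwidth: float | str = "auto",
        min_per_state: int = 30,
        grid_step: float = GRID_STEP,
    ):
        self.temperature = np.asarray(temperature, float)
        self.state = np.asarray(state, int)
        if self.temperature.shape != self.state.shape:
            raise ParameterError("temperature and state must have equal length")
        self.bandwidth = bandwidth
        self.min_per_state = min_per_state
        self.grid_step = grid_step

    @classmethod
    def from_aligned(cls, aligned: pd.DataFrame, states: pd.DataFrame, **kwargs) -> "ThermalOptimum":
        """Build from an aligned (epoch, temperature) table and a states frame."""
        joined = states[["state"]].join(aligned[["value_b"]], how="inner").dropna()
        return cls(joined["value_b"].to_numpy(), joined["state"].to_numpy(), **kwargs)

    def densities(self) -> StateDensities:
        active = self.temperature[self.state == 1]
        inactive = self.temperature[self.state == 0]
        for name, arr in (("active", active), ("inactive", inactive)):
            if len(arr) < self.min_per_state:
                raise InsufficientDataError(
                    f"{name} state has {len(arr)} observations (< {self.min_per_state})"
                )
        if self.bandwidth == "auto":
            h = max(silverman_bandwidth(active), silverman_bandwidth(inactive))
        else:
            h = float(self.bandwidth)
            if not h > 0:
                raise ParameterError("bandwidth must be > 0")
        lo = self.temperature.min() - 3 * h
        hi = self.temperature.max() + 3 * h
        grid = np.arange(lo, hi + self.grid_step, self.grid_step)
        return StateDensities(
            grid=grid,
            active_density=gaussian_kde_on_grid(active, grid, h),
            inactive_density=gaussian_kde_on_grid(inactive, grid, h),
            bandwidth=h,
            n_active=len(active),
            n_inactive=len(inactive),
        )

    def fit(self) -> "ThermalOptimumResults":
        dens = self.densities()
        rng = optimum_range(dens)
        active = self.temperature[self.state == 1]
        summ = active_temperature_summary(active)
        return ThermalOptimumResults(
            model=self,
            densities=dens,
            range_=OptimumRange(
                low=rng.low,
                high=rng.high,
                defined=rng.defined,
                mean_active=summ.mean_active,
                sd_active=summ.sd_active,
                q25=summ.q25,
                q75=summ.q75,
                bandwidth=dens.bandwidth,
                secondary_runs=rng.secondary_runs,
            ),
        )


@dataclass
class ThermalOptimumResults:
    """Fitted densities and the derived optimum range."""

    model: ThermalOptimum
    densities: StateDensities
    range_: OptimumRange

    @property
    def low(self) -> float:
        return self.range_.low

    @property
    def high(self) -> float:
        return self.range_.high

    def summary(self) -> str:
        r = self.range_
        d = self.densities
        lines = [
            "Thermal optimum (state-conditional KDE)",
            f"  n active / inactive : {d.n_active} / {d.n_inactive}",
            f"  bandwidth           : {d.bandwidth:.3f} degC",
            (
                f"  T_a-opt range       : {r.low:.1f} - {r.high:.1f} degC"
                if r.defined
                else "  T_a-opt range       : undefined (active never exceeds inactive)"
            ),
            f"  mean T_air (active) : {r.mean_active:.1f} degC (SD {r.sd_active:.1f})",
            f"  quartiles (active)  : {r.q25:.1f} - {r.q75:.1f} degC",
        ]
        if r.secondary_runs:
            runs = ", ".join(f"{a:.1f}-{b:.1f}" for a, b in r.secondary_runs)
            lines.append(f"  minor crossing runs : {runs}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Density table (grid, active, inactive) for export or plotting."""
        return pd.DataFrame(
            {
                "temperature_c": self.densities.grid,
                "active_density": self.densities.active_density,
                "inactive_density": self.densities.inactive_density,
            }
        )

    def plot(self, ax=None):  # pragma: no cover - thin plotting shim
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.densities
        ax.plot(d.grid, d.active_density, label="active", color="tab:red")
        ax.plot(d.grid, d.inactive_density, label="inactive", color="tab:blue")
        if self.range_.defined:
            ax.axvline(self.range_.low, ls="--", color="grey")
            ax.axvline(self.range_.high, ls="--", color="grey")
        ax.set_xlabel("air temperature (degC)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# functional surface


def conditional_state_densities(
    paired: pd.DataFrame | None = None,
    bandwidth: float | str = "auto",
    min_per_state: int = 30,
    temperature=None,
    state=None,
) -> StateDensities:
    """State-conditional densities from a paired (T_air, state) table."""
    if paired is not None:
        temperature = paired["value_b" if "value_b" in paired else "temperature_c"].to_numpy()
        state = paired["state" if "state" in paired else "value_a"].to_numpy()
    return ThermalOptimum(
        temperature, state, bandwidth=bandwidth, min_per_state=min_per_state
    ).densities()


def optimum_range(dens: StateDensities) -> OptimumRange:
    """Longest contiguous grid run where the active density exceeds the inactive.

    Multiple crossing runs can occur; the longest (by temperature span) is
    the reported interval and the others are listed in
    ``secondary_runs``.  If the active density never exceeds the inactive
    one the result is flagged undefined rather than raising.
    """
    above = dens.active_density > dens.inactive_density
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    if not runs:
        return OptimumRange(
            np.nan, np.nan, False, np.nan, np.nan, np.nan, np.nan, dens.bandwidth
        )
    spans = [dens.grid[b] - dens.grid[a] for a, b in runs]
    best = int(np.argmax(spans))
    a, b = runs[best]
    secondary = [
        (float(dens.grid[i]), float(dens.grid[j]))
        for idx, (i, j) in enumerate(runs)
        if idx != best
    ]
    return OptimumRange(
        low=float(dens.grid[a]),
        high=float(dens.grid[b]),
        defined=True,
        mean_active=np.nan,
        sd_active=np.nan,
        q25=np.nan,
        q75=np.nan,
        bandwidth=dens.bandwidth,
        secondary_runs=secondary,
    )


def active_temperature_summary(active_temps) -> OptimumRange:
    """Mean, SD (n-1) and 25/75% quartiles of temperatures during activity."""
    arr = np.asarray(active_temps, float)
    if len(arr) == 0:
        raise InsufficientDataError("no active epochs")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else float("nan")
    q25, q75 = (np.percentile(arr, [25, 75]) if len(arr) > 0 else (np.nan, np.nan))
    return OptimumRange(
        low=np.nan,
        high=np.nan,
        defined=False,
        mean_active=mean,
        sd_active=sd,
        q25=float(q25),
        q75=float(q75),
    )
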