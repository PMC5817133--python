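"""Fixed-effects logistic activity model and AIC model comparison.

The activity model regresses the binary 5-min state on year, day period
(I-IV), season (wet/dry), centered shade air temperature, and the
temperature-by-season and temperature-by-period interactions, restricted
to the 06:00-20:00 modelling window.  The fit is the binomial MLE via
iteratively reweighted least squares (IRLS) with standard errors from the
inverse Fisher information.  Random effects are deliberately absent;
individual identity can enter as fixed dummies instead.

The link is the logit by default.  A ``link="log"`` variant exists for
literal replication of analyses phrased that way, but log-link binomial
fits are fragile (fitted probabilities must stay below 1) and the logit is
the conventional reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import (
    ComparabilityError,
    EmptyInputError,
    ParameterError,
    SeparationError,
)
from .rhythms import ACTIVITY_PERIODS, PeriodScheme, discretise_day

WET_MONTHS = (11, 12, 1, 2, 3, 4)  # November-April


def season_of(timestamps: pd.DatetimeIndex) -> np.ndarray:
    """Season factor from the calendar month: Nov-Apr wet, May-Oct dry."""
    months = np.asarray(pd.DatetimeIndex(timestamps).month)
    return np.where(np.isin(months, WET_MONTHS), "wet", "dry")


@dataclass
class DesignMatrix:
    """Response vector and design for the activity model."""

    y: np.ndarray
    X: pd.DataFrame
    n_dropped_unpaired: int = 0
    n_dropped_hours: int = 0

    def __post_init__(self) -> None:
        if len(self.y) == 0:
            raise EmptyInputError("empty design: no epochs in the modelling window")
        zero_cols = [c for c in self.X.columns if np.allclose(self.X[c], 0)]
        if zero_cols:
            raise ParameterError(f"all-zero design columns: {zero_cols}")


def build_activity_design(
    states: pd.DataFrame,
    aligned_env: pd.DataFrame,
    scheme: PeriodScheme = ACTIVITY_PERIODS,
    include_year: bool = True,
    include_interactions: bool = True,
    individual_ids: pd.Series | None = None,
) -> DesignMatrix:
    """Assemble the activity-model design from states and paired temperatures.

    Epochs outside 06:00-20:00 (the scheme's span) are dropped, as are
    epochs with no paired temperature.  Factors are reference-coded
    (period I, wet season, first year); temperature is centered before
    interaction columns are formed, which stabilises IRLS.
    """
    joined = states[["state"]].join(aligned_env[["value_b"]], how="left")
    n_unpaired = int(joined["value_b"].isna().sum())
    joined = joined.dropna(subset=["value_b"])
    periods = discretise_day(joined.index, scheme)
    keep = periods != "excluded"
    n_hours = int((~keep).sum())
    joined = joined.loc[keep.to_numpy()]
    periods = periods.loc[keep.to_numpy()]
    if len(joined) == 0:
        raise EmptyInputError("empty design: no epochs in the modelling window")

    t_centered = joined["value_b"].to_numpy() - joined["value_b"].mean()
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(joined))}
    if include_year:
        years = joined.index.year.to_numpy()
        for yr in np.unique(years)[1:]:
            cols[f"year_{yr}"] = (years == yr).astype(float)
    period_dummies = {}
    observed = set(periods)
    for lab in scheme.labels[1:]:
        if lab not in observed:  # absent level would make an all-zero column
            continue
        period_dummies[lab] = (periods.to_numpy() == lab).astype(float)
        cols[f"period_{lab}"] = period_dummies[lab]
    season = season_of(joined.index)
    has_both_seasons = len(np.unique(season)) > 1
    if has_both_seasons:
        cols["season_dry"] = (season == "dry").astype(float)
    cols["t_air_c"] = t_centered
    if include_interactions:
        if has_both_seasons:
            cols["t_air_c:season_dry"] = t_centered * cols["season_dry"]
        for lab, dummy in period_dummies.items():
            cols[f"t_air_c:period_{lab}"] = t_centered * dummy
    if individual_ids is not None:
        # optional fixed-effect dummies standing in for the random intercept
        ids = individual_ids.reindex(joined.index).to_numpy()
        for ind in pd.unique(ids)[1:]:
            cols[f"id_{ind}"] = (ids == ind).astype(float)
    X = pd.DataFrame(cols, index=joined.index)
    return DesignMatrix(
        y=joined["state"].to_numpy(float),
        X=X,
        n_dropped_unpaired=n_unpaired,
        n_dropped_hours=n_hours,
    )


class ActivityLogit:
    """Binomial GLM for binary activity, fitted by IRLS."""

    def __init__(self, y, X, link: str = "logit"):
        self.y = np.asarray(y, float)
        self.X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        if link not in ("logit", "log"):
            raise ParameterError(f"link must be logit|log, got {link!r}")
        self.link = link
        if len(self.y) != len(self.X):
            raise ParameterError("y and X length mismatch")
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ParameterError("response must be binary 0/1")

    @classmethod
    def from_design(cls, design: DesignMatrix, link: str = "logit") -> "ActivityLogit":
        rank = np.linalg.matrix_rank(design.X.to_numpy())
        if rank < design.X.shape[1]:
            raise ParameterError(
                f"rank-deficient design: rank {rank} < {design.X.shape[1]} columns"
            )
        return cls(design.y, design.X, link=link)

    def _mu_eta(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.link == "logit":
            mu = expit(eta)
            d_mu = mu * (1 - mu)  # d mu / d eta
        else:  # log link: mu = exp(eta), clipped below 1
            mu = np.clip(np.exp(eta), 1e-10, 1 - 1e-10)
            d_mu = mu
        return mu, d_mu

    def loglike(self, beta: np.ndarray) -> float:
        eta = self.X.to_numpy() @ beta
        mu, _ = self._mu_eta(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(np.sum(self.y * np.log(mu) + (1 - self.y) * np.log(1 - mu)))

    def fit(self, max_iter: int = 50, tol: float = 1e-10) -> "ActivityLogitResults":
        Xm = self.X.to_numpy(float)
        n, k = Xm.shape
        beta = np.zeros(k)
        col_scale = np.maximum(Xm.std(axis=0), 1e-12)
        llf_old = -np.inf
        llf_path = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            eta = Xm @ beta
            mu, d_mu = self._mu_eta(eta)
            mu_c = np.clip(mu, 1e-10, 1 - 1e-10)
            var = mu_c * (1 - mu_c)
            w = d_mu**2 / var
            z = eta + (self.y - mu_c) / np.where(d_mu == 0, 1e-10, d_mu)
            WX = Xm * w[:, None]
            try:
                beta = np.linalg.solve(Xm.T @ WX, WX.T @ z)
            except np.linalg.LinAlgError as exc:
                raise SeparationError(f"IRLS normal equations singular: {exc}") from exc
            if np.max(np.abs(beta * col_scale)) > 50.0:
                raise SeparationError(
                    "coefficients diverging (|beta| > 50 on the standardized scale): "
                    "perfect separation"
                )
            llf = self.loglike(beta)
            llf_path.append(llf)
            if abs(llf - llf_old) < tol * (abs(llf) + 1.0):
                converged = True
                break
            llf_old = llf
        eta = Xm @ beta
        mu, d_mu = self._mu_eta(eta)
        var = np.clip(mu * (1 - mu), 1e-10, None)
        w = d_mu**2 / var
        fisher = Xm.T @ (Xm * w[:, None])
        cov = np.linalg.inv(fisher)
        bse = np.sqrt(np.diag(cov))
        llf = self.loglike(beta)
        return ActivityLogitResults(
            model=self,
            params=pd.Series(beta, index=self.X.columns),
            bse=pd.Series(bse, index=self.X.columns),
            cov_params=pd.DataFrame(cov, index=self.X.columns, columns=self.X.columns),
            llf=llf,
            n_iter=n_iter,
            converged=converged,
            llf_path=llf_path,
        )


@dataclass
class ActivityLogitResults:
    model: ActivityLogit
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    llf: float
    n_iter: int
    converged: bool
    llf_path: list[float] = field(default_factory=list)

    @property
    def nobs(self) -> int:
        return len(self.model.y)

    @property
    def df_model(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2 * self.df_model - 2 * self.llf

    @property
    def fittedvalues(self) -> np.ndarray:
        mu, _ = self.model._mu_eta(self.model.X.to_numpy() @ self.params.to_numpy())
        return mu

    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary(self) -> str:
        from scipy import stats as _st

        z = self.zvalues()
        p = 2 * _st.norm.sf(np.abs(z))
        head = (
            f"Activity model ({self.model.link} link, IRLS)\n"
            f"  n = {self.nobs}, k = {self.df_model}, "
            f"logLik = {self.llf:.2f}, AIC = {self.aic:.2f}, "
            f"converged = {self.converged} ({self.n_iter} iter)\n"
        )
        tab = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "z": z, "p": p}
        ).to_string(float_format=lambda v: f"{v:10.4f}")
        return head + tab


def compare_models(fits: list[ActivityLogitResults]) -> pd.DataFrame:
    """Rank fitted models by AIC (Delta-AIC relative to the best).

    All fits must be on the same response rows; otherwise AICs are not
    comparable and a :class:`ComparabilityError` is raised.
    """
    if not fits:
        raise EmptyInputError("no fits to compare")
    n0 = fits[0].nobs
    y0 = fits[0].model.y
    for f in fits[1:]:
        if f.nobs != n0 or not np.array_equal(f.model.y, y0):
            raise ComparabilityError("fits use different response rows")
    rows = [
        {"model": i, "k": f.df_model, "loglik": f.llf, "aic": f.aic}
        for i, f in enumerate(fits)
    ]
    tab = pd.DataFrame(rows).set_index("model")
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    return tab.sort_values("delta_aic")
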