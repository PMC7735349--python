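"""Daily water budget: turnover, weather aggregation, temperature model.

Water turnover is the product of the washout rate constant and the body
water pool (r = kd * TBW, litres per day).  Its dependence on body mass and
air temperature is modelled on the natural-log scale with a linear mixed
model: standardized (z-scored) mass and period-mean temperature as fixed
effects and a subject random intercept, fitted by REML.  The mass x
temperature interaction is fitted first and dropped when not significant
at the 0.05 level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .kinetics import WashoutFit

__all__ = [
    "MEASUREMENT_WINDOW_DAYS",
    "MeasurementPeriod",
    "TemperatureModelFit",
    "MissingWeatherError",
    "water_turnover",
    "turnover_pct_tbw",
    "aggregate_weather",
    "fit_temperature_model",
    "drinking_interval",
]

#: calendar days per measurement window, inclusive of the dose day
MEASUREMENT_WINDOW_DAYS = 10


class MissingWeatherError(ValueError):
    """Daily weather records missing inside a measurement window."""


@dataclass(frozen=True)
class MeasurementPeriod:
    """Weather-annotated turnover record for one subject-period."""

    subject_id: str
    period_id: str
    body_mass: float  # kg
    tbw: float  # litres
    water_turnover: float  # litres / day
    mean_temp: float  # deg C, mean of daily means over the window
    max_temp: float = np.nan
    min_temp: float = np.nan
    dewpoint: float = np.nan
    cum_precip: float = np.nan  # mm over the window

    @property
    def turnover_pct_tbw(self) -> float:
        return turnover_pct_tbw(self.water_turnover, self.tbw)


@dataclass(frozen=True)
class TemperatureModelFit:
    """Mixed-model fit of log water turnover on standardized predictors.

    Coefficients are per SD of the predictor on the natural-log turnover
    scale; `standardization` stores the means/SDs used so predictions are
    reproducible.
    """

    coef_mass: float
    coef_temp: float
    coef_mass_se: float
    coef_temp_se: float
    intercept: float
    subject_intercept_sd: float
    interaction_kept: bool
    coef_interaction: float | None
    standardization: dict = field(default_factory=dict)
    n_obs: int = 0
    n_subjects: int = 0

    def predict_log_turnover(self, body_mass: float, mean_temp: float) -> float:
        """Population-level prediction (random intercept at zero)."""
        s = self.standardization
        zm = (body_mass - s["mass_mean"]) / s["mass_sd"]
        zt = (mean_temp - s["temp_mean"]) / s["temp_sd"]
        y = self.intercept + self.coef_mass * zm + self.coef_temp * zt
        if self.interaction_kept and self.coef_interaction is not None:
            y += self.coef_interaction * zm * zt
        return y


def water_turnover(fit: WashoutFit, tbw: float, *, require_qc: bool = True) -> float:
    """Daily water turnover r = kd * TBW, litres per day."""
    if require_qc and not fit.qc_pass:
        raise ValueError(
            f"washout fit for {fit.subject_id}/{fit.period_id} failed QC"
        )
    if tbw <= 0:
        raise ValueError(f"tbw must be positive, got {tbw}")
    return fit.kd * tbw


def turnover_pct_tbw(turnover: float, tbw: float) -> float:
    """Turnover as percent of the body-water pool per day."""
    if tbw <= 0:
        raise ValueError(f"tbw must be positive, got {tbw}")
    return 100.0 * turnover / tbw


def aggregate_weather(
    daily: pd.DataFrame,
    window_start,
    *,
    window_days: int = MEASUREMENT_WINDOW_DAYS,
) -> dict:
    """Aggregate daily weather over a measurement window.

    ``daily`` needs columns date, tmean, tmax, tmin, dewpoint, precip with
    one row per calendar day.  The window covers ``window_days`` calendar
    days starting at (and including) ``window_start``.  Temperatures and
    dewpoint are averaged; precipitation is summed.

    Raises
    ------
    MissingWeatherError
        listing every day of the window absent from ``daily``.
    """
    start = pd.Timestamp(window_start).normalize()
    wanted = pd.date_range(start, periods=window_days, freq="D")
    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"]).dt.normalize()
    d = d.set_index("date")
    missing = [str(day.date()) for day in wanted if day not in d.index]
    if missing:
        raise MissingWeatherError(
            f"weather missing for {len(missing)} day(s) in window starting "
            f"{start.date()}: {missing}"
        )
    win = d.loc[wanted]
    return {
        "mean_temp": float(win["tmean"].mean()),
        "max_temp": float(win["tmax"].mean()),
        "min_temp": float(win["tmin"].mean()),
        "dewpoint": float(win["dewpoint"].mean()),
        "cum_precip": float(win["precip"].sum()),
    }


def fit_temperature_model(
    periods: list[MeasurementPeriod] | pd.DataFrame,
    *,
    interaction_alpha: float = 0.05,
) -> TemperatureModelFit:
    """REML mixed model of ln(turnover) on z-mass and z-temperature.

    Subject identity enters as a random intercept.  The mass x temperature
    interaction is fitted first and removed when its Wald p-value is at or
    above ``interaction_alpha``.

    Requires at least two subjects and, overall, variation in both
    predictors; otherwise raises ``ValueError`` describing the singular
    design.
    """
    if isinstance(periods, pd.DataFrame):
        df = periods.copy()
    else:
        df = pd.DataFrame(
            {
                "subject_id": [p.subject_id for p in periods],
                "body_mass": [p.body_mass for p in periods],
                "mean_temp": [p.mean_temp for p in periods],
                "water_turnover": [p.water_turnover for p in periods],
            }
        )
    n_subjects = df["subject_id"].nunique()
    if n_subjects < 2:
        raise ValueError("need >= 2 subjects for a random-intercept model")
    if df.groupby("subject_id").size().min() < 2:
        raise ValueError("every subject needs >= 2 periods")
    if np.any(df["water_turnover"] <= 0):
        raise ValueError("water_turnover must be positive for the log transform")

    # observation-level (global) standardization, ddof=1
    mass_mean, mass_sd = df["body_mass"].mean(), df["body_mass"].std(ddof=1)
    temp_mean, temp_sd = df["mean_temp"].mean(), df["mean_temp"].std(ddof=1)
    if mass_sd == 0 or temp_sd == 0:
        raise ValueError("a predictor is constant; the design is singular")
    df["z_mass"] = (df["body_mass"] - mass_mean) / mass_sd
    df["z_temp"] = (df["mean_temp"] - temp_mean) / temp_sd
    df["log_turnover"] = np.log(df["water_turnover"])

    def _fit(formula: str):
        # variance components at the zero boundary can make a single
        # optimizer's score step singular; fall through a few methods
        last_err: Exception | None = None
        for method in (["lbfgs", "powell"], ["powell"], ["nm"], ["bfgs"]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, df, groups=df["subject_id"])
                try:
                    return model.fit(reml=True, method=method)
                except np.linalg.LinAlgError as err:
                    last_err = err
        raise last_err

    full = _fit("log_turnover ~ z_mass + z_temp + z_mass:z_temp")
    p_int = full.pvalues.get("z_mass:z_temp", 1.0)
    keep_interaction = bool(np.isfinite(p_int) and p_int < interaction_alpha)
    res = full if keep_interaction else _fit("log_turnover ~ z_mass + z_temp")

    return TemperatureModelFit(
        coef_mass=float(res.params["z_mass"]),
        coef_temp=float(res.params["z_temp"]),
        coef_mass_se=float(res.bse["z_mass"]),
        coef_temp_se=float(res.bse["z_temp"]),
        intercept=float(res.params["Intercept"]),
        subject_intercept_sd=float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0))),
        interaction_kept=keep_interaction,
        coef_interaction=float(res.params["z_mass:z_temp"]) if keep_interaction else None,
        standardization={
            "mass_mean": float(mass_mean),
            "mass_sd": float(mass_sd),
            "temp_mean": float(temp_mean),
            "temp_sd": float(temp_sd),
        },
        n_obs=int(len(df)),
        n_subjects=int(n_subjects),
    )


def drinking_interval(
    body_mass: float,
    net_daily_loss: float,
    critical_fraction: float = 0.10,
) -> float:
    """Days until net water loss reaches ``critical_fraction`` of body mass.

    ``net_daily_loss`` is the caller's net loss (L/d): gross turnover less
    any preformed and metabolic water gained without drinking.  With water
    at 1 kg/L the interval is critical_fraction * body_mass / net_daily_loss.
    """
    if body_mass <= 0:
        raise ValueError(f"body_mass must be positive, got {body_mass}")
    if net_daily_loss <= 0:
        raise ValueError(f"net_daily_loss must be positive, got {net_daily_loss}")
    if not 0 < critical_fraction < 1:
        raise ValueError(f"critical_fraction must be in (0,1), got {critical_fraction}")
    return critical_fraction * body_mass / net_daily_loss
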