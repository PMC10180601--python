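"""Climate variables and indices from daily meteorology.

Nine heat-, water- and cold-related variables are derived on three time
scales (calendar month, vegetation period = current April-September,
previous winter = previous October-current March):

====== ==========================================================
T_mean mean air temperature [degC]
hs     heat sum: sum of (T_mean - 20) over days with T_mean > 20 [degC d]
nhd    number of hot days, T_max >= 30 degC
VPD    vapour pressure deficit [hPa], mean of daily maxima
PPT    precipitation sum [mm]
nrd    number of rain days, PPT > 1 mm (strict)
spei3  standardised precipitation-evapotranspiration index, 3 months
nfd    number of frost days, T_min <= 0 degC
nid    number of ice days, T_max <= 0 degC
====== ==========================================================

PET is computed with the Thornthwaite temperature/latitude method, SPEI
by fitting a three-parameter log-logistic distribution (unbiased
probability-weighted moments) to the 3-month climatic water balance
D = PPT - PET per calendar month and mapping the CDF to standard-normal
deviates.  Stress years are flagged where vegetation-period T_mean is at
or above the 90th percentile and/or vegetation-period PPT at or below the
10th percentile of the study years, with confirmation flags from the
remaining heat/water indices.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MAGNUS_CONSTANTS",
    "PeriodWindow",
    "month_window",
    "vegetation_period",
    "previous_winter",
    "aggregate_period",
    "heat_sum",
    "threshold_day_count",
    "saturation_vapour_pressure",
    "vpd",
    "daily_max_vpd",
    "mean_daily_max_vpd",
    "monthly_series",
    "thornthwaite_pet",
    "spei",
    "SpeiSeries",
    "classify_drought",
    "ClimateIndexTable",
    "climate_index_table",
    "StressYearReport",
    "detect_stress_years",
]

# Magnus-type saturation vapour pressure over water:
# e_s(T) = a * exp(b*T / (T + c))  [hPa], T in degC
MAGNUS_CONSTANTS = (6.1078, 17.27, 237.3)

#: months of the vegetation period (current April-September)
VEGETATION_MONTHS = (4, 5, 6, 7, 8, 9)

#: Table of time scales on which each variable is defined/used
VARIABLE_WINDOWS = {
    "tmean": ("monthly", "VP", "PW"),
    "hs": ("monthly", "VP"),
    "nhd": ("monthly", "VP"),
    "vpd": ("monthly", "VP"),
    "ppt": ("monthly", "VP", "PW"),
    "nrd": ("monthly", "VP", "PW"),
    "spei3": ("monthly", "VP"),
    "nfd": ("monthly", "VP", "PW"),
    "nid": ("monthly", "PW"),
}


@dataclass(frozen=True)
class PeriodWindow:
    """A labelled day range used for climate aggregation."""

    label: str
    start: pd.Timestamp
    end: pd.Timestamp  # inclusive

    @property
    def n_days(self) -> int:
        return int((self.end - self.start).days) + 1

    def mask(self, index: pd.DatetimeIndex) -> np.ndarray:
        return (index >= self.start) & (index <= self.end)


def month_window(year: int, month: int) -> PeriodWindow:
    last = calendar.monthrange(year, month)[1]
    return PeriodWindow(
        label=f"M{month:02d}",
        start=pd.Timestamp(year, month, 1),
        end=pd.Timestamp(year, month, last),
    )


def vegetation_period(year: int) -> PeriodWindow:
    """Current April through September of ``year``."""
    return PeriodWindow("VP", pd.Timestamp(year, 4, 1), pd.Timestamp(year, 9, 30))


def previous_winter(year: int) -> PeriodWindow:
    """Previous October through current March of ``year``."""
    return PeriodWindow("PW", pd.Timestamp(year - 1, 10, 1), pd.Timestamp(year, 3, 31))


def _window_values(daily: pd.DataFrame, window: PeriodWindow, column: str,
                   tolerance: float = 0.05) -> pd.Series:
    if column not in daily.columns:
        raise KeyError(f"daily climate has no column '{column}'")
    sub = daily.loc[window.mask(daily.index), column].dropna()
    missing = 1.0 - len(sub) / window.n_days
    if missing > tolerance:
        raise ValueError(
            f"window {window.label} {window.start.date()}..{window.end.date()}: "
            f"{missing:.0%} of days missing exceeds tolerance {tolerance:.0%}"
        )
    return sub


def aggregate_period(daily: pd.DataFrame, window: PeriodWindow, variable: str,
                     statistic: str = "mean", tolerance: float = 0.05) -> float:
    """Mean or sum of a daily variable over a window.

    Raises if more than ``tolerance`` of the window's days are missing.
    """
    vals = _window_values(daily, window, variable, tolerance)
    if statistic == "mean":
        return float(vals.mean())
    if statistic == "sum":
        return float(vals.sum())
    raise ValueError(f"unknown statistic '{statistic}'")


def heat_sum(daily: pd.DataFrame, window: PeriodWindow, threshold: float = 20.0,
             tolerance: float = 0.05) -> float:
    """Sum of daily mean-temperature excess above ``threshold`` (strict)."""
    t = _window_values(daily, window, "tmean", tolerance)
    excess = t[t > threshold] - threshold
    return float(excess.sum())


_COUNT_RULES = {
    "hot": ("tmax", "ge", 30.0),
    "frost": ("tmin", "le", 0.0),
    "ice": ("tmax", "le", 0.0),
    "rain": ("ppt", "gt", 1.0),
}


def threshold_day_count(daily: pd.DataFrame, window: PeriodWindow, kind: str,
                        tolerance: float = 0.05) -> int:
    """Count days meeting a threshold: hot (Tmax >= 30), frost (Tmin <= 0),
    ice (Tmax <= 0), rain (PPT > 1 mm, strict)."""
    if kind not in _COUNT_RULES:
        raise ValueError(f"unknown day-count kind '{kind}'")
    column, op, thr = _COUNT_RULES[kind]
    vals = _window_values(daily, window, column, tolerance)
    if op == "ge":
        return int((vals >= thr).sum())
    if op == "le":
        return int((vals <= thr).sum())
    return int((vals > thr).sum())


# ---------------------------------------------------------------------------
# Vapour pressure deficit
# ---------------------------------------------------------------------------

def saturation_vapour_pressure(t) -> np.ndarray | float:
    """Magnus saturation vapour pressure e_s(T) in hPa (T in degC)."""
    a, b, c = MAGNUS_CONSTANTS
    return a * np.exp(b * np.asarray(t, dtype=float) / (np.asarray(t, dtype=float) + c))


def vpd(t, rh) -> np.ndarray | float:
    """Vapour pressure deficit e_s - e_a in hPa; rh is relative humidity in %."""
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity out of [0, 100]")
    es = saturation_vapour_pressure(t)
    return es * (1.0 - rh / 100.0)


def daily_max_vpd(subdaily: pd.DataFrame) -> pd.Series:
    """Daily maxima of VPD from sub-daily temperature/humidity samples.

    ``subdaily`` needs a DatetimeIndex and columns ``t`` (degC), ``rh`` (%).
    """
    v = pd.Series(vpd(subdaily["t"].to_numpy(), subdaily["rh"].to_numpy()),
                  index=subdaily.index)
    return v.groupby(v.index.normalize()).max()


def mean_daily_max_vpd(daily: pd.DataFrame, window: PeriodWindow,
                       tolerance: float = 0.05) -> float:
    """Window mean of the daily maximum VPD.

    Expects a precomputed ``vpd_max`` column (from sub-daily data); falls
    back to VPD at daily maximum temperature with the daily mean relative
    humidity when only daily records exist.
    """
    if "vpd_max" in daily.columns:
        vals = _window_values(daily, window, "vpd_max", tolerance)
        return float(vals.mean())
    t = _window_values(daily, window, "tmax", tolerance)
    rh = _window_values(daily, window, "rh", tolerance)
    aligned = pd.concat([t, rh], axis=1).dropna()
    return float(np.mean(vpd(aligned["tmax"].to_numpy(), aligned["rh"].to_numpy())))


# ---------------------------------------------------------------------------
# Thornthwaite PET and SPEI
# ---------------------------------------------------------------------------

def monthly_series(daily: pd.DataFrame) -> pd.DataFrame:
    """Monthly mean temperature and precipitation sum from daily records."""
    grouper = pd.PeriodIndex(daily.index, freq="M")
    out = pd.DataFrame({
        "tmean": daily["tmean"].groupby(grouper).mean(),
        "ppt": daily["ppt"].groupby(grouper).sum(),
    })
    out.index.name = "month"
    return out


def _monthly_daylength_correction(latitude: float, year: int) -> np.ndarray:
    """Thornthwaite day-length correction L_m = (N/12) * (days/30) per month."""
    phi = np.deg2rad(latitude)
    L = np.empty(12)
    for m in range(1, 13):
        ndays = calendar.monthrange(year, m)[1]
        mid = pd.Timestamp(year, m, 15).dayofyear
        delta = 0.4093 * np.sin(2.0 * np.pi * mid / 365.25 - 1.405)
        cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
        ws = np.arccos(cos_ws)
        N = 24.0 * ws / np.pi
        L[m - 1] = (N / 12.0) * (ndays / 30.0)
    return L


def thornthwaite_pet(monthly_tmean: pd.Series, latitude: float | None = None) -> pd.Series:
    """Monthly potential evapotranspiration (mm) by the Thornthwaite method.

    Heat index I = sum over months with T > 0 of (T/5)^1.514 per year;
    a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239;
    PET_m = 16 (10 T_m / I)^a * L_m, zero for T_m <= 0.  ``latitude`` in
    degrees drives the day-length correction L_m; with ``latitude=None``
    L_m = 1 (useful for closed-form checks).
    """
    tm = monthly_tmean.copy()
    if not isinstance(tm.index, pd.PeriodIndex):
        tm.index = pd.PeriodIndex(tm.index, freq="M")
    pet = pd.Series(np.nan, index=tm.index, dtype=float)
    for year, grp in tm.groupby(tm.index.year):
        if len(grp) < 12:
            continue  # Thornthwaite needs the full calendar year's heat index
        t = grp.to_numpy(dtype=float)
        pos = np.clip(t, 0.0, None)
        I = float(np.sum((pos[pos > 0] / 5.0) ** 1.514))
        if I == 0.0:
            raise ValueError(f"thornthwaite_pet: all months <= 0 degC in {year}")
        a = 6.75e-7 * I**3 - 7.71e-5 * I**2 + 1.792e-2 * I + 0.49239
        L = np.ones(12) if latitude is None else _monthly_daylength_correction(latitude, int(year))
        months = grp.index.month.to_numpy() - 1
        vals = np.where(t > 0.0, 16.0 * (10.0 * pos / I) ** a * L[months], 0.0)
        pet.loc[grp.index] = vals
    return pet.dropna()


def _unbiased_pwms(x: np.ndarray) -> tuple[float, float, float]:
    """Unbiased probability-weighted moments b_s = E[X F^s], s = 0, 1, 2."""
    x = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    b0 = x.mean()
    b1 = np.sum(x * (i - 1)) / (n * (n - 1))
    b2 = np.sum(x * (i - 1) * (i - 2)) / (n * (n - 1) * (n - 2))
    return float(b0), float(b1), float(b2)


def _loglogistic_params(x: np.ndarray) -> tuple[float, float, float]:
    """Fit the 3-parameter log-logistic distribution by unbiased PWMs.

    The fit goes through L-moments in the generalized-logistic
    parameterisation (xi location, alpha scale, kappa = -tau3 shape),
    which is the log-logistic for positive skew and remains well defined
    for near-symmetric and negatively skewed samples.  Returns
    (xi, alpha, kappa); the CDF is 1 / (1 + exp(-y)) with
    y = -log(1 - kappa (x - xi) / alpha) / kappa (y = (x - xi)/alpha as
    kappa -> 0).
    """
    b0, b1, b2 = _unbiased_pwms(x)
    l1 = b0
    l2 = 2.0 * b1 - b0
    l3 = 6.0 * b2 - 6.0 * b1 + b0
    if l2 <= 0:
        raise ValueError("log-logistic PWM fit failed: non-positive L-scale")
    kappa = -l3 / l2
    if abs(kappa) >= 1.0:
        raise ValueError("log-logistic PWM fit failed: |tau3| >= 1")
    if abs(kappa) < 1e-8:
        alpha = l2
        xi = l1
    else:
        gg = kappa * np.pi / np.sin(kappa * np.pi)
        alpha = l2 / gg
        xi = l1 - alpha * (1.0 / kappa - gg / kappa)
    return float(xi), float(alpha), float(kappa)


def _loglogistic_cdf(x: np.ndarray, xi: float, alpha: float, kappa: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if abs(kappa) < 1e-8:
        y = (x - xi) / alpha
    else:
        arg = 1.0 - kappa * (x - xi) / alpha
        # beyond the support bound the CDF saturates at 0 or 1
        y = np.where(arg > 0, -np.log(np.maximum(arg, 1e-300)) / kappa,
                     np.inf if kappa > 0 else -np.inf)
    return 1.0 / (1.0 + np.exp(-y))


@dataclass
class SpeiSeries:
    """SPEI values with their water-balance aggregates and calibration span."""

    scale: int
    data: pd.DataFrame  # PeriodIndex (monthly); columns: D, spei
    calibration: tuple[int, int]

    def value(self, year: int, month: int) -> float:
        return float(self.data.loc[pd.Period(f"{year}-{month:02d}", "M"), "spei"])

    def vegetation_period_mean(self, year: int) -> float:
        idx = [pd.Period(f"{year}-{m:02d}", "M") for m in VEGETATION_MONTHS]
        vals = self.data.reindex(idx)["spei"]
        return float(vals.mean())


def spei(ppt_monthly: pd.Series, pet_monthly: pd.Series, scale: int = 3,
         calibration: tuple[int, int] | None = None) -> SpeiSeries:
    """Standardised precipitation-evapotranspiration index.

    The climatic water balance D = PPT - PET is summed over ``scale``
    backward-looking months (assigned to the ending month); per calendar
    month a 3-parameter log-logistic distribution is fitted over the
    calibration years by unbiased probability-weighted moments, and the
    CDF value is mapped to a standard-normal deviate.
    """
    d = (ppt_monthly - pet_monthly).dropna()
    if not isinstance(d.index, pd.PeriodIndex):
        d.index = pd.PeriodIndex(d.index, freq="M")
    d = d.sort_index()
    dk = d.rolling(scale).sum().dropna()
    years = dk.index.year
    if calibration is None:
        calibration = (int(years.min()), int(years.max()))
    ncal = calibration[1] - calibration[0] + 1
    if ncal < 30:
        warnings.warn(
            f"SPEI calibration period has only {ncal} years (< 30 recommended)",
            stacklevel=2,
        )
    out = pd.DataFrame({"D": dk, "spei": np.nan})
    for month in range(1, 13):
        in_month = dk.index.month == month
        cal = dk[in_month & (years >= calibration[0]) & (years <= calibration[1])]
        if len(cal) < 3 or np.ptp(cal.to_numpy()) == 0.0:
            raise ValueError(f"SPEI: degenerate water balance in calendar month {month}")
        xi, alpha, kappa = _loglogistic_params(cal.to_numpy())
        F = _loglogistic_cdf(dk[in_month].to_numpy(), xi, alpha, kappa)
        F = np.clip(F, 1e-6, 1.0 - 1e-6)
        out.loc[in_month, "spei"] = norm.ppf(F)
    return SpeiSeries(scale=scale, data=out, calibration=calibration)


def classify_drought(spei3: float) -> str:
    """Drought class from SPEI: moderate [-1.49, -1.00], severe
    [-1.99, -1.50], extreme (<= -2.00), else none."""
    if not np.isfinite(spei3):
        raise ValueError("classify_drought: non-finite SPEI value")
    if spei3 <= -2.0:
        return "extreme"
    if spei3 <= -1.5:
        return "severe"
    if spei3 <= -1.0:
        return "moderate"
    return "none"


# ---------------------------------------------------------------------------
# Yearly climate index table
# ---------------------------------------------------------------------------

@dataclass
class ClimateIndexTable:
    """Per-year climate variable values on monthly / VP / PW windows.

    ``data`` has one row per year and MultiIndex columns
    (variable, window) with window in M01..M12, VP, PW.
    """

    data: pd.DataFrame
    spei_series: SpeiSeries | None = None

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def column(self, variable: str, window: str) -> pd.Series:
        return self.data[(variable, window)]

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack([0, 1], future_stack=True).rename("value").reset_index()
        long.columns = ["year", "variable", "window", "value"]
        return long


_AGGREGATES = {
    "tmean": lambda d, w, tol: aggregate_period(d, w, "tmean", "mean", tol),
    "hs": lambda d, w, tol: heat_sum(d, w, tolerance=tol),
    "nhd": lambda d, w, tol: threshold_day_count(d, w, "hot", tol),
    "vpd": lambda d, w, tol: mean_daily_max_vpd(d, w, tol),
    "ppt": lambda d, w, tol: aggregate_period(d, w, "ppt", "sum", tol),
    "nrd": lambda d, w, tol: threshold_day_count(d, w, "rain", tol),
    "nfd": lambda d, w, tol: threshold_day_count(d, w, "frost", tol),
    "nid": lambda d, w, tol: threshold_day_count(d, w, "ice", tol),
}


def climate_index_table(
    daily: pd.DataFrame,
    years: list[int] | np.ndarray,
    latitude: float | None = 49.93,
    spei_scale: int = 3,
    spei_calibration: tuple[int, int] | None = None,
    tolerance: float = 0.05,
) -> ClimateIndexTable:
    """Compute every variable on every window for the given years.

    Windows whose day range is not (sufficiently) covered by the daily
    record yield NaN.  SPEI monthly values are the index at the ending
    month; the VP value is the April-September mean.
    """
    monthly = monthly_series(daily)
    pet = daily.get("pet")
    if pet is not None and pet.notna().all():
        pet_monthly = pet.groupby(pd.PeriodIndex(daily.index, freq="M")).sum()
    else:
        pet_monthly = thornthwaite_pet(monthly["tmean"], latitude)
    try:
        spei_series = spei(monthly["ppt"], pet_monthly, scale=spei_scale,
                           calibration=spei_calibration)
    except ValueError as exc:
        warnings.warn(f"SPEI unavailable: {exc}", stacklevel=2)
        spei_series = None

    windows = [f"M{m:02d}" for m in range(1, 13)] + ["VP", "PW"]
    columns = pd.MultiIndex.from_product(
        [list(_AGGREGATES) + ["spei3"], windows], names=["variable", "window"]
    )
    table = pd.DataFrame(index=pd.Index(years, name="year"), columns=columns, dtype=float)

    for year in years:
        wins = {f"M{m:02d}": month_window(int(year), m) for m in range(1, 13)}
        wins["VP"] = vegetation_period(int(year))
        wins["PW"] = previous_winter(int(year))
        for var, fn in _AGGREGATES.items():
            for wlabel, win in wins.items():
                try:
                    table.loc[year, (var, wlabel)] = fn(daily, win, tolerance)
                except (ValueError, KeyError):
                    table.loc[year, (var, wlabel)] = np.nan
        if spei_series is not None:
            for m in range(1, 13):
                period = pd.Period(f"{int(year)}-{m:02d}", "M")
                if period in spei_series.data.index:
                    table.loc[year, ("spei3", f"M{m:02d}")] = spei_series.data.loc[period, "spei"]
            try:
                table.loc[year, ("spei3", "VP")] = spei_series.vegetation_period_mean(int(year))
            except KeyError:
                pass

    return ClimateIndexTable(data=table, spei_series=spei_series)


@dataclass
class StressYearReport:
    """Primary and confirmation stress flags for one year."""

    year: int
    tmean_vp: float
    ppt_vp: float
    primary_hot: bool       # VP T_mean >= 90th percentile
    primary_dry: bool       # VP PPT <= 10th percentile
    confirmations: dict[str, bool] = field(default_factory=dict)
    spei_vp: float = np.nan
    drought_class_by_month: dict[int, str] = field(default_factory=dict)

    @property
    def is_stress(self) -> bool:
        return self.primary_hot or self.primary_dry


def detect_stress_years(
    table: ClimateIndexTable,
    study_years: list[int] | np.ndarray | None = None,
) -> list[StressYearReport]:
    """Flag climatic stress years from vegetation-period extremes.

    Primary criteria: VP T_mean >= 90th percentile of the study years,
    VP PPT <= 10th percentile.  Confirmation flags: nhd/hs/VPD >= their
    90th percentiles, nrd <= its 10th, and VP-average SPEI3 < -1.
    Percentiles use linear interpolation between order statistics, so
    ties at the threshold all flag.
    """
    years = np.asarray(study_years if study_years is not None else table.years, dtype=int)
    if len(years) < 10:
        warnings.warn(f"only {len(years)} study years; percentiles are coarse", stacklevel=2)
    sub = table.data.loc[years]

    def pct(var: str, q: float) -> float:
        vals = sub[(var, "VP")].dropna().to_numpy()
        return float(np.percentile(vals, q))

    thresholds = {
        "tmean_p90": pct("tmean", 90), "ppt_p10": pct("ppt", 10),
        "nhd_p90": pct("nhd", 90), "hs_p90": pct("hs", 90),
        "vpd_p90": pct("vpd", 90), "nrd_p10": pct("nrd", 10),
    }
    reports = []
    for year in years:
        row = sub.loc[year]
        tm, pp = row[("tmean", "VP")], row[("ppt", "VP")]
        spei_vp = row[("spei3", "VP")]
        classes = {}
        for m in range(1, 13):
            v = row[("spei3", f"M{m:02d}")]
            if np.isfinite(v):
                classes[m] = classify_drought(float(v))
        reports.append(StressYearReport(
            year=int(year),
            tmean_vp=float(tm),
            ppt_vp=float(pp),
            primary_hot=bool(np.isfinite(tm) and tm >= thresholds["tmean_p90"]),
            primary_dry=bool(np.isfinite(pp) and pp <= thresholds["ppt_p10"]),
            confirmations={
                "nhd": bool(row[("nhd", "VP")] >= thresholds["nhd_p90"]),
                "hs": bool(row[("hs", "VP")] >= thresholds["hs_p90"]),
                "vpd": bool(row[("vpd", "VP")] >= thresholds["vpd_p90"]),
                "nrd": bool(row[("nrd", "VP")] <= thresholds["nrd_p10"]),
                "spei3": bool(np.isfinite(spei_vp) and spei_vp < -1.0),
            },
            spei_vp=float(spei_vp) if np.isfinite(spei_vp) else np.nan,
            drought_class_by_month=classes,
        ))
    return reports
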