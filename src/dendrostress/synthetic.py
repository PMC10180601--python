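"""Synthetic daily climate and multi-species ring-width forests.

The generator produces datasets with the shape of a temperate
single-site conifer comparison — a ~26-year bivariate growth/climate
record, 13-27 trees per species with two cores each, an age-related
negative-exponential growth trend, species-specific monthly climate
sensitivity, and engineered hot-dry vegetation periods — with the ground
truth (driver month/variable, sensitivity, drought multipliers) returned
so every pipeline stage has a recovery test.

Climate defaults target a transitional oceanic/continental site: annual
mean temperature 8.2 degC, annual precipitation ~741 mm, vegetation-
period (April-September) mean 13.9 degC and ~399 mm.  Growth is
multiplicative: ring width = age trend x exp(beta * driver z-score) x
drought multiplier x lognormal year/tree/core noise, which keeps widths
positive and makes the programmed drought multiplier the analytic
expectation of per-tree resistance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import VEGETATION_MONTHS, monthly_series
from .ringwidth import CoreSeries

__all__ = [
    "ClimateGenConfig",
    "ForestGenConfig",
    "simulate_climate",
    "simulate_forest",
    "default_climate_config",
    "default_forest_configs",
]


@dataclass
class ClimateGenConfig:
    """Parameters of the daily weather generator.

    ``drought_years`` maps a year to (vegetation-period temperature offset
    in degC, vegetation-period precipitation multiplier in (0, 1]).
    """

    start_year: int = 1994
    years: int = 26
    seed: int = 0
    mean_temp: float = 8.2            # degC, annual mean
    seasonal_amplitude: float = 9.4   # degC; peaks in mid-July (doy 200)
    peak_doy: int = 200
    ar1_phi: float = 0.7              # day-to-day temperature noise memory
    noise_sd: float = 3.0             # degC, innovation sd
    diurnal_half_range: float = 5.5   # degC, (tmax - tmin)/2 around tmean
    wet_day_prob: float = 0.5
    gamma_shape: float = 0.9
    vp_daily_ppt: float = 2.18        # mm/day target, April-September
    winter_daily_ppt: float = 1.88    # mm/day target, rest of the year
    rh_base: float = 85.0             # %, before temperature-anomaly coupling
    rh_temp_slope: float = 1.3        # % per degC of temperature anomaly
    rh_noise_sd: float = 5.0
    drought_years: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for year, (_, mult) in self.drought_years.items():
            if not 0.0 < mult <= 1.0:
                raise ValueError(f"drought {year}: precipitation multiplier must be in (0, 1]")
        if self.vp_daily_ppt < 0 or self.winter_daily_ppt < 0:
            raise ValueError("precipitation rates must be >= 0")


def simulate_climate(config: ClimateGenConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a daily climate record (tmin/tmax/tmean/ppt/rh).

    Reproducible given the seed; drought years get their configured
    vegetation-period temperature offset and precipitation multiplier.
    Set ``noise_sd=0``, ``rh_noise_sd=0`` and ``wet_day_prob=0`` for the
    deterministic seasonal cycle.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dates = pd.date_range(
        start=f"{config.start_year}-01-01",
        end=f"{config.start_year + config.years - 1}-12-31",
        freq="D",
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()
    year = dates.year.to_numpy()

    seasonal = config.mean_temp + config.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - config.peak_doy) / 365.25
    )
    if config.noise_sd > 0:
        innov = rng.normal(0.0, config.noise_sd, size=n)
        anom = np.empty(n)
        anom[0] = innov[0] / np.sqrt(1.0 - config.ar1_phi**2)
        for i in range(1, n):
            anom[i] = config.ar1_phi * anom[i - 1] + innov[i]
    else:
        anom = np.zeros(n)

    in_vp = np.isin(month, VEGETATION_MONTHS)
    temp_offset = np.zeros(n)
    ppt_mult = np.ones(n)
    for dyear, (toff, pmult) in config.drought_years.items():
        mask = (year == dyear) & in_vp
        temp_offset[mask] = toff
        ppt_mult[mask] = pmult

    tmean = seasonal + anom + temp_offset
    half = config.diurnal_half_range
    tmin = tmean - half + rng.normal(0.0, 1.0, n)
    tmax = tmean + half + rng.normal(0.0, 1.0, n)
    tmin = np.minimum(tmin, tmean)
    tmax = np.maximum(tmax, tmean)

    rate = np.where(in_vp, config.vp_daily_ppt, config.winter_daily_ppt)
    if config.wet_day_prob > 0:
        wet = rng.random(n) < config.wet_day_prob
        mean_amount = rate / config.wet_day_prob
        amounts = rng.gamma(config.gamma_shape, mean_amount / config.gamma_shape, size=n)
        ppt = np.where(wet, amounts, 0.0) * ppt_mult
    else:
        ppt = np.zeros(n)

    rh = config.rh_base - config.rh_temp_slope * (anom + temp_offset)
    if config.rh_noise_sd > 0:
        rh = rh + rng.normal(0.0, config.rh_noise_sd, n)
    rh = np.clip(rh, 20.0, 100.0)

    return pd.DataFrame(
        {"tmin": tmin, "tmax": tmax, "tmean": tmean, "ppt": ppt, "rh": rh},
        index=dates,
    )


@dataclass
class ForestGenConfig:
    """Parameters of the ring-width generator for one species.

    ``driver`` is a (variable, window) pair, e.g. ("ppt", "FEB") for
    current-year February precipitation or ("ppt", "feb") for the previous
    year's February (lower case = previous year, as in correlation-function
    tables); "VP"/"PW" select the seasonal aggregates.  ``beta`` scales the
    standardised driver; ``drought_multipliers`` maps years to the growth
    multiplier realised in those years (the ground truth for resistance).

    The default ``beta`` makes the chronology-level true correlation with
    the driver ~0.6 once the shared year effect, the per-tree noise
    (attenuated by averaging over ~20-27 trees) and the drought-multiplier
    variance are accounted for:
    r = beta / sqrt(beta^2 + sd_year^2 + var_drought + sd_tree^2 / n).
    """

    species: str
    n_trees: int = 20
    cores_per_tree: int = 2
    seed: int = 0
    trend_initial: float = 3.0      # mm above asymptote at the series start
    trend_tau: float = 15.0         # years, e-folding of the age trend
    trend_asymptote: float = 3.0    # mm
    age_offset: int = 14            # rings formed before the record starts
    driver: tuple[str, str] = ("ppt", "FEB")
    beta: float = 0.165
    common_year_sd: float = 0.20    # lognormal sd of the shared year effect
    tree_noise_sd: float = 0.25     # lognormal sd per tree-year
    core_noise_sd: float = 0.10     # lognormal sd per core-year
    drought_multipliers: dict[int, float] = field(default_factory=dict)
    #: species growing on the same site should share the year effect (it
    #: stands for site weather not captured by the driver); give them the
    #: same value here.  None draws it from the species' own stream.
    year_effect_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 2:
            raise ValueError("need at least 2 trees")
        if self.trend_asymptote <= 0:
            raise ValueError("age trend must stay positive")
        for year, mult in self.drought_multipliers.items():
            if mult <= 0:
                raise ValueError(f"drought multiplier for {year} must be > 0")


def _driver_zscore(daily: pd.DataFrame, driver: tuple[str, str],
                   years: np.ndarray) -> pd.Series:
    """Standardised yearly values of the configured climate driver."""
    variable, window = driver
    monthly = monthly_series(daily)
    if variable != "ppt":
        raise ValueError("the growth generator supports precipitation drivers")
    month_names = ["jan", "feb", "mar", "apr", "may", "jun",
                   "jul", "aug", "sep", "oct", "nov", "dec"]
    if window == "VP":
        vals = pd.Series({
            y: monthly.loc[[pd.Period(f"{y}-{m:02d}", "M") for m in VEGETATION_MONTHS], "ppt"].sum()
            for y in years
        })
    elif window == "PW":
        vals = pd.Series({
            y: monthly.reindex(
                [pd.Period(f"{y - 1}-{m:02d}", "M") for m in (10, 11, 12)]
                + [pd.Period(f"{y}-{m:02d}", "M") for m in (1, 2, 3)]
            )["ppt"].sum()
            for y in years
        })
    else:
        lag = 1 if window.islower() else 0
        m = month_names.index(window.lower()) + 1
        vals = pd.Series({
            y: monthly["ppt"].get(pd.Period(f"{y - lag}-{m:02d}", "M"), np.nan)
            for y in years
        })
    vals = vals.astype(float)
    return (vals - vals.mean()) / vals.std(ddof=0)


def simulate_forest(
    config: ForestGenConfig, daily: pd.DataFrame, seed: int | None = None
) -> tuple[list[CoreSeries], dict]:
    """Generate two-core trees driven by a climate variable plus droughts.

    Returns the cores and a ground-truth record (driver, beta, drought
    multipliers, the realised driver z-scores and the noise-free expected
    widths) for recovery tests.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    years = np.unique(daily.index.year.to_numpy())
    z = _driver_zscore(daily, config.driver, years)
    if z.isna().any():
        missing = [int(y) for y in z.index[z.isna()]]
        raise ValueError(f"climate does not cover the driver for years {missing}")

    t = np.arange(len(years), dtype=float) + config.age_offset
    trend = config.trend_initial * np.exp(-t / config.trend_tau) + config.trend_asymptote
    mult = np.array([config.drought_multipliers.get(int(y), 1.0) for y in years])
    expected = trend * np.exp(config.beta * z.to_numpy()) * mult
    if (expected <= 0).any():
        raise ValueError("configuration produces non-positive expected widths")

    if config.year_effect_seed is not None:
        site_rng = np.random.default_rng(config.year_effect_seed)
        year_effect = site_rng.normal(0.0, config.common_year_sd, size=len(years))
    else:
        year_effect = rng.normal(0.0, config.common_year_sd, size=len(years))
    cores: list[CoreSeries] = []
    for i in range(config.n_trees):
        tree_effect = rng.normal(0.0, config.tree_noise_sd, size=len(years))
        tree_signal = expected * np.exp(year_effect + tree_effect)
        for c in range(config.cores_per_tree):
            core_noise = rng.normal(0.0, config.core_noise_sd, size=len(years))
            widths = tree_signal * np.exp(core_noise)
            cores.append(CoreSeries(
                tree_id=f"{config.species}{i + 1:03d}",
                core_id=f"{config.species}{i + 1:03d}{chr(ord('a') + c)}",
                species=config.species,
                first_year=int(years[0]),
                widths=widths,
            ))
    truth = {
        "species": config.species,
        "driver": config.driver,
        "beta": config.beta,
        "drought_multipliers": dict(config.drought_multipliers),
        "driver_z": {int(y): float(v) for y, v in z.items()},
        "expected_widths": {int(y): float(v) for y, v in zip(years, expected)},
    }
    return cores, truth


#: Default drought years (year -> (VP temperature offset, VP precip multiplier)).
#: Two severe hot-dry years and two milder ones, at record positions 10/19/22/25.
DEFAULT_DROUGHTS = {
    2003: (3.0, 0.45),
    2012: (0.5, 0.85),
    2015: (1.5, 0.70),
    2018: (3.0, 0.50),
}


def default_climate_config(seed: int = 0) -> ClimateGenConfig:
    """The 26-year study-shaped climate with the default drought years."""
    return ClimateGenConfig(seed=seed, drought_years=dict(DEFAULT_DROUGHTS))


def default_forest_configs(seed: int = 0) -> list[ForestGenConfig]:
    """Three species mimicking the study layout: a cedar-like species
    sensitive to February precipitation, a spruce-like one to June
    precipitation and a pine-like one to July precipitation, with
    graded drought tolerance (cedar > pine > spruce)."""
    return [
        ForestGenConfig(
            species="CED", n_trees=27, seed=(seed * 7919 + 1) % 2**31,
            year_effect_seed=(seed * 7919 + 17) % 2**31,
            driver=("ppt", "FEB"),
            drought_multipliers={2003: 0.75, 2012: 0.80, 2015: 0.95, 2018: 0.95},
        ),
        ForestGenConfig(
            species="SPR", n_trees=17, seed=(seed * 7919 + 2) % 2**31,
            year_effect_seed=(seed * 7919 + 17) % 2**31,
            driver=("ppt", "JUN"),
            drought_multipliers={2003: 0.50, 2012: 0.70, 2015: 0.85, 2018: 0.55},
        ),
        ForestGenConfig(
            species="PIN", n_trees=13, seed=(seed * 7919 + 3) % 2**31,
            year_effect_seed=(seed * 7919 + 17) % 2**31,
            driver=("ppt", "JUL"),
            drought_multipliers={2003: 0.70, 2012: 1.00, 2015: 0.80, 2018: 0.65},
        ),
    ]
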