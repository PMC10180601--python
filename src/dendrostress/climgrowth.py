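"""Bootstrapped Pearson correlation functions between growth and climate.

A growth index chronology is paired year-by-year with monthly and
seasonal climate variables from the previous-year September through the
current-year September (previous-year months are labelled in lower case,
current-year months in capitals, following dendroclimatological
convention), plus vegetation-period and previous-winter aggregates.  For
every (variable, window) cell the full-sample Pearson coefficient is
reported with a percentile confidence interval from resampling year pairs
with replacement; a cell is significant when the interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimateIndexTable, VARIABLE_WINDOWS
from .detrend import GrowthIndexChronology

__all__ = [
    "MONTH_LABELS",
    "default_month_windows",
    "build_design_matrix",
    "CorrelationResult",
    "bootstrap_pearson",
    "correlation_function",
]

MONTH_LABELS = ["jan", "feb", "mar", "apr", "may", "jun",
                "jul", "aug", "sep", "oct", "nov", "dec"]


def default_month_windows() -> list[tuple[int, int]]:
    """(lag, month) pairs from previous September to current September.

    lag 1 = previous calendar year (lower-case label), lag 0 = current.
    """
    return [(1, m) for m in range(9, 13)] + [(0, m) for m in range(1, 10)]


def _window_label(lag: int, month: int) -> str:
    name = MONTH_LABELS[month - 1]
    return name if lag == 1 else name.upper()


def build_design_matrix(
    gic: GrowthIndexChronology,
    climate: ClimateIndexTable,
    month_windows: list[tuple[int, int]] | None = None,
    min_overlap: int = 15,
) -> pd.DataFrame:
    """Year-aligned matrix of climate predictors plus the GIC response.

    One row per overlapping year; previous-year months of row year y read
    calendar year y-1.  Zero-variance or incomplete columns are dropped
    with a warning.  The GIC is the last column, named ``gic``.
    """
    if month_windows is None:
        month_windows = default_month_windows()
    years = np.asarray(
        sorted(set(gic.values.index) & set(int(y) for y in climate.years)), dtype=int
    )
    if len(years) < min_overlap:
        raise ValueError(
            f"only {len(years)} overlapping years (< {min_overlap}) between GIC and climate"
        )
    cols: dict[tuple[str, str], np.ndarray] = {}
    for var, scales in VARIABLE_WINDOWS.items():
        if "monthly" in scales:
            for lag, month in month_windows:
                src = climate.data[(var, f"M{month:02d}")]
                vals = src.reindex(years - lag).to_numpy()
                cols[(var, _window_label(lag, month))] = vals
        for seasonal in ("VP", "PW"):
            if seasonal in scales:
                cols[(var, seasonal)] = climate.data[(var, seasonal)].reindex(years).to_numpy()

    design = pd.DataFrame(cols, index=pd.Index(years, name="year"))
    # leading years lack lagged/previous-winter climate: drop rows first,
    # as long as enough years remain, then any still-incomplete or
    # constant columns (e.g. summer ice-day counts)
    complete_rows = design.dropna()
    if len(complete_rows) >= min_overlap:
        design = complete_rows
    bad = [c for c in design.columns
           if design[c].isna().any() or np.nanstd(design[c].to_numpy()) == 0.0]
    if bad:
        warnings.warn(f"dropping {len(bad)} incomplete/constant climate columns", stacklevel=2)
        design = design.drop(columns=bad)
    design[("gic", "")] = gic.values.reindex(design.index).to_numpy()
    return design


@dataclass
class CorrelationResult:
    """Bootstrapped Pearson correlation for one (variable, window) cell."""

    variable: str
    window: str
    r: float
    ci_low: float
    ci_high: float
    significant: bool
    n_years: int
    n_boot: int
    seed: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd, yd = x - x.mean(), y - y.mean()
    return float(np.dot(xd, yd) / np.sqrt(np.dot(xd, xd) * np.dot(yd, yd)))


def _bootstrap_r(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pearson r for each row of resampled indices (vectorised)."""
    xs, ys = x[idx], y[idx]
    xd = xs - xs.mean(axis=1, keepdims=True)
    yd = ys - ys.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", xd, yd)
    den = np.sqrt(np.einsum("ij,ij->i", xd, xd) * np.einsum("ij,ij->i", yd, yd))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_pearson(
    x, y, n_boot: int = 1000, ci: float = 0.95, seed: int = 0,
    variable: str = "", window: str = "",
) -> CorrelationResult:
    """Full-sample Pearson r with a percentile bootstrap confidence interval.

    Pairs are resampled with replacement ``n_boot`` times; the reported r
    is the full-sample coefficient, the bootstrap supplies only the CI.
    Significance means the CI excludes zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"bootstrap_pearson: n={n} pairs is too small (< 10)")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("bootstrap_pearson: zero-variance input")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = _bootstrap_r(x, y, idx)
    boots = boots[np.isfinite(boots)]
    alpha = 1.0 - ci
    lo, hi = np.percentile(boots, [100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)])
    return CorrelationResult(
        variable=variable, window=window,
        r=_pearson(x, y), ci_low=float(lo), ci_high=float(hi),
        significant=bool(lo > 0.0 or hi < 0.0),
        n_years=n, n_boot=n_boot, seed=seed,
    )


def correlation_function(
    gic: GrowthIndexChronology,
    climate: ClimateIndexTable,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
    month_windows: list[tuple[int, int]] | None = None,
    significant_only: bool = False,
) -> list[CorrelationResult]:
    """Bootstrapped correlation for every design-matrix cell.

    Each cell gets its own child seed spawned deterministically from
    ``seed`` so the result is reproducible and independent of cell order.
    """
    design = build_design_matrix(gic, climate, month_windows)
    y = design[("gic", "")].to_numpy()
    results = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(design.columns) - 1)
    for (col, child) in zip([c for c in design.columns if c != ("gic", "")], children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        res = bootstrap_pearson(
            design[col].to_numpy(), y, n_boot=n_boot, ci=ci, seed=child_seed,
            variable=col[0], window=col[1],
        )
        results.append(res)
    if significant_only:
        results = [r for r in results if r.significant]
    return results


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy frame shaped like a published correlation-function table."""
    return pd.DataFrame([{
        "variable": r.variable, "window": r.window, "r": r.r,
        "ci_low": r.ci_low, "ci_high": r.ci_high,
        "significant": r.significant, "n_years": r.n_years,
    } for r in results])
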