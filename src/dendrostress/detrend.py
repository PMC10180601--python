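"""Age-trend removal and standardised growth-index chronologies.

Each tree's mean ring-width series is detrended with a cubic smoothing
spline whose frequency response is 50% at a wavelength of 67% of the
series length (the conventional flexible-spline choice for removing
age/size trend while keeping interannual climate signal).  Growth indices
are the ratio measured/fitted, dimensionless and oscillating around 1.
Per species the indices are combined with Tukey's biweight robust mean
into a growth index chronology (GIC), whose common signal is summarised
by the mean inter-series correlation (Rbar) and the expressed population
signal (EPS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .ringwidth import TreeSeries

__all__ = [
    "SplineFit",
    "GrowthIndexSeries",
    "GrowthIndexChronology",
    "spline_smoothing_parameter",
    "fit_spline",
    "growth_indices",
    "biweight_mean",
    "chronology_stats",
    "build_gic",
]


@dataclass
class SplineFit:
    """Cubic smoothing-spline fit to an annual series."""

    values: np.ndarray
    fitted: np.ndarray
    cutoff_fraction: float
    amplitude: float
    lam: float


@dataclass
class GrowthIndexSeries:
    """Detrended, standardised growth indices of one tree (year -> index)."""

    tree_id: str
    indices: pd.Series


@dataclass
class GrowthIndexChronology:
    """Species growth index chronology (GIC) with quality statistics."""

    species: str
    values: pd.Series
    depth: pd.Series
    rbar: float = field(default=np.nan)
    eps: float = field(default=np.nan)
    mean_depth: float = field(default=np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": self.values, "depth": self.depth})


def spline_smoothing_parameter(period: float, amplitude: float = 0.5) -> float:
    """Smoothing parameter lam with frequency-response gain ``amplitude`` at
    wavelength ``period`` (years).

    For the penalised cubic smoothing spline (squared second-derivative
    penalty) the stationary response at angular frequency w is
    1 / (1 + lam * w^4), so lam = (1/amplitude - 1) / w^4.
    """
    if not 0 < amplitude < 1:
        raise ValueError("amplitude must be in (0, 1)")
    w = 2.0 * np.pi / period
    return (1.0 / amplitude - 1.0) / w**4


def fit_spline(
    x, cutoff_fraction: float = 0.67, amplitude: float = 0.5, period: float | None = None
) -> SplineFit:
    """Fit the detrending spline to an annual series.

    The cutoff wavelength defaults to ``cutoff_fraction`` times the series
    length; ``period`` overrides it with an explicit wavelength in years.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"fit_spline: series too short (n={n} < 10)")
    if not np.all(np.isfinite(x)):
        raise ValueError("fit_spline: non-finite values")
    p = float(period) if period is not None else cutoff_fraction * n
    lam = spline_smoothing_parameter(p, amplitude)
    t = np.arange(n, dtype=float)
    fitted = make_smoothing_spline(t, x, lam=lam)(t)
    return SplineFit(values=x, fitted=fitted, cutoff_fraction=cutoff_fraction,
                     amplitude=amplitude, lam=lam)


def growth_indices(raw: TreeSeries, fit: SplineFit) -> GrowthIndexSeries:
    """Ratio indices: measured ring width divided by the spline's fitted value."""
    if fit.fitted.size != raw.widths.size:
        raise ValueError("growth_indices: fit length does not match series")
    bad = np.nonzero(fit.fitted <= 0)[0]
    if bad.size:
        year = int(raw.widths.index[bad[0]])
        raise ValueError(f"growth_indices: non-positive fitted value in year {year}")
    idx = pd.Series(raw.widths.to_numpy() / fit.fitted, index=raw.widths.index)
    return GrowthIndexSeries(tree_id=raw.tree_id, indices=idx)


def detrend_tree(
    tree: TreeSeries, cutoff_fraction: float = 0.67, amplitude: float = 0.5
) -> GrowthIndexSeries:
    """Convenience: spline fit + ratio indices for one tree."""
    fit = fit_spline(tree.widths.to_numpy(), cutoff_fraction, amplitude)
    return growth_indices(tree, fit)


def biweight_mean(values, c: float = 9.0, tol: float = 1e-6, max_iter: int = 50) -> float:
    """Tukey's biweight robust location.

    u_i = (x_i - M) / (c * MAD(M)); weights (1 - u^2)^2 for |u| < 1, else 0;
    M is iterated from the median until it moves by less than ``tol``.
    Degenerate spread (MAD = 0) falls back to the median.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("biweight_mean: no finite values")
    if x.size == 1:
        return float(x[0])
    m = float(np.median(x))
    for _ in range(max_iter):
        mad = float(np.median(np.abs(x - m)))
        if mad == 0.0:
            return float(np.median(x))
        u = (x - m) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0.0:
            return float(np.median(x))
        m_new = float(np.sum(w * x) / np.sum(w))
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


def chronology_stats(
    indices: list[GrowthIndexSeries], min_overlap: int = 10, mean_depth: float | None = None
) -> tuple[float, float]:
    """Rbar and EPS of a set of growth-index series.

    Rbar is the mean Pearson correlation over all tree pairs on each
    pair's common years (pairs with fewer than ``min_overlap`` common
    years are ignored).  EPS = n*rbar / (n*rbar + (1 - rbar)) with n the
    mean per-year sample depth (Wigley form).
    """
    if len(indices) < 2:
        raise ValueError("chronology_stats: need at least 2 series")
    table = pd.concat(
        [s.indices for s in indices], axis=1, keys=[s.tree_id for s in indices]
    )
    corrs = []
    for a, b in combinations(table.columns, 2):
        pair = table[[a, b]].dropna()
        if len(pair) < min_overlap:
            continue
        va, vb = pair[a].to_numpy(), pair[b].to_numpy()
        if va.std() == 0 or vb.std() == 0:
            continue
        corrs.append(float(np.corrcoef(va, vb)[0, 1]))
    if not corrs:
        raise ValueError("chronology_stats: no pair with sufficient overlap")
    rbar = float(np.mean(corrs))
    if mean_depth is None:
        mean_depth = float(table.notna().sum(axis=1).mean())
    eps = eps_from_rbar(rbar, mean_depth)
    return rbar, eps


def eps_from_rbar(rbar: float, n: float) -> float:
    """Expressed population signal: EPS = n*rbar / (n*rbar + (1 - rbar))."""
    denom = n * rbar + (1.0 - rbar)
    if denom == 0:
        return np.nan
    return float(n * rbar / denom)


def build_gic(
    trees: list[TreeSeries],
    cutoff_fraction: float = 0.67,
    amplitude: float = 0.5,
    min_depth: int = 2,
    biweight_c: float = 9.0,
) -> GrowthIndexChronology:
    """Detrend every tree, then combine indices into the species GIC.

    Per year (with at least ``min_depth`` trees) the chronology value is
    the Tukey biweight robust mean of the trees' indices; Rbar/EPS are
    attached.
    """
    if len(trees) < 2:
        raise ValueError("build_gic: need at least 2 trees")
    index_series = [detrend_tree(t, cutoff_fraction, amplitude) for t in trees]
    table = pd.concat(
        [s.indices for s in index_series], axis=1, keys=[s.tree_id for s in index_series]
    )
    depth = table.notna().sum(axis=1)
    keep = depth >= min_depth
    values = table[keep].apply(
        lambda row: biweight_mean(row.dropna().to_numpy(), c=biweight_c), axis=1
    )
    mean_depth = float(depth[keep].mean())
    rbar, eps = chronology_stats(index_series, mean_depth=mean_depth)
    return GrowthIndexChronology(
        species=trees[0].species,
        values=values,
        depth=depth[keep].astype(int),
        rbar=rbar,
        eps=eps,
        mean_depth=mean_depth,
    )
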