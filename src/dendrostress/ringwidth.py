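"""Raw ring-width series and species-level raw chronologies.

Ring widths are annual radial increments measured on increment cores
(stored in mm; RWL files carry them as 0.01-mm integers).  Two cores per
tree are arithmetically averaged to a per-tree mean radial growth series
(RGS); the RGS of all trees of a species are averaged to a raw radial
growth chronology (RGC) with a minimum replication requirement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CoreSeries",
    "TreeSeries",
    "RawChronology",
    "average_cores",
    "build_rgc",
    "lag1_autocorrelation",
]


@dataclass
class CoreSeries:
    """One increment core: consecutive annual ring widths in mm.

    ``widths`` may contain NaN for locally absent ("missing") rings; such
    years are treated as not measured, never as zero growth.
    """

    tree_id: str
    core_id: str
    species: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size < 2:
            raise ValueError(f"core {self.core_id}: need at least 2 rings")
        present = self.widths[~np.isnan(self.widths)]
        if (present < 0).any():
            raise ValueError(f"core {self.core_id}: negative ring width")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.widths.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.widths.size - 1

    def to_series(self) -> pd.Series:
        return pd.Series(self.widths, index=self.years, name=self.core_id)


@dataclass
class TreeSeries:
    """Mean radial growth series (RGS) of one tree, year -> width in mm."""

    tree_id: str
    species: str
    widths: pd.Series  # index: calendar year, ascending

    def __post_init__(self) -> None:
        self.widths = self.widths.dropna().astype(float).sort_index()
        if (self.widths <= 0).any():
            raise ValueError(f"tree {self.tree_id}: non-positive mean width")

    @property
    def years(self) -> np.ndarray:
        return self.widths.index.to_numpy()


@dataclass
class RawChronology:
    """Species-level raw chronology (RGC): per-year mean width and depth."""

    species: str
    values: pd.Series       # year -> mean ring width (mm)
    depth: pd.Series        # year -> number of contributing trees
    ar1: float = field(default=np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "depth": self.depth})


def average_cores(cores: list[CoreSeries]) -> TreeSeries:
    """Average a tree's cores into its mean radial growth series.

    Years present in only some cores take the mean over the cores that
    have a value there (missing rings are absent, not zero); the year span
    is the union of the core spans.
    """
    if not cores:
        raise ValueError("average_cores: no cores given")
    tree_ids = {c.tree_id for c in cores}
    if len(tree_ids) > 1:
        raise ValueError(f"average_cores: cores from different trees {sorted(tree_ids)}")
    if len(cores) == 1:
        logger.warning("tree %s has a single core; RGS equals that core", cores[0].tree_id)
    table = pd.concat(
        [c.to_series() for c in cores], axis=1, keys=range(len(cores))
    )
    mean = table.mean(axis=1, skipna=True).dropna()
    return TreeSeries(tree_id=cores[0].tree_id, species=cores[0].species, widths=mean)


def build_rgc(trees: list[TreeSeries], min_depth: int = 2) -> RawChronology:
    """Build the species raw chronology as a per-year arithmetic mean of RGS.

    Years covered by fewer than ``min_depth`` trees are dropped, following
    the requirement of at least two replicate series per retained year.
    """
    if not trees:
        raise ValueError("build_rgc: no trees given")
    species = {t.species for t in trees}
    if len(species) > 1:
        raise ValueError(f"build_rgc: trees from different species {sorted(species)}")
    table = pd.concat([t.widths for t in trees], axis=1, keys=[t.tree_id for t in trees])
    depth = table.notna().sum(axis=1)
    keep = depth >= min_depth
    if not keep.any():
        raise ValueError(f"build_rgc: no year reaches min_depth={min_depth}")
    values = table.mean(axis=1, skipna=True)[keep]
    chron = RawChronology(
        species=trees[0].species,
        values=values,
        depth=depth[keep].astype(int),
    )
    if len(values) >= 3 and np.ptp(values.to_numpy()) > 0:
        chron.ar1 = lag1_autocorrelation(values.to_numpy())
    return chron


def lag1_autocorrelation(x) -> float:
    """First-order autocorrelation (Ar1): previous year's hold on growth.

    Biased autocovariance-ratio estimator
    r1 = sum_{t=2..n} (x_t - xbar)(x_{t-1} - xbar) / sum_t (x_t - xbar)^2.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("lag1_autocorrelation: need at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("lag1_autocorrelation: non-finite values")
    d = x - x.mean()
    denom = float(np.dot(d, d))
    if denom == 0.0:
        raise ValueError("lag1_autocorrelation: zero variance")
    return float(np.dot(d[1:], d[:-1]) / denom)
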