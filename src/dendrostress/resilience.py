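"""Resistance, recovery and resilience around climatic stress events.

The Lloret indices compare a tree's radial growth in the stress-event
year (RG_SE) with the year(s) before and after:

    Rs = RG_SE / RG_pre      (resistance: depth of the growth depression)
    Rc = RG_post / RG_SE     (recovery: rebound relative to the event year)
    Rl = RG_post / RG_pre    (resilience: return to pre-event growth)

With window width w = 2 the pre/post values are the arithmetic means of
the two years before/after, which balances out single favourable or
unfavourable years.  The identity Rl = Rs * Rc holds exactly for both
widths.  Indices are computed on raw per-tree ring widths (not detrended
indices) and summarised per species with medians; species differences are
tested with Kruskal-Wallis plus Dunn's pairwise test (Holm-Sidak adjusted,
rejecting at p <= alpha/2), and size/growth comparisons with one-way
ANOVA plus Tukey's HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ringwidth import TreeSeries

__all__ = [
    "StressEvent",
    "ResponseIndices",
    "lloret_indices",
    "indices_for_forest",
    "SpeciesResponseSummary",
    "species_summary",
    "percent_decline",
    "kruskal_dunn",
    "anova_tukey",
]


@dataclass(frozen=True)
class StressEvent:
    """A stress-event year with the pre/post window width (1 or 2 years)."""

    year: int
    window: int = 1

    def __post_init__(self) -> None:
        if self.window not in (1, 2):
            raise ValueError("window width must be 1 or 2")

    def required_years(self) -> list[int]:
        w = self.window
        return list(range(self.year - w, self.year + w + 1))


@dataclass
class ResponseIndices:
    """Per-tree response to one stress event."""

    tree_id: str
    species: str
    event_year: int
    window: int
    resistance: float
    recovery: float
    resilience: float
    rg_se: float
    rg_pre: float
    rg_post: float


def lloret_indices(tree: TreeSeries, event: StressEvent) -> ResponseIndices:
    """Resistance/recovery/resilience of one tree for one stress event.

    Requires all pre/post years with positive growth; raises otherwise so
    incomplete windows (e.g. an event too close to the series end) are
    excluded rather than silently padded.
    """
    needed = event.required_years()
    missing = [y for y in needed if y not in tree.widths.index]
    if missing:
        raise ValueError(
            f"tree {tree.tree_id}: years {missing} missing for event {event.year} "
            f"(w={event.window})"
        )
    w = event.window
    rg = tree.widths
    rg_se = float(rg.loc[event.year])
    rg_pre = float(rg.loc[event.year - w: event.year - 1].mean())
    rg_post = float(rg.loc[event.year + 1: event.year + w].mean())
    if rg_se <= 0 or rg_pre <= 0:
        raise ValueError(f"tree {tree.tree_id}: non-positive growth around {event.year}")
    return ResponseIndices(
        tree_id=tree.tree_id, species=tree.species,
        event_year=event.year, window=w,
        resistance=rg_se / rg_pre,
        recovery=rg_post / rg_se,
        resilience=rg_post / rg_pre,
        rg_se=rg_se, rg_pre=rg_pre, rg_post=rg_post,
    )


def indices_for_forest(
    trees: list[TreeSeries], events: list[StressEvent]
) -> list[ResponseIndices]:
    """All computable per-tree indices; incomplete windows are dropped with a warning."""
    out, dropped = [], 0
    for event in events:
        for tree in trees:
            try:
                out.append(lloret_indices(tree, event))
            except ValueError:
                dropped += 1
    if dropped:
        warnings.warn(f"{dropped} tree/event combinations lacked complete windows",
                      stacklevel=2)
    return out


@dataclass
class SpeciesResponseSummary:
    """Species medians per event plus the across-event average.

    Two across-event conventions are reported: ``average_of_medians`` (the
    median of the per-event species medians) and ``pooled_median`` (the
    median over all per-tree-per-event values).
    """

    species: str
    window: int
    per_event: pd.DataFrame  # index: event year; columns Rs, Rc, Rl
    average_of_medians: pd.Series = field(default=None)
    pooled_median: pd.Series = field(default=None)


def species_summary(indices: list[ResponseIndices]) -> list[SpeciesResponseSummary]:
    """Median response indices per species, event and window width."""
    if not indices:
        raise ValueError("species_summary: no indices")
    df = pd.DataFrame([{
        "species": r.species, "window": r.window, "event": r.event_year,
        "Rs": r.resistance, "Rc": r.recovery, "Rl": r.resilience,
    } for r in indices])
    out = []
    for (species, window), grp in df.groupby(["species", "window"]):
        per_event = grp.groupby("event")[["Rs", "Rc", "Rl"]].median()
        out.append(SpeciesResponseSummary(
            species=species, window=int(window), per_event=per_event,
            average_of_medians=per_event.median(),
            pooled_median=grp[["Rs", "Rc", "Rl"]].median(),
        ))
    return out


def percent_decline(resistance: float) -> float:
    """Ring-width decline in the event year, percent: (1 - Rs) * 100."""
    return (1.0 - resistance) * 100.0


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def _ranked(groups: dict[str, np.ndarray]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    pooled = np.concatenate(list(groups.values()))
    ranks = stats.rankdata(pooled)
    out, pos = {}, 0
    for name, vals in groups.items():
        out[name] = ranks[pos: pos + len(vals)]
        pos += len(vals)
    return ranks, out


def kruskal_dunn(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """Kruskal-Wallis H test with Dunn's pairwise post-hoc comparisons.

    Dunn z statistics use mean ranks with the standard tie correction;
    p-values are Holm-Sidak adjusted and the null is rejected at
    p_adjusted <= alpha/2.  Identical observations across all groups give
    H = 0 and no rejections.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("kruskal_dunn: need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0.0:
        return {"H": 0.0, "p": 1.0, "pairwise": [], "alpha": alpha}
    H, p = stats.kruskal(*groups.values())

    ranks, group_ranks = _ranked(groups)
    N = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    names = list(groups)
    pairs, zs, praw = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            z = (group_ranks[a].mean() - group_ranks[b].mean()) / se
            pairs.append((a, b))
            zs.append(float(z))
            praw.append(float(2.0 * stats.norm.sf(abs(z))))
    reject, p_adj, _, _ = multipletests(praw, alpha=alpha / 2.0, method="holm-sidak")
    pairwise = [{
        "groups": pair, "z": z, "p_raw": pr, "p_adjusted": float(pa),
        "reject": bool(pa <= alpha / 2.0),
    } for pair, z, pr, pa in zip(pairs, zs, praw, p_adj)]
    return {"H": float(H), "p": float(p), "pairwise": pairwise, "alpha": alpha}


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """One-way ANOVA with Tukey's HSD pairwise comparisons."""
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("anova_tukey: need >= 2 groups")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0.0:
        return {"F": 0.0, "p": 1.0, "pairwise": [], "alpha": alpha}
    F, p = stats.f_oneway(*groups.values())
    hsd = stats.tukey_hsd(*groups.values())
    names = list(groups)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            padj = float(hsd.pvalue[i, j])
            pairwise.append({
                "groups": (names[i], names[j]),
                "p_adjusted": padj,
                "reject": bool(padj <= alpha),
            })
    return {"F": float(F), "p": float(p), "pairwise": pairwise, "alpha": alpha}
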