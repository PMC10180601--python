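"""Tucson/RWL decadal ring-width files and the daily-climate CSV format.

RWL values are hundredths of a millimetre; a series ends with the 999
marker (or -9999 for files in thousandths of a millimetre).  Core IDs are
expected to end in a single core letter (e.g. ``CED001a``/``CED001b`` are
the two cores of tree ``CED001``); the leading alphabetic prefix is taken
as the species code unless one is supplied.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .ringwidth import CoreSeries

__all__ = ["read_rwl", "write_rwl", "read_daily_climate", "write_daily_climate"]


def _species_from_id(core_id: str) -> str:
    m = re.match(r"([A-Za-z]+)", core_id)
    return m.group(1) if m else core_id


def read_rwl(path: str | Path, species: str | None = None) -> list[CoreSeries]:
    """Read a Tucson decadal RWL file into CoreSeries (widths in mm)."""
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    scales: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 3:
            raise ValueError(f"{path}:{lineno}: malformed decade row")
        core_id = tokens[0]
        try:
            decade_year = int(tokens[1])
            values = [int(t) for t in tokens[2:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed decade row") from exc
        if 999 in values:
            cut = values.index(999)
            values = values[:cut]
            scales.setdefault(core_id, 0.01)
        if -9999 in values:
            cut = values.index(-9999)
            values = values[:cut]
            scales[core_id] = 0.001
        raw.setdefault(core_id, []).append((decade_year, values))

    cores = []
    for core_id, rows in raw.items():
        rows.sort(key=lambda r: r[0])
        scale = scales.get(core_id, 0.01)
        years: list[int] = []
        widths: list[float] = []
        for decade_year, values in rows:
            for k, v in enumerate(values):
                year = decade_year + k
                if year in years:
                    raise ValueError(f"{path}: duplicate year {year} in core {core_id}")
                years.append(year)
                widths.append(v * scale)
        if len(years) >= 2 and years != list(range(years[0], years[0] + len(years))):
            raise ValueError(f"{path}: non-consecutive years in core {core_id}")
        tree_id = core_id[:-1] if core_id[-1].isalpha() and len(core_id) > 1 else core_id
        cores.append(CoreSeries(
            tree_id=tree_id,
            core_id=core_id,
            species=species if species is not None else _species_from_id(core_id),
            first_year=years[0],
            widths=np.asarray(widths),
        ))
    return cores


def write_rwl(cores: list[CoreSeries], path: str | Path) -> None:
    """Write CoreSeries to a Tucson decadal file (0.01 mm, 999-terminated)."""
    lines = []
    for core in cores:
        years = core.years
        values = np.round(core.widths * 100).astype(int)
        year = int(years[0])
        last = int(years[-1])
        while year <= last:
            decade_end = (year // 10) * 10 + 9
            row_years = range(year, min(decade_end, last) + 1)
            row_vals = [values[y - years[0]] for y in row_years]
            if row_years[-1] == last:
                row_vals = list(row_vals) + [999]
            lines.append(
                f"{core.core_id:<8}{year:>4}" + "".join(f"{v:>6}" for v in row_vals)
            )
            year = decade_end + 1
    Path(path).write_text("\n".join(lines) + "\n")


def read_daily_climate(path: str | Path) -> pd.DataFrame:
    """Daily climate CSV: date, tmin, tmax, tmean, ppt[, rh][, pet]."""
    df = pd.read_csv(path, parse_dates=["date"], index_col="date")
    required = {"tmin", "tmax", "tmean", "ppt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing climate columns {sorted(missing)}")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate dates")
    return df.sort_index()


def write_daily_climate(daily: pd.DataFrame, path: str | Path) -> None:
    out = daily.copy()
    out.index.name = "date"
    out.to_csv(path, float_format="%.3f")
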