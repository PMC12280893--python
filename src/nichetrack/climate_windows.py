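"""Window climate summaries and species-level niche estimates.

Over each window, precipitation and climatic water deficit are summed and
monthly mean temperature is averaged (unweighted across months).  Specimen
summaries are then averaged within species to give one value per climate
variable, window kind and species; the standard error is sd/sqrt(n) with the
n-1 divisor (reported as 0 for singleton species, with a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ClimateSeries, SpecimenRecord
from .phenology import Window

__all__ = [
    "WindowSummary",
    "summarize_window",
    "specimen_window_table",
    "species_niche_table",
    "species_niche",
    "delta_cwd",
]

VARIABLES = ("tmean_c", "ppt_mm", "cwd_mm")


@dataclass(frozen=True)
class WindowSummary:
    specimen_id: str
    kind: str
    tmean_c: float  # mean of monthly means, deg C
    ppt_mm: float   # summed precipitation, mm
    cwd_mm: float   # summed climatic water deficit, mm
    n_months: int


def summarize_window(series: ClimateSeries, w: Window,
                     specimen_id: str = "") -> WindowSummary:
    """Sum ppt and CWD, average temperature over the window months.

    Raises ``KeyError`` naming the first missing month if the series does
    not cover the window.
    """
    sub = series.slice(w.start, w.end)
    return WindowSummary(
        specimen_id=specimen_id or series.location_id,
        kind=w.kind,
        tmean_c=float(np.mean(sub.tmean_c)),
        ppt_mm=float(np.sum(sub.ppt_mm)),
        cwd_mm=float(np.sum(sub.cwd_mm)),
        n_months=w.n_months,
    )


def _parse_ym(s: str) -> tuple[int, int]:
    y, m = s.split("-")
    return int(y), int(m)


def specimen_window_table(phenology: pd.DataFrame,
                          climate: dict[str, ClimateSeries]) -> pd.DataFrame:
    """Window summaries for every (specimen, kind) row of a phenology table."""
    rows = []
    for row in phenology.itertuples(index=False):
        if row.kind == "none":
            continue
        w = Window(_parse_ym(row.window_start), _parse_ym(row.window_end), row.kind)
        s = summarize_window(climate[row.specimen_id], w, row.specimen_id)
        rows.append({"specimen_id": s.specimen_id, "species": row.species,
                     "kind": s.kind, "tmean_c": s.tmean_c, "ppt_mm": s.ppt_mm,
                     "cwd_mm": s.cwd_mm, "n_months": s.n_months})
    return pd.DataFrame(rows)


def species_niche(summaries: pd.DataFrame, records: list[SpecimenRecord],
                  kind: str) -> pd.DataFrame:
    """Species-level niche for one window kind: per-variable mean and SE,
    specimen count and mean latitude.  Species order is sorted; specimen
    order within species does not matter."""
    sub = summaries[summaries["kind"] == kind]
    if sub.empty:
        raise ValueError(f"no window summaries of kind {kind!r}")
    lat = pd.DataFrame({"specimen_id": [r.specimen_id for r in records],
                        "lat": [r.lat for r in records]})
    sub = sub.merge(lat, on="specimen_id", how="left")
    rows = []
    for species, g in sub.groupby("species", sort=True):
        n = len(g)
        row = {"species": species, "kind": kind, "n_specimens": n,
               "mean_latitude": float(g["lat"].mean()), "se_is_zero_n1": n == 1}
        for var in VARIABLES:
            vals = g[var].to_numpy(dtype=float)
            row[f"{var}_mean"] = float(vals.mean())
            row[f"{var}_se"] = 0.0 if n == 1 else float(
                vals.std(ddof=1) / np.sqrt(n))
        rows.append(row)
    return pd.DataFrame(rows)


def species_niche_table(summaries: pd.DataFrame,
                        records: list[SpecimenRecord]) -> pd.DataFrame:
    """Species niches for every window kind present in the summaries."""
    kinds = summaries["kind"].unique()
    return pd.concat([species_niche(summaries, records, k) for k in sorted(kinds)],
                     ignore_index=True)


def delta_cwd(species_niches: pd.DataFrame) -> pd.DataFrame:
    """Per-species tracking statistic: mean specimen-specific summed CWD minus
    mean clade-seasonal summed CWD.  Positive values mean the lived season is
    more arid than the fixed Oct-Apr season."""
    ss = species_niches[species_niches["kind"] == "specimen_specific"]
    cs = species_niches[species_niches["kind"] == "clade_seasonal"]
    missing = set(ss["species"]).symmetric_difference(cs["species"])
    if missing or ss.empty:
        raise ValueError(
            f"species missing a window kind for delta CWD: {sorted(missing)}")
    merged = ss.merge(cs, on="species", suffixes=("_ss", "_cs"))
    return pd.DataFrame({
        "species": merged["species"],
        "delta_cwd_mm": merged["cwd_mm_mean_ss"] - merged["cwd_mm_mean_cs"],
        "mean_latitude": merged["mean_latitude_ss"],
    })
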