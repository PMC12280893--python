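"""Germination-month estimation and growing-season windows.

Each herbarium specimen's "lived" growing season is reconstructed from
monthly rainfall at its collection site: germination is placed in the first
month of the water year (September 1 - August 30) with more than 25 mm of
rain, restricted to the plausible germination months September-February and
to months at or before collection.  If no month clears the threshold the
wettest candidate month is used; specimens whose candidate months saw no
rain at all are dropped.  Three windows are then built per specimen:

* specimen_specific - germination month through collection month,
* annual            - the full water year (Sep..Aug, 12 months),
* clade_seasonal    - the clade-average season (Oct..Apr, 7 months).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import pandas as pd

from .io_formats import ClimateSeries, SpecimenRecord, index_ym, ym_index

__all__ = [
    "Window",
    "GerminationEstimate",
    "water_year_start",
    "estimate_germination",
    "lived_window",
    "annual_window",
    "clade_seasonal_window",
    "phenology_table",
]

SEP, FEB, APR, AUG, OCT = 9, 2, 4, 8, 10
DEFAULT_THRESHOLD_MM = 25.0


@dataclass(frozen=True)
class Window:
    """Inclusive (year, month) interval with a window kind."""

    start: tuple[int, int]
    end: tuple[int, int]
    kind: str  # annual | clade_seasonal | specimen_specific

    def __post_init__(self) -> None:
        if ym_index(*self.start) > ym_index(*self.end):
            raise ValueError(f"window start {self.start} after end {self.end}")
        if self.kind == "annual" and self.n_months != 12:
            raise ValueError("annual window must span 12 months")

    @property
    def n_months(self) -> int:
        return ym_index(*self.end) - ym_index(*self.start) + 1

    def months(self) -> list[tuple[int, int]]:
        return [index_ym(i) for i in
                range(ym_index(*self.start), ym_index(*self.end) + 1)]


@dataclass(frozen=True)
class GerminationEstimate:
    specimen_id: str
    germ_month: tuple[int, int] | None
    rule_used: str  # threshold | fallback_max | dropped_no_rain
    threshold_mm: float = DEFAULT_THRESHOLD_MM


def water_year_start(collection_date: _dt.date | tuple[int, int]) -> tuple[int, int]:
    """(year, September) anchoring the water year containing the date.

    Collections in January-August belong to the water year that started the
    previous September.
    """
    if isinstance(collection_date, _dt.date):
        y, m = collection_date.year, collection_date.month
    else:
        y, m = collection_date
    return (y - 1, SEP) if m <= AUG else (y, SEP)


def _candidate_months(collection: tuple[int, int]) -> list[tuple[int, int]]:
    """September..February of the water year, truncated at collection."""
    wy, _ = water_year_start(collection)
    start = ym_index(wy, SEP)
    end = min(ym_index(wy + 1, FEB), ym_index(*collection))
    if end < start:
        raise ValueError(
            f"collection {collection} precedes its water-year start ({wy}, Sep)")
    return [index_ym(i) for i in range(start, end + 1)]


def estimate_germination(series: ClimateSeries, collection: tuple[int, int],
                         threshold_mm: float = DEFAULT_THRESHOLD_MM,
                         epsilon_mm: float = 0.0,
                         specimen_id: str = "") -> GerminationEstimate:
    """Place the germination month from monthly rainfall.

    Rule: first candidate month with rainfall strictly above ``threshold_mm``;
    failing that, the candidate month with the greatest rainfall (earliest on
    ties); if every candidate month has rainfall <= ``epsilon_mm`` the
    specimen is marked ``dropped_no_rain``.
    """
    candidates = _candidate_months(collection)
    ppt = [series.at(y, m)[1] for y, m in candidates]
    for (y, m), p in zip(candidates, ppt):
        if p > threshold_mm:
            return GerminationEstimate(specimen_id, (y, m), "threshold", threshold_mm)
    if max(ppt) <= epsilon_mm:
        return GerminationEstimate(specimen_id, None, "dropped_no_rain", threshold_mm)
    best = candidates[max(range(len(ppt)), key=lambda i: (ppt[i], -i))]
    return GerminationEstimate(specimen_id, best, "fallback_max", threshold_mm)


def lived_window(germ: GerminationEstimate, collection: tuple[int, int]) -> Window:
    """Specimen-specific window: germination month through collection month."""
    if germ.germ_month is None:
        raise ValueError(
            f"specimen {germ.specimen_id!r} was dropped ({germ.rule_used}); "
            "no lived window exists")
    return Window(germ.germ_month, collection, "specimen_specific")


def annual_window(collection: tuple[int, int]) -> Window:
    """Full water year: September before collection through August after."""
    wy, _ = water_year_start(collection)
    return Window((wy, SEP), (wy + 1, AUG), "annual")


def clade_seasonal_window(collection: tuple[int, int]) -> Window:
    """Clade-average growing season: October through April of the water year."""
    wy, _ = water_year_start(collection)
    return Window((wy, OCT), (wy + 1, APR), "clade_seasonal")


def phenology_table(records: list[SpecimenRecord],
                    climate: dict[str, ClimateSeries],
                    threshold_mm: float = DEFAULT_THRESHOLD_MM,
                    epsilon_mm: float = 0.0,
                    ) -> tuple[pd.DataFrame, list[SpecimenRecord]]:
    """Germination estimates and all three windows for every specimen.

    Returns the phenology table (one row per specimen and window kind; dropped
    specimens appear with kind ``none``) and the list of retained records
    (those with a germination month).
    """
    rows = []
    retained = []
    for rec in records:
        coll = (rec.collection_date.year, rec.collection_date.month)
        series = climate[rec.specimen_id]
        germ = estimate_germination(series, coll, threshold_mm, epsilon_mm,
                                    specimen_id=rec.specimen_id)
        if germ.germ_month is None:
            rows.append({"specimen_id": rec.specimen_id, "species": rec.species,
                         "germ_year": "", "germ_month": "",
                         "rule_used": germ.rule_used, "kind": "none",
                         "window_start": "", "window_end": ""})
            continue
        retained.append(rec)
        for w in (lived_window(germ, coll), annual_window(coll),
                  clade_seasonal_window(coll)):
            rows.append({
                "specimen_id": rec.specimen_id, "species": rec.species,
                "germ_year": germ.germ_month[0], "germ_month": germ.germ_month[1],
                "rule_used": germ.rule_used, "kind": w.kind,
                "window_start": f"{w.start[0]}-{w.start[1]:02d}",
                "window_end": f"{w.end[0]}-{w.end[1]:02d}"})
    return pd.DataFrame(rows), retained
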