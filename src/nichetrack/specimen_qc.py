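"""Specimen inclusion/exclusion filters and geographic subsampling.

The QC chain runs in a fixed, documented order: georeferencing-error radius
filter (inclusive at 5 km; unknown radius drops the record), reproductive
structure filter (any of buds/flowers/fruits), disjunct-coordinate flagging
(a k-nearest-neighbour outlier heuristic with a manual override list), and
seeded round-robin subsampling across counties for over-collected species.
Each filter reconciles its counts in a QCReport.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import SpecimenRecord, logger

__all__ = [
    "QCReport",
    "filter_error_radius",
    "filter_reproductive",
    "flag_disjunct",
    "subsample_by_county",
    "apply_qc",
]

DEFAULT_MAX_RADIUS_KM = 5.0
DEFAULT_SUBSAMPLE_MAX_N = 200


@dataclass
class QCReport:
    n_input: int = 0
    n_dropped_radius: int = 0
    n_dropped_nonreproductive: int = 0
    n_dropped_disjunct: int = 0
    n_dropped_subsample: int = 0
    n_retained: int = 0
    dropped_ids: dict = field(default_factory=dict)  # reason -> [specimen_id]

    def reconcile(self) -> None:
        total = (self.n_retained + self.n_dropped_radius
                 + self.n_dropped_nonreproductive + self.n_dropped_disjunct
                 + self.n_dropped_subsample)
        if total != self.n_input:
            raise AssertionError(
                f"QC counts do not reconcile: input {self.n_input}, accounted {total}")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": reason, "n_dropped": len(ids),
                 "dropped_ids": ";".join(ids)}
                for reason, ids in self.dropped_ids.items()]
        rows.append({"reason": "retained", "n_dropped": self.n_retained,
                     "dropped_ids": ""})
        return pd.DataFrame(rows, columns=["reason", "n_dropped", "dropped_ids"])


def filter_error_radius(records: list[SpecimenRecord],
                        max_km: float = DEFAULT_MAX_RADIUS_KM,
                        ) -> tuple[list[SpecimenRecord], QCReport]:
    """Keep specimens georeferenced to within ``max_km`` (inclusive).
    Records with an unknown radius are dropped."""
    kept, dropped = [], []
    for r in records:
        if r.error_radius_km is not None and r.error_radius_km <= max_km:
            kept.append(r)
        else:
            dropped.append(r.specimen_id)
    rep = QCReport(n_input=len(records), n_dropped_radius=len(dropped),
                   n_retained=len(kept), dropped_ids={"radius": dropped})
    rep.reconcile()
    return kept, rep


def filter_reproductive(records: list[SpecimenRecord],
                        ) -> tuple[list[SpecimenRecord], QCReport]:
    """Keep specimens with any reproductive structure (buds, flowers, fruits)."""
    kept = [r for r in records if r.has_reproductive]
    dropped = [r.specimen_id for r in records if not r.has_reproductive]
    rep = QCReport(n_input=len(records), n_dropped_nonreproductive=len(dropped),
                   n_retained=len(kept), dropped_ids={"nonreproductive": dropped})
    rep.reconcile()
    return kept, rep


def _km_distance(lat1, lon1, lat2, lon2) -> float:
    """Equirectangular small-angle distance in km."""
    mean_lat = math.radians((lat1 + lat2) / 2.0)
    dx = (lon2 - lon1) * 111.320 * math.cos(mean_lat)
    dy = (lat2 - lat1) * 110.574
    return math.hypot(dx, dy)


def flag_disjunct(records: list[SpecimenRecord], k_nn: int = 1,
                  mult: float = 10.0,
                  manual_drops: tuple[str, ...] = ()) -> set[str]:
    """Flag geographically disjunct specimens per species.

    A record is flagged when its distance to its k-th nearest conspecific
    exceeds ``mult`` times the species' median k-th-neighbour distance.  An
    explicit ``manual_drops`` id list is always flagged.  Species with fewer
    than ``k_nn + 1`` records yield no flags (warned).
    """
    flagged: set[str] = set(manual_drops) & {r.specimen_id for r in records}
    by_species: dict[str, list[SpecimenRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    for species, recs in by_species.items():
        if len(recs) < k_nn + 1:
            logger.warning("flag_disjunct: %s has %d record(s), need > %d; skipped",
                           species, len(recs), k_nn)
            continue
        lat = np.array([r.lat for r in recs])
        lon = np.array([r.lon for r in recs])
        mean_lat = np.radians(lat.mean())
        x = lon * 111.320 * np.cos(mean_lat)
        y = lat * 110.574
        d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
        np.fill_diagonal(d, np.inf)
        knn_dist = np.sort(d, axis=1)[:, k_nn - 1]
        med = float(np.median(knn_dist))
        cutoff = mult * med
        if med == 0.0:
            # all (or most) points coincident; only positive distances could
            # exceed the cutoff, but 10 * 0 = 0 would flag everything -- flag
            # nothing instead.
            continue
        for r, dist in zip(recs, knn_dist):
            if dist > cutoff:
                flagged.add(r.specimen_id)
    return flagged


def subsample_by_county(records: list[SpecimenRecord],
                        max_n: int = DEFAULT_SUBSAMPLE_MAX_N,
                        seed: int = 0) -> tuple[list[SpecimenRecord], QCReport]:
    """Cap each species at ``max_n`` records, spreading retention across
    counties: counties are visited round-robin (seeded random order within a
    county) drawing one record per visit until the cap is reached."""
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[SpecimenRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    keep_ids: set[str] = set()
    for species in sorted(by_species):
        recs = by_species[species]
        if len(recs) <= max_n:
            keep_ids.update(r.specimen_id for r in recs)
            continue
        counties: dict[str, list[SpecimenRecord]] = {}
        for r in recs:
            counties.setdefault(r.county, []).append(r)
        queues = []
        for county in sorted(counties):
            q = list(counties[county])
            rng.shuffle(q)
            queues.append(q)
        taken = 0
        while taken < max_n:
            progressed = False
            for q in queues:
                if taken >= max_n:
                    break
                if q:
                    keep_ids.add(q.pop().specimen_id)
                    taken += 1
                    progressed = True
            if not progressed:
                break
        logger.info("subsample_by_county: %s capped %d -> %d", species,
                    len(recs), taken)
    kept = [r for r in records if r.specimen_id in keep_ids]
    dropped = [r.specimen_id for r in records if r.specimen_id not in keep_ids]
    rep = QCReport(n_input=len(records), n_dropped_subsample=len(dropped),
                   n_retained=len(kept), dropped_ids={"subsample": dropped})
    rep.reconcile()
    return kept, rep


def apply_qc(records: list[SpecimenRecord],
             max_error_radius_km: float = DEFAULT_MAX_RADIUS_KM,
             k_nn: int = 1, mult: float = 10.0,
             manual_drops: tuple[str, ...] = (),
             subsample_max_n: int = DEFAULT_SUBSAMPLE_MAX_N,
             seed: int = 0) -> tuple[list[SpecimenRecord], QCReport]:
    """Full QC chain: radius -> reproductive -> disjunct -> subsample."""
    n_input = len(records)
    records, rep_r = filter_error_radius(records, max_error_radius_km)
    records, rep_p = filter_reproductive(records)
    disjunct = flag_disjunct(records, k_nn=k_nn, mult=mult,
                             manual_drops=manual_drops)
    records = [r for r in records if r.specimen_id not in disjunct]
    records, rep_s = subsample_by_county(records, subsample_max_n, seed=seed)
    report = QCReport(
        n_input=n_input,
        n_dropped_radius=rep_r.n_dropped_radius,
        n_dropped_nonreproductive=rep_p.n_dropped_nonreproductive,
        n_dropped_disjunct=len(disjunct),
        n_dropped_subsample=rep_s.n_dropped_subsample,
        n_retained=len(records),
        dropped_ids={"radius": rep_r.dropped_ids["radius"],
                     "nonreproductive": rep_p.dropped_ids["nonreproductive"],
                     "disjunct": sorted(disjunct),
                     "subsample": rep_s.dropped_ids["subsample"]},
    )
    report.reconcile()
    return records, report
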