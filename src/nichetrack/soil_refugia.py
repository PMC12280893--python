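"""Soil microhabitat selectivity statistics.

For every specimen locality the occupied grid cell's water-holding capacity
(WHC) is compared against the mean of 100 random background points drawn
area-uniformly within a 20 km disk (radius R*sqrt(u), uniform angle;
geographic offsets via a local equirectangular approximation with the
cos-latitude correction, adequate at this scale).  Background points that
fall on nodata or outside the grid are skipped and counted, not redrawn.
Species-mean deltas feed a two-tailed sign test and PGLS regressions
against species annual temperature and annual CWD; field-soil coarse
fractions get the same pair of PGLS fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SpecimenRecord, Tree, WHCGrid, logger
from .niche_stats import SignTestResult, sign_test
from .phylo_comparative import PGLSFit, pgls

__all__ = [
    "WHCDelta",
    "LocalityOmitted",
    "whc_delta",
    "specimen_whc_deltas",
    "species_whc_deltas",
    "refugia_tests",
    "coarse_fraction_tests",
    "soil_stage",
]

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320


@dataclass(frozen=True)
class WHCDelta:
    specimen_id: str
    occupied_whc: float        # mm
    background_mean_whc: float # mm, mean over valid random points
    delta: float               # mm, occupied - background
    n_valid_random: int


class LocalityOmitted(Exception):
    """The occupied cell has no WHC data; the locality is omitted."""


def _disk_points(lat: float, lon: float, radius_km: float, n: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Area-uniform random points in the geographic disk: radius scales as
    sqrt(u) so density is uniform per unit area, not per unit radius."""
    r = radius_km * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * np.pi
    dx_km = r * np.cos(theta)
    dy_km = r * np.sin(theta)
    lat_pts = lat + dy_km / KM_PER_DEG_LAT
    lon_pts = lon + dx_km / (KM_PER_DEG_LON_EQ * math.cos(math.radians(lat)))
    return lat_pts, lon_pts


def whc_delta(record: SpecimenRecord, grid: WHCGrid, buffer_km: float = 20.0,
              n_random: int = 100, seed: int = 0) -> WHCDelta:
    """Occupied-minus-background WHC for one specimen locality.

    Raises :class:`LocalityOmitted` when the occupied cell is nodata or
    outside the grid, and ``ValueError`` when no random point lands on
    valid data.  Deterministic under the seed.
    """
    occ = grid.value_at(record.lon, record.lat)
    if occ is None:
        raise LocalityOmitted(record.specimen_id)
    rng = np.random.default_rng(seed)
    lat_pts, lon_pts = _disk_points(record.lat, record.lon, buffer_km,
                                    n_random, rng)
    vals = [grid.value_at(x, y) for x, y in zip(lon_pts, lat_pts)]
    valid = [v for v in vals if v is not None]
    if not valid:
        raise ValueError(
            f"{record.specimen_id}: no valid background points in the "
            f"{buffer_km} km buffer")
    background = float(np.mean(valid))
    return WHCDelta(specimen_id=record.specimen_id, occupied_whc=occ,
                    background_mean_whc=background, delta=occ - background,
                    n_valid_random=len(valid))


def specimen_whc_deltas(records: list[SpecimenRecord], grid: WHCGrid,
                        buffer_km: float = 20.0, n_random: int = 100,
                        seed: int = 0) -> tuple[list[WHCDelta], list[str]]:
    """Deltas for all localities; returns (deltas, omitted specimen ids).
    The accounting n_input = n_used + n_omitted is logged."""
    deltas, omitted = [], []
    for i, rec in enumerate(records):
        try:
            deltas.append(whc_delta(rec, grid, buffer_km, n_random,
                                    seed=seed + i))
        except LocalityOmitted:
            omitted.append(rec.specimen_id)
    logger.info("specimen_whc_deltas: %d localities in = %d used + %d omitted",
                len(records), len(deltas), len(omitted))
    return deltas, omitted


def species_whc_deltas(deltas: list[WHCDelta],
                       records: list[SpecimenRecord]) -> pd.DataFrame:
    """Arithmetic per-species mean of the locality deltas."""
    sp = {r.specimen_id: r.species for r in records}
    df = pd.DataFrame({"species": [sp[d.specimen_id] for d in deltas],
                       "delta": [d.delta for d in deltas]})
    out = df.groupby("species", sort=True).agg(
        mean_delta_mm=("delta", "mean"), n_specimens=("delta", "size"))
    return out.reset_index()


def _species_vectors(df: pd.DataFrame, niche: pd.DataFrame, tree: Tree,
                     value_col: str) -> tuple[dict, dict, dict]:
    an = niche[niche["kind"] == "annual"]
    sp_df = set(df["species"])
    sp_niche = set(an["species"])
    sp_tree = set(tree.tip_labels)
    if sp_df != sp_niche or sp_df != sp_tree:
        raise ValueError(
            "species sets disagree between soil data "
            f"({sorted(sp_df)[:3]}...), annual niche and tree tips")
    y = dict(zip(df["species"], df[value_col]))
    temp = dict(zip(an["species"], an["tmean_c_mean"]))
    cwd = dict(zip(an["species"], an["cwd_mm_mean"]))
    return y, temp, cwd


def refugia_tests(species_deltas: pd.DataFrame, species_annual_niche: pd.DataFrame,
                  tree: Tree) -> dict:
    """Sign test on the species deltas plus PGLS of delta against annual
    temperature and against annual CWD."""
    y, temp, cwd = _species_vectors(species_deltas, species_annual_niche,
                                    tree, "mean_delta_mm")
    return {
        "sign_test": sign_test(list(y.values())),
        "pgls_temperature": pgls(tree, y, [temp],
                                 coef_names=("intercept", "annual_tmean_c")),
        "pgls_cwd": pgls(tree, y, [cwd], coef_names=("intercept", "annual_cwd_mm")),
    }


def coarse_fraction_tests(soils: pd.DataFrame, species_annual_niche: pd.DataFrame,
                          tree: Tree) -> dict:
    """PGLS of species-mean coarse soil fraction against annual temperature
    and annual CWD.  ``soils`` is the site-level field table; sites are
    averaged per species first."""
    per_species = soils.groupby("species", sort=True).agg(
        mean_coarse_fraction=("coarse_fraction_pct", "mean"),
        n_sites=("coarse_fraction_pct", "size")).reset_index()
    y, temp, cwd = _species_vectors(per_species, species_annual_niche, tree,
                                    "mean_coarse_fraction")
    return {
        "per_species": per_species,
        "pgls_temperature": pgls(tree, y, [temp],
                                 coef_names=("intercept", "annual_tmean_c")),
        "pgls_cwd": pgls(tree, y, [cwd], coef_names=("intercept", "annual_cwd_mm")),
    }


def soil_stage(records, grid, soils, niche_by_species, tree,
               buffer_km: float = 20.0, n_random: int = 100,
               seed: int = 0) -> pd.DataFrame:
    """Pipeline wrapper: WHC deltas, species summaries, sign test and all
    four PGLS fits, flattened into one results table."""
    btree = tree.resolve_polytomies() if tree is not None and tree.has_polytomy() else tree
    deltas, omitted = specimen_whc_deltas(records, grid, buffer_km, n_random, seed)
    sp_deltas = species_whc_deltas(deltas, records)
    rows = [{"analysis": "whc_delta_species", "species": r.species,
             "estimate": r.mean_delta_mm, "se": "", "p": "",
             "n": r.n_specimens}
            for r in sp_deltas.itertuples(index=False)]
    rows.append({"analysis": "omitted_localities", "species": "",
                 "estimate": len(omitted), "se": "", "p": "", "n": len(records)})
    if niche_by_species is not None and btree is not None:
        ref = refugia_tests(sp_deltas, niche_by_species, btree)
        st: SignTestResult = ref["sign_test"]
        rows.append({"analysis": "sign_test", "species": "", "estimate": st.k,
                     "se": "", "p": st.p, "n": st.n})
        for name in ("pgls_temperature", "pgls_cwd"):
            fit: PGLSFit = ref[name]
            rows.append({"analysis": f"whc_delta_{name}", "species": "",
                         "estimate": fit.beta[1], "se": fit.se[1],
                         "p": fit.p[1], "n": fit.n})
        if soils is not None:
            cf = coarse_fraction_tests(soils, niche_by_species, btree)
            for name in ("pgls_temperature", "pgls_cwd"):
                fit = cf[name]
                rows.append({"analysis": f"coarse_fraction_{name}", "species": "",
                             "estimate": fit.beta[1], "se": fit.se[1],
                             "p": fit.p[1], "n": fit.n})
    return pd.DataFrame(rows)
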