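"""Synthetic trees, Mediterranean climates, specimens and soils.

The generator emulates the statistical structure the analysis assumes for a
clade of winter-annual plants in a Mediterranean climate: a wet season
beginning in fall and ending in spring, no appreciable summer rain, a
latitudinal gradient in rainfall onset (southern sites start later) and in
temperature (southern sites hotter), herbarium collection dates
concentrated in March-July, and spatially autocorrelated soil
water-holding-capacity (WHC) grids.

Latitude is the only geographic driver of climate in the default scenario.
The climatic-water-deficit proxy is ``cwd = max(0, PET - ppt)`` with
``PET = c * max(tmean, 0)`` (c = 5 mm per deg C month by default), a
deliberately simple stand-in that preserves the monotone relations the
analysis relies on (hotter and drier months have higher CWD).

The "niche-tracking" scenario is the key signal-recovery construction: with
``tracking_strength = 1`` each species' collection months are drawn from a
two-point distribution chosen so that the expected summed lived CWD is the
same across species, while the fixed Oct-Apr (clade-seasonal) CWD still
follows the latitudinal gradient.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import ClimateSeries, SpecimenRecord, Tree, TreeNode, WHCGrid

__all__ = [
    "ScenarioSpec",
    "ScenarioBundle",
    "gen_tree",
    "gen_climate_series",
    "gen_specimens",
    "gen_soil_grid",
    "gen_field_soils",
    "gen_scenario",
    "monthly_climate",
    "onset_month_offset",
    "species_annual_tmean",
]

SEP, OCT, APR, MAY, MAR, JUL = 9, 10, 4, 5, 3, 7
TEMP_ELEV_LAPSE_C_PER_KM = 6.5
# within-water-year month indices: Sep=0 ... Aug=11
_WY_APR = 7


@dataclass
class ScenarioSpec:
    """Parameters of a synthetic study scenario (defaults are the standard
    study conditions: 14 species, ~8 degrees of latitude, wet Oct-Apr
    season, collections centred on May)."""

    n_species: int = 14
    n_specimens_per_species: int = 50
    year_span: tuple = (1950, 2000)
    lat_range: tuple = (33.0, 41.0)
    onset_gradient: float = 0.25       # months of onset delay per degree southward
    wet_season_ppt_mm: float = 500.0   # clade-mean wet-season total
    temp_params: tuple = (17.0, 0.7, 8.0)  # (southern-edge mean degC, degC per deg lat, seasonal amplitude)
    tracking_strength: float = 1.0     # 0 = fixed phenology, 1 = full CWD compensation
    noise_sd_ppt: float = 10.0         # mm, wet-month rainfall noise
    noise_sd_temp: float = 0.5         # degC, monthly temperature noise
    noise_month_jitter_p: float = 0.2  # extra +-1-month collection jitter probability
    pet_coeff_mm_per_degc: float = 5.0
    elev_mean_m: float = 500.0
    elev_sd_m: float = 150.0
    spatial_jitter_deg: float = 0.3    # specimen scatter around the species centroid
    lon_center: float = -120.0
    soil_whc_offset_mm: float = 0.0    # planted WHC offset at occupied cells
    soil_whc_temp_slope: float = 0.0   # extra offset per degC of species annual tmean
    coarse_slope_pct_per_degc: float = 0.0  # field-soil coarse fraction vs annual tmean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_specimens_per_species < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.tracking_strength <= 1.0:
            raise ValueError("tracking_strength must be in [0, 1]")
        if isinstance(self.year_span, list):
            self.year_span = tuple(self.year_span)
        if isinstance(self.lat_range, list):
            self.lat_range = tuple(self.lat_range)
        if isinstance(self.temp_params, list):
            self.temp_params = tuple(self.temp_params)


# ---------------------------------------------------------------------------
# trees

def gen_tree(n_tips: int, seed: int) -> Tree:
    """Pure-birth (Yule) binary tree, rescaled to unit root-to-tip height
    (hence ultrametric).  Deterministic under the seed."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode(None, 0.0)
    start_time = {}  # active tip -> time its branch began
    a, b = TreeNode(), TreeNode()
    root.add_child(a)
    root.add_child(b)
    start_time[a] = start_time[b] = 0.0
    t = 0.0
    active = [a, b]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active[i]
        node.length = t - start_time.pop(node)
        c1, c2 = TreeNode(), TreeNode()
        node.add_child(c1)
        node.add_child(c2)
        start_time[c1] = start_time[c2] = t
        active[i] = c1
        active.append(c2)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t_end - start_time[node]
    # rescale to unit height and label tips in preorder before validation
    stack, order = [root], []
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(reversed(n.children))
    i = 0
    for n in order:
        n.length /= t_end
        if not n.children:
            i += 1
            n.label = f"t{i}"
    return Tree(root)


# ---------------------------------------------------------------------------
# climate (closed-form core + noise)

def onset_month_offset(lat: float, spec: ScenarioSpec) -> int:
    """Whole months of rainfall-onset delay relative to the northern edge
    (October onset); southern sites start later."""
    off = int(round(spec.onset_gradient * (spec.lat_range[1] - lat)))
    return int(np.clip(off, 0, 4))  # never later than February


# triangular wet-season shape, peaking at December (water-year index 3)
def _wet_weights(onset_wy: int) -> np.ndarray:
    idx = np.arange(onset_wy, _WY_APR + 1)
    w = np.maximum(0.3, 1.0 - 0.25 * np.abs(idx - 3))
    return w / w.sum()


def monthly_climate(lat: float, elevation_m: float, month: int,
                    spec: ScenarioSpec) -> tuple[float, float, float]:
    """Noise-free (tmean_c, ppt_mm, cwd_mm) for one calendar month."""
    base, lapse, amp = spec.temp_params
    tmean = (base - lapse * (lat - spec.lat_range[0])
             + amp * np.cos(2.0 * np.pi * (month - 7) / 12.0)
             - TEMP_ELEV_LAPSE_C_PER_KM * elevation_m / 1000.0)
    onset = onset_month_offset(lat, spec) + 1  # water-year index of first wet month
    wy_idx = (month - SEP) % 12
    ppt = 0.0
    if onset <= wy_idx <= _WY_APR:
        weights = _wet_weights(onset)
        ppt = spec.wet_season_ppt_mm * float(weights[wy_idx - onset])
    pet = spec.pet_coeff_mm_per_degc * max(tmean, 0.0)
    cwd = max(0.0, pet - ppt)
    return float(tmean), float(ppt), float(cwd)


def species_annual_tmean(lat: float, elevation_m: float,
                         spec: ScenarioSpec) -> float:
    """Annual mean temperature of the noise-free climate (the seasonal
    sinusoid averages out over 12 months)."""
    return float(np.mean([monthly_climate(lat, elevation_m, m, spec)[0]
                          for m in range(1, 13)]))


def gen_climate_series(lat: float, elevation_m: float, years: tuple,
                       spec: ScenarioSpec,
                       rng: np.random.Generator | None = None,
                       location_id: str = "synthetic") -> ClimateSeries:
    """Monthly series over calendar years ``years = (first, last)``
    inclusive.  Noise (when the spec's noise_sd terms are positive) is
    added to wet-month rainfall and to every month's temperature; dry-summer
    months stay exactly rain-free."""
    y0, y1 = years
    if y0 < spec.year_span[0] or y1 > spec.year_span[1]:
        raise ValueError(f"years {years} outside scenario span {spec.year_span}")
    months = np.arange((y1 - y0 + 1) * 12)
    year = y0 + months // 12
    month = months % 12 + 1
    tmean = np.empty(len(months))
    ppt = np.empty(len(months))
    for i, m in enumerate(month):
        tmean[i], ppt[i], _ = monthly_climate(lat, elevation_m, int(m), spec)
    if rng is not None:
        if spec.noise_sd_temp > 0:
            tmean = tmean + rng.normal(0.0, spec.noise_sd_temp, len(months))
        if spec.noise_sd_ppt > 0:
            wet = ppt > 0
            ppt[wet] = np.maximum(
                0.0, ppt[wet] + rng.normal(0.0, spec.noise_sd_ppt, int(wet.sum())))
    pet = spec.pet_coeff_mm_per_degc * np.maximum(tmean, 0.0)
    cwd = np.maximum(0.0, pet - ppt)
    return ClimateSeries(location_id, year, month, tmean, ppt, cwd)


# ---------------------------------------------------------------------------
# niche-tracking collection phenology

def _lived_cwd_by_collection_month(lat: float, elev: float,
                                   spec: ScenarioSpec) -> dict[int, float]:
    """Noise-free summed lived CWD (germination month = rainfall onset)
    for each candidate collection month March..July."""
    onset_wy = onset_month_offset(lat, spec) + 1
    # water-year indices Mar=6 .. Jul=10
    cwd_by_wy = {}
    for wy_idx in range(onset_wy, 11):
        month = (SEP - 1 + wy_idx) % 12 + 1
        cwd_by_wy[wy_idx] = monthly_climate(lat, elev, month, spec)[2]
    out = {}
    for coll_m, coll_wy in ((3, 6), (4, 7), (5, 8), (6, 9), (7, 10)):
        out[coll_m] = sum(cwd_by_wy[i] for i in range(onset_wy, coll_wy + 1))
    return out


def _tracking_month_distribution(lived: dict[int, float], target: float,
                                 strength: float) -> tuple[int, int, float]:
    """Two-point collection-month distribution (m_lo, m_hi, p_hi) whose
    expected lived CWD equals (1-strength)*lived[May] + strength*target,
    clipped to the achievable March-July range."""
    goal = (1.0 - strength) * lived[MAY] + strength * target
    months = sorted(lived)
    vals = [lived[m] for m in months]
    goal = float(np.clip(goal, min(vals), max(vals)))
    for m_lo, m_hi in zip(months[:-1], months[1:]):
        lo, hi = lived[m_lo], lived[m_hi]
        if lo <= goal <= hi:
            p_hi = 0.0 if hi == lo else (goal - lo) / (hi - lo)
            return m_lo, m_hi, float(p_hi)
    return months[-1], months[-1], 0.0


# ---------------------------------------------------------------------------
# specimens

@dataclass
class ScenarioBundle:
    spec: ScenarioSpec
    tree: Tree
    species_table: pd.DataFrame            # species, centroid lat/lon/elev, annual tmean
    specimens: list                        # SpecimenRecord
    climate: dict                          # specimen_id -> ClimateSeries
    soil_grid: WHCGrid | None = None
    field_soils: pd.DataFrame | None = None


def _species_latitudes(tree: Tree, spec: ScenarioSpec,
                       rng: np.random.Generator) -> dict[str, float]:
    """Species mean latitudes: Brownian motion on the tree, mapped affinely
    onto the scenario latitude band (so phylogenetic structure in geography
    is preserved)."""
    from .phylo_comparative import simulate_bm

    z = simulate_bm(tree, 1, rng)[:, 0]
    lo, hi = float(z.min()), float(z.max())
    lat0, lat1 = spec.lat_range
    if hi == lo:
        lats = np.full(len(z), 0.5 * (lat0 + lat1))
    else:
        lats = lat0 + (z - lo) / (hi - lo) * (lat1 - lat0)
    return dict(zip(tree.tip_labels, lats))


def gen_specimens(tree: Tree, spec: ScenarioSpec,
                  ) -> tuple[list[SpecimenRecord], dict[str, ClimateSeries],
                             pd.DataFrame]:
    """Specimen records plus per-specimen climate series for every species
    on the tree.  Returns (records, climate, species_table)."""
    rng = np.random.default_rng(spec.seed)
    lats = _species_latitudes(tree, spec, rng)
    species = tree.tip_labels
    elevs = {s: float(np.clip(rng.normal(spec.elev_mean_m, spec.elev_sd_m),
                              0.0, 3000.0)) for s in species}
    lons = {s: float(rng.normal(spec.lon_center, 0.5)) for s in species}

    # clade-wide tracking target: median noise-free lived CWD at the base
    # (May) collection month
    lived = {s: _lived_cwd_by_collection_month(lats[s], elevs[s], spec)
             for s in species}
    target = float(np.median([lived[s][MAY] for s in species]))

    records: list[SpecimenRecord] = []
    climate: dict[str, ClimateSeries] = {}
    sp_rows = []
    y_lo, y_hi = spec.year_span[0] + 2, spec.year_span[1]
    for s in species:
        m_lo, m_hi, p_hi = _tracking_month_distribution(
            lived[s], target, spec.tracking_strength)
        sp_rows.append({
            "species": s, "lat_centroid": lats[s], "lon_centroid": lons[s],
            "elev_centroid_m": elevs[s],
            "annual_tmean_c": species_annual_tmean(lats[s], elevs[s], spec),
            "onset_offset_months": onset_month_offset(lats[s], spec),
            "tracking_month_lo": m_lo, "tracking_month_hi": m_hi,
            "tracking_p_hi": p_hi})
        for j in range(spec.n_specimens_per_species):
            sid = f"{s}_{j + 1:03d}"
            lat = float(lats[s] + rng.normal(0.0, spec.spatial_jitter_deg))
            lon = float(lons[s] + rng.normal(0.0, spec.spatial_jitter_deg))
            elev = float(np.clip(elevs[s] + rng.normal(0.0, 50.0), 0.0, 3500.0))
            month = m_hi if rng.random() < p_hi else m_lo
            if spec.noise_month_jitter_p > 0:
                u = rng.random()
                if u < spec.noise_month_jitter_p / 2:
                    month = max(MAR, month - 1)
                elif u < spec.noise_month_jitter_p:
                    month = min(JUL, month + 1)
            year = int(rng.integers(y_lo, y_hi + 1))
            day = int(rng.integers(1, 29))
            radius = float(min(rng.lognormal(np.log(0.5), 0.6), 5.0))
            fruits = bool(rng.random() < 0.71)
            flowers = bool(rng.random() < 0.8)
            buds = bool(rng.random() < 0.3)
            if not (fruits or flowers or buds):
                flowers = True
            county = f"county_{int((lat - spec.lat_range[0]) // 0.5)}"
            records.append(SpecimenRecord(
                specimen_id=sid, species=s, lat=lat, lon=lon,
                elevation_m=elev,
                collection_date=_dt.date(year, month, day),
                error_radius_km=radius, has_buds=buds, has_flowers=flowers,
                has_fruits=fruits, county=county))
            climate[sid] = gen_climate_series(
                lat, elev, (year - 2, year), spec, rng, location_id=sid)
    return records, climate, pd.DataFrame(sp_rows)


# ---------------------------------------------------------------------------
# soils

def gen_soil_grid(extent: tuple, cell_size: float, autocorr_range: float,
                  seed: int, mean_mm: float = 150.0,
                  sd_mm: float = 30.0) -> WHCGrid:
    """Spatially autocorrelated WHC field: white noise smoothed with a
    Gaussian kernel of the given range (same units as cell_size), rescaled
    to the target mean and SD and clipped at zero.  ``autocorr_range = 0``
    gives i.i.d. cells."""
    xmin, ymin, xmax, ymax = extent
    ncols = max(1, int(np.ceil((xmax - xmin) / cell_size)))
    nrows = max(1, int(np.ceil((ymax - ymin) / cell_size)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((nrows, ncols))
    if autocorr_range > 0:
        z = ndimage.gaussian_filter(z, sigma=autocorr_range / cell_size,
                                    mode="reflect")
        sd = z.std()
        if sd > 0:
            z = z / sd
    values = np.clip(mean_mm + sd_mm * z, 0.0, None)
    return WHCGrid(ncols=ncols, nrows=nrows, xllcorner=xmin, yllcorner=ymin,
                   cellsize=cell_size, nodata=-9999.0, values=values)


def plant_soil_effect(grid: WHCGrid, records: list,
                      species_annual_tmean_map: dict,
                      offset_mm: float, temp_slope: float = 0.0) -> WHCGrid:
    """Return a copy of the grid with occupied cells shifted by the planted
    WHC offset (optionally varying with species annual temperature around
    the clade mean).  Cells occupied by several species get the mean shift."""
    values = grid.values.copy()
    mean_t = float(np.mean(list(species_annual_tmean_map.values())))
    shifts: dict[tuple, list] = {}
    for r in records:
        cell = grid.cell_of(r.lon, r.lat)
        if cell is None or grid.values[cell] == grid.nodata:
            continue
        s = offset_mm + temp_slope * (species_annual_tmean_map[r.species] - mean_t)
        shifts.setdefault(cell, []).append(s)
    for cell, ss in shifts.items():
        values[cell] = max(0.0, values[cell] + float(np.mean(ss)))
    return WHCGrid(grid.ncols, grid.nrows, grid.xllcorner, grid.yllcorner,
                   grid.cellsize, grid.nodata, values)


def gen_field_soils(species_table: pd.DataFrame, spec: ScenarioSpec,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Field soil-sample table: a handful of sites per species (3-6, mean
    4.5) with coarse fractions that decline with species annual temperature
    at the planted slope (plus site noise)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 7)
    mean_t = float(species_table["annual_tmean_c"].mean())
    rows = []
    for row in species_table.itertuples(index=False):
        n_sites = int(rng.integers(3, 7))
        for k in range(n_sites):
            cf = (40.0 + spec.coarse_slope_pct_per_degc
                  * (row.annual_tmean_c - mean_t) + rng.normal(0.0, 5.0))
            rows.append({"species": row.species, "site_id": f"{row.species}_s{k + 1}",
                         "coarse_fraction_pct": float(np.clip(cf, 0.0, 100.0))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole scenario

def gen_scenario(spec: ScenarioSpec) -> ScenarioBundle:
    """Generate every input the pipeline needs under one scenario spec:
    tree, specimens + climate, soil WHC grid (with any planted effect) and
    field soils.  Fully reproducible under the spec's seed."""
    tree = gen_tree(spec.n_species, spec.seed)
    records, climate, species_table = gen_specimens(tree, spec)
    lat_pad = 0.35  # degrees beyond the specimen scatter
    lats = [r.lat for r in records]
    lons = [r.lon for r in records]
    extent = (min(lons) - lat_pad, min(lats) - lat_pad,
              max(lons) + lat_pad, max(lats) + lat_pad)
    grid = gen_soil_grid(extent, cell_size=0.02, autocorr_range=0.06,
                         seed=spec.seed + 11)
    if spec.soil_whc_offset_mm != 0.0 or spec.soil_whc_temp_slope != 0.0:
        tmap = dict(zip(species_table["species"],
                        species_table["annual_tmean_c"]))
        grid = plant_soil_effect(grid, records, tmap,
                                 spec.soil_whc_offset_mm,
                                 spec.soil_whc_temp_slope)
    soils = gen_field_soils(species_table, spec)
    return ScenarioBundle(spec=spec, tree=tree, species_table=species_table,
                          specimens=records, climate=climate,
                          soil_grid=grid, field_soils=soils)
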