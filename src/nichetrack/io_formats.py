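"""Readers, writers and core domain types.

File formats are deliberately plain: CSV tables for specimens, climate and
field soils, Newick for the phylogeny, ESRI ASCII grids for soil
water-holding capacity.  Dates are ISO-8601 in files.  Coordinates are
decimal degrees (WGS84); raster lookups use the nearest cell centre with no
interpolation, matching point extraction from a gridded product.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "NichetrackError",
    "FormatError",
    "ConfigError",
    "RowIssue",
    "SpecimenRecord",
    "ClimateSeries",
    "WHCGrid",
    "Tree",
    "TreeNode",
    "ym_index",
    "index_ym",
    "read_specimens",
    "write_specimens",
    "specimens_to_frame",
    "frame_to_specimens",
    "read_climate",
    "write_climate",
    "read_tree",
    "write_tree",
    "read_whc_grid",
    "write_whc_grid",
    "read_field_soils",
    "write_field_soils",
    "load_config",
    "setup_logging",
    "run_full_pipeline",
]

logger = logging.getLogger("nichetrack")


def setup_logging(level: str = "INFO") -> None:
    """Configure stage-granularity logging to stderr."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# errors

class NichetrackError(Exception):
    """Base class for package errors."""


class FormatError(NichetrackError):
    """A file does not conform to its documented schema."""


class ConfigError(NichetrackError):
    """Pipeline configuration is inconsistent or incomplete."""


@dataclass(frozen=True)
class RowIssue:
    """A malformed row, reported with its 1-based line number."""

    line: int
    message: str


# ---------------------------------------------------------------------------
# month arithmetic (used by every windowing operation)

def ym_index(year: int, month: int) -> int:
    """Serial month number: ``year*12 + month - 1``.  Month is 1..12."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return year * 12 + (month - 1)


def index_ym(idx: int) -> tuple[int, int]:
    """Inverse of :func:`ym_index`."""
    return idx // 12, idx % 12 + 1


# ---------------------------------------------------------------------------
# specimen records

SPECIMEN_COLUMNS = [
    "specimen_id", "species", "lat", "lon", "elevation_m",
    "collection_date", "error_radius_km", "has_buds", "has_flowers",
    "has_fruits", "county",
]


@dataclass
class SpecimenRecord:
    """One herbarium specimen with location, date and QC fields."""

    specimen_id: str
    species: str
    lat: float
    lon: float
    elevation_m: float
    collection_date: _dt.date
    error_radius_km: float | None  # None = unknown, flagged for QC
    has_buds: bool
    has_flowers: bool
    has_fruits: bool
    county: str

    @property
    def has_reproductive(self) -> bool:
        """Any reproductive structure present (buds, flowers or fruits)."""
        return self.has_buds or self.has_flowers or self.has_fruits

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon out of range: {self.lon}")
        if self.error_radius_km is not None and self.error_radius_km < 0:
            raise ValueError("error_radius_km must be >= 0")


_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}
_NA = {"", "na", "nan", "none", "null"}


def _parse_bool(raw: object) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"unparseable flag: {raw!r}")


def read_specimens(path: str | Path) -> tuple[list[SpecimenRecord], list[RowIssue]]:
    """Read a specimen CSV.

    Returns the parsed records and a list of row-level issues (with 1-based
    file line numbers).  Rows with an unparseable date or coordinates are
    collected as issues, never silently dropped.  A missing required column
    raises :class:`FormatError`.  A missing/NA ``error_radius_km`` yields a
    record with ``error_radius_km=None``, flagged for QC downstream.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    records: list[SpecimenRecord] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            date = _dt.date.fromisoformat(str(row.collection_date).strip())
            radius_raw = str(row.error_radius_km).strip().lower()
            radius = None if radius_raw in _NA else float(radius_raw)
            records.append(SpecimenRecord(
                specimen_id=str(row.specimen_id),
                species=str(row.species),
                lat=float(row.lat),
                lon=float(row.lon),
                elevation_m=float(row.elevation_m),
                collection_date=date,
                error_radius_km=radius,
                has_buds=_parse_bool(row.has_buds),
                has_flowers=_parse_bool(row.has_flowers),
                has_fruits=_parse_bool(row.has_fruits),
                county=str(row.county),
            ))
        except (ValueError, TypeError) as exc:
            issues.append(RowIssue(line, str(exc)))
    if issues:
        logger.warning("read_specimens: %d malformed row(s) in %s", len(issues), path)
    return records, issues


def specimens_to_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "specimen_id": r.specimen_id,
            "species": r.species,
            "lat": r.lat,
            "lon": r.lon,
            "elevation_m": r.elevation_m,
            "collection_date": r.collection_date.isoformat(),
            "error_radius_km": "" if r.error_radius_km is None else r.error_radius_km,
            "has_buds": r.has_buds,
            "has_flowers": r.has_flowers,
            "has_fruits": r.has_fruits,
            "county": r.county,
        })
    return pd.DataFrame(rows, columns=SPECIMEN_COLUMNS)


def frame_to_specimens(df: pd.DataFrame) -> list[SpecimenRecord]:
    out = []
    for row in df.itertuples(index=False):
        radius = row.error_radius_km
        if isinstance(radius, str):
            radius = None if radius.strip().lower() in _NA else float(radius)
        elif radius is not None and (isinstance(radius, float) and math.isnan(radius)):
            radius = None
        out.append(SpecimenRecord(
            specimen_id=str(row.specimen_id), species=str(row.species),
            lat=float(row.lat), lon=float(row.lon),
            elevation_m=float(row.elevation_m),
            collection_date=_dt.date.fromisoformat(str(row.collection_date)),
            error_radius_km=radius,
            has_buds=bool(row.has_buds) if not isinstance(row.has_buds, str) else _parse_bool(row.has_buds),
            has_flowers=bool(row.has_flowers) if not isinstance(row.has_flowers, str) else _parse_bool(row.has_flowers),
            has_fruits=bool(row.has_fruits) if not isinstance(row.has_fruits, str) else _parse_bool(row.has_fruits),
            county=str(row.county),
        ))
    return out


def write_specimens(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    specimens_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# climate series

@dataclass
class ClimateSeries:
    """Monthly climate at one location: mean temperature (deg C), total
    precipitation (mm) and total climatic water deficit (mm)."""

    location_id: str
    year: np.ndarray
    month: np.ndarray
    tmean_c: np.ndarray
    ppt_mm: np.ndarray
    cwd_mm: np.ndarray
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.year = np.asarray(self.year, dtype=int)
        self.month = np.asarray(self.month, dtype=int)
        self.tmean_c = np.asarray(self.tmean_c, dtype=float)
        self.ppt_mm = np.asarray(self.ppt_mm, dtype=float)
        self.cwd_mm = np.asarray(self.cwd_mm, dtype=float)
        if np.any(self.ppt_mm < 0) or np.any(self.cwd_mm < 0):
            raise ValueError("ppt_mm and cwd_mm must be >= 0")
        order = np.argsort(self.year * 12 + self.month - 1, kind="stable")
        for name in ("year", "month", "tmean_c", "ppt_mm", "cwd_mm"):
            setattr(self, name, getattr(self, name)[order])
        mi = self.year * 12 + self.month - 1
        if len(mi) and not np.array_equal(mi, np.arange(mi[0], mi[0] + len(mi))):
            raise ValueError(f"{self.location_id}: months not contiguous")
        self._index = {int(m): i for i, m in enumerate(mi)}

    def __len__(self) -> int:
        return len(self.year)

    def has(self, year: int, month: int) -> bool:
        return ym_index(year, month) in self._index

    def at(self, year: int, month: int) -> tuple[float, float, float]:
        """(tmean_c, ppt_mm, cwd_mm) for one month."""
        try:
            i = self._index[ym_index(year, month)]
        except KeyError:
            raise KeyError(f"{self.location_id}: no climate for {year}-{month:02d}") from None
        return float(self.tmean_c[i]), float(self.ppt_mm[i]), float(self.cwd_mm[i])

    def slice(self, start: tuple[int, int], end: tuple[int, int]) -> "ClimateSeries":
        """Sub-series over the inclusive month interval [start, end]."""
        a, b = ym_index(*start), ym_index(*end)
        if a > b:
            raise ValueError("start after end")
        for idx in (a, b):
            if idx not in self._index:
                y, m = index_ym(idx)
                raise KeyError(f"{self.location_id}: no climate for {y}-{m:02d}")
        i, j = self._index[a], self._index[b] + 1
        return ClimateSeries(self.location_id, self.year[i:j], self.month[i:j],
                             self.tmean_c[i:j], self.ppt_mm[i:j], self.cwd_mm[i:j])


CLIMATE_COLUMNS = ["location_id", "year", "month", "tmean_c", "ppt_mm", "cwd_mm"]


def read_climate(path: str | Path) -> dict[str, ClimateSeries]:
    """Read a long-format monthly climate CSV into per-location series."""
    df = pd.read_csv(path)
    missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    out: dict[str, ClimateSeries] = {}
    for loc, g in df.groupby("location_id", sort=False):
        out[str(loc)] = ClimateSeries(
            str(loc), g["year"].to_numpy(), g["month"].to_numpy(),
            g["tmean_c"].to_numpy(), g["ppt_mm"].to_numpy(), g["cwd_mm"].to_numpy())
    return out


def write_climate(series: dict[str, ClimateSeries] | Iterable[ClimateSeries],
                  path: str | Path) -> None:
    if isinstance(series, dict):
        series = series.values()
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "location_id": s.location_id, "year": s.year, "month": s.month,
            "tmean_c": s.tmean_c, "ppt_mm": s.ppt_mm, "cwd_mm": s.cwd_mm}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# trees

class TreeNode:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


class Tree:
    """Rooted phylogeny with branch lengths.

    Tip labels are unique.  Polytomies are tolerated on read; comparative
    operations that require a binary tree raise and point at
    :meth:`resolve_polytomies`.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [t.label for t in self.tips()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise FormatError(f"duplicate tip label(s): {dupes}")
        if any(lab is None for lab in labels):
            raise FormatError("unlabeled tip")
        for node in self.preorder():
            if node is not self.root and node.length < 0:
                raise FormatError(f"negative branch length at {node.label or 'internal node'}")

    # -- traversal -----------------------------------------------------
    def preorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def postorder(self) -> list[TreeNode]:
        return list(reversed([n for n in self._preorder_rl()]))

    def _preorder_rl(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    # -- structure -----------------------------------------------------
    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.preorder())

    def has_polytomy(self) -> bool:
        return any(len(n.children) > 2 for n in self.preorder())

    def resolve_polytomies(self) -> "Tree":
        """Return a copy with polytomies resolved by zero-length branches
        (arbitrary but deterministic caterpillar expansion)."""
        t = self.copy()
        for node in t.preorder():
            while len(node.children) > 2:
                a = node.children.pop()
                b = node.children.pop()
                joint = TreeNode(None, 0.0)
                joint.add_child(b)
                joint.add_child(a)
                node.add_child(joint)
        return Tree(t.root)

    def copy(self) -> "Tree":
        def rec(n: TreeNode) -> TreeNode:
            m = TreeNode(n.label, n.length)
            for c in n.children:
                m.add_child(rec(c))
            return m
        return Tree(rec(self.root))

    def scaled(self, factor: float) -> "Tree":
        t = self.copy()
        for n in t.preorder():
            n.length *= factor
        return t

    # -- numerics ------------------------------------------------------
    def depths(self) -> dict[TreeNode, float]:
        """Root-to-node path lengths (root edge excluded)."""
        d = {self.root: 0.0}
        for n in self.preorder():
            if n is not self.root:
                d[n] = d[n.parent] + n.length
        return d

    def tip_depths(self) -> np.ndarray:
        d = self.depths()
        return np.array([d[t] for t in self.tips()])

    def vcv(self) -> tuple[np.ndarray, list[str]]:
        """Brownian-motion covariance structure: ``C[i, j]`` is the shared
        root-to-MRCA path length of tips i and j; diagonal is tip depth.
        Returns (C, tip order)."""
        tips = self.tips()
        n = len(tips)
        tip_idx = {id(t): i for i, t in enumerate(tips)}
        C = np.zeros((n, n))
        depth = self.depths()
        # postorder sweep: at each internal node, its depth is the shared
        # path for every cross-child tip pair below it
        below: dict[int, list[int]] = {}
        for node in self.postorder():
            if node.is_tip:
                i = tip_idx[id(node)]
                below[id(node)] = [i]
                C[i, i] = depth[node]
            else:
                groups = [below.pop(id(c)) for c in node.children]
                h = depth[node]
                for gi in range(len(groups)):
                    for gj in range(gi + 1, len(groups)):
                        for i in groups[gi]:
                            for j in groups[gj]:
                                C[i, j] = C[j, i] = h
                below[id(node)] = [i for g in groups for i in g]
        return C, [t.label for t in tips]

    def newick(self, precision: int = 10) -> str:
        def rec(n: TreeNode) -> str:
            if n.is_tip:
                core = _quote_label(n.label)
            else:
                core = "(" + ",".join(rec(c) for c in n.children) + ")"
                if n.label:
                    core += _quote_label(n.label)
            if n is self.root:
                return core
            return f"{core}:{n.length:.{precision}g}"
        return rec(self.root) + ";"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[] '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_tree(path_or_string: str | Path) -> Tree:
    """Parse a Newick tree (file path or literal string) with branch lengths.

    Polytomies are accepted and logged.  Unbalanced parentheses raise
    :class:`FormatError`; so do duplicate tip labels.
    """
    import dendropy

    s = str(path_or_string)
    if not s.strip().startswith("(") and Path(s).exists():
        s = Path(s).read_text()
    try:
        dt = dendropy.Tree.get(data=s, schema="newick",
                               suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"Newick parse error: {exc}") from exc

    def convert(dn) -> TreeNode:
        label = dn.taxon.label if dn.taxon is not None else (dn.label or None)
        node = TreeNode(label, dn.edge.length if dn.edge.length is not None else 0.0)
        for c in dn.child_nodes():
            node.add_child(convert(c))
        return node

    tree = Tree(convert(dt.seed_node))
    if tree.n_tips < 2:
        raise FormatError("tree must have at least 2 tips")
    if tree.has_polytomy():
        logger.info("read_tree: tree contains polytomies (resolvable with "
                    "Tree.resolve_polytomies())")
    return tree


def write_tree(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# soil water-holding-capacity grids (ESRI ASCII)

@dataclass
class WHCGrid:
    """Rectangular water-holding-capacity raster (mm per cell).

    ``values`` is (nrows, ncols) with row 0 the NORTHERNMOST row, as stored
    in an ESRI ASCII grid; ``(xllcorner, yllcorner)`` is the lower-left
    corner of the lower-left cell.
    """

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise FormatError(
                f"grid shape {self.values.shape} != (nrows={self.nrows}, ncols={self.ncols})")
        valid = self.values != self.nodata
        if np.any(self.values[valid] < 0):
            raise FormatError("WHC values must be >= 0 or nodata")

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing point (x, y), or None if outside."""
        col = int(math.floor((x - self.xllcorner) / self.cellsize))
        row_from_bottom = int(math.floor((y - self.yllcorner) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def value_at(self, x: float, y: float) -> float | None:
        """Nearest-cell value at (x, y); None if outside or nodata."""
        cell = self.cell_of(x, y)
        if cell is None:
            return None
        v = self.values[cell]
        return None if v == self.nodata else float(v)

    @property
    def n_nodata(self) -> int:
        return int(np.sum(self.values == self.nodata))


def read_whc_grid(path: str | Path) -> WHCGrid:
    """Read an ESRI ASCII raster (ncols/nrows/xllcorner/yllcorner/cellsize/
    NODATA_value header followed by row-major values, northern row first)."""
    text = Path(path).read_text().split()
    header: dict[str, float] = {}
    pos = 0
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    while pos + 1 < len(text) and text[pos].lower() in keys:
        header[text[pos].lower()] = float(text[pos + 1])
        pos += 2
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise FormatError(f"{path}: missing header field {req}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    body = text[pos:]
    if len(body) != ncols * nrows:
        raise FormatError(
            f"{path}: expected {ncols * nrows} values, found {len(body)}")
    values = np.array([float(v) for v in body]).reshape(nrows, ncols)
    return WHCGrid(ncols, nrows, header["xllcorner"], header["yllcorner"],
                   header["cellsize"], nodata, values)


def write_whc_grid(grid: WHCGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\nnrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.10g}\nyllcorner {grid.yllcorner:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\nNODATA_value {grid.nodata:.10g}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# field soils

SOILS_COLUMNS = ["species", "site_id", "coarse_fraction_pct"]


def read_field_soils(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SOILS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    bad = df[(df.coarse_fraction_pct < 0) | (df.coarse_fraction_pct > 100)]
    if len(bad):
        raise FormatError(f"{path}: coarse_fraction_pct outside [0, 100]")
    return df


def write_field_soils(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# configuration and pipeline orchestration

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return cfg


_ALL_STAGES = ["qc", "phenology", "windows", "stats", "evolve", "soil"]


def run_full_pipeline(config: dict | str | Path, out_dir: str | Path | None = None,
                      seed: int | None = None) -> dict:
    """Run the whole analysis from a config mapping (or YAML path).

    The config either names input files (``inputs:`` with keys specimens,
    climate, tree, soil_grid, field_soils) or a synthetic scenario
    (``scenario:``).  Results are returned as a dict of DataFrames and, when
    ``out_dir`` is set, written as CSV tables plus a machine-readable
    ``manifest.json``.  Identical config + seed give identical outputs.
    """
    from . import climate_windows, niche_models, niche_stats, phenology, \
        phylo_comparative, soil_refugia, specimen_qc
    from .synthetic_data import ScenarioSpec, gen_scenario

    if not isinstance(config, dict):
        config = load_config(config)
    stages = config.get("stages", _ALL_STAGES)
    unknown = set(stages) - set(_ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    if seed is None:
        seed = int(config.get("seed", 0))
    out_dir = Path(out_dir) if out_dir is not None else (
        Path(config["out_dir"]) if "out_dir" in config else None)

    # ---- inputs
    tree = None
    grid = None
    soils = None
    if "scenario" in config:
        spec = ScenarioSpec(**{**config["scenario"], "seed": seed})
        scen = gen_scenario(spec)
        records, climate, tree = scen.specimens, scen.climate, scen.tree
        grid, soils = scen.soil_grid, scen.field_soils
    elif "inputs" in config:
        inputs = config["inputs"]
        if "specimens" not in inputs or "climate" not in inputs:
            raise ConfigError("inputs must name 'specimens' and 'climate' files")
        records, issues = read_specimens(inputs["specimens"])
        if issues:
            logger.warning("pipeline: %d malformed specimen row(s) skipped", len(issues))
        climate = read_climate(inputs["climate"])
        if "tree" in inputs:
            tree = read_tree(inputs["tree"])
        if "soil_grid" in inputs:
            grid = read_whc_grid(inputs["soil_grid"])
        if "field_soils" in inputs:
            soils = read_field_soils(inputs["field_soils"])
    else:
        raise ConfigError("config must contain either 'scenario' or 'inputs'")

    if "evolve" in stages and tree is None:
        raise ConfigError("comparative stage enabled but no tree provided")
    if "soil" in stages and grid is None:
        raise ConfigError("soil stage enabled but no soil grid provided")

    results: dict = {}
    logger.info("pipeline: %d specimens in", len(records))

    # ---- qc
    if "qc" in stages:
        qc_cfg = config.get("qc", {})
        records, report = specimen_qc.apply_qc(
            records,
            max_error_radius_km=qc_cfg.get("max_error_radius_km", 5.0),
            k_nn=qc_cfg.get("k_nn", 1),
            mult=qc_cfg.get("mult", 10.0),
            manual_drops=qc_cfg.get("manual_drops", ()),
            subsample_max_n=qc_cfg.get("subsample_max_n", 200),
            seed=seed,
        )
        results["qc_report"] = report.to_frame()
        logger.info("pipeline: qc retained %d of %d", report.n_retained, report.n_input)

    # ---- phenology: germination month + three windows per specimen
    if "phenology" in stages:
        phen, records = phenology.phenology_table(records, climate)
        results["phenology"] = phen

    # ---- windows: per-specimen and species-level summaries
    if "windows" in stages:
        if "phenology" not in results:
            raise ConfigError("windows stage requires the phenology stage")
        by_spec = climate_windows.specimen_window_table(results["phenology"], climate)
        by_species = climate_windows.species_niche_table(by_spec, records)
        deltas = climate_windows.delta_cwd(by_species)
        results["niche_by_specimen"] = by_spec
        results["niche_by_species"] = by_species
        results["delta_cwd"] = deltas

    # ---- stats: window-variance comparisons
    if "stats" in stages:
        if "niche_by_species" not in results:
            raise ConfigError("stats stage requires the windows stage")
        results["stats_windows"] = niche_stats.window_comparison_table(
            results["niche_by_species"])

    # ---- evolve: comparative analyses on the tree
    if "evolve" in stages:
        if "niche_by_species" not in results:
            raise ConfigError("evolve stage requires the windows stage")
        results["comparative_results"] = _comparative_stage(
            tree, results["niche_by_species"], results["delta_cwd"],
            phylo_comparative, seed=seed,
            n_perm=config.get("evolve", {}).get("n_perm", 1000),
            n_sim=config.get("evolve", {}).get("n_sim", 1000))
        results["model_fits"] = _model_fit_stage(
            tree, results["niche_by_species"], niche_models,
            n_bins=config.get("evolve", {}).get("n_bins", 100))

    # ---- soil
    if "soil" in stages:
        soil_cfg = config.get("soil", {})
        results["soil_results"] = soil_refugia.soil_stage(
            records, grid, soils, results.get("niche_by_species"), tree,
            buffer_km=soil_cfg.get("buffer_km", 20.0),
            n_random=soil_cfg.get("n_random", 100), seed=seed)

    # ---- write
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": seed, "stages": list(stages), "tables": {}}
        for name, table in results.items():
            f = out_dir / f"{name}.csv"
            table.to_csv(f, index=False, float_format="%.10g")
            manifest["tables"][name] = {"file": f.name, "n_rows": int(len(table))}
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return results


def _trait_vectors(by_species: pd.DataFrame, kind: str) -> dict[str, dict[str, float]]:
    """Per-variable {species: mean} maps for one window kind."""
    sub = by_species[by_species["kind"] == kind]
    return {var: dict(zip(sub["species"], sub[f"{var}_mean"]))
            for var in ("tmean_c", "ppt_mm", "cwd_mm")}


def _comparative_stage(tree, by_species, deltas, pc, seed, n_perm, n_sim) -> pd.DataFrame:
    rows = []
    btree = tree.resolve_polytomies() if tree.has_polytomy() else tree
    ss = _trait_vectors(by_species, "specimen_specific")
    cs = _trait_vectors(by_species, "clade_seasonal")
    an = _trait_vectors(by_species, "annual")
    # cross-window PIC correlations per variable
    for var in ("tmean_c", "ppt_mm", "cwd_mm"):
        for (ka, a), (kb, b) in ((("specimen_specific", ss), ("clade_seasonal", cs)),
                                 (("specimen_specific", ss), ("annual", an))):
            r = pc.pic_correlation(btree, a[var], b[var])
            rows.append({"analysis": "pic_correlation", "variables": f"{var}:{ka}~{kb}",
                         "statistic": "r", "estimate": r.r, "se_or_ci": f"{r.ci95[0]:.4g},{r.ci95[1]:.4g}",
                         "p": r.p, "n_perm": "", "n_sim": "", "seed": seed})
    # PGLS of delta CWD on mean latitude
    lat = dict(zip(by_species[by_species["kind"] == "specimen_specific"]["species"],
                   by_species[by_species["kind"] == "specimen_specific"]["mean_latitude"]))
    dmap = dict(zip(deltas["species"], deltas["delta_cwd_mm"]))
    fit = pc.pgls(btree, dmap, [lat])
    rows.append({"analysis": "pgls_delta_cwd_vs_latitude", "variables": "delta_cwd~mean_latitude",
                 "statistic": "slope", "estimate": fit.beta[1], "se_or_ci": fit.se[1],
                 "p": fit.p[1], "n_perm": "", "n_sim": "", "seed": seed})
    # phylogenetic signal per variable and window kind
    rng_seed = seed
    for kind, traits in (("specimen_specific", ss), ("clade_seasonal", cs), ("annual", an)):
        for var in ("tmean_c", "ppt_mm", "cwd_mm"):
            rng_seed += 1
            kres = pc.K_tests(btree, traits[var], n_perm=n_perm, n_sim=n_sim, seed=rng_seed)
            rows.append({"analysis": "blomberg_K", "variables": f"{var}:{kind}",
                         "statistic": "K", "estimate": kres.K,
                         "se_or_ci": f"p_perm={kres.p_perm:.4g}", "p": kres.p_gt1,
                         "n_perm": n_perm, "n_sim": n_sim, "seed": rng_seed})
    return pd.DataFrame(rows)


def _model_fit_stage(tree, by_species, nm, n_bins) -> pd.DataFrame:
    rows = []
    btree = tree.resolve_polytomies() if tree.has_polytomy() else tree
    for kind in ("specimen_specific", "clade_seasonal", "annual"):
        traits = _trait_vectors(by_species, kind)
        for var, x in traits.items():
            fits = [nm.fit_bm(btree, x), nm.fit_ou(btree, x),
                    nm.fit_bbm(btree, x, n_bins=n_bins)]
            comp = nm.compare_models(fits)
            for f, d in zip(comp.fits, comp.delta_aic):
                rows.append({"trait": var, "kind": kind, "model": f.model,
                             "params": json.dumps(f.params, sort_keys=True),
                             "logLik": f.log_lik, "AIC": f.aic, "deltaAIC": d,
                             "supported": f.model in comp.supported})
    return pd.DataFrame(rows)
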