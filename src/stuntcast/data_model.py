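"""Domain types and plain-text readers/writers shared by every pipeline stage.

The pipeline works on a single planar raster geometry (km units, 1x1 km cells
by default).  Cluster surveys are point-referenced binomial records; gridded
inputs (environmental covariates, region labels, under-five population) are
stored as ESRI ASCII grids so that every artifact is human-readable text.

Conventions
-----------
* Planar km coordinates throughout; no geodesy.  Real-world use requires a
  projected CRS upstream.
* Cells follow the half-open convention ``[origin + i*cell, origin + (i+1)*cell)``;
  grids are stored north-up (first file row = northernmost row).
* Grid arrays are indexed ``[row, col]`` with row 0 the *southernmost* row in
  memory; the ASCII writer flips to north-first on disk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RasterGeometry",
    "ClusterRecord",
    "CovariateStack",
    "RegionMap",
    "PopulationRaster",
    "SchemaError",
    "ValidationError",
    "RasterParseError",
    "read_clusters",
    "write_clusters",
    "clusters_to_frame",
    "extract_covariates",
    "read_raster",
    "write_raster",
    "read_region_lookup",
    "write_region_lookup",
]

CLUSTER_COLUMNS = ("cluster_id", "x", "y", "year", "season", "n_examined", "n_stunted")
SEASONS = ("Gu", "Deyr")


class SchemaError(ValueError):
    """A table is missing a required column or has the wrong layout."""


class ValidationError(ValueError):
    """A record violates a domain invariant (named in the message)."""


class RasterParseError(ValueError):
    """An ASCII grid file could not be parsed; message carries the line number."""


@dataclass(frozen=True)
class RasterGeometry:
    """Shape and placement of the common analysis grid.

    ``origin_x``/``origin_y`` are the coordinates of the lower-left (south-west)
    corner of the grid, in km.  ``nodata_mask`` is True where a pixel carries
    no data; it participates in equality.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("raster geometry requires n_rows >= 1 and n_cols >= 1")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be > 0")
        if self.nodata_mask is not None:
            mask = np.asarray(self.nodata_mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise ValidationError("nodata_mask shape does not match geometry")
            object.__setattr__(self, "nodata_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the covered rectangle."""
        return (
            self.origin_x,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def mask(self) -> np.ndarray:
        """Boolean nodata mask (all-False if none was set)."""
        if self.nodata_mask is None:
            return np.zeros(self.shape, dtype=bool)
        return self.nodata_mask

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RasterGeometry):
            return NotImplemented
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.cell_size == other.cell_size
            and np.array_equal(self.mask(), other.mask())
        )

    def __hash__(self) -> int:  # frozen dataclass with custom eq
        return hash((self.n_rows, self.n_cols, self.origin_x, self.origin_y, self.cell_size))

    def pixel_of(self, x: float | np.ndarray, y: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing (x, y) under the half-open convention."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x: float | np.ndarray, y: float | np.ndarray) -> np.ndarray:
        row, col = self.pixel_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped (n_rows, n_cols)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class ClusterRecord:
    """One survey cluster: location, wave, binomial stunting counts, covariates."""

    cluster_id: str
    x: float
    y: float
    year: int
    season: str
    n_examined: int
    n_stunted: int
    covariates: dict[str, float] = field(default_factory=dict)
    region: int | str | None = None

    def __post_init__(self) -> None:
        if self.n_examined < 1:
            raise ValidationError(f"cluster {self.cluster_id}: n_examined must be >= 1")
        if not 0 <= self.n_stunted <= self.n_examined:
            raise ValidationError(
                f"cluster {self.cluster_id}: n_stunted={self.n_stunted} outside "
                f"[0, n_examined={self.n_examined}]"
            )

    @property
    def prevalence(self) -> float:
        return self.n_stunted / self.n_examined


@dataclass
class CovariateStack:
    """Per-year gridded covariates on one shared raster geometry.

    ``layers[name]`` maps a covariate name to ``{year: 2-D array}``.
    """

    geometry: RasterGeometry
    years: list[int]
    layers: dict[str, dict[int, np.ndarray]]

    def __post_init__(self) -> None:
        for name, per_year in self.layers.items():
            for year in self.years:
                if year not in per_year:
                    raise ValidationError(f"covariate {name!r} missing year {year}")
                grid = np.asarray(per_year[year], dtype=float)
                if grid.shape != self.geometry.shape:
                    raise ValidationError(
                        f"covariate {name!r} year {year}: grid shape {grid.shape} "
                        f"!= geometry {self.geometry.shape}"
                    )
                per_year[year] = grid
        self._check_ranges()

    def _check_ranges(self) -> None:
        ok = ~self.geometry.mask()
        for name, per_year in self.layers.items():
            for year, grid in per_year.items():
                vals = grid[ok]
                if name == "EVI" and (np.any(vals < 0) or np.any(vals > 1)):
                    raise ValidationError(f"EVI year {year}: values outside [0, 1]")
                if name in ("precipitation", "distance_to_water") and np.any(vals < 0):
                    raise ValidationError(f"{name} year {year}: negative values")

    @property
    def names(self) -> list[str]:
        return sorted(self.layers)


@dataclass
class RegionMap:
    """Integer region label per pixel plus region -> zone lookup."""

    geometry: RasterGeometry
    region_id: np.ndarray
    zone_of: dict[int, str]
    name_of: dict[int, str] = field(default_factory=dict)

    NODATA = -1

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id, dtype=int)
        if self.region_id.shape != self.geometry.shape:
            raise ValidationError("region raster shape does not match geometry")
        labels = self.labels()
        missing = [r for r in labels if r not in self.zone_of]
        if missing:
            raise ValidationError(f"regions without a zone: {missing}")

    def labels(self) -> list[int]:
        lab = np.unique(self.region_id)
        return [int(r) for r in lab if r != self.NODATA]

    def region_at(self, x: float | np.ndarray, y: float | np.ndarray) -> np.ndarray:
        row, col = self.geometry.pixel_of(x, y)
        return self.region_id[row, col]


@dataclass
class PopulationRaster:
    """Under-five population per pixel per year (non-negative reals)."""

    geometry: RasterGeometry
    years: list[int]
    counts: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        for year in self.years:
            if year not in self.counts:
                raise ValidationError(f"population raster missing year {year}")
            grid = np.asarray(self.counts[year], dtype=float)
            if grid.shape != self.geometry.shape:
                raise ValidationError(f"population year {year}: shape mismatch")
            if np.any(grid[~self.geometry.mask()] < 0):
                raise ValidationError(f"population year {year}: negative values")
            self.counts[year] = grid


# ---------------------------------------------------------------------------
# Cluster table IO (CSV with header, UTF-8)
# ---------------------------------------------------------------------------

def clusters_to_frame(clusters: Sequence[ClusterRecord]) -> pd.DataFrame:
    cov_names = sorted({name for c in clusters for name in c.covariates})
    rows = []
    for c in clusters:
        row: dict[str, object] = {
            "cluster_id": c.cluster_id,
            "x": c.x,
            "y": c.y,
            "year": c.year,
            "season": c.season,
            "n_examined": c.n_examined,
            "n_stunted": c.n_stunted,
        }
        for name in cov_names:
            row[name] = c.covariates.get(name, np.nan)
        if c.region is not None:
            row["region"] = c.region
        rows.append(row)
    return pd.DataFrame(rows)


def write_clusters(clusters: Sequence[ClusterRecord], path: str | Path) -> None:
    clusters_to_frame(clusters).to_csv(path, index=False)


def _parse_region(value: object) -> int | str:
    try:
        return int(value)  # numeric region labels
    except (TypeError, ValueError):
        return str(value)


def read_clusters(path: str | Path) -> list[ClusterRecord]:
    """Read a cluster survey table, one :class:`ClusterRecord` per row.

    Any column beyond the required schema (other than ``region``) is attached
    as a covariate.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")  # lossless round-trips
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cluster table missing column(s): {', '.join(missing)}")
    cov_names = [c for c in df.columns if c not in CLUSTER_COLUMNS and c != "region"]
    records = []
    for _, row in df.iterrows():
        covs = {name: float(row[name]) for name in cov_names if pd.notna(row[name])}
        records.append(
            ClusterRecord(
                cluster_id=str(row["cluster_id"]),
                x=float(row["x"]),
                y=float(row["y"]),
                year=int(row["year"]),
                season=str(row["season"]),
                n_examined=int(row["n_examined"]),
                n_stunted=int(row["n_stunted"]),
                covariates=covs,
                region=_parse_region(row["region"]) if "region" in df.columns and pd.notna(row.get("region")) else None,
            )
        )
    return records


def extract_covariates(
    clusters: Sequence[ClusterRecord], stack: CovariateStack
) -> list[ClusterRecord]:
    """Attach to each cluster the pixel value of every covariate for its year.

    Pixel lookup uses the half-open cell convention.  Idempotent: re-running
    overwrites the same keys with the same values.  Returns new records; the
    inputs are not mutated.
    """
    geom = stack.geometry
    out = []
    for c in clusters:
        if c.year not in stack.years:
            raise ValidationError(f"cluster {c.cluster_id}: year {c.year} not in covariate stack")
        if not bool(geom.contains(c.x, c.y)):
            raise ValidationError(f"cluster {c.cluster_id}: location ({c.x}, {c.y}) outside raster")
        row, col = geom.pixel_of(c.x, c.y)
        if geom.mask()[row, col]:
            raise ValidationError(f"cluster {c.cluster_id}: location falls on a nodata pixel")
        covs = dict(c.covariates)
        for name, per_year in stack.layers.items():
            covs[name] = float(per_year[c.year][row, col])
        out.append(dataclasses.replace(c, covariates=covs))
    return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid IO
# ---------------------------------------------------------------------------

_NODATA_DEFAULT = -9999.0
_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_raster(
    grid: np.ndarray,
    geometry: RasterGeometry,
    path: str | Path,
    nodata_value: float = _NODATA_DEFAULT,
    fmt: str = "%.8g",
) -> None:
    """Write a grid as an ESRI ASCII grid (.asc), north row first."""
    grid = np.asarray(grid, dtype=float)
    if grid.shape != geometry.shape:
        raise ValidationError(f"grid shape {grid.shape} does not match geometry {geometry.shape}")
    out = grid.copy()
    out[geometry.mask()] = nodata_value
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {geometry.n_cols}\n")
        fh.write(f"nrows {geometry.n_rows}\n")
        fh.write(f"xllcorner {geometry.origin_x:.8g}\n")
        fh.write(f"yllcorner {geometry.origin_y:.8g}\n")
        fh.write(f"cellsize {geometry.cell_size:.8g}\n")
        fh.write(f"NODATA_value {nodata_value:.8g}\n")
        for r in range(geometry.n_rows - 1, -1, -1):  # north row first
            fh.write(" ".join(fmt % v for v in out[r]) + "\n")


def read_raster(path: str | Path) -> tuple[np.ndarray, RasterGeometry]:
    """Read an ESRI ASCII grid; returns (grid, geometry with nodata mask)."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path, "r", encoding="utf-8") as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(header) < 6 and key in _HEADER_KEYS:
                if len(parts) != 2:
                    raise RasterParseError(f"line {lineno}: malformed header line {line!r}")
                try:
                    header[key] = float(parts[1])
                except ValueError as exc:
                    raise RasterParseError(f"line {lineno}: bad header value {parts[1]!r}") from exc
                continue
            try:
                rows.append(np.array(parts, dtype=float))
            except ValueError as exc:
                raise RasterParseError(f"line {lineno}: non-numeric grid value") from exc
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise RasterParseError(f"missing header key {key!r}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", _NODATA_DEFAULT)
    if len(rows) != n_rows or any(len(r) != n_cols for r in rows):
        raise RasterParseError(
            f"grid body is {len(rows)} rows; header declares {n_rows}x{n_cols}"
        )
    grid = np.vstack(rows)[::-1]  # file is north-first; memory is south-first
    mask = grid == nodata
    geometry = RasterGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata_mask=mask if mask.any() else None,
    )
    grid = grid.copy()
    grid[mask] = np.nan
    return grid, geometry


def write_region_lookup(regions: RegionMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "region_id": regions.labels(),
            "region_name": [regions.name_of.get(r, f"region_{r}") for r in regions.labels()],
            "zone_name": [regions.zone_of[r] for r in regions.labels()],
        }
    )
    df.to_csv(path, index=False)


def read_region_lookup(path: str | Path) -> tuple[dict[int, str], dict[int, str]]:
    """Returns (zone_of, name_of) maps keyed by region id."""
    df = pd.read_csv(path)
    for col in ("region_id", "region_name", "zone_name"):
        if col not in df.columns:
            raise SchemaError(f"region lookup missing column: {col}")
    zone_of = {int(r.region_id): str(r.zone_name) for r in df.itertuples()}
    name_of = {int(r.region_id): str(r.region_name) for r in df.itertuples()}
    return zone_of, name_of
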