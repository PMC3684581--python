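"""Raster and occurrence-table input/output on a regular geographic grid.

Everything downstream works on an :class:`EnvGrid` — a masked multi-layer
raster in geographic (lon/lat) coordinates — and on :class:`PresenceSet`
objects, i.e. sets of occupied grid cells. Cell IDs are ``(row, col)``
pairs with row 0 at the northern edge. A point lying exactly on a cell
boundary belongs to the cell to its south-east (half-open intervals
``[west, east)`` and ``[north, south)``), so binning is deterministic.

Rasters are read and written as ESRI ASCII grids (``.asc``), a plain-text
format with a six-line header; all layers of a stack must share geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nichecast")

#: Equatorial circumference used for arc-length conversions, in km.
EARTH_CIRCUMFERENCE_KM = 40_075.0

CellId = tuple[int, int]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EnvGrid:
    """A masked multi-layer environmental raster with shared geometry.

    Parameters
    ----------
    cell_size_arcmin : float
        Angular cell size in arc-minutes (10.0 for a 10-minute grid).
    origin : tuple of float
        ``(lon, lat)`` of the grid's north-west corner, in degrees.
    layers : dict
        Maps variable name to a ``(n_rows, n_cols)`` float array. Cells
        outside the mask hold NaN in every layer.
    mask : ndarray of bool
        ``(n_rows, n_cols)``; True marks a valid (land) cell.
    """

    cell_size_arcmin: float
    origin: tuple[float, float]
    layers: dict[str, np.ndarray]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvGrid needs at least one layer")
        shapes = {name: arr.shape for name, arr in self.layers.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"layers disagree on shape: {shapes}")
        shape = next(iter(shapes.values()))
        if self.mask.shape != shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match layers {shape}"
            )
        if self.cell_size_arcmin <= 0:
            raise ValueError("cell_size_arcmin must be positive")
        # enforce the invariant: masked cells carry no values
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            arr[~self.mask] = np.nan
            self.layers[name] = arr

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mask.shape[1]

    @property
    def cell_size_deg(self) -> float:
        return self.cell_size_arcmin / 60.0

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    def valid_cells(self) -> list[CellId]:
        """All valid cell IDs in row-major order."""
        rows, cols = np.nonzero(self.mask)
        return list(zip(rows.tolist(), cols.tolist()))

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def cell_centroid(self, cell: CellId) -> tuple[float, float]:
        """(lon, lat) of a cell's centre."""
        r, c = cell
        lon0, lat0 = self.origin
        cs = self.cell_size_deg
        return lon0 + (c + 0.5) * cs, lat0 - (r + 0.5) * cs

    # -- value access -------------------------------------------------------
    def values_at(
        self, cells: Sequence[CellId], variables: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """Predictor values at the given cells, one row per cell.

        The returned frame is indexed by a ``(row, col)`` MultiIndex and has
        one column per requested variable.
        """
        variables = list(variables) if variables is not None else list(self.layers)
        cells = list(cells)
        if cells:
            rows = np.array([c[0] for c in cells])
            cols = np.array([c[1] for c in cells])
            data = {v: self.layers[v][rows, cols] for v in variables}
        else:
            data = {v: np.array([]) for v in variables}
        idx = pd.MultiIndex.from_tuples(cells, names=["row", "col"]) if cells else None
        return pd.DataFrame(data, index=idx)

    def table(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Values of all valid cells (row-major order)."""
        return self.values_at(self.valid_cells(), variables)

    def copy(self) -> "EnvGrid":
        return EnvGrid(
            cell_size_arcmin=self.cell_size_arcmin,
            origin=self.origin,
            layers={k: v.copy() for k, v in self.layers.items()},
            mask=self.mask.copy(),
        )


@dataclass(frozen=True)
class OccurrencePoints:
    """Georeferenced occurrence records, optionally tagged by clade."""

    records: pd.DataFrame  # columns lon, lat[, clade]

    def __post_init__(self) -> None:
        df = self.records
        for col in ("lon", "lat"):
            if col not in df.columns:
                raise ValueError(f"occurrence table lacks column {col!r}")
        if len(df) and not (
            df["lon"].between(-180, 180).all() and df["lat"].between(-90, 90).all()
        ):
            raise ValueError("coordinates outside [-180,180] x [-90,90]")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class PresenceSet:
    """Distinct grid cells occupied by a taxon (set semantics)."""

    cells: frozenset[CellId]
    taxon: str = "species"

    def __len__(self) -> int:
        return len(self.cells)

    def sorted_cells(self) -> list[CellId]:
        return sorted(self.cells)

    def to_frame(self) -> pd.DataFrame:
        cells = self.sorted_cells()
        return pd.DataFrame(
            {"row": [c[0] for c in cells], "col": [c[1] for c in cells]}
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid IO
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array with NaN nodata, header dict)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = np.asarray(data, dtype=float).reshape(nrows, ncols)
    nodata = header.get("nodata_value", _NODATA)
    data[data == nodata] = np.nan
    return data, header


def write_ascii_grid(
    path: str | Path, array: np.ndarray, *, origin: tuple[float, float],
    cell_size_deg: float, nodata: float = _NODATA,
) -> None:
    """Write a 2-D array (NaN = nodata) as an ESRI ASCII grid."""
    array = np.asarray(array, dtype=float)
    nrows, ncols = array.shape
    lon0, lat0 = origin
    yll = lat0 - nrows * cell_size_deg
    out = np.where(np.isnan(array), nodata, array)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {lon0!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cell_size_deg!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, out, fmt="%.10g")


def load_env_stack(
    paths: Sequence[str | Path], variable_names: Sequence[str] | None = None
) -> EnvGrid:
    """Load aligned single-band rasters into one :class:`EnvGrid`.

    The mask is the intersection of validity: a cell is valid only if it
    carries data in *every* layer. A geometry mismatch between rasters is a
    hard error naming the offending file.
    """
    if not paths:
        raise ValueError("no raster paths given")
    if variable_names is None:
        variable_names = [Path(p).stem for p in paths]
    if len(variable_names) != len(paths):
        raise ValueError("variable_names must match paths in length")
    if len(set(variable_names)) != len(variable_names):
        raise ValueError("variable names must be unique")

    arrays, ref_header, ref_path = [], None, None
    for path in paths:
        arr, header = read_ascii_grid(path)
        if ref_header is None:
            ref_header, ref_path = header, path
        else:
            for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
                if not np.isclose(header[key], ref_header[key], atol=1e-9):
                    raise ValueError(
                        f"raster geometry mismatch: {path} disagrees with "
                        f"{ref_path} on {key} "
                        f"({header[key]} vs {ref_header[key]})"
                    )
        arrays.append(arr)

    mask = np.all([np.isfinite(a) for a in arrays], axis=0)
    cs_deg = ref_header["cellsize"]
    lat_top = ref_header["yllcorner"] + ref_header["nrows"] * cs_deg
    return EnvGrid(
        cell_size_arcmin=cs_deg * 60.0,
        origin=(ref_header["xllcorner"], lat_top),
        layers=dict(zip(variable_names, arrays)),
        mask=mask,
    )


def read_occurrences(path: str | Path) -> OccurrencePoints:
    """Read a lon,lat[,clade] CSV of occurrence points."""
    df = pd.read_csv(path)
    return OccurrencePoints(records=df)


def write_occurrences(points: OccurrencePoints, path: str | Path) -> None:
    points.records.to_csv(path, index=False)


def write_presence_set(presences: PresenceSet, path: str | Path) -> None:
    presences.to_frame().to_csv(path, index=False)


def read_presence_set(path: str | Path, taxon: str = "species") -> PresenceSet:
    df = pd.read_csv(path)
    cells = frozenset(zip(df["row"].astype(int), df["col"].astype(int)))
    return PresenceSet(cells=cells, taxon=taxon)


# ---------------------------------------------------------------------------
# Gridding and sampling
# ---------------------------------------------------------------------------

def grid_occurrences(
    points: OccurrencePoints,
    grid: EnvGrid,
    clade_filter: object | None = None,
    taxon: str | None = None,
) -> PresenceSet:
    """Convert occurrence points to a set of occupied grid cells.

    A cell is a presence whether one or several points fall inside it.
    Points that fall outside the grid or in masked cells are dropped (a
    count is logged). ``clade_filter`` keeps only rows whose ``clade``
    column equals the given value.
    """
    df = points.records
    if clade_filter is not None:
        if "clade" not in df.columns:
            raise ValueError("clade_filter given but no 'clade' column present")
        df = df[df["clade"] == clade_filter]
    if taxon is None:
        taxon = "species" if clade_filter is None else f"clade{clade_filter}"
    if df.empty:
        return PresenceSet(cells=frozenset(), taxon=taxon)

    lon0, lat0 = grid.origin
    cs = grid.cell_size_deg
    cols = np.floor((df["lon"].to_numpy() - lon0) / cs).astype(int)
    rows = np.floor((lat0 - df["lat"].to_numpy()) / cs).astype(int)

    inside = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    n_outside = int((~inside).sum())
    rows, cols = rows[inside], cols[inside]
    on_land = grid.mask[rows, cols]
    n_masked = int((~on_land).sum())
    if n_outside or n_masked:
        logger.info(
            "grid_occurrences: dropped %d points outside the grid and %d in masked cells",
            n_outside, n_masked,
        )
    cells = frozenset(zip(rows[on_land].tolist(), cols[on_land].tolist()))
    return PresenceSet(cells=cells, taxon=taxon)


def cell_width_at_equator(cell_size_arcmin: float) -> float:
    """Arc length (km) a cell spans at the equator.

    Uses a 40,075 km equatorial circumference: a 10-arcmin cell spans
    ~18.6 km.
    """
    if cell_size_arcmin <= 0:
        raise ValueError("cell_size_arcmin must be positive")
    return EARTH_CIRCUMFERENCE_KM * cell_size_arcmin / (360.0 * 60.0)


def sample_background(
    grid: EnvGrid, n: int, seed: int | np.random.Generator
) -> frozenset[CellId]:
    """Sample ``n`` distinct valid cells uniformly without replacement.

    Background cells represent the available environment rather than true
    absences, so presence cells are deliberately *not* excluded.
    """
    valid = grid.valid_cells()
    if n > len(valid):
        raise ValueError(f"requested {n} background cells but only {len(valid)} valid")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.choice(len(valid), size=n, replace=False)
    return frozenset(valid[i] for i in idx)
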