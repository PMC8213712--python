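"""Raster data model and spatial primitives for the LULC simulation pipeline.

All spatial layers travel through :class:`Grid`, a plain in-memory raster
with ESRI-ASCII-style geometry metadata (row 0 is the northernmost row,
indices are 0-based, cells are square area elements of side ``cellsize``
metres). Categorical land-use/land-cover maps wrap a Grid through
:class:`LULCMap` over the fixed six-class codebook, and the seven driving
factors travel together in a :class:`DriverStack`.

I/O is restricted to the plain-text ESRI ASCII grid format (.asc): a
six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by rows written north to south.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "CLASS_CODES",
    "CLASS_NAMES",
    "DRIVER_NAMES",
    "Grid",
    "LULCMap",
    "DriverStack",
    "GridParseError",
    "read_ascii_grid",
    "write_ascii_grid",
    "resample_categorical",
    "resample_continuous",
    "euclidean_distance",
    "slope_from_dem",
    "cross_tabulate",
    "majority_filter",
]

#: Fixed six-class codebook for the mining-area landscape.
CLASS_NAMES: dict[int, str] = {
    1: "farmland",
    2: "other agricultural land",
    3: "urban and rural construction land",
    4: "subsided seeper area",
    5: "water area",
    6: "tidal wetland",
}
CLASS_CODES: tuple[int, ...] = tuple(CLASS_NAMES)
N_CLASSES = len(CLASS_CODES)

#: Canonical driver order: five accessibility distances plus two terrain layers.
DRIVER_NAMES: tuple[str, ...] = (
    "dist_residential",
    "dist_mines",
    "dist_roads",
    "dist_rivers",
    "dist_ditches",
    "elevation",
    "slope",
)

DEFAULT_NODATA = -9999.0


class GridParseError(ValueError):
    """Raised when an ASCII grid file cannot be parsed; carries the line number."""


@dataclass
class Grid:
    """A single-band raster; ``values[0, :]`` is the northernmost row.

    Parameters
    ----------
    values
        2-D array, shape ``(nrows, ncols)``. Integer arrays mark
        categorical layers and are written to disk without decimal points.
    cellsize
        Side of the square cell, in metres.
    xllcorner, yllcorner
        Coordinates of the lower-left corner of the lower-left cell (m).
    nodata_value
        Sentinel marking cells outside the study area.
    """

    values: np.ndarray
    cellsize: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cellsize > 0:
            raise ValueError(f"cellsize must be positive, got {self.cellsize}")
        if np.issubdtype(self.values.dtype, np.floating):
            bad = ~np.isfinite(self.values) & ~self._nodata_mask(self.values)
            if bad.any():
                raise ValueError("grid contains non-finite values that are not nodata")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (cellsize² / 10,000)."""
        return self.cellsize * self.cellsize / 10_000.0

    def _nodata_mask(self, arr: np.ndarray) -> np.ndarray:
        if np.issubdtype(arr.dtype, np.floating):
            return np.isclose(arr, self.nodata_value) | np.isnan(arr)
        return arr == int(self.nodata_value)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells inside the study area."""
        return ~self._nodata_mask(self.values)

    def same_geometry(self, other: "Grid", *, tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cellsize, other.cellsize, rel_tol=0, abs_tol=tol)
            and math.isclose(self.xllcorner, other.xllcorner, rel_tol=0, abs_tol=tol)
            and math.isclose(self.yllcorner, other.yllcorner, rel_tol=0, abs_tol=tol)
        )

    def copy(self, values: np.ndarray | None = None) -> "Grid":
        return replace(self, values=self.values.copy() if values is None else values)


@dataclass
class LULCMap:
    """Integer-coded categorical grid over the six-class codebook."""

    grid: Grid
    codebook: Mapping[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self) -> None:
        vals = np.asarray(self.grid.values)
        if not np.issubdtype(vals.dtype, np.integer):
            if np.issubdtype(vals.dtype, np.floating) and np.all(
                np.isclose(vals[self.grid.valid_mask] % 1, 0)
            ):
                self.grid = self.grid.copy(values=vals.astype(np.int32))
            else:
                raise ValueError("LULC map requires integer class codes")
        valid = self.grid.values[self.grid.valid_mask]
        if valid.size and not np.isin(valid, list(self.codebook)).all():
            bad = sorted(set(valid.tolist()) - set(self.codebook))
            raise ValueError(f"LULC map contains codes outside the codebook: {bad}")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def class_counts(self) -> dict[int, int]:
        valid = self.grid.values[self.grid.valid_mask]
        return {c: int(np.count_nonzero(valid == c)) for c in self.codebook}

    def class_areas_ha(self) -> dict[int, float]:
        """Per-class area in hectares; sums exactly to the valid-cell area."""
        a = self.grid.cell_area_ha
        return {c: n * a for c, n in self.class_counts().items()}

    def copy(self) -> "LULCMap":
        return LULCMap(self.grid.copy(), dict(self.codebook))


class DriverStack:
    """The seven driving-factor rasters on one common geometry.

    Behaves like an ordered mapping name -> Grid. The five ``dist_*``
    layers are nearest-feature distances in metres (nonnegative),
    ``elevation`` is in metres and ``slope`` in degrees.
    """

    def __init__(self, layers: Mapping[str, Grid], *, raw: bool = True):
        missing = [n for n in DRIVER_NAMES if n not in layers]
        extra = [n for n in layers if n not in DRIVER_NAMES]
        if missing or extra:
            raise ValueError(f"driver stack mismatch: missing={missing} extra={extra}")
        ref = layers[DRIVER_NAMES[0]]
        for name in DRIVER_NAMES:
            g = layers[name]
            if not g.same_geometry(ref):
                raise ValueError(f"driver {name!r} geometry differs from the stack")
            # distance layers are nonnegative on the measurement scale only
            # (standardization recentres them below zero)
            if raw and name.startswith("dist_"):
                vals = g.values[g.valid_mask]
                if vals.size and vals.min() < 0:
                    raise ValueError(f"distance layer {name!r} has negative values")
        self._layers = {n: layers[n] for n in DRIVER_NAMES}

    def __getitem__(self, name: str) -> Grid:
        return self._layers[name]

    def __iter__(self):
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def items(self):
        return self._layers.items()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._layers)

    @property
    def geometry(self) -> Grid:
        return self._layers[DRIVER_NAMES[0]]

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer of the stack."""
        m = np.ones(self.geometry.shape, dtype=bool)
        for g in self._layers.values():
            m &= g.valid_mask
        return m

    def as_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Stack layers to an (n_cells, 7) design matrix over ``mask`` cells."""
        if mask is None:
            mask = self.valid_mask
        return np.column_stack(
            [np.asarray(self._layers[n].values, dtype=float)[mask] for n in DRIVER_NAMES]
        )

    def map_layers(self, fn, *, raw: bool = False) -> "DriverStack":
        return DriverStack({n: fn(n, g) for n, g in self._layers.items()}, raw=raw)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _format_value(v: float, is_int: bool) -> str:
    if is_int:
        return str(int(v))
    return f"{v:.6g}"


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid file into a :class:`Grid`.

    Integer-valued bodies are returned with an integer dtype so that
    categorical maps round-trip without decoration.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()

    header: dict[str, float] = {}
    idx = 0
    for idx, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError:
                raise GridParseError(
                    f"{path}: line {idx + 1}: non-numeric header value {parts[1]!r}"
                ) from None
        else:
            break
    else:
        idx += 1

    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise GridParseError(f"{path}: missing header key {req!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)

    rows: list[list[float]] = []
    all_int = True
    for lineno in range(idx, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        toks = line.split()
        row: list[float] = []
        for t in toks:
            try:
                row.append(float(t))
            except ValueError:
                raise GridParseError(
                    f"{path}: line {lineno + 1}: non-numeric token {t!r}"
                ) from None
            if all_int and ("." in t or "e" in t.lower()):
                all_int = False
        if len(row) != ncols:
            raise GridParseError(
                f"{path}: line {lineno + 1}: expected {ncols} values, got {len(row)}"
            )
        rows.append(row)
    if len(rows) != nrows:
        raise GridParseError(f"{path}: expected {nrows} data rows, got {len(rows)}")

    dtype = np.int32 if all_int else float
    values = np.array(rows, dtype=dtype)
    return Grid(
        values,
        cellsize=header["cellsize"],
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        nodata_value=nodata if not all_int else float(int(nodata)),
    )


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write ``grid`` as an ESRI ASCII file (canonical header key order).

    Integer grids are written without decimal points; floats with at most
    six significant digits.
    """
    is_int = np.issubdtype(grid.values.dtype, np.integer)
    lines = [
        f"ncols {grid.ncols}",
        f"nrows {grid.nrows}",
        f"xllcorner {_format_value(grid.xllcorner, float(grid.xllcorner).is_integer())}",
        f"yllcorner {_format_value(grid.yllcorner, float(grid.yllcorner).is_integer())}",
        f"cellsize {_format_value(grid.cellsize, float(grid.cellsize).is_integer())}",
        f"NODATA_value {_format_value(grid.nodata_value, float(grid.nodata_value).is_integer())}",
    ]
    nodata_tok = _format_value(grid.nodata_value, float(grid.nodata_value).is_integer())
    mask = grid.valid_mask
    for i in range(grid.nrows):
        toks = [
            _format_value(grid.values[i, j], is_int) if mask[i, j] else nodata_tok
            for j in range(grid.ncols)
        ]
        lines.append(" ".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _pad_to_blocks(arr: np.ndarray, factor: int, fill) -> np.ndarray:
    nr, nc = arr.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)), constant_values=fill)
    return arr


def resample_categorical(lulc: LULCMap, factor: int) -> LULCMap:
    """Majority-vote block aggregation of a categorical map.

    Each ``factor``×``factor`` block of source cells (trailing partial
    blocks allowed) collapses to the majority class among its valid cells;
    ties go to the smallest class code; blocks that are entirely nodata
    stay nodata. Output cellsize is the input cellsize times ``factor``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"resampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    g = lulc.grid
    nodata = int(g.nodata_value)
    arr = _pad_to_blocks(np.asarray(g.values, dtype=np.int32), factor, nodata)
    nr, nc = arr.shape
    blocks = arr.reshape(nr // factor, factor, nc // factor, factor)
    counts = np.stack(
        [(blocks == c).sum(axis=(1, 3)) for c in CLASS_CODES], axis=0
    )  # (6, R, C)
    any_valid = counts.sum(axis=0) > 0
    # argmax returns the first (smallest-code) maximum: the tie rule.
    winner = np.asarray(CLASS_CODES, dtype=np.int32)[np.argmax(counts, axis=0)]
    out = np.where(any_valid, winner, np.int32(nodata))
    # trailing partial blocks extend the footprint southward (row 0 = north)
    grid = Grid(
        out,
        cellsize=g.cellsize * factor,
        xllcorner=g.xllcorner,
        yllcorner=g.yllcorner - (arr.shape[0] - g.nrows) * g.cellsize,
        nodata_value=nodata,
    )
    return LULCMap(grid, dict(lulc.codebook))


def resample_continuous(grid: Grid, factor: int) -> Grid:
    """Block-mean aggregation of a continuous layer (valid cells only)."""
    if int(factor) != factor or factor < 1:
        raise ValueError(f"resampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    vals = np.asarray(grid.values, dtype=float).copy()
    vals[~grid.valid_mask] = np.nan
    arr = _pad_to_blocks(vals, factor, np.nan)
    nr, nc = arr.shape
    blocks = arr.reshape(nr // factor, factor, nc // factor, factor)
    valid = np.isfinite(blocks)
    n = valid.sum(axis=(1, 3))
    s = np.nansum(blocks, axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), grid.nodata_value)
    return Grid(
        mean,
        cellsize=grid.cellsize * factor,
        xllcorner=grid.xllcorner,
        yllcorner=grid.yllcorner - (arr.shape[0] - grid.nrows) * grid.cellsize,
        nodata_value=grid.nodata_value,
    )


# ---------------------------------------------------------------------------
# Driver derivation
# ---------------------------------------------------------------------------

def euclidean_distance(features: Grid, cellsize: float | None = None) -> Grid:
    """Centre-to-centre Euclidean distance (m) to the nearest feature cell.

    ``features`` is a binary mask grid (nonzero = feature). Feature cells
    map to distance 0. Raises if the mask holds no feature cell, where the
    distance would be undefined.
    """
    cs = features.cellsize if cellsize is None else cellsize
    mask = (np.asarray(features.values) != 0) & features.valid_mask
    if not mask.any():
        raise ValueError("feature mask is empty: distance is undefined")
    dist = ndimage.distance_transform_edt(~mask, sampling=cs)
    return Grid(
        np.asarray(dist, dtype=float),
        cellsize=features.cellsize,
        xllcorner=features.xllcorner,
        yllcorner=features.yllcorner,
        nodata_value=features.nodata_value,
    )


def slope_from_dem(dem: Grid) -> Grid:
    """Slope in degrees from a DEM via Horn's 3×3 weighted finite differences.

    Border cells use one-sided differences, implemented by linear
    extrapolation of the DEM one cell outward (exact for planar surfaces).
    Cells that are nodata in the DEM stay nodata in the output.
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("slope requires a DEM of at least 3×3 cells")
    z = np.asarray(dem.values, dtype=float).copy()
    invalid = ~dem.valid_mask
    if invalid.any():
        # fill nodata with nearest valid value so neighbours stay usable
        idx = ndimage.distance_transform_edt(invalid, return_distances=False, return_indices=True)
        z = z[tuple(idx)]
    zp = np.pad(z, 1, mode="edge")
    # linear extrapolation => one-sided differences at the border
    zp[0, :] = 2 * zp[1, :] - zp[2, :]
    zp[-1, :] = 2 * zp[-2, :] - zp[-3, :]
    zp[:, 0] = 2 * zp[:, 1] - zp[:, 2]
    zp[:, -1] = 2 * zp[:, -2] - zp[:, -3]

    cs = dem.cellsize
    a, b, c = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    d, f = zp[1:-1, :-2], zp[1:-1, 2:]
    g, h, i = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope[invalid] = dem.nodata_value
    return Grid(
        slope,
        cellsize=cs,
        xllcorner=dem.xllcorner,
        yllcorner=dem.yllcorner,
        nodata_value=dem.nodata_value,
    )


# ---------------------------------------------------------------------------
# Map overlay
# ---------------------------------------------------------------------------

def cross_tabulate(a: LULCMap, b: LULCMap) -> np.ndarray:
    """6×6 overlay count matrix: entry (u−1, v−1) counts cells coded u in
    ``a`` and v in ``b``. Cells nodata in either map are skipped."""
    if not a.grid.same_geometry(b.grid):
        raise ValueError("cross-tabulation requires identical geometry")
    joint = a.grid.valid_mask & b.grid.valid_mask
    av = np.asarray(a.values)[joint].astype(np.int64) - 1
    bv = np.asarray(b.values)[joint].astype(np.int64) - 1
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (av, bv), 1)
    return counts


def majority_filter(lulc: LULCMap, passes: int = 1) -> LULCMap:
    """3×3 modal filter (centre included); ties to the smallest code.

    Used to give synthetic maps the patchy texture of interpreted imagery.
    Nodata cells are preserved and excluded from every vote.
    """
    out = np.asarray(lulc.values, dtype=np.int32).copy()
    valid = lulc.grid.valid_mask
    kernel = np.ones((3, 3))
    for _ in range(passes):
        counts = np.stack(
            [
                ndimage.convolve(
                    ((out == c) & valid).astype(np.int32), kernel, mode="constant", cval=0
                )
                for c in CLASS_CODES
            ],
            axis=0,
        )
        winner = np.asarray(CLASS_CODES, dtype=np.int32)[np.argmax(counts, axis=0)]
        out = np.where(valid, winner, out)
    return LULCMap(lulc.grid.copy(values=out), dict(lulc.codebook))
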