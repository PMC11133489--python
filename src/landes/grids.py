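"""Raster data model shared by every stage of the pipeline.

A :class:`Grid` is a single-band raster: a 2-D array of values, a boolean
nodata mask, a square cell size in metres and the map coordinates of the
upper-left corner.  All grids taking part in one analysis must be aligned
(same shape, cell size and origin); arithmetic across misaligned grids is a
user error and raises, never silently resamples.

Supported on-disk formats are single-band GeoTIFF (via :mod:`tifffile`,
writing the standard ModelPixelScale / ModelTiepoint / GDAL_NODATA tags) and
the ESRI ASCII grid.  Reprojection between coordinate reference systems is
out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "Grid",
    "LandUseMap",
    "ClassMapping",
    "CLASS_NAMES",
    "CLASS_CODES",
    "AlignmentError",
    "RasterFormatError",
    "assert_aligned",
    "read_raster",
    "write_raster",
    "reclassify",
    "distance_surface",
    "class_census",
    "resample",
    "refine",
    "load_default_mapping",
]

#: The six land-use classes, in code order 0..5.
CLASS_NAMES = ("cropland", "forest", "grassland", "water", "urban", "barren")
CLASS_CODES = {name: code for code, name in enumerate(CLASS_NAMES)}
N_CLASSES = len(CLASS_NAMES)

# GeoTIFF tag ids
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_DEFAULT_NODATA = -9999.0


class AlignmentError(ValueError):
    """Two grids do not share shape, cell size and origin."""


class RasterFormatError(ValueError):
    """A file could not be parsed as a supported raster format."""


@dataclass
class Grid:
    """Single-band raster with nodata mask and square-cell georeferencing.

    Parameters
    ----------
    values
        2-D array of cell values.  Stored as float64 (or the given dtype).
    nodata_mask
        Boolean array, True where the cell carries no data.  Defaults to
        all-valid.
    cell_size
        Edge length of a cell in metres (> 0).
    origin
        (x, y) map coordinates of the upper-left corner of the upper-left
        cell.  Row 0 / col 0 is the upper-left cell.
    """

    values: np.ndarray
    nodata_mask: np.ndarray | None = None
    cell_size: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    @property
    def valid_values(self) -> np.ndarray:
        """1-D array of the values at valid cells."""
        return self.values[~self.nodata_mask]

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 1e4

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy(),
                       nodata_mask=self.nodata_mask.copy())

    def like(self, values: np.ndarray) -> "Grid":
        """A new grid with the same georeferencing and mask, new values."""
        return Grid(np.asarray(values), self.nodata_mask.copy(),
                    self.cell_size, self.origin)

    def mean(self) -> float:
        return float(self.valid_values.mean())


@dataclass
class LandUseMap(Grid):
    """Categorical :class:`Grid` over the six land-use classes (codes 0–5)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values[~self.nodata_mask]
        as_int = vals.astype(np.int64)
        if vals.size and (np.any(vals != as_int) or as_int.min() < 0
                          or as_int.max() >= N_CLASSES):
            bad = np.unique(vals[(vals != as_int) | (vals < 0)
                                 | (vals >= N_CLASSES)])
            raise ValueError(f"invalid land-use codes present: {bad.tolist()}")
        self.values = self.values.astype(np.int16)

    def census(self) -> dict[str, int]:
        return class_census(self)

    def class_mask(self, code: int) -> np.ndarray:
        return (~self.nodata_mask) & (self.values == code)


@dataclass
class ClassMapping:
    """Total mapping from a source code scheme to the six target classes."""

    mapping: dict[int, int]
    source_scheme: str = "custom"

    def __post_init__(self) -> None:
        self.mapping = {int(k): int(v) for k, v in self.mapping.items()}
        bad = {v for v in self.mapping.values() if not 0 <= v < N_CLASSES}
        if bad:
            raise ValueError(f"targets outside the 6-class scheme: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.mapping)

    @classmethod
    def from_csv(cls, path: str | Path, source_scheme: str = "csv") -> "ClassMapping":
        """Load a two-column ``source_code,target_class`` CSV.

        ``target_class`` may be a class name or an integer code 0–5.
        """
        df = pd.read_csv(path)
        cols = list(df.columns[:2])
        out = {}
        for _, row in df.iterrows():
            tgt = row[cols[1]]
            if isinstance(tgt, str):
                tgt = CLASS_CODES[tgt.strip().lower()]
            out[int(row[cols[0]])] = int(tgt)
        return cls(out, source_scheme)


def load_default_mapping(scheme: str) -> ClassMapping:
    """Shipped reclassification defaults: ``esa_cci`` (22 land-cover types)
    or ``luh2`` (12 land-use states) onto the six-class scheme.

    The CSVs under ``landes/data`` are editable; replace them to match a
    locally preferred legend.
    """
    names = {"esa_cci": "esa_cci_to_6class.csv", "luh2": "luh2_to_6class.csv"}
    if scheme not in names:
        raise KeyError(f"unknown mapping scheme {scheme!r}; "
                       f"choose from {sorted(names)}")
    path = Path(__file__).parent / "data" / names[scheme]
    return ClassMapping.from_csv(path, source_scheme=scheme)


def assert_aligned(*grids: Grid) -> None:
    """Raise :class:`AlignmentError` unless all grids share shape, cell size
    and origin."""
    if not grids:
        return
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or g.cell_size != ref.cell_size \
                or g.origin != ref.origin:
            raise AlignmentError(
                f"misaligned grids: {g.shape}/{g.cell_size}/{g.origin} vs "
                f"{ref.shape}/{ref.cell_size}/{ref.origin}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    if "ncols" not in header or "nrows" not in header:
        raise RasterFormatError(f"{path}: not an ESRI ASCII grid")
    values = np.loadtxt(lines[n_header:], ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise RasterFormatError(
            f"{path}: data block {values.shape} != header ({nrows}, {ncols})")
    cell = header.get("cellsize", 1.0)
    if "nodata_value" in header:
        mask = values == header["nodata_value"]
    else:
        warnings.warn(f"{path}: no NODATA_value declared; all cells valid")
        mask = np.zeros_like(values, dtype=bool)
    origin = (header.get("xllcorner", 0.0),
              header.get("yllcorner", 0.0) + nrows * cell)
    return Grid(values, mask, cell, origin)


def _read_geotiff(path: Path, band: int) -> Grid:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[band]
        values = page.asarray()
        if values.ndim == 3:
            values = values[..., 0]
        tags = page.tags
        scale = tags.get(_TAG_PIXEL_SCALE)
        cell = float(scale.value[0]) if scale is not None else 1.0
        tie = tags.get(_TAG_TIEPOINT)
        origin = (float(tie.value[3]), float(tie.value[4])) if tie is not None \
            else (0.0, 0.0)
        nd = tags.get(_TAG_GDAL_NODATA)
    if nd is not None:
        nodata = float(str(nd.value))
        mask = values == nodata
    else:
        warnings.warn(f"{path}: no nodata tag; all cells treated valid")
        mask = np.zeros_like(values, dtype=bool)
    return Grid(values.astype(np.float64), mask, cell, origin)


def read_raster(path: str | Path, band: int = 0) -> Grid:
    """Read a single-band GeoTIFF or ESRI ASCII grid as a :class:`Grid`.

    Nodata cells are masked; a file with no nodata declaration is read with a
    warning and all cells valid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return _read_geotiff(path, band)
    if suffix in (".asc", ".txt", ".grd"):
        return _read_ascii(path)
    # sniff: TIFF magic
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] in (b"II", b"MM"):
        return _read_geotiff(path, band)
    try:
        return _read_ascii(path)
    except Exception as exc:  # pragma: no cover - defensive
        raise RasterFormatError(f"cannot read {path}: {exc}") from exc


def write_raster(grid: Grid, path: str | Path, format: str | None = None,
                 nodata: float = _DEFAULT_NODATA) -> None:
    """Write ``grid`` to ``path`` as ``geotiff`` or ``ascii``.

    The format defaults from the file suffix.  Nodata cells are written as
    ``nodata`` and round-trip through :func:`read_raster`.
    """
    path = Path(path)
    if format is None:
        format = "ascii" if path.suffix.lower() in (".asc", ".txt", ".grd") \
            else "geotiff"
    values = np.where(grid.nodata_mask, nodata, grid.values)
    if format == "ascii":
        nrows, ncols = grid.shape
        x0, y0 = grid.origin
        header = (f"ncols {ncols}\nnrows {nrows}\n"
                  f"xllcorner {x0!r}\nyllcorner {y0 - nrows * grid.cell_size!r}\n"
                  f"cellsize {grid.cell_size!r}\nNODATA_value {nodata!r}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, values, fmt="%.17g")
    elif format == "geotiff":
        tifffile.imwrite(
            path, values.astype(np.float64),
            extratags=[
                (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
                (_TAG_TIEPOINT, "d", 6,
                 (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
                (_TAG_GDAL_NODATA, "s", 0, repr(nodata)),
            ])
    else:
        raise ValueError(f"unknown raster format {format!r}")


# ---------------------------------------------------------------------------
# raster algebra
# ---------------------------------------------------------------------------

def reclassify(source: Grid, mapping: ClassMapping) -> LandUseMap:
    """Map a categorical grid of source codes onto the six-class scheme.

    Every valid source code must appear in the mapping; the output census is
    the push-forward of the input census, so the valid-cell count is
    conserved.
    """
    valid = ~source.nodata_mask
    codes = np.unique(source.values[valid].astype(np.int64))
    missing = [int(c) for c in codes if int(c) not in mapping.mapping]
    if missing:
        raise KeyError(f"source code(s) {missing} absent from mapping "
                       f"({mapping.source_scheme})")
    lut = np.zeros(int(codes.max()) + 1 if codes.size else 1, dtype=np.int16)
    for src, tgt in mapping.mapping.items():
        if 0 <= src < lut.size:
            lut[src] = tgt
    out = np.zeros(source.shape, dtype=np.int16)
    out[valid] = lut[source.values[valid].astype(np.int64)]
    return LandUseMap(out, source.nodata_mask.copy(), source.cell_size,
                      source.origin)


def distance_surface(mask: Grid, cell_size: float | None = None) -> Grid:
    """Euclidean distance (m) from every cell to the nearest source cell.

    ``mask`` holds 1 on source cells and 0 elsewhere; sources get distance 0.
    """
    cell = cell_size if cell_size is not None else mask.cell_size
    src = (mask.values == 1) & ~mask.nodata_mask
    if not src.any():
        raise ValueError("distance_surface: no source cells")
    dist = ndimage.distance_transform_edt(~src, sampling=cell)
    return Grid(dist, mask.nodata_mask.copy(), cell, mask.origin)


def class_census(lu: LandUseMap) -> dict[str, int]:
    """Cell count per land-use class; counts sum to the valid-cell count."""
    valid = lu.values[~lu.nodata_mask]
    counts = np.bincount(valid.astype(np.int64), minlength=N_CLASSES)
    return {name: int(counts[code]) for code, name in enumerate(CLASS_NAMES)}


def resample(grid: Grid, factor: int, categorical: bool = False,
             rule: str = "nearest") -> Grid:
    """Coarsen a grid by an integer block ``factor``.

    Continuous grids are block-averaged (bilinear-equivalent at integer
    factors); categorical grids use ``nearest`` (block upper-left cell) or
    ``majority`` vote.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nr, nc = grid.shape
    nr2, nc2 = nr // factor, nc // factor
    v = grid.values[:nr2 * factor, :nc2 * factor]
    m = grid.nodata_mask[:nr2 * factor, :nc2 * factor]
    blocks = v.reshape(nr2, factor, nc2, factor)
    mask_blocks = m.reshape(nr2, factor, nc2, factor)
    new_mask = mask_blocks.all(axis=(1, 3))
    if categorical:
        if rule == "nearest":
            out = blocks[:, 0, :, 0]
        elif rule == "majority":
            flat = blocks.transpose(0, 2, 1, 3).reshape(nr2, nc2,
                                                        factor * factor)
            out = np.zeros((nr2, nc2), dtype=np.int64)
            for i in range(nr2):
                for j in range(nc2):
                    out[i, j] = np.bincount(
                        flat[i, j].astype(np.int64)).argmax()
        else:
            raise ValueError("rule must be 'nearest' or 'majority'")
        out = out.astype(grid.values.dtype)
    else:
        masked = np.ma.MaskedArray(blocks, mask=mask_blocks)
        out = masked.mean(axis=(1, 3)).filled(0.0)
    cls = LandUseMap if categorical else Grid
    return cls(out, new_mask, grid.cell_size * factor, grid.origin)


def refine(grid: Grid, factor: int, categorical: bool = False) -> Grid:
    """Refine a grid onto a ``factor``-times finer mesh.

    Continuous grids are bilinearly interpolated; categorical grids use
    nearest-neighbour (block replication).  The stand-in for statistical
    downscaling of coarse climate anomalies onto a fine analysis grid.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if categorical:
        out = np.repeat(np.repeat(grid.values, factor, axis=0), factor,
                        axis=1)
    else:
        out = ndimage.zoom(grid.values.astype(float), factor, order=1,
                           mode="nearest", grid_mode=True)
    mask = np.repeat(np.repeat(grid.nodata_mask, factor, axis=0), factor,
                     axis=1)
    cls = LandUseMap if categorical else Grid
    return cls(out, mask, grid.cell_size / factor, grid.origin)
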