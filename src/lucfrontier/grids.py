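"""Core grid containers and land-cover I/O.

All spatial layers in the package share a :class:`GridGeometry`: a regular,
row-major grid anchored at its upper-left corner in a projected planar
coordinate system (metres).  Cell ``(r, c)`` has its centre at
``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``.

Categorical land-cover maps and continuous covariate surfaces are read and
written as single-band plain-text ESRI ASCII grids (``nrows``/``ncols``/
``xllcorner``/``yllcorner``/``cellsize``/``NODATA_value`` header), which
round-trip losslessly for integer-coded categorical data and for floats at
``repr`` precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_CLASS_LABELS",
    "GridGeometry",
    "LandCoverMap",
    "ContinuousSurface",
    "TransitionMatrix",
    "read_landcover",
    "write_landcover",
    "read_surface",
    "write_surface",
    "transition_matrix",
    "GridAlignmentError",
    "ClassCodeError",
]

#: Canonical class roster for a deforestation-frontier scene.
DEFAULT_CLASS_LABELS: dict[int, str] = {
    1: "forest",
    2: "agriculture",
    3: "bare_soil",
    4: "built",
    5: "water",
    6: "wetland",
}

DEFAULT_NODATA = -9999


class GridAlignmentError(ValueError):
    """Two layers that must share a geometry do not."""


class ClassCodeError(ValueError):
    """A categorical grid contains codes outside its declared class map."""


@dataclass(frozen=True)
class GridGeometry:
    """Shape, resolution and placement of a raster grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions.
    cell_size
        Cell edge length in metres (default 30 m, the Landsat-derived
        resolution this package is designed around).
    origin_x, origin_y
        Projected coordinates of the grid's **upper-left** corner.
    nodata_code
        Integer sentinel for missing cells.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata_code: int = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (0.09 ha at 30 m)."""
        return self.cell_size**2 / 10_000.0

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    @property
    def extent_km2(self) -> float:
        return self.n_rows * self.n_cols * self.cell_area_km2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def same_grid(self, other: "GridGeometry") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
        )


def _require_aligned(a: GridGeometry, b: GridGeometry, what: str = "layers") -> None:
    if not a.same_grid(b):
        raise GridAlignmentError(f"{what} are not pixel-aligned: {a} vs {b}")


@dataclass
class LandCoverMap:
    """Categorical land-cover grid at one epoch."""

    geometry: GridGeometry
    cells: np.ndarray
    class_labels: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_LABELS)
    )

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int32)
        if self.cells.shape != self.geometry.shape:
            raise GridAlignmentError(
                f"cells shape {self.cells.shape} != geometry {self.geometry.shape}"
            )
        self.validate_codes()

    def validate_codes(self) -> None:
        present = np.unique(self.cells)
        allowed = set(self.class_labels) | {self.geometry.nodata_code}
        unknown = sorted(int(c) for c in present if int(c) not in allowed)
        if unknown:
            raise ClassCodeError(
                f"land-cover grid contains undeclared class codes {unknown}; "
                f"declared codes are {sorted(self.class_labels)}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return self.cells != self.geometry.nodata_code

    def class_mask(self, label: str) -> np.ndarray:
        """Boolean mask of cells carrying the class named *label*."""
        codes = [c for c, lab in self.class_labels.items() if lab == label]
        if not codes:
            return np.zeros(self.geometry.shape, dtype=bool)
        return np.isin(self.cells, codes)

    def code_of(self, label: str) -> int:
        for c, lab in self.class_labels.items():
            if lab == label:
                return c
        raise KeyError(f"no class named {label!r}")

    def copy(self) -> "LandCoverMap":
        return LandCoverMap(self.geometry, self.cells.copy(), dict(self.class_labels))

    def class_area_ha(self, label: str) -> float:
        return float(self.class_mask(label).sum()) * self.geometry.cell_area_ha


@dataclass
class ContinuousSurface:
    """A single named continuous raster layer (covariate or probability)."""

    geometry: GridGeometry
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise GridAlignmentError(
                f"values shape {self.values.shape} != geometry {self.geometry.shape}"
            )


# ---------------------------------------------------------------------------
# ASCII-grid I/O


def _parse_ascii(text: str) -> tuple[GridGeometry, np.ndarray, float]:
    lines = text.splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "nrows",
            "ncols",
            "xllcorner",
            "yllcorner",
            "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    required = {"nrows", "ncols", "xllcorner", "yllcorner", "cellsize"}
    missing = required - set(header)
    if missing:
        raise ValueError(
            f"ASCII grid header incomplete (missing {sorted(missing)}); "
            "georeferencing is required"
        )
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", float(DEFAULT_NODATA))
    data = np.loadtxt(io.StringIO("\n".join(lines[i:])), ndmin=2)
    if data.shape != (n_rows, n_cols):
        raise ValueError(
            f"grid body shape {data.shape} disagrees with header "
            f"({n_rows}, {n_cols})"
        )
    geom = GridGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        nodata_code=int(nodata),
    )
    return geom, data, nodata


def _format_ascii(geom: GridGeometry, data: np.ndarray, fmt: str) -> str:
    header = (
        f"ncols {geom.n_cols}\n"
        f"nrows {geom.n_rows}\n"
        f"xllcorner {geom.origin_x!r}\n"
        f"yllcorner {geom.origin_y - geom.n_rows * geom.cell_size!r}\n"
        f"cellsize {geom.cell_size!r}\n"
        f"NODATA_value {geom.nodata_code}\n"
    )
    if fmt == "%r":  # shortest lossless decimal for floats
        body = "\n".join(" ".join(repr(float(v)) for v in row) for row in data)
    else:
        body = "\n".join(" ".join(fmt % v for v in row) for row in data)
    return header + body + "\n"


def read_landcover(
    path: str | Path, class_map: dict[int, str] | None = None
) -> LandCoverMap:
    """Read a categorical ASCII grid into a validated :class:`LandCoverMap`.

    Every code present in the file must appear in *class_map* or equal the
    grid's nodata code; violations raise :class:`ClassCodeError` naming the
    offending codes.
    """
    geom, data, _ = _parse_ascii(Path(path).read_text())
    if class_map is None:
        class_map = dict(DEFAULT_CLASS_LABELS)
    cells = data.astype(np.int32)
    if not np.array_equal(cells, data):
        raise ClassCodeError(f"{path}: categorical grid contains non-integer values")
    return LandCoverMap(geom, cells, dict(class_map))


def write_landcover(lc_map: LandCoverMap, path: str | Path) -> None:
    """Write a land-cover map as an integer ASCII grid (lossless round trip)."""
    Path(path).write_text(_format_ascii(lc_map.geometry, lc_map.cells, "%d"))


def read_surface(path: str | Path, name: str = "", units: str = "") -> ContinuousSurface:
    geom, data, nodata = _parse_ascii(Path(path).read_text())
    values = np.where(data == nodata, np.nan, data)
    return ContinuousSurface(geom, values, name=name or Path(path).stem, units=units)


def write_surface(surface: ContinuousSurface, path: str | Path) -> None:
    geom = surface.geometry
    data = np.where(np.isnan(surface.values), float(geom.nodata_code), surface.values)
    Path(path).write_text(_format_ascii(geom, data, "%r"))


# ---------------------------------------------------------------------------
# Transition matrices


@dataclass
class TransitionMatrix:
    """Between-epoch class-transition counts and row-normalised probabilities.

    ``counts[i, j]`` is the number of cells in class ``classes[i]`` at the
    first epoch and ``classes[j]`` at the second; ``probabilities`` divides
    each row by its sum (rows with zero count are left as zeros).
    """

    classes: list[str]
    counts: np.ndarray
    probabilities: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.probabilities, index=self.classes, columns=self.classes)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def prob(self, from_label: str, to_label: str) -> float:
        return float(
            self.probabilities[self.classes.index(from_label), self.classes.index(to_label)]
        )


def transition_matrix(map_t0: LandCoverMap, map_t1: LandCoverMap) -> TransitionMatrix:
    """Cross-tabulate class transitions between two co-registered epochs.

    Cells that are nodata in *either* epoch are excluded.  Probabilities are
    the counts normalised within each origin-class row, so e.g. the
    forest-row/agriculture-column entry is the per-pixel probability that a
    forest cell converted to agriculture over the epoch.
    """
    _require_aligned(map_t0.geometry, map_t1.geometry, "epoch maps")
    if map_t0.class_labels != map_t1.class_labels:
        raise GridAlignmentError("epoch maps carry different class rosters")
    codes = sorted(map_t0.class_labels)
    labels = [map_t0.class_labels[c] for c in codes]
    k = len(codes)
    lut = {c: i for i, c in enumerate(codes)}
    valid = map_t0.valid_mask & map_t1.valid_mask
    a = np.vectorize(lut.__getitem__, otypes=[np.int64])(map_t0.cells[valid])
    b = np.vectorize(lut.__getitem__, otypes=[np.int64])(map_t1.cells[valid])
    counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k).astype(np.int64)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / row_sums, 0.0)
    return TransitionMatrix(classes=labels, counts=counts, probabilities=probs)
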