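"""Raster / occurrence / tree I-O and spatial pre-processing.

Environmental layers travel as :class:`EnvStack` — a set of co-registered
grids (ESRI ASCII dialect) sharing one geotransform and one nodata mask.
Occurrence records are per-species point sets in map units.  Pre-processing
covers the two steps a presence-only niche-modeling study applies before
fitting: spatial thinning of occurrences to the grid resolution, and a greedy
decorrelation filter that keeps a single representative of each block of
highly inter-correlated variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class EnvStack:
    """Aligned environmental grids with a shared mask.

    Attributes
    ----------
    variables : list of str
        Layer names, e.g. ``["bio4", "bio6", "cti"]``.
    grids : dict mapping variable -> 2-D float array
        Cell values; row 0 is the northernmost row.
    x0, y0 : float
        Lower-left corner of the grid (map units).
    cellsize : float
        Cell edge length (map units), > 0.
    mask : 2-D bool array
        True where the cell is valid on *every* layer.
    """

    variables: list[str]
    grids: dict[str, np.ndarray]
    x0: float
    y0: float
    cellsize: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        shape = self.mask.shape
        for v in self.variables:
            if self.grids[v].shape != shape:
                raise ValueError(f"grid {v!r} shape {self.grids[v].shape} != mask {shape}")
            if not np.all(np.isfinite(self.grids[v][self.mask])):
                raise ValueError(f"grid {v!r} has non-finite values on unmasked cells")

    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mask.shape[1]

    @property
    def n_cells(self) -> int:
        """Number of valid (unmasked) cells."""
        return int(self.mask.sum())

    def values(self, variable: str) -> np.ndarray:
        """Valid-cell values of one layer, flattened in row-major order."""
        return self.grids[variable][self.mask]

    def table(self) -> np.ndarray:
        """Valid cells × variables matrix, column order = ``self.variables``."""
        if not self.variables:
            return np.empty((self.n_cells, 0))
        return np.column_stack([self.values(v) for v in self.variables])

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y).

        Cells are half-open: ``[x0, x0+cs)`` horizontally and ``(ytop-cs, ytop]``
        vertically, with row 0 the northernmost row.
        """
        col = int(np.floor((x - self.x0) / self.cellsize))
        y_top = self.y0 + self.n_rows * self.cellsize
        row = int(np.ceil((y_top - y) / self.cellsize)) - 1
        if y == y_top:
            row = 0
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x0 + (col + 0.5) * self.cellsize
        y = self.y0 + (self.n_rows - row - 0.5) * self.cellsize
        return x, y

    def subset(self, variables: Sequence[str]) -> "EnvStack":
        missing = [v for v in variables if v not in self.grids]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        return EnvStack(
            variables=list(variables),
            grids={v: self.grids[v] for v in variables},
            x0=self.x0,
            y0=self.y0,
            cellsize=self.cellsize,
            mask=self.mask,
        )


@dataclass
class OccurrenceSet:
    """Presence coordinates for one species, in map units."""

    species: str
    points: np.ndarray  # (n, 2) array of x, y
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    def validate(self, stack: EnvStack) -> "OccurrenceSet":
        """Drop points off-grid or on masked cells."""
        keep = []
        for x, y in self.points:
            try:
                r, c = stack.cell_of(x, y)
            except ValueError:
                continue
            if stack.mask[r, c]:
                keep.append((x, y))
        return OccurrenceSet(self.species, np.array(keep).reshape(-1, 2), self.source)

    def cells(self, stack: EnvStack) -> list[tuple[int, int]]:
        return [stack.cell_of(x, y) for x, y in self.points]


# ---------------------------------------------------------------------------
# ESRI ASCII grid I-O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _read_asc(path: Path) -> tuple[dict, np.ndarray]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: empty or truncated file")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"{path}: missing header field {key.upper()}")
        data = np.loadtxt(fh, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = np.asarray(data, dtype=float).reshape(nrows, ncols)
    return header, data


def read_env_stack(paths: Iterable[str | Path], names: Sequence[str] | None = None) -> EnvStack:
    """Read co-registered ESRI ASCII grids into one stack.

    All files must agree on ``NCOLS/NROWS/XLLCORNER/YLLCORNER/CELLSIZE``.
    The stack mask is the union of per-file nodata cells, so every analysis
    sees a single common support.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no grid files given")
    if names is None:
        names = [p.stem for p in paths]
    grids: dict[str, np.ndarray] = {}
    ref_header: dict | None = None
    ref_path: Path | None = None
    mask: np.ndarray | None = None
    for name, path in zip(names, paths):
        header, data = _read_asc(path)
        geom = tuple(header[k] for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"))
        if ref_header is None:
            ref_header, ref_path = header, path
            ref_geom = geom
            mask = np.ones(data.shape, dtype=bool)
        elif geom != ref_geom:
            raise ValueError(
                f"grid geometry of {path} does not match {ref_path}: {geom} vs {ref_geom}"
            )
        nodata = header.get("nodata_value")
        valid = np.isfinite(data)
        if nodata is not None:
            valid &= data != nodata
        mask &= valid
        grids[name] = data
    for name in grids:
        grids[name] = np.where(mask, grids[name], np.nan)
    return EnvStack(
        variables=list(names),
        grids=grids,
        x0=ref_header["xllcorner"],
        y0=ref_header["yllcorner"],
        cellsize=ref_header["cellsize"],
        mask=mask,
    )


def write_env_stack(stack: EnvStack, directory: str | Path, nodata: float = -9999.0) -> list[Path]:
    """Write each layer as ``<variable>.asc``; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for v in stack.variables:
        path = directory / f"{v}.asc"
        grid = np.where(stack.mask, stack.grids[v], nodata)
        with open(path, "w") as fh:
            fh.write(f"NCOLS {stack.n_cols}\n")
            fh.write(f"NROWS {stack.n_rows}\n")
            fh.write(f"XLLCORNER {float(stack.x0)!r}\n")
            fh.write(f"YLLCORNER {float(stack.y0)!r}\n")
            fh.write(f"CELLSIZE {float(stack.cellsize)!r}\n")
            fh.write(f"NODATA_VALUE {float(nodata)!r}\n")
            for row in grid:
                # repr round-trips doubles exactly
                fh.write(" ".join(repr(float(val)) for val in row) + "\n")
        out.append(path)
    return out


def write_surface(
    surface: np.ndarray, stack: EnvStack, path: str | Path, nodata: float = -9999.0
) -> Path:
    """Write an arbitrary per-cell surface on the stack's grid as .asc."""
    tmp = EnvStack(["surface"], {"surface": np.where(stack.mask, surface, np.nan)},
                   stack.x0, stack.y0, stack.cellsize, stack.mask)
    path = Path(path)
    written = write_env_stack(tmp, path.parent, nodata=nodata)[0]
    written.rename(path)
    return path


# ---------------------------------------------------------------------------
# Occurrence I-O

def read_occurrences(path: str | Path) -> dict[str, OccurrenceSet]:
    """Read a ``species,x,y`` CSV into per-species occurrence sets."""
    df = pd.read_csv(path)
    required = {"species", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"occurrence CSV must have columns {sorted(required)}")
    out = {}
    for sp, sub in df.groupby("species", sort=False):
        out[str(sp)] = OccurrenceSet(str(sp), sub[["x", "y"]].to_numpy(float), source=str(path))
    return out


def write_occurrences(occs: Iterable[OccurrenceSet], path: str | Path) -> Path:
    rows = [
        {"species": o.species, "x": x, "y": y} for o in occs for x, y in o.points
    ]
    pd.DataFrame(rows, columns=["species", "x", "y"]).to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Pre-processing

def thin_occurrences(occ: OccurrenceSet, min_dist: float) -> OccurrenceSet:
    """Greedy spatial thinning: keep a point iff it is >= ``min_dist`` (Euclidean,
    map units) from every already-kept point, scanning in input order.

    Deterministic (first record wins) and idempotent.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be non-negative")
    if min_dist == 0 or len(occ) == 0:
        return OccurrenceSet(occ.species, occ.points.copy(), occ.source)
    kept: list[np.ndarray] = []
    for pt in occ.points:
        if all(np.hypot(*(pt - k)) >= min_dist for k in kept):
            kept.append(pt)
    return OccurrenceSet(occ.species, np.array(kept), occ.source)


def filter_variables(
    stack: EnvStack,
    r_threshold: float = 0.9,
    priority: Sequence[str] | None = None,
) -> tuple[EnvStack, pd.DataFrame]:
    """Greedy decorrelation over a priority order.

    Walking ``priority`` from most to least preferred, a variable is retained
    iff its absolute Pearson correlation (over unmasked cells) with every
    already-retained variable is <= ``r_threshold``.  The caller encodes
    domain preference (e.g. extremes over averages) in the priority order.

    Returns the filtered stack and a report with one row per dropped
    variable naming the retained partner that blocked it.  A zero-variance
    variable has undefined correlation; it is treated as uncorrelated, with
    a warning.
    """
    if priority is None:
        priority = list(stack.variables)
    if set(priority) != set(stack.variables):
        raise ValueError("priority must list exactly the stack's variables")
    data = {v: stack.values(v) for v in stack.variables}
    sd = {v: float(np.std(data[v])) for v in stack.variables}
    for v, s in sd.items():
        if s == 0.0:
            warnings.warn(f"variable {v!r} is constant; correlation undefined, treated as 0")

    def corr(a: str, b: str) -> float:
        if sd[a] == 0.0 or sd[b] == 0.0:
            return 0.0
        return float(np.corrcoef(data[a], data[b])[0, 1])

    retained: list[str] = []
    dropped: list[dict] = []
    for v in priority:
        blocker = next(
            (u for u in retained if abs(corr(v, u)) > r_threshold), None
        )
        if blocker is None:
            retained.append(v)
        else:
            dropped.append({"variable": v, "blocked_by": blocker, "r": corr(v, blocker)})
    report = pd.DataFrame(dropped, columns=["variable", "blocked_by", "r"])
    # retained follows the priority order, so the result does not depend on
    # how the input stack happened to order its layers
    return stack.subset(retained), report
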