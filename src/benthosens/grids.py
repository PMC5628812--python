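"""Grid data model shared by all spatial stages.

Environmental layers live on a common geographic grid (cell centres,
north-up, row 0 = northernmost row). An :class:`EnvGrid` couples a 2-D
value array with a boolean missing-data mask; masked cells are excluded
from every statistic computed downstream (min/max for rescaling,
percentiles, index formulas). Any operation combining grids masks a cell
if any operand is masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GridSpec",
    "EnvGrid",
    "GridStack",
    "DegenerateLayerError",
    "EmptyIntersectionError",
    "rescale01",
    "align",
    "temporal_percentile",
    "read_ascii_grid",
    "write_ascii_grid",
]


class DegenerateLayerError(ValueError):
    """Raised when a layer is constant over its unmasked cells and thus
    cannot be min-max rescaled."""


class EmptyIntersectionError(ValueError):
    """Raised when a source grid does not overlap the target grid."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lat-lon grid.

    ``origin_lon``/``origin_lat`` are the centre of the top-left
    (north-west) cell. Rows run north to south.
    """

    n_rows: int
    n_cols: int
    cell_size_deg: float = 0.03
    origin_lon: float = 0.0
    origin_lat: float = 51.0
    crs_tag: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lons(self) -> np.ndarray:
        """Cell-centre longitudes, west to east."""
        return self.origin_lon + self.cell_size_deg * np.arange(self.n_cols)

    def lats(self) -> np.ndarray:
        """Cell-centre latitudes, north to south (row order)."""
        return self.origin_lat - self.cell_size_deg * np.arange(self.n_rows)


@dataclass
class EnvGrid:
    """One georeferenced scalar field with a missing-data mask.

    ``mask`` is True where data are MISSING.
    """

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray | None = None
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"spec {self.spec.shape}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spec.shape:
                raise ValueError("mask shape does not match grid spec")
            self.mask = self.mask | ~np.isfinite(self.values)

    def unmasked(self) -> np.ndarray:
        """1-D array of valid cell values."""
        return self.values[~self.mask]

    def with_values(
        self, values: np.ndarray, *, name: str | None = None, units: str | None = None,
        extra_mask: np.ndarray | None = None,
    ) -> "EnvGrid":
        mask = self.mask.copy()
        if extra_mask is not None:
            mask |= extra_mask
        return EnvGrid(
            spec=self.spec,
            values=np.asarray(values, dtype=float),
            mask=mask,
            name=self.name if name is None else name,
            units=self.units if units is None else units,
        )


@dataclass
class GridStack:
    """An ordered collection of layers sharing one grid geometry."""

    spec: GridSpec
    layers: list[EnvGrid] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [g.name for g in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for g in self.layers:
            if g.spec != self.spec:
                raise ValueError(f"layer {g.name!r} is not on the stack grid")

    def __getitem__(self, name: str) -> EnvGrid:
        for g in self.layers:
            if g.name == name:
                return g
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(g.name == name for g in self.layers)

    def __iter__(self):
        return iter(self.layers)

    def names(self) -> list[str]:
        return [g.name for g in self.layers]

    def add(self, grid: EnvGrid) -> None:
        if grid.name in self:
            raise ValueError(f"duplicate layer name {grid.name!r}")
        if grid.spec != self.spec:
            raise ValueError("layer is not on the stack grid")
        self.layers.append(grid)


def combine_masks(*grids: EnvGrid) -> np.ndarray:
    """Union of the grids' missing-data masks (conservative propagation)."""
    mask = np.zeros(grids[0].spec.shape, dtype=bool)
    for g in grids:
        if g.spec.shape != mask.shape:
            raise ValueError("grids must share one spec")
        mask |= g.mask
    return mask


def rescale01(g: EnvGrid) -> EnvGrid:
    """Min-max rescale a layer to [0, 1] over its unmasked cells.

    (x - min) / (max - min), with min and max taken over the unmasked
    cells of the analysis extent only. Raises
    :class:`DegenerateLayerError` on a constant layer.
    """
    vals = g.unmasked()
    if vals.size < 2:
        raise DegenerateLayerError(
            f"layer {g.name!r} has fewer than 2 unmasked cells"
        )
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise DegenerateLayerError(
            f"layer {g.name!r} is constant ({lo}); cannot rescale"
        )
    out = (g.values - lo) / (hi - lo)
    out = np.where(g.mask, np.nan, out)
    return g.with_values(out, units="1")


def temporal_percentile(series: Sequence[EnvGrid], q: float) -> EnvGrid:
    """Per-cell empirical percentile over time steps.

    ``q`` is a fraction in [0, 1]. Linear interpolation between order
    statistics; cells are computed over the unmasked time steps only and
    masked where every step is masked.
    """
    if len(series) == 0:
        raise ValueError("empty time series")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    spec = series[0].spec
    for g in series:
        if g.spec != spec:
            raise ValueError("all grids must share one spec")
    cube = np.stack([np.where(g.mask, np.nan, g.values) for g in series])
    with np.errstate(all="ignore"):
        out = np.nanquantile(cube, q, axis=0)
    all_masked = np.all([g.mask for g in series], axis=0)
    out = np.where(all_masked, np.nan, out)
    g0 = series[0]
    return EnvGrid(spec=spec, values=out, mask=all_masked,
                   name=g0.name, units=g0.units)


def _align_one(g: EnvGrid, target: GridSpec, method: str) -> EnvGrid:
    if g.spec == target:
        return g
    src_lats = g.spec.lats()[::-1]  # ascending for the interpolator
    src_lons = g.spec.lons()
    tgt_lats = target.lats()
    tgt_lons = target.lons()
    # Half-cell tolerance: a target centre within the source's outer cell
    # boundary still counts as covered.
    tol = g.spec.cell_size_deg / 2
    if (tgt_lons.max() < src_lons.min() - tol
            or tgt_lons.min() > src_lons.max() + tol
            or tgt_lats.max() < src_lats.min() - tol
            or tgt_lats.min() > src_lats.max() + tol):
        raise EmptyIntersectionError(
            f"layer {g.name!r} does not overlap the target grid"
        )
    vals = np.where(g.mask, np.nan, g.values)[::-1, :]
    lat_grid, lon_grid = np.meshgrid(tgt_lats, tgt_lons, indexing="ij")
    pts = np.column_stack([lat_grid.ravel(), lon_grid.ravel()])
    kind = {"bilinear": "linear", "nearest": "nearest"}[method]
    interp = RegularGridInterpolator(
        (src_lats, src_lons), vals, method=kind,
        bounds_error=False, fill_value=np.nan,
    )
    out = interp(pts).reshape(target.shape)
    mask_interp = RegularGridInterpolator(
        (src_lats, src_lons), g.mask[::-1, :].astype(float), method="nearest",
        bounds_error=False, fill_value=1.0,
    )
    mask = mask_interp(pts).reshape(target.shape) > 0.5
    mask |= ~np.isfinite(out)
    return EnvGrid(spec=target, values=out, mask=mask, name=g.name,
                   units=g.units)


def align(
    stack: GridStack,
    target: GridSpec,
    method_per_layer: Mapping[str, str] | None = None,
    default_method: str = "bilinear",
) -> GridStack:
    """Resample every layer onto ``target``.

    ``method_per_layer`` maps a layer name to ``"bilinear"`` or
    ``"nearest"``; categorical layers (e.g. sediment class) must use
    nearest so no new category values appear. Source masks are
    propagated (a target cell near a masked source cell is masked).
    """
    method_per_layer = dict(method_per_layer or {})
    out = GridStack(spec=target)
    for g in stack:
        method = method_per_layer.get(g.name, default_method)
        if method not in ("bilinear", "nearest"):
            raise ValueError(f"unknown resampling method {method!r}")
        out.add(_align_one(g, target, method))
    return out


# ---------------------------------------------------------------------------
# Plain-text grid I/O: ESRI ASCII grid plus a YAML sidecar for metadata.
# ---------------------------------------------------------------------------

def write_ascii_grid(g: EnvGrid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (.asc) with a ``.yaml`` metadata sidecar."""
    path = Path(path)
    spec = g.spec
    half = spec.cell_size_deg / 2
    xll = spec.origin_lon - half
    yll = spec.origin_lat - half - spec.cell_size_deg * (spec.n_rows - 1)
    vals = np.where(g.mask, nodata, g.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {spec.cell_size_deg!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    sidecar = {"name": g.name, "units": g.units, "crs_tag": spec.crs_tag}
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_ascii_grid(path: str | Path) -> EnvGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`.

    The YAML sidecar is optional; without it name/units default to the
    file stem and the empty string.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    vals = np.loadtxt(lines[n_header:], dtype=float).reshape(n_rows, n_cols)
    half = cell / 2
    origin_lon = header["xllcorner"] + half
    origin_lat = header["yllcorner"] + half + cell * (n_rows - 1)
    name, units, crs = path.stem, "", "EPSG:4326"
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        name = meta.get("name", name)
        units = meta.get("units", units)
        crs = meta.get("crs_tag", crs)
    spec = GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size_deg=cell,
                    origin_lon=origin_lon, origin_lat=origin_lat, crs_tag=crs)
    mask = vals == nodata
    values = np.where(mask, np.nan, vals)
    return EnvGrid(spec=spec, values=values, mask=mask, name=name, units=units)
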