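"""Grid data model, raster I/O, resolution changes and bioclimatic predictors.

The lattice convention throughout the package: cell-centre registration,
row 0 is the northernmost row, geographic (lat/lon) coordinates on the
WGS84 sphere.  Missing data are NaN internally; every operation on a
missing cell yields missing, never zero.

Three raster formats are supported: ESRI ASCII grid and GeoTIFF for
single 2-D layers, NetCDF (CF-style lat/lon, via xarray) for full
climate stacks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import cell_areas_km2

# surface-mask categories
MASK_LAND = 0
MASK_ICE = 1
MASK_SEA = 2

ASCII_NODATA = -9999.0

MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


# ---------------------------------------------------------------------------
# lattice and grid types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Geographic lattice: cell-centre registered, row 0 northernmost.

    ``lat0``/``lon0`` are the centre coordinates of the upper-left
    (north-west) cell; ``cellsize`` is in degrees.
    """

    lat0: float
    lon0: float
    cellsize: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.cellsize <= 0:
            raise ValueError("cell size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat0 - self.cellsize * np.arange(self.n_rows)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon0 + self.cellsize * np.arange(self.n_cols)

    def cell_latlon(self, rows, cols):
        """Centre coordinates of cells addressed by (row, col) indices."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        return self.lat0 - self.cellsize * rows, self.lon0 + self.cellsize * cols

    def cell_areas(self) -> np.ndarray:
        """Spherical cell areas in km², shape (n_rows, n_cols)."""
        return cell_areas_km2(self.lat_centers, self.cellsize, self.n_cols)

    def refined(self, factor: int) -> "GridSpec":
        """The lattice obtained by splitting every cell into factor² children."""
        f = int(factor)
        cs = self.cellsize / f
        return GridSpec(
            lat0=self.lat0 + self.cellsize / 2 - cs / 2,
            lon0=self.lon0 - self.cellsize / 2 + cs / 2,
            cellsize=cs,
            n_rows=self.n_rows * f,
            n_cols=self.n_cols * f,
        )

    def coarsened(self, factor: int) -> "GridSpec":
        f = int(factor)
        if self.n_rows % f or self.n_cols % f:
            raise ValueError("dimensions not divisible by aggregation factor")
        cs = self.cellsize * f
        return GridSpec(
            lat0=self.lat0 + self.cellsize / 2 - cs / 2,
            lon0=self.lon0 - self.cellsize / 2 + cs / 2,
            cellsize=cs,
            n_rows=self.n_rows // f,
            n_cols=self.n_cols // f,
        )

    def nesting_factor(self, fine: "GridSpec", tol: float = 1e-6) -> int:
        """Integer refinement factor by which ``fine`` nests in this lattice.

        Raises ``ValueError`` if the lattices do not nest exactly.
        """
        ratio = self.cellsize / fine.cellsize
        f = int(round(ratio))
        if f < 1 or abs(ratio - f) > tol:
            raise ValueError("cell sizes are not an integer ratio")
        expect = self.refined(f)
        for a, b in ((expect.lat0, fine.lat0), (expect.lon0, fine.lon0)):
            if abs(a - b) > tol * self.cellsize:
                raise ValueError("fine lattice is not aligned with the coarse one")
        if (expect.n_rows, expect.n_cols) != fine.shape:
            raise ValueError("fine lattice extent does not match the coarse one")
        return f


@dataclass
class Layer:
    """A single 2-D (or stacked 3-D) raster layer on a lattice."""

    spec: GridSpec
    values: np.ndarray
    name: str = "layer"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[-2:] != self.spec.shape:
            raise ValueError("layer shape does not match lattice")


@dataclass
class ElevationGrid:
    """Digital elevation model on a geographic lattice (metres)."""

    spec: GridSpec
    elevation: np.ndarray

    def __post_init__(self):
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.shape != self.spec.shape:
            raise ValueError("elevation shape does not match lattice")


@dataclass
class ClimateGrid:
    """Monthly climate normals plus a land/ice/sea mask.

    monthly_temperature : (12, n_rows, n_cols) °C
    monthly_precipitation : (12, n_rows, n_cols) mm per month
    surface_mask : per-cell category {MASK_LAND, MASK_ICE, MASK_SEA}
    reference_elevation : metres; the elevation at which the climate values
        are valid (used by the treeline elevation scan).
    """

    spec: GridSpec
    monthly_temperature: np.ndarray
    monthly_precipitation: np.ndarray
    surface_mask: np.ndarray
    reference_elevation: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.monthly_temperature = np.asarray(self.monthly_temperature, dtype=float)
        self.monthly_precipitation = np.asarray(self.monthly_precipitation, dtype=float)
        self.surface_mask = np.asarray(self.surface_mask, dtype=np.int8)
        if self.reference_elevation is None:
            self.reference_elevation = np.zeros(self.spec.shape)
        self.reference_elevation = np.asarray(self.reference_elevation, dtype=float)
        self.validate()

    def validate(self):
        shp = self.spec.shape
        for arr, nm in ((self.monthly_temperature, "temperature"),
                        (self.monthly_precipitation, "precipitation")):
            if arr.shape != (12,) + shp:
                raise ValueError(f"monthly {nm} must have 12 layers of shape {shp}")
        if self.surface_mask.shape != shp or self.reference_elevation.shape != shp:
            raise ValueError("mask/reference elevation shape mismatch")
        land = self.land_mask
        if not np.all(np.isfinite(self.monthly_temperature[:, land])):
            raise ValueError("temperature must be finite on land cells")
        prec_land = self.monthly_precipitation[:, land]
        if np.any(prec_land[np.isfinite(prec_land)] < 0):
            raise ValueError("precipitation must be non-negative")

    @property
    def land_mask(self) -> np.ndarray:
        return self.surface_mask == MASK_LAND

    def with_offset(self, delta_t: float, label: str = "") -> "ClimateGrid":
        """A copy with a spatially uniform temperature offset applied."""
        return dataclasses.replace(
            self, monthly_temperature=self.monthly_temperature + delta_t,
            label=label or self.label)


@dataclass
class BioclimLayers:
    """The three niche predictors on a ClimateGrid's lattice.

    summer_mean_temperature (°C), coldest_month_temperature (°C),
    annual_precipitation (mm).
    """

    spec: GridSpec
    summer_mean_temperature: np.ndarray
    coldest_month_temperature: np.ndarray
    annual_precipitation: np.ndarray

    VARIABLES = ("summer_mean_temperature", "coldest_month_temperature",
                 "annual_precipitation")

    def stack(self) -> np.ndarray:
        """(3, n_rows, n_cols) array in VARIABLES order."""
        return np.stack([getattr(self, v) for v in self.VARIABLES])

    def values_at(self, rows, cols) -> np.ndarray:
        """Predictor matrix (n_points, 3) for cells addressed by indices."""
        return np.column_stack([getattr(self, v)[rows, cols] for v in self.VARIABLES])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    return {".asc": "ascii_grid", ".tif": "geotiff", ".tiff": "geotiff",
            ".nc": "netcdf"}.get(suffix, "")


def write_grid(obj, path: str | Path, format: str | None = None) -> None:
    """Write a Layer, ElevationGrid or ClimateGrid to disk.

    ASCII grid and GeoTIFF carry single 2-D layers; NetCDF carries any of
    the three types (a ClimateGrid round-trips in full, with mask and
    reference elevation).
    """
    fmt = _infer_format(path, format)
    if fmt == "ascii_grid":
        _write_ascii(obj, path)
    elif fmt == "geotiff":
        _write_geotiff(obj, path)
    elif fmt == "netcdf":
        _write_netcdf(obj, path)
    else:
        raise ValueError(f"unknown grid format {fmt!r}")


def read_grid(path: str | Path, format: str | None = None):
    """Read a raster; returns ClimateGrid, ElevationGrid or Layer.

    No-data values are mapped to NaN (the missing/sea category).  A NetCDF
    file with 12-layer ``tas``/``pr`` variables yields a ClimateGrid; one
    with an ``elevation`` variable yields an ElevationGrid; anything else
    yields a Layer.
    """
    fmt = _infer_format(path, format)
    if fmt == "ascii_grid":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    if fmt == "netcdf":
        return _read_netcdf(path)
    raise ValueError(f"unknown grid format {fmt!r}")


def _as_layer(obj) -> Layer:
    if isinstance(obj, Layer):
        return obj
    if isinstance(obj, ElevationGrid):
        return Layer(obj.spec, obj.elevation, name="elevation")
    raise TypeError("this format carries single layers; pass a Layer or ElevationGrid")


def _write_ascii(obj, path):
    layer = _as_layer(obj)
    if layer.values.ndim != 2:
        raise ValueError("ASCII grid holds a single 2-D layer")
    s = layer.spec
    vals = np.where(np.isfinite(layer.values), layer.values, ASCII_NODATA)
    xll = s.lon0 - s.cellsize / 2
    yll = s.lat0 + s.cellsize / 2 - s.n_rows * s.cellsize
    with open(path, "w") as fh:
        fh.write(f"ncols {s.n_cols}\n")
        fh.write(f"nrows {s.n_rows}\n")
        fh.write(f"xllcorner {xll:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {s.cellsize:.10g}\n")
        fh.write(f"NODATA_value {ASCII_NODATA:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def _read_ascii(path) -> Layer:
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "xllcenter", "yllcenter", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    vals = np.array(rows, dtype=float)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if vals.shape != (nrows, ncols):
        vals = vals.reshape(nrows, ncols)
    cs = header["cellsize"]
    if "xllcenter" in header:
        lon0, yc = header["xllcenter"], header["yllcenter"]
    else:
        lon0, yc = header["xllcorner"] + cs / 2, header["yllcorner"] + cs / 2
    lat0 = yc + (nrows - 1) * cs
    nodata = header.get("nodata_value", ASCII_NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    spec = GridSpec(lat0=lat0, lon0=lon0, cellsize=cs, n_rows=nrows, n_cols=ncols)
    return Layer(spec, vals, name=Path(path).stem)


# GeoTIFF georeferencing tags
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


def _write_geotiff(obj, path):
    import tifffile

    layer = _as_layer(obj)
    if layer.values.ndim != 2:
        raise ValueError("GeoTIFF writer holds a single 2-D layer")
    s = layer.spec
    west = s.lon0 - s.cellsize / 2
    north = s.lat0 + s.cellsize / 2
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (s.cellsize, s.cellsize, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, west, north, 0.0)),
    ]
    tifffile.imwrite(path, layer.values.astype(np.float64), extratags=extratags)


def _read_geotiff(path) -> Layer:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        vals = page.asarray().astype(float)
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
    cs = float(scale[0])
    west, north = float(tie[3]), float(tie[4])
    nrows, ncols = vals.shape
    spec = GridSpec(lat0=north - cs / 2, lon0=west + cs / 2, cellsize=cs,
                    n_rows=nrows, n_cols=ncols)
    return Layer(spec, vals, name=Path(path).stem)


def _coords(spec: GridSpec):
    return {"lat": ("lat", spec.lat_centers), "lon": ("lon", spec.lon_centers)}


def _spec_attrs(spec: GridSpec) -> dict:
    # exact lattice metadata; coordinate arrays alone lose precision
    return {"lat0": spec.lat0, "lon0": spec.lon0, "cellsize": spec.cellsize}


def _write_netcdf(obj, path):
    import xarray as xr

    if isinstance(obj, ClimateGrid):
        ds = xr.Dataset(
            {
                "tas": (("month", "lat", "lon"), obj.monthly_temperature),
                "pr": (("month", "lat", "lon"), obj.monthly_precipitation),
                "surface_mask": (("lat", "lon"), obj.surface_mask.astype(np.int32)),
                "reference_elevation": (("lat", "lon"), obj.reference_elevation),
            },
            coords={"month": np.arange(1, 13), **_coords(obj.spec)},
            attrs={"label": obj.label, **_spec_attrs(obj.spec)},
        )
    elif isinstance(obj, ElevationGrid):
        ds = xr.Dataset({"elevation": (("lat", "lon"), obj.elevation)},
                        coords=_coords(obj.spec), attrs=_spec_attrs(obj.spec))
    elif isinstance(obj, Layer):
        if obj.values.ndim == 2:
            ds = xr.Dataset({obj.name: (("lat", "lon"), obj.values)},
                            coords=_coords(obj.spec),
                            attrs=_spec_attrs(obj.spec))
        else:
            ds = xr.Dataset(
                {obj.name: (("month", "lat", "lon"), obj.values)},
                coords={"month": np.arange(1, obj.values.shape[0] + 1),
                        **_coords(obj.spec)}, attrs=_spec_attrs(obj.spec))
    else:
        raise TypeError(f"cannot write {type(obj).__name__} to NetCDF")
    ds.to_netcdf(path, engine="scipy")


def _spec_from_coords(lat: np.ndarray, lon: np.ndarray) -> GridSpec:
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    cs = abs(lat[1] - lat[0]) if lat.size > 1 else abs(lon[1] - lon[0])
    lat0 = lat.max()
    return GridSpec(lat0=lat0, lon0=lon.min(), cellsize=cs,
                    n_rows=lat.size, n_cols=lon.size)


def _read_netcdf(path):
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if {"lat0", "lon0", "cellsize"} <= set(ds.attrs):
        spec = GridSpec(lat0=float(ds.attrs["lat0"]),
                        lon0=float(ds.attrs["lon0"]),
                        cellsize=float(ds.attrs["cellsize"]),
                        n_rows=ds.sizes["lat"], n_cols=ds.sizes["lon"])
    else:
        spec = _spec_from_coords(ds["lat"].values, ds["lon"].values)
    # row 0 must be northernmost
    if ds["lat"].values[0] < ds["lat"].values[-1]:
        ds = ds.isel(lat=slice(None, None, -1))
    if {"tas", "pr"} <= set(ds.data_vars):
        if ds["tas"].shape[0] != 12:
            raise ValueError("ClimateGrid NetCDF requires 12 monthly layers")
        mask = (ds["surface_mask"].values.astype(np.int8)
                if "surface_mask" in ds else
                np.where(np.isfinite(ds["tas"].values).all(axis=0),
                         MASK_LAND, MASK_SEA).astype(np.int8))
        ref = (ds["reference_elevation"].values
               if "reference_elevation" in ds else None)
        return ClimateGrid(spec, ds["tas"].values, ds["pr"].values, mask,
                           ref, label=str(ds.attrs.get("label", "")))
    if "elevation" in ds.data_vars:
        return ElevationGrid(spec, ds["elevation"].values)
    name = next(iter(ds.data_vars))
    return Layer(spec, ds[name].values, name=name)


# ---------------------------------------------------------------------------
# resolution changes and delta downscaling
# ---------------------------------------------------------------------------

def change_resolution(values: np.ndarray, factor: int, mode: str) -> np.ndarray:
    """Refine or coarsen the last two axes of a layer by an integer factor.

    ``disaggregate`` replicates each parent value into factor² children
    (conservative block replication, no interpolation); ``aggregate_mean``
    averages the non-missing children of each block (all-missing → missing).
    """
    f = int(factor)
    if f < 1:
        raise ValueError("factor must be >= 1")
    values = np.asarray(values, dtype=float)
    if mode == "disaggregate":
        return np.repeat(np.repeat(values, f, axis=-2), f, axis=-1)
    if mode == "aggregate_mean":
        r, c = values.shape[-2:]
        if r % f or c % f:
            raise ValueError("dimensions not divisible by aggregation factor")
        lead = values.shape[:-2]
        blocks = values.reshape(*lead, r // f, f, c // f, f)
        with np.errstate(invalid="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return np.nanmean(blocks, axis=(-3, -1))
    raise ValueError(f"unknown mode {mode!r}")


def _bilinear_to_fine(coarse_spec: GridSpec, coarse_vals: np.ndarray,
                      fine_spec: GridSpec) -> np.ndarray:
    """Bilinear interpolation of coarse cell-centre values to fine centres.

    Extrapolates linearly beyond the outermost coarse centres so the fine
    lattice's edge cells (which lie inside the coarse edge cells but
    outside their centres) are covered.
    """
    from scipy.interpolate import RegularGridInterpolator

    lat_c = coarse_spec.lat_centers[::-1]  # ascending for the interpolator
    lon_c = coarse_spec.lon_centers
    vals = np.flip(np.asarray(coarse_vals, float), axis=-2)
    stacked = vals.ndim == 3
    if stacked:
        vals = np.moveaxis(vals, 0, -1)  # trailing layer axis
    interp = RegularGridInterpolator((lat_c, lon_c), vals, method="linear",
                                     bounds_error=False, fill_value=None)
    flat_lat, flat_lon = np.meshgrid(fine_spec.lat_centers,
                                     fine_spec.lon_centers, indexing="ij")
    out = interp(np.column_stack([flat_lat.ravel(), flat_lon.ravel()]))
    if stacked:
        out = out.reshape(fine_spec.shape + (coarse_vals.shape[0],))
        out = np.moveaxis(out, -1, 0)
    else:
        out = out.reshape(fine_spec.shape)
    return out


def delta_downscale(coarse_reference: ClimateGrid, coarse_scenario: ClimateGrid,
                    fine_baseline: ClimateGrid, label: str = "") -> ClimateGrid:
    """Anomaly (delta-change) downscaling of a coarse scenario.

    Per month, the fine scenario temperature is the fine baseline plus the
    coarse (scenario − reference) anomaly interpolated bilinearly to the
    fine lattice.  Precipitation uses the multiplicative scenario/reference
    ratio; where the coarse reference is ≤ 0.1 mm the anomaly is forced
    additive to avoid ratio blow-ups.  Coarse cells with missing data
    contribute a neutral anomaly (0 / ratio 1) — missing fine-baseline
    cells stay missing regardless.
    """
    if coarse_reference.spec != coarse_scenario.spec:
        raise ValueError("coarse grids must share a lattice")
    coarse_reference.spec.nesting_factor(fine_baseline.spec)

    dt = coarse_scenario.monthly_temperature - coarse_reference.monthly_temperature
    dt = np.where(np.isfinite(dt), dt, 0.0)

    ref_p = coarse_reference.monthly_precipitation
    scn_p = coarse_scenario.monthly_precipitation
    wet = np.isfinite(ref_p) & np.isfinite(scn_p) & (ref_p > 0.1)
    ratio = np.where(wet, scn_p / np.where(wet, ref_p, 1.0), 1.0)
    add = np.where(np.isfinite(ref_p) & np.isfinite(scn_p) & ~wet,
                   scn_p - ref_p, 0.0)

    fine = fine_baseline.spec
    t_out = fine_baseline.monthly_temperature + _bilinear_to_fine(
        coarse_reference.spec, dt, fine)
    p_out = (fine_baseline.monthly_precipitation
             * _bilinear_to_fine(coarse_reference.spec, ratio, fine)
             + _bilinear_to_fine(coarse_reference.spec, add, fine))
    p_out = np.where(np.isfinite(p_out), np.clip(p_out, 0.0, None), p_out)
    return ClimateGrid(fine, t_out, p_out, fine_baseline.surface_mask.copy(),
                       fine_baseline.reference_elevation.copy(),
                       label=label or coarse_scenario.label)


# ---------------------------------------------------------------------------
# bioclimatic predictors
# ---------------------------------------------------------------------------

DEFAULT_SUMMER_MONTHS = frozenset({6, 7, 8})  # JJA; all study regions are NH


def derive_bioclim(grid: ClimateGrid,
                   summer_months=DEFAULT_SUMMER_MONTHS) -> BioclimLayers:
    """The three niche predictors from monthly normals.

    summer mean temperature = mean of the configured summer months
    (default June–August); coldest-month temperature = minimum over the
    12 monthly means; annual precipitation = sum over the 12 months.
    """
    months = sorted(int(m) for m in summer_months)
    if not months:
        raise ValueError("summer month set must be non-empty")
    if any(m < 1 or m > 12 for m in months):
        raise ValueError("months are 1-based (1..12)")
    idx = [m - 1 for m in months]
    return BioclimLayers(
        spec=grid.spec,
        summer_mean_temperature=grid.monthly_temperature[idx].mean(axis=0),
        coldest_month_temperature=grid.monthly_temperature.min(axis=0),
        annual_precipitation=grid.monthly_precipitation.sum(axis=0),
    )
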