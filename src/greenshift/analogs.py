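"""Reciprocal climate-analog mapping between two regions.

Two cells have analogous climates at niche breadth b (% of each
variable's domain range) when, for every bioclimatic variable j,

    |v_cell,j − v_focal,j| ≤ (b/100) · R_j / 2,

where R_j is the range of variable j over the full analysis domain
(both regions pooled).  Because the window is symmetric and uses shared
domain ranges, the analog relation is symmetric and nested in b: the
analog set at 5% is contained in the one at 25%, which is contained in
the one at 50%.  For each focal cell the analog area in the counterpart
region (as a percentage of a stated reference area) and the
great-circle distance to the nearest analog cell quantify potential
source/sink structure for immigrant species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import haversine_km
from .grids import BioclimLayers, GridSpec

DEFAULT_BREADTHS = (5.0, 25.0, 50.0)


@dataclass
class AnalogParams:
    """Niche breadths (% of domain range) and the shared domain ranges."""

    breadths: tuple[float, ...] = DEFAULT_BREADTHS
    domain_ranges: np.ndarray | None = None

    def __post_init__(self):
        for b in self.breadths:
            if not 0.0 < b <= 100.0:
                raise ValueError("niche breadths must be in (0, 100]")


@dataclass
class Region:
    """One side of the comparison: predictors plus a validity mask."""

    bioclim: BioclimLayers
    mask: np.ndarray                 # True on analysable (ice-free land) cells
    name: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)

    @property
    def spec(self) -> GridSpec:
        return self.bioclim.spec

    def cell_table(self):
        """(values (n,3), lat (n,), lon (n,), area_km2 (n,)) of masked cells."""
        rows, cols = np.nonzero(self.mask)
        vals = self.bioclim.values_at(rows, cols)
        lat, lon = self.spec.cell_latlon(rows, cols)
        areas = self.spec.cell_areas()[rows, cols]
        return vals, np.asarray(lat, float), np.asarray(lon, float), areas


@dataclass
class AnalogMap:
    """Per-focal-cell analog area (%) and distance to nearest analog (km)."""

    spec: GridSpec
    area_pct: np.ndarray
    distance_km: np.ndarray          # NaN where no analog exists
    breadth: float
    direction: str = ""
    reference_area_km2: float = float("nan")


def domain_ranges(*regions: Region) -> np.ndarray:
    """Per-variable value ranges R_j over the pooled analysis domain."""
    stacks = [r.cell_table()[0] for r in regions]
    allv = np.vstack(stacks)
    rng = allv.max(axis=0) - allv.min(axis=0)
    if np.any(rng <= 0):
        raise ValueError("degenerate (constant) variable over the analysis "
                         "domain; its range is zero")
    return rng


def analog_mask(focal_values: np.ndarray, counterpart: Region,
                breadth: float, ranges: np.ndarray) -> np.ndarray:
    """Boolean grid of counterpart cells analogous to one focal climate."""
    focal_values = np.asarray(focal_values, float)
    half = (breadth / 100.0) * np.asarray(ranges, float) / 2.0
    out = np.zeros(counterpart.spec.shape, bool)
    rows, cols = np.nonzero(counterpart.mask)
    vals = counterpart.bioclim.values_at(rows, cols)
    ok = np.all(np.abs(vals - focal_values[None, :]) <= half[None, :], axis=1)
    out[rows, cols] = ok
    return out


def _pairwise_analogs(fv: np.ndarray, cv: np.ndarray, half: np.ndarray,
                      chunk: int = 256) -> "np.ndarray":
    """Boolean (n_focal, n_counterpart) analog matrix, chunked over focals."""
    n_f = fv.shape[0]
    out = np.empty((n_f, cv.shape[0]), bool)
    for a in range(0, n_f, chunk):
        b = min(a + chunk, n_f)
        diff = np.abs(fv[a:b, None, :] - cv[None, :, :])
        out[a:b] = np.all(diff <= half[None, None, :], axis=2)
    return out


def analog_area(focal: Region, counterpart: Region, breadth: float,
                ranges: np.ndarray | None = None,
                reference_area_km2: float | None = None,
                with_distance: bool = True) -> AnalogMap:
    """Analog area and distance-to-analog for every focal cell.

    The analog area of a focal cell is the summed spherical area of its
    analog cells in the counterpart region, expressed as a percentage of
    ``reference_area_km2`` (default: the counterpart region's total
    masked area, i.e. its ice-free land).  Distance is the haversine
    distance to the nearest analog cell centre, NaN when no analog
    exists.
    """
    if ranges is None:
        ranges = domain_ranges(focal, counterpart)
    half = (breadth / 100.0) * np.asarray(ranges, float) / 2.0
    fv, flat, flon, _ = focal.cell_table()
    cv, clat, clon, careas = counterpart.cell_table()
    if reference_area_km2 is None:
        reference_area_km2 = float(careas.sum())

    analog = _pairwise_analogs(fv, cv, half)
    area = analog @ careas / reference_area_km2 * 100.0

    dist = np.full(fv.shape[0], np.nan)
    if with_distance and cv.shape[0] > 0:
        # pairwise haversine, chunked over focal cells
        for a in range(0, fv.shape[0], 256):
            b = min(a + 256, fv.shape[0])
            d = haversine_km(flat[a:b, None], flon[a:b, None],
                             clat[None, :], clon[None, :])
            d = np.where(analog[a:b], d, np.inf)
            dmin = d.min(axis=1)
            dist[a:b] = np.where(np.isfinite(dmin), dmin, np.nan)

    area_grid = np.full(focal.spec.shape, np.nan)
    dist_grid = np.full(focal.spec.shape, np.nan)
    rows, cols = np.nonzero(focal.mask)
    area_grid[rows, cols] = area
    dist_grid[rows, cols] = dist
    return AnalogMap(spec=focal.spec, area_pct=area_grid,
                     distance_km=dist_grid, breadth=float(breadth),
                     direction=f"{focal.name}->{counterpart.name}",
                     reference_area_km2=float(reference_area_km2))


def distance_to_analog(focal: Region, counterpart: Region, breadth: float,
                       ranges: np.ndarray | None = None) -> np.ndarray:
    """Great-circle km from each focal cell to its nearest analog cell."""
    return analog_area(focal, counterpart, breadth, ranges=ranges).distance_km


def analog_maps(focal: Region, counterpart: Region,
                params: AnalogParams = AnalogParams()) -> dict[float, AnalogMap]:
    """Analog maps at every configured breadth, sharing domain ranges."""
    ranges = (params.domain_ranges if params.domain_ranges is not None
              else domain_ranges(focal, counterpart))
    return {b: analog_area(focal, counterpart, b, ranges=ranges)
            for b in params.breadths}
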