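"""Synthetic climate worlds, warming trajectories and virtual species.

Downstream stages (treeline scan, niche ensemble, spread simulation,
analog mapping) are exercised on generated inputs with known truth:
a climate grid whose monthly temperatures follow a prescribed
latitudinal gradient, elevational lapse and seasonal cycle, and virtual
species whose occurrences are drawn from a known rectilinear climatic
niche and then degraded the way heterogeneous-precision occurrence
archives degrade coordinates.

The seasonal cycle is anchored so July is the warmest month, matching a
Northern Hemisphere study region.  All generators are deterministic per
seed: the same seed reproduces every layer bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import (MASK_ICE, MASK_LAND, MASK_SEA, BioclimLayers, ClimateGrid,
                    ElevationGrid, GridSpec, derive_bioclim)
from .occurrences import OccurrenceRecord


@dataclass(frozen=True)
class WorldTruth:
    """Generation parameters recorded alongside a synthetic world."""

    lapse_rate: float          # K per m
    gradient: float            # °C per degree latitude
    amplitude: float           # °C seasonal half-range
    noise_sd: float            # °C
    base_temperature: float    # °C at the reference latitude, sea level
    seed: int


@dataclass
class SyntheticWorld:
    climate: ClimateGrid
    dem: ElevationGrid
    truth: WorldTruth

    def bioclim(self) -> BioclimLayers:
        return derive_bioclim(self.climate)


def _seasonal_cycle(amplitude: float) -> np.ndarray:
    """Monthly deviations (°C) peaking in July (month 7)."""
    months = np.arange(1, 13)
    return amplitude * np.cos(2.0 * np.pi * (months - 7) / 12.0)


def make_world(n_rows: int = 40, n_cols: int = 40,
               lat_range: tuple[float, float] = (58.0, 78.0),
               lon0: float = -55.0,
               base_temperature: float = 8.0,
               gradient: float = 0.7,
               amplitude: float = 12.0,
               lapse: float = 0.0055,
               relief: float = 800.0,
               noise_sd: float = 0.5,
               precip_base: float = 60.0,
               precip_gradient: float = -1.5,
               ice_above: float | None = None,
               sea_fraction: float = 0.0,
               seed: int = 0) -> SyntheticWorld:
    """Generate a climate grid + DEM pair with known structure.

    Monthly temperature at each cell is

        T(m) = base − gradient·(lat − lat_min) − lapse·elevation
               + amplitude·cos(2π(m − 7)/12) + ε,   ε ~ N(0, noise_sd²)

    so the configured lapse and latitudinal gradient are exactly
    recoverable by regression when ``noise_sd`` is 0.  Precipitation is a
    positive monthly field with a linear latitudinal trend
    (``precip_base + precip_gradient·(lat − lat_min)`` mm per month,
    clipped at 1 mm).  The DEM is smoothed uniform random relief scaled to
    ``relief`` metres.  Optional surface structure: cells with elevation
    above ``ice_above`` become ice; a ``sea_fraction`` of the lowest-lying
    cells becomes sea.

    Defaults sketch a subarctic coastal region: 20° of latitude from the
    boreal zone into the high Arctic, a 0.7 °C/°lat gradient, 12 °C
    seasonal half-range, 0.55 K/100 m lapse and up to ~800 m of relief.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    rng = np.random.default_rng(seed)
    lat_min, lat_max = min(lat_range), max(lat_range)
    cellsize = (lat_max - lat_min) / n_rows
    spec = GridSpec(lat0=lat_max - cellsize / 2, lon0=lon0,
                    cellsize=cellsize, n_rows=n_rows, n_cols=n_cols)

    if relief > 0:
        rough = rng.uniform(0.0, 1.0, size=spec.shape)
        smooth = gaussian_filter(rough, sigma=max(2.0, n_rows / 10.0),
                                 mode="reflect")
        smooth -= smooth.min()
        peak = smooth.max()
        elevation = relief * (smooth / peak if peak > 0 else smooth)
    else:
        elevation = np.zeros(spec.shape)

    lat2d = np.repeat(spec.lat_centers[:, None], n_cols, axis=1)
    annual = (base_temperature - gradient * (lat2d - lat_min)
              - lapse * elevation)
    cycle = _seasonal_cycle(amplitude)
    temp = annual[None, :, :] + cycle[:, None, None]
    if noise_sd > 0:
        temp = temp + rng.normal(0.0, noise_sd, size=temp.shape)

    monthly_p = np.clip(precip_base + precip_gradient * (lat2d - lat_min),
                        1.0, None)
    prec = np.repeat(monthly_p[None, :, :], 12, axis=0)

    mask = np.full(spec.shape, MASK_LAND, dtype=np.int8)
    if ice_above is not None:
        mask[elevation > ice_above] = MASK_ICE
    if sea_fraction > 0:
        n_sea = int(round(sea_fraction * mask.size))
        if n_sea:
            order = np.argsort(elevation, axis=None, kind="stable")
            mask.ravel()[order[:n_sea]] = MASK_SEA

    climate = ClimateGrid(spec, temp, prec, mask, reference_elevation=elevation,
                          label="baseline")
    truth = WorldTruth(lapse_rate=lapse, gradient=gradient, amplitude=amplitude,
                       noise_sd=noise_sd, base_temperature=base_temperature,
                       seed=seed)
    return SyntheticWorld(climate=climate,
                          dem=ElevationGrid(spec, elevation), truth=truth)


def make_trajectory(world: SyntheticWorld,
                    slice_offsets: list[tuple[str, float]]) -> list[ClimateGrid]:
    """Climate slices from a baseline world under uniform warming offsets.

    Emulates a time series of climate snapshots — a glacial baseline
    through Holocene slices into future decades — as spatially uniform
    temperature offsets from the world's baseline.  Labels are preserved
    in each slice's metadata.
    """
    out = []
    for label, dt in slice_offsets:
        if not np.isfinite(dt):
            raise ValueError("slice offsets must be finite")
        out.append(world.climate.with_offset(float(dt), label=str(label)))
    return out


@dataclass
class VirtualSpecies:
    """A species with a known rectilinear climatic niche.

    ``bounds`` maps predictor name → (min, max).  ``truth_mask`` marks the
    suitable land cells under those bounds; every presence was sampled
    from a truth-suitable cell before its coordinates were rounded.
    """

    species: str
    bounds: dict[str, tuple[float, float]]
    truth_mask: np.ndarray
    presences: list[OccurrenceRecord]
    presence_cells: np.ndarray       # (n, 2) row/col of the source cells
    prevalence: float
    seed: int


def truth_suitability(bioclim: BioclimLayers, bounds: dict,
                      land_mask: np.ndarray) -> np.ndarray:
    """Boolean suitability of every land cell under rectilinear bounds."""
    ok = np.asarray(land_mask, bool).copy()
    for var, (lo, hi) in bounds.items():
        vals = getattr(bioclim, var)
        ok &= np.isfinite(vals) & (vals >= lo) & (vals <= hi)
    return ok


def make_virtual_species(world: SyntheticWorld,
                         bounds: dict[str, tuple[float, float]],
                         n_presence: int = 300,
                         digit_model=None,
                         bias_model=None,
                         species: str = "virtualis",
                         seed: int = 0) -> VirtualSpecies:
    """Sample occurrences of a species with a known box niche.

    Presences are drawn (with replacement) from the truth-suitable land
    cells, uniformly or weighted by ``bias_model`` (a non-negative weight
    surface emulating sampling bias, e.g. a distance-to-coast proxy).
    Each record's position is jittered uniformly within its cell, then
    rounded to a per-record decimal digit count drawn from
    ``digit_model(rng, n)`` — emulating the precision heterogeneity of
    aggregated occurrence archives.  The default digit model mixes
    imprecise (0–2 digit) and precise (3–6 digit) records.
    """
    rng = np.random.default_rng(seed)
    bio = world.bioclim()
    land = world.climate.land_mask
    truth = truth_suitability(bio, bounds, land)
    cells = np.argwhere(truth)
    if cells.shape[0] == 0:
        raise ValueError("niche bounds overlap no land cell's climate")

    # sampling weights: bias surface evaluated at the suitable cells
    if bias_model is not None:
        w = np.asarray(bias_model, float)[cells[:, 0], cells[:, 1]]
        w = np.clip(w, 0.0, None)
        if w.sum() <= 0:
            raise ValueError("bias model assigns zero weight to all suitable cells")
        p = w / w.sum()
    else:
        p = None

    picks = rng.choice(cells.shape[0], size=n_presence, replace=True, p=p)
    chosen = cells[picks]

    if digit_model is None:
        def digit_model(r, n):
            return r.choice([0, 1, 2, 3, 4, 5, 6], size=n,
                            p=[0.05, 0.1, 0.15, 0.2, 0.2, 0.15, 0.15])

    spec = world.climate.spec
    lat_c, lon_c = spec.cell_latlon(chosen[:, 0], chosen[:, 1])
    half = spec.cellsize / 2.0
    lat = lat_c + rng.uniform(-half, half, size=n_presence)
    lon = lon_c + rng.uniform(-half, half, size=n_presence)
    d_lat = np.asarray(digit_model(rng, n_presence), dtype=int)
    d_lon = np.asarray(digit_model(rng, n_presence), dtype=int)

    records = [
        OccurrenceRecord(
            species=species,
            latitude=round(float(la), int(da)),
            longitude=round(float(lo), int(dl)),
            digits_lat=int(da), digits_lon=int(dl), source="observation")
        for la, lo, da, dl in zip(lat, lon, d_lat, d_lon)
    ]
    prevalence = truth.sum() / max(int(land.sum()), 1)
    return VirtualSpecies(species=species, bounds=dict(bounds), truth_mask=truth,
                          presences=records,
                          presence_cells=chosen, prevalence=float(prevalence),
                          seed=seed)
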