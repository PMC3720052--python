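"""Potential climatic treeline from a thermal growing-season criterion.

Tree life-form persistence is modelled as a threshold on the thermal
growing season: at least ``min_season_days`` days whose daily mean air
temperature reaches ``day_threshold`` °C, with a mean over those days of
at least ``season_mean_threshold`` °C.  Daily series are interpolated
from monthly normals, shifted along an elevation scan with a constant
adiabatic lapse rate, and the highest elevation still satisfying both
criteria is the potential treeline of that climate cell.  A finer DEM
then yields the below-treeline mask — terrain at or below the local
treeline on ice-free land.

Equality counts as qualifying throughout ("a minimum of", "at least").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .grids import (MASK_LAND, MONTH_DAYS, ClimateGrid, ElevationGrid,
                    GridSpec)


@dataclass(frozen=True)
class TreelineParams:
    """Thresholds and scan geometry of the treeline algorithm.

    Defaults: growing season of ≥ 94 days with daily means ≥ 0.9 °C and a
    season mean ≥ 6.4 °C; standard adiabatic lapse rate 0.55 K per 100 m;
    elevation scan 0–2000 m in 25 m steps.  ``season_definition`` selects
    whether the season is all qualifying days (default) or the longest
    contiguous run of qualifying days (circular over the year boundary).
    """

    min_season_days: int = 94
    day_threshold: float = 0.9
    season_mean_threshold: float = 6.4
    lapse_rate: float = 0.0055          # K per metre
    z_min: float = 0.0
    z_max: float = 2000.0
    z_step: float = 25.0
    season_definition: str = "all_days"

    def __post_init__(self):
        if self.z_step <= 0 or self.z_min > self.z_max:
            raise ValueError("invalid elevation scan")
        if self.season_definition not in {"all_days", "longest_run"}:
            raise ValueError("season_definition must be all_days or longest_run")

    @property
    def elevations(self) -> np.ndarray:
        return np.arange(self.z_min, self.z_max + self.z_step / 2, self.z_step)


@dataclass
class TreelineSurface:
    """Per-climate-cell potential treeline elevation (NaN where absent)."""

    spec: GridSpec
    elevation: np.ndarray
    params: TreelineParams
    source_label: str = ""


# month mid-points (cumulative day centre) on a fixed 365-day calendar
_MONTH_MID = np.cumsum(MONTH_DAYS) - MONTH_DAYS / 2.0


def monthly_to_daily(monthly: np.ndarray) -> np.ndarray:
    """365 daily means by linear interpolation between month mid-points.

    December wraps to January so the cycle is continuous; the value at
    each month's mid-point day equals that month's mean.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.shape[-1] != 12:
        raise ValueError("12 monthly values required")
    if not np.all(np.isfinite(monthly)):
        raise ValueError("monthly values must be finite")
    x = np.concatenate([[_MONTH_MID[-1] - 365.0], _MONTH_MID,
                        [_MONTH_MID[0] + 365.0]])
    days = np.arange(365) + 0.5
    if monthly.ndim == 1:
        y = np.concatenate([[monthly[-1]], monthly, [monthly[0]]])
        return np.interp(days, x, y)
    flat = monthly.reshape(-1, 12)
    out = np.empty((flat.shape[0], 365))
    for i, row in enumerate(flat):
        y = np.concatenate([[row[-1]], row, [row[0]]])
        out[i] = np.interp(days, x, y)
    return out.reshape(monthly.shape[:-1] + (365,))


def _longest_circular_run(qualify: np.ndarray) -> np.ndarray:
    """Boolean mask of the longest circular run of True in each row."""
    qualify = np.atleast_2d(qualify)
    n = qualify.shape[-1]
    out = np.zeros_like(qualify)
    for r in range(qualify.shape[0]):
        q = qualify[r]
        if q.all():
            out[r] = True
            continue
        if not q.any():
            continue
        # unroll twice to capture wraps; runs longer than n impossible here
        qq = np.concatenate([q, q])
        best_len, best_start = 0, 0
        run = 0
        for i, v in enumerate(qq):
            run = run + 1 if v else 0
            if run > best_len and i - run + 1 < n:
                best_len, best_start = run, i - run + 1
        idx = (np.arange(best_start, best_start + best_len)) % n
        out[r, idx] = True
    return out


def season_stats(daily: np.ndarray, params: TreelineParams = TreelineParams()
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Growing-season length (days) and mean temperature (°C).

    With ``all_days`` the season is every day with a daily mean at or
    above the day threshold; with ``longest_run`` only the longest
    contiguous (circular) block of such days.  The mean is NaN when the
    season is empty.  Works on a single series or a stack (..., 365).
    """
    daily = np.asarray(daily, dtype=float)
    if daily.shape[-1] != 365:
        raise ValueError("365 daily values required")
    qualify = daily >= params.day_threshold
    if params.season_definition == "longest_run":
        shape = daily.shape
        qualify = _longest_circular_run(qualify.reshape(-1, 365)).reshape(shape)
    length = qualify.sum(axis=-1)
    total = np.where(qualify, daily, 0.0).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(length > 0, total / np.maximum(length, 1), np.nan)
    if daily.ndim == 1:
        return int(length), float(mean)
    return length, mean


# round-off guard (°C) so exact-equality cases at the season-mean threshold
# qualify: the mean of n identical qualifying days must compare equal to them
_MEAN_EPS = 1e-9


def _qualifies(length, mean, params: TreelineParams):
    ok_mean = np.where(np.isnan(mean), False,
                       mean >= params.season_mean_threshold - _MEAN_EPS)
    return (length >= params.min_season_days) & ok_mean


def season_qualifies(daily: np.ndarray,
                     params: TreelineParams = TreelineParams()) -> bool:
    """Whether a 365-day series meets both growing-season criteria."""
    length, mean = season_stats(daily, params)
    return bool(_qualifies(np.asarray(length), np.asarray(mean), params))


def potential_treeline(monthly: np.ndarray, reference_elevation: float = 0.0,
                       params: TreelineParams = TreelineParams()) -> float:
    """Highest elevation in the scan meeting both growing-season criteria.

    The monthly series (valid at ``reference_elevation``) is converted to
    a daily series, shifted by −lapse·(z − reference) for every scan
    elevation z, and the highest qualifying z is returned (NaN if none
    qualifies).
    """
    daily = monthly_to_daily(np.asarray(monthly, float))
    zs = params.elevations
    shifted = daily[None, :] - params.lapse_rate * (zs - reference_elevation)[:, None]
    length, mean = season_stats(shifted, params)
    ok = _qualifies(length, mean, params)
    if not ok.any():
        return float("nan")
    return float(zs[np.flatnonzero(ok)[-1]])


def treeline_surface(climate: ClimateGrid,
                     params: TreelineParams = TreelineParams(),
                     use_reference_elevation: bool = True) -> TreelineSurface:
    """Potential treeline for every land cell of a climate grid.

    With ``use_reference_elevation`` the scan is relative to the elevation
    at which each cell's climate is valid; without it, a literal
    sea-level-referenced 0–2000 m scan.
    """
    spec = climate.spec
    zs = params.elevations
    out = np.full(spec.shape, np.nan)
    land = climate.land_mask
    rows, cols = np.nonzero(land)
    if rows.size == 0:
        return TreelineSurface(spec, out, params, climate.label)
    monthly = climate.monthly_temperature[:, rows, cols].T        # (n, 12)
    ref = (climate.reference_elevation[rows, cols]
           if use_reference_elevation else np.zeros(rows.size))
    daily = monthly_to_daily(monthly)                             # (n, 365)
    # chunked over cells to bound the (chunk, n_z, 365) working array
    chunk = max(1, int(4e6 // (zs.size * 365)))  # ~32 MB working array
    vals = np.empty(rows.size)
    for a in range(0, rows.size, chunk):
        b = min(a + chunk, rows.size)
        shifted = (daily[a:b, None, :]
                   - params.lapse_rate * (zs[None, :, None]
                                          - ref[a:b, None, None]))
        length, mean = season_stats(shifted, params)
        ok = _qualifies(length, mean, params)                     # (m, n_z)
        has = ok.any(axis=1)
        idx = ok.shape[1] - 1 - np.argmax(ok[:, ::-1], axis=1)
        vals[a:b] = np.where(has, zs[idx], np.nan)
    out[rows, cols] = vals
    return TreelineSurface(spec, out, params, climate.label)


def below_treeline_mask(surface: TreelineSurface, dem: ElevationGrid,
                        surface_mask: np.ndarray) -> np.ndarray:
    """DEM cells on ice-free land at or below their cell's treeline.

    The DEM may be finer than the climate lattice with an exact nesting
    factor; ``surface_mask`` is on the climate lattice.
    """
    f = surface.spec.nesting_factor(dem.spec)
    rows = np.arange(dem.spec.n_rows) // f
    cols = np.arange(dem.spec.n_cols) // f
    tl = surface.elevation[np.ix_(rows, cols)]
    land = (np.asarray(surface_mask) == MASK_LAND)[np.ix_(rows, cols)]
    with np.errstate(invalid="ignore"):
        below = np.isfinite(tl) & (dem.elevation <= tl) & land
    return below


def layer_agreement(layers: list[np.ndarray]) -> np.ndarray:
    """Per-cell count of boolean layers that are True (e.g. GCM agreement)."""
    if not layers:
        raise ValueError("at least one layer required")
    stack = np.stack([np.asarray(l, bool) for l in layers])
    return stack.sum(axis=0).astype(int)
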