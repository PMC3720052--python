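"""Spherical geometry on the WGS84 authalic sphere.

All distances in this package are great-circle distances on a sphere of
radius 6371.0088 km (the WGS84 authalic radius).  Equal-area work (block
lattices for spatial thinning, stratified sampling) uses a spherical
Lambert azimuthal equal-area projection anchored at a local origin.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def laea_forward(lat, lon, lat0, lon0):
    """Lambert azimuthal equal-area forward projection (spherical).

    Returns (x, y) in km relative to the origin (lat0, lon0).
    """
    lat, lon = np.radians(np.asarray(lat, float)), np.radians(np.asarray(lon, float))
    p0, l0 = np.radians(lat0), np.radians(lon0)
    cosc = np.sin(p0) * np.sin(lat) + np.cos(p0) * np.cos(lat) * np.cos(lon - l0)
    # antipodal points are outside any sensible local block lattice
    k = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-12, None))
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(lon - l0)
    y = EARTH_RADIUS_KM * k * (np.cos(p0) * np.sin(lat)
                               - np.sin(p0) * np.cos(lat) * np.cos(lon - l0))
    return x, y


def laea_inverse(x, y, lat0, lon0):
    """Inverse of :func:`laea_forward`; returns (lat, lon) in degrees."""
    x = np.asarray(x, float) / EARTH_RADIUS_KM
    y = np.asarray(y, float) / EARTH_RADIUS_KM
    p0, l0 = np.radians(lat0), np.radians(lon0)
    rho = np.hypot(x, y)
    c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        lat = np.where(
            rho == 0.0, p0,
            np.arcsin(np.clip(np.cos(c) * np.sin(p0)
                              + np.where(rho == 0, 0.0, y * np.sin(c) * np.cos(p0) / np.where(rho == 0, 1.0, rho)),
                              -1.0, 1.0)))
        lon = np.where(
            rho == 0.0, l0,
            l0 + np.arctan2(x * np.sin(c),
                            rho * np.cos(p0) * np.cos(c) - y * np.sin(p0) * np.sin(c)))
    return np.degrees(lat), np.degrees(lon)


def cell_areas_km2(lat_centers: np.ndarray, cellsize_deg: float, n_cols: int) -> np.ndarray:
    """Per-cell areas of a geographic lattice, km².

    Uses the exact spherical quadrilateral formula
    A = R² Δλ (sin φ_n − sin φ_s) for each latitude band; area varies with
    latitude only, so the result is broadcast across columns.

    Parameters
    ----------
    lat_centers : latitudes of row centres (degrees), any order.
    cellsize_deg : angular cell size (degrees).
    n_cols : number of columns.

    Returns
    -------
    (n_rows, n_cols) array of areas.
    """
    half = cellsize_deg / 2.0
    phi_n = np.radians(np.asarray(lat_centers, float) + half)
    phi_s = np.radians(np.asarray(lat_centers, float) - half)
    dlam = np.radians(cellsize_deg)
    band = EARTH_RADIUS_KM ** 2 * dlam * (np.sin(phi_n) - np.sin(phi_s))
    return np.repeat(band[:, None], n_cols, axis=1)


def nearest_great_circle_km(target_lat, target_lon, source_lat, source_lon):
    """Distance from each target point to the nearest source point, km.

    Exact great-circle distances computed via chord lengths on the unit
    sphere (a KD-tree on 3-D Cartesian coordinates finds the nearest
    neighbour; chord → arc conversion is monotone so the nearest chord is
    the nearest great-circle neighbour).
    """
    from scipy.spatial import cKDTree

    def to_xyz(lat, lon):
        lat, lon = np.radians(np.asarray(lat, float)), np.radians(np.asarray(lon, float))
        return np.column_stack([np.cos(lat) * np.cos(lon),
                                np.cos(lat) * np.sin(lon),
                                np.sin(lat)])

    src = to_xyz(np.atleast_1d(source_lat), np.atleast_1d(source_lon))
    tgt = to_xyz(np.atleast_1d(target_lat), np.atleast_1d(target_lon))
    chord, _ = cKDTree(src).query(tgt)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
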