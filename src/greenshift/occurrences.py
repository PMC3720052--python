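"""Occurrence-record hygiene: precision filtering, thinning, sampling.

Aggregated occurrence archives mix records whose coordinates were
reported at anything from whole degrees to six decimal places.  A record
is only usable for niche modelling at ~8 km grid resolution if its
positional ambiguity is below the cell size, and dense collections near
herbaria or roads must be thinned to limit sampling bias.  This module
implements that hygiene chain: a haversine-based precision estimate from
the printed decimal digits, a precision filter, equal-area block
thinning, geographically stratified presence sampling inside range
outlines, and pseudo-absence sampling outside them.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point
from shapely.prepared import prep

from .geometry import haversine_km, laea_forward, laea_inverse

logger = logging.getLogger(__name__)

DEFAULT_MAX_PRECISION_KM = 8.0
DEFAULT_BLOCK_KM = 100.0


@dataclass
class OccurrenceRecord:
    """One georeferenced record with coordinate-precision metadata.

    ``digits_lat``/``digits_lon`` are the number of decimal digits the
    coordinates were reported with; ``source`` is one of
    {observation, specimen, dotmap, outline_sample}.
    """

    species: str
    latitude: float
    longitude: float
    digits_lat: int = 6
    digits_lon: int = 6
    source: str = "observation"

    def __post_init__(self):
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} out of range")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} out of range")
        if self.digits_lat < 0 or self.digits_lon < 0:
            raise ValueError("digit counts must be non-negative")


@dataclass
class OccurrenceSet:
    """Presences plus pseudo-absences for one species."""

    presences: list[OccurrenceRecord]
    pseudo_absences: list[OccurrenceRecord] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def coordinate_precision(record: OccurrenceRecord) -> float:
    """Positional ambiguity of a record's printed coordinates, in km.

    Half the last printed digit in each axis jointly: the great-circle
    (haversine) distance between (lat, lon) and
    (lat + 0.5·10^−d_lat, lon + 0.5·10^−d_lon).  The longitude component
    shrinks with |latitude|, so the same digit count is more precise at
    high latitude.
    """
    dlat = 0.5 * 10.0 ** (-record.digits_lat)
    dlon = 0.5 * 10.0 ** (-record.digits_lon)
    lat2 = min(record.latitude + dlat, 90.0)
    return float(haversine_km(record.latitude, record.longitude,
                              lat2, record.longitude + dlon))


def filter_by_precision(records: list[OccurrenceRecord],
                        max_km: float = DEFAULT_MAX_PRECISION_KM,
                        sources: tuple[str, ...] | None = None,
                        ) -> list[OccurrenceRecord]:
    """Keep records whose coordinate precision is at or below ``max_km``.

    Optionally restrict to given source types (e.g. observations and
    specimens) first.  The number of discarded records is logged.
    """
    pool = [r for r in records if sources is None or r.source in sources]
    kept = [r for r in pool if coordinate_precision(r) <= max_km]
    logger.info("precision filter (<= %g km): kept %d of %d records",
                max_km, len(kept), len(pool))
    return kept


def _block_indices(lats, lons, block_km: float,
                   anchor: tuple[float, float] | None = None):
    """Equal-area block index (bi, bj) per point.

    Points are projected with a Lambert azimuthal equal-area projection
    anchored at the data centroid (or an explicit anchor) and binned into
    a square ``block_km`` lattice whose central block is centred on the
    anchor (so a tight cluster at the centroid shares one block); floor
    binning breaks boundary ties toward the lower-index block.
    """
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    if anchor is None:
        anchor = (float(lats.mean()), float(lons.mean()))
    x, y = laea_forward(lats, lons, anchor[0], anchor[1])
    bi = np.floor((np.asarray(x) + block_km / 2) / block_km).astype(int)
    bj = np.floor((np.asarray(y) + block_km / 2) / block_km).astype(int)
    return bi, bj, anchor


def spatial_thin(records: list[OccurrenceRecord],
                 block_km: float = DEFAULT_BLOCK_KM,
                 max_per_block: int = 3,
                 seed: int = 0) -> list[OccurrenceRecord]:
    """Retain at most ``max_per_block`` records per equal-area block.

    Within each block the retained subset is a seeded uniform draw
    without replacement; the result is deterministic given the seed.
    """
    if block_km <= 0:
        raise ValueError("block size must be positive")
    if max_per_block < 1:
        raise ValueError("max_per_block must be >= 1")
    if not records:
        return []
    bi, bj, _ = _block_indices([r.latitude for r in records],
                               [r.longitude for r in records], block_km)
    rng = np.random.default_rng(seed)
    blocks: dict[tuple[int, int], list[int]] = {}
    for idx, key in enumerate(zip(bi.tolist(), bj.tolist())):
        blocks.setdefault(key, []).append(idx)
    keep: list[int] = []
    for key in sorted(blocks):
        members = blocks[key]
        if len(members) <= max_per_block:
            keep.extend(members)
        else:
            keep.extend(rng.choice(members, size=max_per_block,
                                   replace=False).tolist())
    kept = [records[i] for i in sorted(keep)]
    logger.info("thinning (%g km blocks, max %d): kept %d of %d",
                block_km, max_per_block, len(kept), len(records))
    return kept


def _sample_point_in(geom, bounds, rng, prepared=None, max_tries: int = 200):
    """Uniform point inside geom ∩ the given bounding box, by rejection."""
    minx, miny, maxx, maxy = bounds
    test = prepared if prepared is not None else prep(geom)
    for _ in range(max_tries):
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if test.contains(p):
            return p
    # degenerate slivers: fall back to a deterministic interior point
    return geom.representative_point()


def _stratified_sample(region, block_km: float, seed: int):
    """One uniform point per occupied block of a projected region.

    ``region`` is a shapely geometry in projected (km) coordinates.
    Returns a list of projected Points, ordered by block index.
    """
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = region.bounds
    i0, i1 = int(np.floor(minx / block_km)), int(np.floor(maxx / block_km))
    j0, j1 = int(np.floor(miny / block_km)), int(np.floor(maxy / block_km))
    prepared = prep(region)
    pts = []
    from shapely.geometry import box
    for i in range(i0, i1 + 1):
        for j in range(j0, j1 + 1):
            cell = box(i * block_km, j * block_km,
                       (i + 1) * block_km, (j + 1) * block_km)
            piece = region.intersection(cell)
            if piece.is_empty or piece.area <= 0:
                continue
            pts.append(_sample_point_in(piece, piece.bounds, rng))
    return pts


def _project_polygon(outline, anchor, densify_deg: float = 0.02):
    """Project a lon/lat polygon to local LAEA km coordinates.

    Boundaries are densified first so projected edges follow the true
    (curved) image of the geographic boundary closely rather than cutting
    chords between distant vertices.
    """
    import shapely
    from shapely.ops import transform

    dense = shapely.segmentize(outline, densify_deg)

    def fwd(x, y):
        px, py = laea_forward(np.asarray(y), np.asarray(x), anchor[0], anchor[1])
        return px, py

    return transform(fwd, dense)


def sample_outline(outline, species: str = "sp",
                   block_km: float = DEFAULT_BLOCK_KM,
                   seed: int = 0) -> list[OccurrenceRecord]:
    """Geographically stratified presences from a range outline.

    One random point per ``block_km`` × ``block_km`` equal-area block that
    the outline polygon occupies.  ``outline`` is a shapely (multi)polygon
    in lon/lat coordinates (x=lon, y=lat).
    """
    if outline.is_empty or outline.area <= 0:
        raise ValueError("degenerate range outline")
    anchor = (outline.centroid.y, outline.centroid.x)
    region = _project_polygon(outline, anchor)
    pts = _stratified_sample(region, block_km, seed)
    out = []
    for p in pts:
        lat, lon = laea_inverse(p.x, p.y, anchor[0], anchor[1])
        out.append(OccurrenceRecord(species=species, latitude=float(lat),
                                    longitude=float(lon), digits_lat=6,
                                    digits_lon=6, source="outline_sample"))
    return out


def sample_pseudo_absences(outline, continent_mask, species: str = "sp",
                           block_km: float = DEFAULT_BLOCK_KM,
                           seed: int = 0) -> list[OccurrenceRecord]:
    """Pseudo-absences outside the range outline, inside the continent mask.

    One random point per occupied equal-area block of
    (continent_mask − outline); both geometries are shapely polygons in
    lon/lat coordinates.
    """
    if continent_mask.is_empty:
        raise ValueError("empty continent mask")
    allowed = continent_mask.difference(outline)
    if allowed.is_empty or allowed.area <= 0:
        return []
    anchor = (continent_mask.centroid.y, continent_mask.centroid.x)
    region = _project_polygon(allowed, anchor)
    pts = _stratified_sample(region, block_km, seed)
    out = []
    for p in pts:
        lat, lon = laea_inverse(p.x, p.y, anchor[0], anchor[1])
        out.append(OccurrenceRecord(species=species, latitude=float(lat),
                                    longitude=float(lon), digits_lat=6,
                                    digits_lon=6, source="outline_sample"))
    return out


# ---------------------------------------------------------------------------
# delimited-text interchange
# ---------------------------------------------------------------------------

FIELDNAMES = ("species", "lat", "lon", "digits_lat", "digits_lon", "source")


def write_records(records: list[OccurrenceRecord], path: str | Path,
                  kept: set[int] | None = None) -> None:
    """Write records as tab-delimited text (with optional kept_flag)."""
    fields = list(FIELDNAMES) + (["kept_flag"] if kept is not None else [])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(fields)
        for i, r in enumerate(records):
            row = [r.species, repr(r.latitude), repr(r.longitude),
                   r.digits_lat, r.digits_lon, r.source]
            if kept is not None:
                row.append(int(i in kept))
            w.writerow(row)


def read_records(path: str | Path) -> list[OccurrenceRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(OccurrenceRecord(
                species=row["species"], latitude=float(row["lat"]),
                longitude=float(row["lon"]),
                digits_lat=int(row["digits_lat"]),
                digits_lon=int(row["digits_lon"]), source=row["source"]))
    return out
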