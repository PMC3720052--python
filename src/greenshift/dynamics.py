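"""Range dynamics: suitability time series, migration lags, spread.

Three complementary views of how a species' realized range chases its
climatically suitable area:

* a time series of binary suitability grids yields suitable-cell counts
  per slice, the first slice at which suitable climate appears, and —
  combined with a (pollen-dated) arrival time — the immigration lag;
* a distance-based view converts the great-circle (or barrier-aware
  land-path) distance from the current range front into likely-colonized
  area under an assumed spread rate, migration-lag maps (distance/rate)
  and required-rate maps (distance/horizon);
* a seeded cellular-automaton simulation spreads occupancy over
  per-step suitability grids with a distance-class dispersal kernel and
  a maturity delay, in decadal steps.

Time handling: slice labels for the past are kyr before present; the
lag arithmetic works on that axis and converts to years at the
interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import haversine_km, nearest_great_circle_km
from .grids import GridSpec


# ---------------------------------------------------------------------------
# suitability series
# ---------------------------------------------------------------------------

@dataclass
class SuitabilitySeries:
    """Time-ordered binary suitability grids for one species.

    ``times`` are numeric labels on a single strictly-ordered axis
    (e.g. kyr BP, descending toward the present, or calendar decades
    ascending); ``grids`` are boolean arrays sharing one lattice.
    """

    times: list[float]
    grids: list[np.ndarray]
    species: str = ""
    agreement_level: int = 3

    def __post_init__(self):
        if len(self.times) != len(self.grids):
            raise ValueError("one grid per time label required")
        shapes = {np.asarray(g).shape for g in self.grids}
        if len(shapes) > 1:
            raise ValueError("all grids must share a lattice")
        diffs = np.diff(self.times)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("time labels must be strictly ordered")
        self.grids = [np.asarray(g, bool) for g in self.grids]


def suitable_cell_counts(series: SuitabilitySeries) -> pd.DataFrame:
    """Per-slice suitable-cell counts, as a (time, count) table."""
    return pd.DataFrame({
        "time": series.times,
        "count": [int(g.sum()) for g in series.grids],
    })


def first_suitable_time(series: SuitabilitySeries,
                        min_cells: int = 1) -> float | None:
    """Earliest slice whose suitable-cell count reaches ``min_cells``.

    "Earliest" is the first entry in the series' time order; returns None
    if no slice ever qualifies.
    """
    for t, g in zip(series.times, series.grids):
        if int(g.sum()) >= min_cells:
            return t
    return None


def immigration_lag(first_suitable_kyr: float, arrival_kyr: float) -> float:
    """Lag in years between suitable climate and (pollen-dated) arrival.

    Both times are kyr BP; arrival can be no earlier than first
    suitability on the BP axis (a negative lag is flagged as an error).
    """
    lag_kyr = first_suitable_kyr - arrival_kyr
    if lag_kyr < 0:
        raise ValueError(
            f"arrival ({arrival_kyr} kyr BP) precedes first suitability "
            f"({first_suitable_kyr} kyr BP): negative lag")
    return lag_kyr * 1000.0


# ---------------------------------------------------------------------------
# distance-based colonization
# ---------------------------------------------------------------------------

def distance_to_front(occupied: np.ndarray, targets: np.ndarray,
                      spec: GridSpec, mode: str = "great_circle",
                      barrier: np.ndarray | None = None) -> np.ndarray:
    """Distance (km) from each target cell to the nearest occupied cell.

    ``great_circle``: haversine to the nearest occupied cell centre.
    ``land_path``: length of the shortest 8-neighbour path over
    non-barrier cells, each step weighted by the great-circle distance
    between cell centres (∞ where unreachable).  Returns NaN outside the
    target mask.
    """
    occupied = np.asarray(occupied, bool)
    targets = np.asarray(targets, bool)
    if not occupied.any():
        raise ValueError("occupied set is empty")
    out = np.full(spec.shape, np.nan)
    if mode == "great_circle":
        orows, ocols = np.nonzero(occupied)
        trows, tcols = np.nonzero(targets)
        if trows.size == 0:
            return out
        olat, olon = spec.cell_latlon(orows, ocols)
        tlat, tlon = spec.cell_latlon(trows, tcols)
        out[trows, tcols] = nearest_great_circle_km(tlat, tlon, olat, olon)
        return out
    if mode == "land_path":
        dist = _land_path_distances(occupied, spec, barrier)
        out[targets] = dist[targets]
        return out
    raise ValueError(f"unknown distance mode {mode!r}")


def _land_path_distances(occupied: np.ndarray, spec: GridSpec,
                         barrier: np.ndarray | None) -> np.ndarray:
    """Multi-source shortest-path km over the 8-neighbour cell graph."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    passable = np.ones(spec.shape, bool) if barrier is None else ~np.asarray(
        barrier, bool)
    n_rows, n_cols = spec.shape
    idx = np.arange(n_rows * n_cols).reshape(spec.shape)
    lat = np.repeat(spec.lat_centers[:, None], n_cols, axis=1)
    lon = np.repeat(spec.lon_centers[None, :], n_rows, axis=0)
    rows_src, cols_dst, weights = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0 = slice(max(0, -dr), n_rows - max(0, dr))
        r1 = slice(max(0, dr), n_rows - max(0, -dr))
        c0 = slice(max(0, -dc), n_cols - max(0, dc))
        c1 = slice(max(0, dc), n_cols - max(0, -dc))
        ok = passable[r0, c0] & passable[r1, c1]
        a, b = idx[r0, c0][ok], idx[r1, c1][ok]
        w = haversine_km(lat[r0, c0][ok], lon[r0, c0][ok],
                         lat[r1, c1][ok], lon[r1, c1][ok])
        rows_src.append(a)
        cols_dst.append(b)
        weights.append(np.atleast_1d(w))
    a = np.concatenate(rows_src)
    b = np.concatenate(cols_dst)
    w = np.concatenate(weights)
    n = n_rows * n_cols
    graph = coo_matrix((np.concatenate([w, w]),
                        (np.concatenate([a, b]), np.concatenate([b, a]))),
                       shape=(n, n)).tocsr()
    sources = idx[np.asarray(occupied, bool) & passable]
    if sources.size == 0:
        raise ValueError("no occupied cell lies on passable terrain")
    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
    return dist.reshape(spec.shape)


def likely_colonized(current: np.ndarray, suitable: np.ndarray,
                     spec: GridSpec, rate_km_yr: float, horizon_yr: float,
                     mode: str = "great_circle",
                     barrier: np.ndarray | None = None) -> np.ndarray:
    """Suitable cells reachable from the current range within the horizon.

    A cell is likely colonized if its distance to the current range front
    is at most rate × horizon.  Cells already occupied and suitable count
    as colonized (distance 0).
    """
    if rate_km_yr <= 0 or horizon_yr <= 0:
        raise ValueError("rate and horizon must be positive")
    dist = distance_to_front(current, suitable, spec, mode=mode,
                             barrier=barrier)
    with np.errstate(invalid="ignore"):
        return np.asarray(suitable, bool) & (dist <= rate_km_yr * horizon_yr)


def migration_lag_map(current: np.ndarray, suitable: np.ndarray,
                      spec: GridSpec, rate_km_yr: float,
                      mode: str = "great_circle",
                      barrier: np.ndarray | None = None) -> np.ndarray:
    """Years needed to reach each suitable cell at the given rate."""
    if rate_km_yr <= 0:
        raise ValueError("rate must be positive")
    dist = distance_to_front(current, suitable, spec, mode=mode,
                             barrier=barrier)
    return dist / rate_km_yr


def required_rate_map(current: np.ndarray, suitable: np.ndarray,
                      spec: GridSpec, horizon_yr: float,
                      mode: str = "great_circle",
                      barrier: np.ndarray | None = None) -> np.ndarray:
    """Rate (km/yr) needed to reach each suitable cell within the horizon."""
    if horizon_yr <= 0:
        raise ValueError("horizon must be positive")
    dist = distance_to_front(current, suitable, spec, mode=mode,
                             barrier=barrier)
    return dist / horizon_yr


def colonization_summary(lag_map: np.ndarray, rate_map: np.ndarray) -> dict:
    """Species-level summaries: time/rate to reach *all* suitable area.

    ``lag_to_all`` is the maximum cellwise lag (the paper-style "time to
    reach all areas climatically suitable"); the median is also reported
    for distribution-style summaries.
    """
    lags = lag_map[np.isfinite(lag_map)]
    rates = rate_map[np.isfinite(rate_map)]
    return {
        "lag_to_all_yr": float(lags.max()) if lags.size else float("nan"),
        "lag_median_yr": float(np.median(lags)) if lags.size else float("nan"),
        "required_rate_to_all_km_yr": float(rates.max()) if rates.size
        else float("nan"),
        "required_rate_median_km_yr": float(np.median(rates)) if rates.size
        else float("nan"),
    }


# ---------------------------------------------------------------------------
# cellular-automaton spread
# ---------------------------------------------------------------------------

@dataclass
class DispersalParams:
    """Distance-class dispersal kernel for the spread automaton.

    ``kernel`` maps Chebyshev cell distance → per-source colonization
    probability; ``maturity_delay`` is the number of steps a newly
    colonized cell waits before emitting propagules; ``step_years`` is the
    simulated length of one step (decadal by default).
    """

    kernel: dict[int, float]
    maturity_delay: int = 0
    step_years: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not self.kernel:
            raise ValueError("kernel must be non-empty")
        for d, p in self.kernel.items():
            if d < 0 or not (0.0 <= p <= 1.0):
                raise ValueError("kernel: distances >= 0, probabilities in [0,1]")

    @property
    def max_distance(self) -> int:
        return max(self.kernel)


@dataclass
class SpreadState:
    """Result of a spread simulation.

    ``colonized_step`` holds the step index at which each cell first
    became occupied (−1 = never); ``occupancy`` is the per-step stack of
    boolean occupancy grids (step 0 = initial state after the first
    suitability cull).
    """

    occupancy: np.ndarray          # (n_steps+1, rows, cols) bool
    colonized_step: np.ndarray     # (rows, cols) int
    params: DispersalParams

    @property
    def final(self) -> np.ndarray:
        return self.occupancy[-1]


def _ring_kernels(kernel: dict[int, float]) -> list[tuple[np.ndarray, float]]:
    """(footprint, probability) per Chebyshev distance class."""
    rings = []
    for d, p in sorted(kernel.items()):
        if p <= 0:
            continue
        if d == 0:
            continue  # a cell cannot colonize itself
        size = 2 * d + 1
        fp = np.ones((size, size), bool)
        if d > 1:
            fp[1:-1, 1:-1] = False  # keep only the ring at distance exactly d
        else:
            fp[d, d] = False
        rings.append((fp, p))
    return rings


def simulate_spread(initial: np.ndarray, suitability,
                    params: DispersalParams, n_steps: int | None = None,
                    barrier: np.ndarray | None = None) -> SpreadState:
    """Cellular-automaton range spread under shifting suitability.

    Per step: occupied cells persist only while suitable; every occupied
    cell older than the maturity delay attempts to colonize each empty,
    suitable, non-barrier cell within the kernel.  With ``n_d`` mature
    sources at distance class d of a target, the per-step colonization
    probability is 1 − Π_d (1 − p_d)^{n_d} (independent per-source
    Bernoulli draws, aggregated); one seeded uniform draw per target
    decides.  Identical seeds replay bit-identically.

    ``suitability`` is either a single boolean grid (static) or a
    sequence of per-step grids; ``n_steps`` defaults to the number of
    suitability slices.
    """
    from scipy.ndimage import convolve

    initial = np.asarray(initial, bool)
    if isinstance(suitability, np.ndarray) and suitability.ndim == 2:
        if n_steps is None:
            raise ValueError("n_steps required with a static suitability grid")
        suit_seq = [np.asarray(suitability, bool)] * n_steps
    else:
        suit_seq = [np.asarray(s, bool) for s in suitability]
        if n_steps is not None:
            if n_steps > len(suit_seq):
                raise ValueError("n_steps exceeds the suitability sequence")
            suit_seq = suit_seq[:n_steps]
    if any(s.shape != initial.shape for s in suit_seq):
        raise ValueError("suitability lattices must match the initial grid")
    passable = np.ones(initial.shape, bool) if barrier is None else ~np.asarray(
        barrier, bool)

    rng = np.random.default_rng(params.seed)
    rings = _ring_kernels(params.kernel)

    occupied = initial & suit_seq[0] & passable if suit_seq else initial & passable
    colonized_step = np.where(occupied, 0, -1)
    age = np.zeros(initial.shape, int)
    frames = [occupied.copy()]
    for step, suit in enumerate(suit_seq, start=1):
        # mortality: occupied cells that lose suitability die
        survivors = occupied & suit & passable
        age = np.where(survivors, age, 0)
        mature = survivors & (age >= params.maturity_delay)
        # colonization pressure on empty, suitable, passable cells
        p_fail = np.ones(initial.shape)
        for fp, p in rings:
            n_src = convolve(mature.astype(np.int32), fp.astype(np.int32),
                             mode="constant", cval=0)
            p_fail = p_fail * (1.0 - p) ** n_src
        target = (~survivors) & suit & passable
        draws = rng.random(initial.shape)
        newly = target & (draws < 1.0 - p_fail)
        occupied = survivors | newly
        colonized_step = np.where(newly & (colonized_step < 0), step,
                                  colonized_step)
        age = np.where(survivors, age + 1, np.where(newly, 0, age))
        frames.append(occupied.copy())
    return SpreadState(occupancy=np.stack(frames),
                       colonized_step=colonized_step, params=params)
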