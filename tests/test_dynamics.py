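"""Suitability series, lags, distance maps and the spread automaton."""

from collections import deque

import numpy as np
import pytest

from greenshift import (DispersalParams, GridSpec, SuitabilitySeries,
                        distance_to_front, first_suitable_time,
                        immigration_lag, likely_colonized, migration_lag_map,
                        required_rate_map, simulate_spread,
                        suitable_cell_counts)
from greenshift.dynamics import colonization_summary
from greenshift.geometry import haversine_km


def bfs_ball(initial, suitable, t):
    """Independent BFS oracle: cells reachable in ≤ t 8-neighbour steps
    through suitable cells."""
    rows, cols = suitable.shape
    depth = {}
    q = deque()
    for r, c in zip(*np.nonzero(initial & suitable)):
        depth[(r, c)] = 0
        q.append((r, c))
    while q:
        r, c = q.popleft()
        if depth[(r, c)] >= t:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if (0 <= rr < rows and 0 <= cc < cols and suitable[rr, cc]
                        and (rr, cc) not in depth):
                    depth[(rr, cc)] = depth[(r, c)] + 1
                    q.append((rr, cc))
    out = np.zeros_like(suitable)
    for (r, c), d in depth.items():
        if d <= t:
            out[r, c] = True
    return out


@pytest.fixture
def spec():
    return GridSpec(lat0=0.0, lon0=0.0, cellsize=0.5, n_rows=10, n_cols=10)


def _series(counts, shape=(4, 4), times=None):
    grids = []
    for n in counts:
        g = np.zeros(shape, bool)
        g.ravel()[:n] = True
        grids.append(g)
    if times is None:
        times = list(range(len(counts), 0, -1))  # descending kyr BP
    return SuitabilitySeries(times=times, grids=grids)


class TestSuitabilitySeries:
    def test_counts_table(self):
        tab = suitable_cell_counts(_series([0, 3, 9]))
        assert tab["count"].tolist() == [0, 3, 9]

    def test_first_suitable_time(self):
        s = _series([0, 0, 2, 5], times=[21, 15, 9, 6])
        assert first_suitable_time(s) == 9

    def test_first_suitable_with_min_cells(self):
        s = _series([0, 4, 12, 16], times=[21, 15, 9, 6])
        assert first_suitable_time(s, min_cells=10) == 9

    def test_never_suitable_returns_none(self):
        assert first_suitable_time(_series([0, 0, 0])) is None

    def test_unordered_times_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            _series([1, 1], times=[5, 5])


class TestImmigrationLag:
    @pytest.mark.parametrize("first,arrival,lag", [(9, 4, 5000.0),
                                                   (4, 4, 0.0),
                                                   (15, 2, 13000.0)])
    def test_lag_arithmetic(self, first, arrival, lag):
        assert immigration_lag(first, arrival) == lag

    def test_arrival_before_suitability_flagged(self):
        with pytest.raises(ValueError, match="negative lag"):
            immigration_lag(4, 9)


class TestDistanceToFront:
    def test_occupied_targets_have_zero_distance(self, spec):
        occ = np.zeros(spec.shape, bool)
        occ[5, 5] = True
        d = distance_to_front(occ, occ, spec)
        assert d[5, 5] == 0.0

    def test_equatorial_neighbour_distance(self, spec):
        # cell centres 0.5 deg apart on the equator row
        occ = np.zeros(spec.shape, bool)
        tgt = np.zeros(spec.shape, bool)
        occ[0, 0] = True
        tgt[0, 1] = True
        d = distance_to_front(occ, tgt, spec)
        lat, _ = spec.cell_latlon(0, 0)
        expect = haversine_km(lat, 0.0, lat, 0.5)
        assert d[0, 1] == pytest.approx(float(expect), rel=1e-9)
        assert d[0, 1] == pytest.approx(55.6, abs=0.2)

    def test_land_path_dominates_great_circle(self, spec):
        rng = np.random.default_rng(0)
        occ = np.zeros(spec.shape, bool)
        occ[0, 0] = True
        tgt = np.ones(spec.shape, bool)
        barrier = rng.random(spec.shape) < 0.2
        barrier[0, 0] = False
        gc = distance_to_front(occ, tgt, spec, mode="great_circle")
        lp = distance_to_front(occ, tgt, spec, mode="land_path",
                               barrier=barrier)
        ok = np.isfinite(lp)
        assert np.all(lp[ok] >= gc[ok] - 1e-9)

    def test_empty_occupied_rejected(self, spec):
        with pytest.raises(ValueError, match="empty"):
            distance_to_front(np.zeros(spec.shape, bool),
                              np.ones(spec.shape, bool), spec)


class TestDistanceIdentities:
    def test_rate_and_lag_maps_reproduce_distances(self, spec):
        occ = np.zeros(spec.shape, bool)
        occ[9, :3] = True
        suit = np.ones(spec.shape, bool)
        dist = distance_to_front(occ, suit, spec)
        lag = migration_lag_map(occ, suit, spec, rate_km_yr=0.25)
        req = required_rate_map(occ, suit, spec, horizon_yr=90.0)
        # exact up to one floating-point rounding of the divide/multiply pair
        np.testing.assert_array_equal(lag * 0.25, dist)  # 0.25 is a power of 2
        np.testing.assert_allclose(req * 90.0, dist, rtol=1e-15)

    def test_scalar_examples(self):
        assert 500.0 / 0.25 == 2000.0          # lag years at 0.25 km/yr
        assert 900.0 / 90.0 == 10.0            # required rate km/yr

    def test_colonized_monotone_in_rate_and_horizon(self, spec):
        occ = np.zeros(spec.shape, bool)
        occ[5, 5] = True
        suit = np.ones(spec.shape, bool)
        prev = None
        for rate in (0.1, 0.5, 2.0, 10.0):
            cur = likely_colonized(occ, suit, spec, rate, 100.0)
            if prev is not None:
                assert np.all(prev <= cur)
            prev = cur
        prev = None
        for horizon in (10.0, 50.0, 200.0):
            cur = likely_colonized(occ, suit, spec, 1.0, horizon)
            if prev is not None:
                assert np.all(prev <= cur)
            prev = cur

    def test_saturation_when_reach_exceeds_extent(self, spec):
        occ = np.zeros(spec.shape, bool)
        occ[5, 5] = True
        suit = np.ones(spec.shape, bool)
        col = likely_colonized(occ, suit, spec, rate_km_yr=100.0,
                               horizon_yr=100.0)
        np.testing.assert_array_equal(col, suit)

    def test_summary_reports_max_and_median(self, spec):
        occ = np.zeros(spec.shape, bool)
        occ[0, 0] = True
        suit = np.ones(spec.shape, bool)
        lag = migration_lag_map(occ, suit, spec, 1.0)
        req = required_rate_map(occ, suit, spec, 90.0)
        s = colonization_summary(lag, req)
        assert s["lag_to_all_yr"] == np.nanmax(lag)
        assert s["required_rate_to_all_km_yr"] == np.nanmax(req)


class TestSimulateSpread:
    def test_no_dispersal_kernel_keeps_initial_intersection(self):
        init = np.zeros((6, 6), bool)
        init[2, 2] = init[3, 3] = True
        suit = np.ones((6, 6), bool)
        suit[3, 3] = False
        st = simulate_spread(init, suit, DispersalParams(kernel={0: 1.0}),
                             n_steps=4)
        expect = init & suit
        np.testing.assert_array_equal(st.final, expect)

    def test_probability_one_front_advances_like_bfs(self):
        rng = np.random.default_rng(1)
        suit = rng.random((20, 20)) < 0.75
        init = np.zeros((20, 20), bool)
        init[10, 10] = True
        suit[10, 10] = True
        params = DispersalParams(kernel={1: 1.0}, seed=0)
        st = simulate_spread(init, suit, params, n_steps=8)
        for t in range(9):
            np.testing.assert_array_equal(st.occupancy[t],
                                          bfs_ball(init, suit, t))

    def test_total_unsuitability_causes_extinction(self):
        init = np.ones((4, 4), bool)
        suit = np.zeros((4, 4), bool)
        st = simulate_spread(init, suit, DispersalParams(kernel={1: 1.0}),
                             n_steps=2)
        assert not st.final.any()

    def test_never_occupies_barrier_or_unsuitable(self):
        rng = np.random.default_rng(2)
        suit = rng.random((15, 15)) < 0.6
        barrier = rng.random((15, 15)) < 0.2
        init = np.zeros((15, 15), bool)
        init[7, 7] = True
        suit[7, 7], barrier[7, 7] = True, False
        params = DispersalParams(kernel={1: 0.6, 2: 0.2}, seed=3)
        st = simulate_spread(init, suit, params, n_steps=10, barrier=barrier)
        assert not (st.occupancy.any(axis=0) & barrier).any()
        assert not (st.final & ~suit).any()

    def test_identical_seed_replays_bit_identically(self):
        rng = np.random.default_rng(4)
        suit = rng.random((12, 12)) < 0.8
        init = np.zeros((12, 12), bool)
        init[6, 6] = True
        suit[6, 6] = True
        params = DispersalParams(kernel={1: 0.4, 2: 0.1}, seed=9)
        a = simulate_spread(init, suit, params, n_steps=12)
        b = simulate_spread(init, suit, params, n_steps=12)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)
        np.testing.assert_array_equal(a.colonized_step, b.colonized_step)
        c = simulate_spread(init, suit,
                            DispersalParams(kernel={1: 0.4, 2: 0.1}, seed=10),
                            n_steps=12)
        assert not np.array_equal(a.occupancy, c.occupancy)

    def test_maturity_delay_slows_the_front(self):
        init = np.zeros((3, 9), bool)
        init[:, 0] = True
        suit = np.ones((3, 9), bool)
        fast = simulate_spread(init, suit, DispersalParams(kernel={1: 1.0}),
                               n_steps=4)
        slow = simulate_spread(init, suit,
                               DispersalParams(kernel={1: 1.0},
                                               maturity_delay=1),
                               n_steps=4)
        assert fast.final.sum() > slow.final.sum()

    def test_colonization_steps_increase_outward(self):
        init = np.zeros((9, 9), bool)
        init[4, 4] = True
        suit = np.ones((9, 9), bool)
        st = simulate_spread(init, suit, DispersalParams(kernel={1: 1.0}),
                             n_steps=6)
        cheb = np.maximum(np.abs(np.arange(9) - 4)[:, None],
                          np.abs(np.arange(9) - 4)[None, :])
        np.testing.assert_array_equal(st.colonized_step, cheb)

    def test_empty_kernel_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            DispersalParams(kernel={})
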