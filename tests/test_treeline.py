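"""Treeline algorithm: daily interpolation, season criteria, elevation scan."""

import numpy as np
import pytest

from greenshift import (GridSpec, TreelineParams, below_treeline_mask,
                        layer_agreement, monthly_to_daily, potential_treeline,
                        season_stats, treeline_surface)
from greenshift.grids import (MASK_ICE, MASK_LAND, MASK_SEA, MONTH_DAYS,
                              ClimateGrid, ElevationGrid)
from greenshift.treeline import season_qualifies

from conftest import random_monthly_profile


def brute_force_treeline(monthly, reference_elevation, params):
    """Literal day-by-day, step-by-step oracle for the elevation scan."""
    best = float("nan")
    z = params.z_min
    while z <= params.z_max + 1e-9:
        shift = params.lapse_rate * (z - reference_elevation)
        daily = monthly_to_daily(monthly) - shift
        days = [d for d in daily if d >= params.day_threshold]
        if len(days) >= params.min_season_days:
            mean = sum(days) / len(days)
            if mean >= params.season_mean_threshold - 1e-9:
                best = z
        z += params.z_step
    return best


class TestMonthlyToDaily:
    def test_constant_input_constant_output(self):
        daily = monthly_to_daily(np.full(12, 5.0))
        assert daily.shape == (365,)
        np.testing.assert_allclose(daily, 5.0)

    def test_bounded_by_monthly_extremes(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            monthly = rng.normal(0, 10, size=12)
            daily = monthly_to_daily(monthly)
            assert daily.min() >= monthly.min() - 1e-12
            assert daily.max() <= monthly.max() + 1e-12

    def test_midpoint_days_anchor_monthly_means(self):
        rng = np.random.default_rng(1)
        monthly = rng.normal(0, 10, size=12)
        daily = monthly_to_daily(monthly)
        mids = np.cumsum(MONTH_DAYS) - MONTH_DAYS / 2.0
        day_centres = np.arange(365) + 0.5
        # months whose mid-point lands exactly on a sampled day centre
        on_grid = np.isin(mids, day_centres)
        sampled = daily[np.searchsorted(day_centres, mids[on_grid])]
        np.testing.assert_allclose(sampled, monthly[on_grid], atol=1e-12)
        # the rest sit between two day centres; the chord error stays small
        interp_at_mid = np.interp(mids, day_centres, daily)
        np.testing.assert_allclose(interp_at_mid, monthly, atol=0.5)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            monthly_to_daily([np.nan] * 12)


class TestSeasonCriteria:
    def _series(self, n_days, value, rest=-10.0):
        d = np.full(365, rest)
        d[:n_days] = value
        return d

    def test_equality_at_both_thresholds_qualifies(self):
        d = self._series(94, 6.4)
        length, mean = season_stats(d)
        assert length == 94
        assert season_qualifies(d)

    def test_one_day_short_fails(self):
        assert not season_qualifies(self._series(93, 6.4))

    def test_mean_just_below_fails(self):
        assert not season_qualifies(self._series(94, 6.39))

    def test_all_cold_season_is_empty(self):
        length, mean = season_stats(np.zeros(365))  # 0 °C < 0.9 °C threshold
        assert length == 0
        assert np.isnan(mean)

    def test_long_cool_season_fails_mean_criterion(self):
        d = self._series(100, 5.0)
        length, mean = season_stats(d)
        assert (length, mean) == (100, 5.0)
        assert not season_qualifies(d)

    def test_longest_run_definition_drops_disjoint_days(self):
        d = np.full(365, -10.0)
        d[10:50] = 8.0    # 40-day run
        d[200:230] = 8.0  # 30-day run
        params = TreelineParams(season_definition="longest_run")
        length, _ = season_stats(d, params)
        assert length == 40
        all_days_length, _ = season_stats(d)
        assert all_days_length == 70

    def test_longest_run_wraps_year_boundary(self):
        d = np.full(365, -10.0)
        d[340:] = 8.0
        d[:30] = 8.0
        params = TreelineParams(season_definition="longest_run")
        length, _ = season_stats(d, params)
        assert length == 55


class TestPotentialTreeline:
    def test_cold_climate_has_no_treeline(self):
        monthly = np.full(12, -5.0)
        assert np.isnan(potential_treeline(monthly, 0.0))

    def test_warming_by_one_step_lapse_raises_one_step(self):
        params = TreelineParams()
        monthly = 8.0 + 12.0 * np.cos(2 * np.pi * (np.arange(1, 13) - 7) / 12)
        z0 = potential_treeline(monthly, 0.0, params)
        z1 = potential_treeline(monthly + params.lapse_rate * params.z_step,
                                0.0, params)
        assert np.isfinite(z0) and z0 < params.z_max
        assert z1 == z0 + params.z_step

    def test_matches_brute_force_oracle_on_random_profiles(self):
        rng = np.random.default_rng(42)
        params = TreelineParams()
        for _ in range(30):
            monthly = random_monthly_profile(rng)
            ref = rng.uniform(0, 500)
            got = potential_treeline(monthly, ref, params)
            want = brute_force_treeline(monthly, ref, params)
            assert got == want or (np.isnan(got) and np.isnan(want))

    def test_monotone_in_uniform_warming(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            monthly = random_monthly_profile(rng)
            z0 = potential_treeline(monthly, 0.0)
            z1 = potential_treeline(monthly + 1.0, 0.0)
            if np.isfinite(z0):
                assert np.isfinite(z1) and z1 >= z0

    def test_qualifying_elevations_are_downward_closed(self):
        rng = np.random.default_rng(4)
        params = TreelineParams()
        daily_base = monthly_to_daily(random_monthly_profile(rng) + 5.0)
        quals = []
        for z in params.elevations:
            quals.append(season_qualifies(daily_base - params.lapse_rate * z,
                                          params))
        first_fail = next((i for i, q in enumerate(quals) if not q),
                          len(quals))
        assert all(quals[:first_fail])
        assert not any(quals[first_fail:])


class TestBelowTreelineMask:
    def _surface(self, spec, elev_value, params=TreelineParams()):
        from greenshift.treeline import TreelineSurface

        return TreelineSurface(spec, np.full(spec.shape, elev_value), params)

    def test_no_treeline_gives_empty_mask(self):
        spec = GridSpec(65.0, -50.0, 0.5, 4, 4)
        surf = self._surface(spec, np.nan)
        dem = ElevationGrid(spec, np.zeros(spec.shape))
        mask = below_treeline_mask(surf, dem, np.full(spec.shape, MASK_LAND))
        assert not mask.any()

    def test_low_terrain_below_high_treeline_equals_land_mask(self):
        spec = GridSpec(65.0, -50.0, 0.5, 4, 4)
        surf = self._surface(spec, 500.0)
        dem = ElevationGrid(spec, np.zeros(spec.shape))
        land = np.full(spec.shape, MASK_LAND)
        land[0, 0] = MASK_ICE
        land[3, 3] = MASK_SEA
        mask = below_treeline_mask(surf, dem, land)
        np.testing.assert_array_equal(mask, land == MASK_LAND)

    def test_finer_dem_reveals_subcell_valleys(self):
        # coarse DEM averages out a valley; the fine DEM resolves it
        spec = GridSpec(65.0, -50.0, 1.0, 2, 2)
        surf = self._surface(spec, 300.0)
        coarse = ElevationGrid(spec, np.full(spec.shape, 600.0))
        fine_spec = spec.refined(2)
        fine_vals = np.full(fine_spec.shape, 600.0)
        fine_vals[0, 0] = 100.0  # a valley inside the first climate cell
        fine = ElevationGrid(fine_spec, fine_vals)
        land = np.full(spec.shape, MASK_LAND)
        coarse_area = below_treeline_mask(surf, coarse, land).mean()
        fine_area = below_treeline_mask(surf, fine, land).mean()
        assert fine_area > coarse_area


class TestSurfaceAndAgreement:
    def test_surface_warming_never_lowers_treelines(self, world):
        base = treeline_surface(world.climate)
        warm = treeline_surface(world.climate.with_offset(1.0))
        b, w = base.elevation, warm.elevation
        gained = np.isnan(b) & np.isfinite(w)
        both = np.isfinite(b) & np.isfinite(w)
        assert not (np.isfinite(b) & np.isnan(w)).any()
        assert np.all(w[both] >= b[both])
        assert gained.sum() >= 0

    def test_agreement_counts(self):
        a = np.array([[True, False], [True, True]])
        counts = layer_agreement([a] * 6)
        assert set(np.unique(counts)) <= {0, 6}
        np.testing.assert_array_equal(layer_agreement([a]), a.astype(int))
        np.testing.assert_array_equal(layer_agreement([a, ~a]),
                                      np.ones_like(a, dtype=int))
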