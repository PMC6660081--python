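"""Moving-window slope screen, cutting edges and surface trimming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scleratopo import edge_elimination as ee
from scleratopo import levelling, synthetic_eye as syn
from scleratopo.errors import ConfigurationError, QualityError
from scleratopo.surface_io import MeridianProfile, resample_polar

from .conftest import hemisphere_polar, two_arc_meridian


def naive_windowed_median(values, grid, halfwidth, max_elements):
    """Brute-force reference implementation (sort-based)."""
    half_count = (max_elements - 1) // 2
    out = np.empty(len(values))
    for i in range(len(values)):
        sel = [
            j for j in range(len(values))
            if abs(grid[j] - grid[i]) <= halfwidth + 1e-12
            and abs(j - i) <= half_count
        ]
        out[i] = float(np.median(np.sort([values[j] for j in sel])))
    return out


def naive_windowed_mean(values, grid, halfwidth, max_elements):
    """Literal boundary-shrinking windowed mean: m_i = (1/n) sum a_k."""
    half_count = (max_elements - 1) // 2
    out = np.empty(len(values))
    for i in range(len(values)):
        n_b = 0
        while (n_b < half_count and i - n_b - 1 >= 0
               and grid[i] - grid[i - n_b - 1] <= halfwidth + 1e-12):
            n_b += 1
        n_f = 0
        while (n_f < half_count and i + n_f + 1 < len(values)
               and grid[i + n_f + 1] - grid[i] <= halfwidth + 1e-12):
            n_f += 1
        window = values[i - n_b:i + n_f + 1]
        out[i] = sum(window) / len(window)
    return out


class TestMeridianSlope:
    def test_quadratic_exact_interior(self):
        r = 0.05 * np.arange(101)
        prof = MeridianProfile(angle=0, r=r, z=-r**2,
                               valid=np.ones_like(r, dtype=bool))
        slope = ee.meridian_slope(prof)
        np.testing.assert_allclose(slope[1:-1], -2 * r[1:-1], atol=1e-9)

    def test_constant_zero(self):
        r = 0.05 * np.arange(50)
        prof = MeridianProfile(angle=0, r=r, z=np.full_like(r, 3.0),
                               valid=np.ones_like(r, dtype=bool))
        np.testing.assert_allclose(ee.meridian_slope(prof), 0.0, atol=1e-12)

    def test_sine_second_order(self):
        r = 0.05 * np.arange(200)
        prof = MeridianProfile(angle=0, r=r, z=np.sin(r),
                               valid=np.ones_like(r, dtype=bool))
        slope = ee.meridian_slope(prof)
        assert np.max(np.abs(slope[1:-1] - np.cos(r[1:-1]))) < 0.05**2

    def test_too_few_nodes(self):
        r = np.array([0.0, 0.05, 0.1])
        prof = MeridianProfile(angle=0, r=r, z=r, valid=np.array([1, 0, 1], bool))
        assert ee.meridian_slope(prof) is None


class TestMovingStatistic:
    def test_constant_identity(self):
        grid = 0.05 * np.arange(20)
        vals = np.full(20, 4.2)
        for stat in ("median", "mean"):
            cfg = ee.MovingWindowConfig(statistic=stat)
            np.testing.assert_array_equal(
                ee.moving_statistic(vals, grid, cfg), vals
            )

    def test_spike_rejected_by_median(self):
        vals = np.array([0.0, 0.0, 100.0, 0.0, 0.0])
        grid = 0.05 * np.arange(5)
        cfg = ee.MovingWindowConfig(halfwidth=0.05, max_elements=3,
                                    statistic="median")
        np.testing.assert_array_equal(
            ee.moving_statistic(vals, grid, cfg), np.zeros(5)
        )

    def test_spike_smeared_by_mean(self):
        vals = np.array([0.0, 0.0, 100.0, 0.0, 0.0])
        grid = 0.05 * np.arange(5)
        cfg = ee.MovingWindowConfig(halfwidth=0.05, max_elements=3,
                                    statistic="mean")
        expected = np.array([0.0, 100 / 3, 100 / 3, 100 / 3, 0.0])
        np.testing.assert_allclose(
            ee.moving_statistic(vals, grid, cfg), expected, atol=1e-12
        )

    @given(
        data=st.lists(st.floats(-100, 100, allow_nan=False), min_size=1,
                      max_size=40),
        max_elements=st.sampled_from([3, 5, 11]),
        halfwidth=st.sampled_from([0.06, 0.1, 0.3]),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_median(self, data, max_elements, halfwidth):
        vals = np.array(data)
        grid = 0.05 * np.arange(len(vals))
        cfg = ee.MovingWindowConfig(halfwidth=halfwidth,
                                    max_elements=max_elements,
                                    statistic="median")
        np.testing.assert_array_equal(
            ee.moving_statistic(vals, grid, cfg),
            naive_windowed_median(vals, grid, halfwidth, max_elements),
        )

    @given(
        data=st.lists(st.floats(-100, 100, allow_nan=False), min_size=1,
                      max_size=40),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_literal_mean(self, data):
        vals = np.array(data)
        grid = 0.05 * np.arange(len(vals))
        cfg = ee.MovingWindowConfig(statistic="mean")
        np.testing.assert_allclose(
            ee.moving_statistic(vals, grid, cfg),
            naive_windowed_mean(vals, grid, cfg.halfwidth, cfg.max_elements),
            atol=1e-12,
        )

    def test_nonuniform_grid(self):
        grid = np.array([0.0, 0.04, 0.05, 0.2, 0.21, 0.5])
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        cfg = ee.MovingWindowConfig(halfwidth=0.1, max_elements=3,
                                    statistic="median")
        out = ee.moving_statistic(vals, grid, cfg)
        np.testing.assert_array_equal(
            out, naive_windowed_median(vals, grid, 0.1, 3)
        )

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            ee.MovingWindowConfig(max_elements=4)
        with pytest.raises(ConfigurationError):
            ee.MovingWindowConfig(halfwidth=0.0)
        with pytest.raises(ConfigurationError):
            ee.MovingWindowConfig(threshold_factor=1.0)
        with pytest.raises(ConfigurationError):
            ee.MovingWindowConfig(statistic="mode")


class TestFirstCuttingEdge:
    def _screen(self, prof, cfg=None, start=6.2):
        cfg = cfg or ee.MovingWindowConfig()
        slope = ee.meridian_slope(prof)
        r = prof.r[prof.valid]
        m = ee.moving_statistic(np.abs(slope), r, cfg)
        return ee.first_cutting_edge(m, r, cfg, search_start=start)

    def test_smooth_meridian_none(self):
        prof = two_arc_meridian()
        assert self._screen(prof) is None

    def test_planted_liftoff_found(self):
        prof = two_arc_meridian()
        lift = 1.2 * np.clip((prof.r - 7.5) / 0.25, 0, 1)
        prof = MeridianProfile(angle=0, r=prof.r, z=prof.z + lift,
                               valid=prof.valid)
        r1 = self._screen(prof)
        assert r1 is not None
        assert 7.4 <= r1 <= 7.65

    def test_infinite_threshold_never_fires(self):
        prof = two_arc_meridian()
        lift = 1.2 * np.clip((prof.r - 7.5) / 0.25, 0, 1)
        prof = MeridianProfile(angle=0, r=prof.r, z=prof.z + lift,
                               valid=prof.valid)
        cfg = ee.MovingWindowConfig(threshold_factor=np.inf)
        assert self._screen(prof, cfg=cfg) is None


class TestSecondCuttingEdge:
    def test_monotone_none(self):
        prof = two_arc_meridian()
        assert ee.second_cutting_edge(prof, None, search_start=6.2) is None

    def test_tearpool_dip_found(self):
        prof = two_arc_meridian()
        dip = -0.3 * np.exp(-(((prof.r - 7.0) / 0.2) ** 2))
        lift = 1.2 * np.clip((prof.r - 7.8) / 0.25, 0, 1)
        prof = MeridianProfile(angle=0, r=prof.r, z=prof.z + dip + lift,
                               valid=prof.valid)
        r2 = ee.second_cutting_edge(prof, 7.8, search_start=6.2)
        assert r2 is not None
        assert abs(r2 - 7.0) <= 0.1

    def test_two_minima_innermost_wins(self):
        r = 0.05 * np.arange(201)
        z = -0.5 * r
        z = z - 0.2 * np.exp(-(((r - 6.8) / 0.15) ** 2))
        z = z - 0.2 * np.exp(-(((r - 7.4) / 0.15) ** 2))
        prof = MeridianProfile(angle=0, r=r, z=z, valid=np.ones_like(r, bool))
        r2 = ee.second_cutting_edge(prof, None, search_start=6.2)
        # brute-force scan: innermost strict local minimum beyond the start
        mins = [i for i in range(1, 200)
                if z[i] < z[i - 1] and z[i] < z[i + 1] and r[i] > 6.2]
        assert abs(r2 - r[mins[0]]) <= 0.1
        assert r2 < 7.1

    def test_value_ordering_picks_lowest(self):
        r = 0.05 * np.arange(201)
        z = -0.5 * r
        z = z - 0.1 * np.exp(-(((r - 6.8) / 0.15) ** 2))
        z = z - 0.5 * np.exp(-(((r - 7.4) / 0.15) ** 2))
        prof = MeridianProfile(angle=0, r=r, z=z, valid=np.ones_like(r, bool))
        r2 = ee.second_cutting_edge(prof, None, search_start=6.2,
                                    ordering="value")
        assert abs(r2 - 7.4) <= 0.15

    def test_limit_to_first_edge(self):
        prof = two_arc_meridian()
        dip = -0.3 * np.exp(-(((prof.r - 7.6) / 0.2) ** 2))
        prof = MeridianProfile(angle=0, r=prof.r, z=prof.z + dip,
                               valid=prof.valid)
        # dip lies beyond the first edge -> not a second edge
        assert ee.second_cutting_edge(prof, 7.0, search_start=6.2) is None


class TestUltimateEdge:
    @pytest.mark.parametrize(
        "e1, e2, expected",
        [(7.5, 7.0, 7.0), (7.5, None, 7.5), (None, 7.0, 7.0), (None, None, None)],
    )
    def test_min_of_candidates(self, e1, e2, expected):
        assert ee.ultimate_edge(e1, e2) == expected


class TestTrimSurface:
    def test_no_edges_no_change(self):
        surf = hemisphere_polar()
        edges = ee.detect_edges(surf, 5.95)
        trimmed = ee.trim_surface(surf, edges)
        np.testing.assert_array_equal(trimmed.valid, surf.valid)

    def test_single_meridian_cut(self):
        surf = hemisphere_polar()
        n = surf.n_meridians
        edges = ee.EdgeProfile(
            angles=surf.angles,
            r_edge1=np.full(n, np.nan),
            r_edge2=np.full(n, np.nan),
            r_ultimate=np.where(surf.angles == 30.0, 7.0, np.nan),
            strategy=np.full(n, "none", dtype=object),
            limbus_radius=np.full(n, 5.95),
        )
        trimmed = ee.trim_surface(surf, edges)
        i = surf.angle_index(30.0)
        assert not trimmed.valid[i, surf.r >= 7.0].any()
        assert trimmed.valid[i, surf.r < 7.0].all()
        others = np.arange(n) != i
        np.testing.assert_array_equal(trimmed.valid[others], surf.valid[others])

    def test_majority_cut_raises_quality_error(self):
        surf = hemisphere_polar()
        n = surf.n_meridians
        edges = ee.EdgeProfile(
            angles=surf.angles,
            r_edge1=np.full(n, np.nan),
            r_edge2=np.full(n, np.nan),
            r_ultimate=np.full(n, 2.0),  # inside the limbus
            strategy=np.full(n, "2", dtype=object),
            limbus_radius=np.full(n, 5.95),
        )
        with pytest.raises(QualityError):
            ee.trim_surface(surf, edges)


class TestOperatingCharacteristics:
    def test_planted_ring_liftoff(self):
        recipe = syn.EyeRecipe(
            seed=31, noise_sd=0.005,
            artefacts=[syn.ArtefactSpec(kind="liftoff", onset_radius=7.5,
                                        amplitude=1.2, ramp_width=0.25)],
        )
        cloud, _ = syn.generate_eye(recipe)
        levelled, fit, _ = levelling.level_eye(cloud)
        surf = resample_polar(levelled, center=(0.0, 0.0))
        edges = ee.detect_edges(surf, fit.r_limbus)
        err = edges.r_ultimate - 7.5
        detected = np.isfinite(err)
        assert detected.mean() >= 0.95
        assert np.abs(np.nanmedian(err)) <= 0.1
        trimmed = ee.trim_surface(surf, edges)
        max_r = np.array([
            trimmed.r[trimmed.valid[i]].max() if trimmed.valid[i].any() else np.nan
            for i in range(trimmed.n_meridians)
        ])
        in_band = (max_r >= 7.3) & (max_r <= 7.6)
        assert in_band.mean() >= 0.95

    def test_false_cut_rate_artefact_free(self):
        recipe = syn.EyeRecipe(seed=32, noise_sd=0.005)
        cloud, _ = syn.generate_eye(recipe)
        levelled, fit, _ = levelling.level_eye(cloud)
        surf = resample_polar(levelled, center=(0.0, 0.0))
        edges = ee.detect_edges(surf, fit.r_limbus)
        assert np.isfinite(edges.r_ultimate).mean() < 0.05

    def test_trimming_idempotent(self, artefact_eye):
        cloud, _ = artefact_eye
        levelled, fit, _ = levelling.level_eye(cloud)
        surf = resample_polar(levelled, center=(0.0, 0.0))
        edges = ee.detect_edges(surf, fit.r_limbus)
        trimmed = ee.trim_surface(surf, edges)
        edges2 = ee.detect_edges(trimmed, fit.r_limbus)
        new_cut = np.isfinite(edges2.r_ultimate) & (
            edges2.r_ultimate < np.where(np.isfinite(edges.r_ultimate),
                                         edges.r_ultimate, np.inf) - 0.1
        )
        assert new_cut.mean() <= 0.01
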