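"""Bayesian isoscape assignment: posterior, regions, overlap, odds ratios.

Small grids are cross-checked against brute-force recomputation with plain
normal densities and full sorts, independent of the log-domain
implementation.
"""

import math

import numpy as np
import pytest
from shapely.geometry import box

from toothtrace.assign import (
    AssignmentRegion,
    RangePolygon,
    SrAssignmentModel,
    odds_ratio,
    posterior,
    range_probability,
    read_ranges,
    region_overlap,
    top_fraction_region,
    write_ranges,
)
from toothtrace.raster import (
    Isoscape,
    crop_isoscape,
    read_ascii_grid,
    read_isoscape,
    write_ascii_grid,
    write_isoscape,
)


def uniform_iso(nrows=4, ncols=5, mu=0.710, sd=0.0005):
    return Isoscape(mean=np.full((nrows, ncols), mu),
                    error_sd=np.full((nrows, ncols), sd))


def random_iso(rng, nrows=8, ncols=9, sd=0.0005):
    mean = 0.710 + rng.normal(0, 1e-3, (nrows, ncols))
    return Isoscape(mean=mean, error_sd=np.full((nrows, ncols), sd))


class TestCrop:
    def test_full_extent_crop_is_identity(self):
        iso = uniform_iso()
        out = crop_isoscape(iso, (0, 0, 5, 4))
        np.testing.assert_array_equal(out.mean, iso.mean)
        assert (out.xll, out.yll) == (iso.xll, iso.yll)

    def test_single_cell_crop(self, rng):
        iso = random_iso(rng)
        out = crop_isoscape(iso, (2.4, 3.4, 2.6, 3.6))
        assert out.shape == (1, 1)
        # y=3.5 is the centre of grid row nrows-4
        assert out.mean[0, 0] == iso.mean[iso.shape[0] - 4, 2]

    def test_crop_is_idempotent(self, rng):
        iso = random_iso(rng)
        window = (1.2, 0.8, 6.3, 5.9)
        once = crop_isoscape(iso, window)
        twice = crop_isoscape(once, window)
        np.testing.assert_array_equal(once.mean, twice.mean)
        assert (once.xll, once.yll) == (twice.xll, twice.yll)

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(ValueError, match="intersect"):
            crop_isoscape(uniform_iso(), (100, 100, 101, 101))


class TestPosterior:
    def test_uniform_isoscape_gives_flat_posterior(self):
        iso = uniform_iso(nrows=3, ncols=4)
        surf = posterior(iso, 0.7102, analytical_sd=0.0)
        np.testing.assert_allclose(surf.probabilities, 1.0 / 12, atol=1e-12)

    def test_two_cell_closed_form(self):
        iso = Isoscape(mean=np.array([[0.710, 0.712]]),
                       error_sd=np.array([[0.0005, 0.0005]]))
        surf = posterior(iso, 0.710, analytical_sd=0.0)
        # normal-density ratio exp(0) : exp(-(0.002/0.0005)^2 / 2) = 1 : e^-8
        expected = 1.0 / (1.0 + math.exp(-8.0))
        assert surf.probabilities[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_distant_sample_still_normalizes(self):
        iso = uniform_iso(mu=0.710, sd=0.0002)
        surf = posterior(iso, 0.740, analytical_sd=0.0)  # 150 SD away
        assert surf.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nodata_cells_carry_no_mass(self):
        mean = np.full((3, 3), 0.710)
        mean[1, 1] = np.nan
        iso = Isoscape(mean=mean, error_sd=np.full((3, 3), 5e-4))
        surf = posterior(iso, 0.710)
        assert surf.probabilities[1, 1] == 0.0
        assert surf.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_analytical_sd_flattens_posterior(self, rng):
        iso = random_iso(rng)
        maxima = [
            posterior(iso, 0.7105, analytical_sd=s).probabilities.max()
            for s in (0.0, 2e-4, 5e-4, 1e-3, 3e-3)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(maxima, maxima[1:]))

    def test_brute_force_equivalence_small_grid(self, rng):
        iso = random_iso(rng, nrows=6, ncols=7)
        sample, asd = 0.7108, 3e-4
        surf = posterior(iso, sample, analytical_sd=asd)
        sd = np.sqrt(iso.error_sd**2 + asd**2)
        dens = np.exp(-0.5 * ((sample - iso.mean) / sd) ** 2) / (
            sd * np.sqrt(2 * np.pi)
        )
        np.testing.assert_allclose(
            surf.probabilities, dens / dens.sum(), atol=1e-12
        )


class TestTopFractionRegion:
    def test_uniform_surface_ties_include_all_cells(self):
        surf = posterior(uniform_iso(), 0.710)
        region = top_fraction_region(surf, 0.20)
        assert region.mask.all()

    def test_strictly_decreasing_posterior_selects_exact_count(self):
        mean = 0.710 + np.arange(10).reshape(1, 10) * 1e-4
        iso = Isoscape(mean=mean, error_sd=np.full((1, 10), 2e-4))
        surf = posterior(iso, 0.710)
        region = top_fraction_region(surf, 0.20)
        assert region.mask.sum() == 2
        assert region.mask[0, :2].all()

    def test_matches_sort_and_take_oracle(self, rng):
        iso = random_iso(rng)
        surf = posterior(iso, 0.7102)
        region = top_fraction_region(surf, 0.20)
        flat = np.sort(surf.probabilities.ravel())[::-1]
        k = math.ceil(0.20 * surf.probabilities.size)
        oracle = surf.probabilities >= flat[k - 1]
        np.testing.assert_array_equal(region.mask, oracle)


class TestOverlap:
    def test_identical_regions_overlap_fully(self, rng):
        surf = posterior(random_iso(rng), 0.7102)
        r = top_fraction_region(surf)
        assert region_overlap(r, r) == 100.0

    def test_disjoint_regions_do_not_overlap(self):
        a = AssignmentRegion(np.array([[True, False]]), 0.5, 0.0)
        b = AssignmentRegion(np.array([[False, True]]), 0.5, 0.0)
        assert region_overlap(a, b) == 0.0

    def test_containment_depends_on_denominator(self):
        small = AssignmentRegion(np.array([[True, False, False, False]]), 0.25, 0)
        big = AssignmentRegion(np.array([[True, True, False, False]]), 0.5, 0)
        assert region_overlap(small, big) == 100.0
        assert region_overlap(big, small) == 50.0

    def test_geometry_mismatch_is_an_error(self):
        a = AssignmentRegion(np.ones((2, 2), bool), 0.2, 0)
        b = AssignmentRegion(np.ones((3, 3), bool), 0.2, 0)
        with pytest.raises(ValueError):
            region_overlap(a, b)


class TestRangeProbability:
    def test_whole_grid_polygon_conserves_mass(self, rng):
        iso = random_iso(rng)
        surf = posterior(iso, 0.7101)
        poly = RangePolygon("summer", box(0, 0, iso.shape[1], iso.shape[0]))
        assert range_probability(surf, poly) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_polygons_are_additive(self, rng):
        iso = random_iso(rng, nrows=6, ncols=8)
        surf = posterior(iso, 0.7103)
        left = RangePolygon("winter", box(0, 0, 3.9, 6))
        right = RangePolygon("summer", box(3.9, 0, 8, 6))
        total = range_probability(surf, left) + range_probability(surf, right)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_uniform_surface_probability_proportional_to_area(self):
        iso = uniform_iso(nrows=10, ncols=10)
        surf = posterior(iso, 0.710)
        poly = RangePolygon("summer", box(0, 0, 10, 2.9))  # 30 of 100 centres
        assert range_probability(surf, poly) == pytest.approx(0.30, abs=1e-12)

    def test_polygon_off_grid_warns_and_returns_zero(self, rng):
        surf = posterior(random_iso(rng), 0.710)
        poly = RangePolygon("summer", box(100, 100, 110, 110))
        with pytest.warns(UserWarning, match="no valid cell"):
            assert range_probability(surf, poly) == 0.0


class TestOddsRatio:
    def test_symmetric_ranges_give_unit_odds(self):
        mean = np.array([[0.712, 0.712], [0.710, 0.710]])  # mirror zones
        iso = Isoscape(mean=mean, error_sd=np.full((2, 2), 5e-4))
        surf = posterior(iso, 0.711)
        summer = RangePolygon("summer", box(0, 1, 2, 2))
        winter = RangePolygon("winter", box(0, 0, 2, 1))
        assert odds_ratio(surf, summer, winter).odds_ratio == pytest.approx(
            1.0, abs=1e-12
        )

    def test_uniform_surface_odds_follow_cell_counts(self):
        iso = uniform_iso(nrows=3, ncols=4)
        surf = posterior(iso, 0.710)
        summer = RangePolygon("summer", box(0, 1, 4, 3))  # 8 cells
        winter = RangePolygon("winter", box(0, 0, 4, 1))  # 4 cells
        assert odds_ratio(surf, summer, winter).odds_ratio == pytest.approx(
            2.0, abs=1e-12
        )

    def test_two_zone_oracle(self):
        # winter zone mu=0.7095 (bottom row), summer mu=0.7120 (top row)
        mean = np.array([[0.7120] * 3, [0.7095] * 3])
        iso = Isoscape(mean=mean, error_sd=np.full((2, 3), 5e-4))
        surf = posterior(iso, 0.7095)
        summer = RangePolygon("summer", box(0, 1, 3, 2))
        winter = RangePolygon("winter", box(0, 0, 3, 1))
        res = odds_ratio(surf, summer, winter)
        dens_s = math.exp(-0.5 * (0.0025 / 0.0005) ** 2)
        assert res.odds_ratio == pytest.approx(dens_s / 1.0, rel=1e-9)
        assert res.odds_ratio < 1
        assert res.assigned_range == "winter"

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        iso = random_iso(rng)
        surf = posterior(iso, 0.7104)
        summer = RangePolygon("summer", box(0, 4, 9, 8))
        winter = RangePolygon("winter", box(0, 0, 9, 4))
        res = odds_ratio(surf, summer, winter, n_boot=200, seed=3)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_ci_spanning_one_reads_not_significant(self):
        from toothtrace.assign import OddsResult

        assert OddsResult(0.99, 0.972, 1.009).assigned_range == "NS"
        assert OddsResult(0.23, 0.225, 0.235).assigned_range == "winter"
        assert OddsResult(1.63, 1.599, 1.658).assigned_range == "summer"

    def test_zero_winter_mass_is_an_error(self):
        mean = np.full((2, 2), 0.710)
        mean[0, :] = np.nan  # no valid cell under the winter polygon
        iso = Isoscape(mean=mean, error_sd=np.full((2, 2), 5e-4))
        surf = posterior(iso, 0.710)
        summer = RangePolygon("summer", box(0, 0, 2, 1))
        winter = RangePolygon("winter", box(0, 1, 2, 2))
        with pytest.raises(ZeroDivisionError):
            odds_ratio(surf, summer, winter)


class TestModelResults:
    def test_fit_summary_reports_assignment(self, rng):
        iso = random_iso(rng)
        model = SrAssignmentModel(
            iso,
            summer=RangePolygon("summer", box(0, 4, 9, 8)),
            winter=RangePolygon("winter", box(0, 0, 9, 4)),
            analytical_sd=1e-4,
        )
        res = model.fit(0.7102, q=0.20)
        table = res.summary()
        assert table.loc[0, "q"] == 0.20
        assert table.loc[0, "assigned_range"] in ("summer", "winter", "NS")
        assert res.surface.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.region.mask.sum() >= math.ceil(0.2 * iso.n_valid)


class TestIO:
    def test_ascii_grid_round_trip(self, tmp_path, rng):
        arr = rng.normal(0.71, 1e-3, (5, 7))
        arr[2, 3] = np.nan
        path = tmp_path / "grid.asc"
        write_ascii_grid(arr, path, xll=10.0, yll=-5.0, cell_size=2.0)
        back, xll, yll, cs = read_ascii_grid(path)
        assert (xll, yll, cs) == (10.0, -5.0, 2.0)
        np.testing.assert_allclose(back, arr, atol=1e-9)

    def test_isoscape_pair_round_trip(self, tmp_path, rng):
        iso = random_iso(rng)
        write_isoscape(iso, tmp_path / "m.asc", tmp_path / "s.asc")
        back = read_isoscape(tmp_path / "m.asc", tmp_path / "s.asc")
        np.testing.assert_allclose(back.mean, iso.mean, atol=1e-9)
        assert back.cell_size == iso.cell_size

    def test_geojson_ranges_round_trip(self, tmp_path):
        ranges = [RangePolygon("summer", box(0, 5, 10, 10)),
                  RangePolygon("winter", box(0, 0, 10, 4))]
        path = tmp_path / "ranges.geojson"
        write_ranges(ranges, path)
        back = read_ranges(path)
        assert set(back) == {"summer", "winter"}
        assert back["summer"].geometry.equals(ranges[0].geometry)
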