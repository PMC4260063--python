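"""Standardization, weighted KDE surfaces and raster IO."""

import math

import numpy as np
import pytest

import geodens as g
from geodens.density import GAUSS_TRUNC, _GAUSS_MASS_3SD
from geodens.errors import EmptyInputError, InvalidParameterError, ParseError


def stop(x, y, radius, count, sid="s0"):
    """A sample point with `count` white captures, built directly."""
    return g.SamplePoint(
        id=sid, x=x, y=y, radius_mi=radius,
        captured=[(f"{sid}-p{i}", 0.0) for i in range(count)],
        race_counts={"white": count, "black": 0, "other": 0},
        age_counts={">30": count},
        cross_counts={("white", ">30"): count},
    )


def naive_kde(stops_weights, grid, h, kernel):
    """Independent double-loop evaluation of the kernel sum."""
    xs = grid.x_centers()
    ys = grid.y_centers()
    out = np.zeros((grid.nrows, grid.ncols))
    for i in range(grid.nrows):
        for j in range(grid.ncols):
            total = 0.0
            for (px, py, w) in stops_weights:
                r2 = (xs[j] - px) ** 2 + (ys[i] - py) ** 2
                if kernel == "gaussian-truncated":
                    if r2 <= (GAUSS_TRUNC * h) ** 2:
                        total += w * math.exp(-r2 / (2 * h * h)) / (2 * math.pi * h * h * _GAUSS_MASS_3SD)
                else:
                    u2 = r2 / (h * h)
                    if u2 < 1.0:
                        total += w * 3.0 / (math.pi * h * h) * (1 - u2) ** 2
            out[i, j] = total
    return out


class TestStandardize:
    def test_radius_one_identity(self):
        per_circle, per_sqmi = g.standardize_count(50, 1.0)
        assert per_circle == 50.0
        assert per_sqmi == pytest.approx(50 / math.pi)

    def test_two_mile_circle_rescales_by_area(self):
        per_circle, per_sqmi = g.standardize_count(12, 2.0)
        assert per_circle == pytest.approx(3.0)
        assert per_sqmi == pytest.approx(12 / (4 * math.pi))
        assert per_circle == pytest.approx(per_sqmi * math.pi)

    def test_zero_count(self):
        assert g.standardize_count(0, 2.0) == (0.0, 0.0)

    def test_zero_radius_rejected(self):
        with pytest.raises(InvalidParameterError):
            g.standardize_count(5, 0.0)


class TestKernelDensity:
    def test_single_point_peak_matches_closed_form(self):
        # grid cell centered exactly on the point; weight 10 per-circle
        grid = g.GridSpec(xll=-5.05, yll=-5.05, cell_size=0.1, ncols=101, nrows=101)
        sp = stop(0.0, 0.0, 1.0, 10)  # radius 1 => per-circle weight = count
        for h in (1.0, 2.0):
            surf = g.kernel_density([sp], stratum="white", bandwidth_mi=h, grid=grid)
            peak = surf.values[grid.cell_of(0.0, 0.0)]
            exact = 10 / (2 * math.pi * h * h * _GAUSS_MASS_3SD)
            assert peak == pytest.approx(exact, rel=1e-12)
            # within 1.2% of the untruncated bivariate-normal peak w/(2 pi h^2)
            assert peak == pytest.approx(10 / (2 * math.pi * h * h), rel=0.012)

    def test_zero_weights_give_zero_surface(self):
        grid = g.GridSpec(xll=0, yll=0, cell_size=0.5, ncols=10, nrows=10)
        sp = stop(2.5, 2.5, 2.0, 0)
        surf = g.kernel_density([sp], stratum="white", bandwidth_mi=1.0, grid=grid)
        assert (surf.values == 0).all()

    @pytest.mark.parametrize("kernel", ["gaussian-truncated", "quartic"])
    def test_matches_naive_double_loop_oracle(self, kernel, rng):
        grid = g.GridSpec(xll=0, yll=0, cell_size=0.25, ncols=30, nrows=24)
        stops = [
            stop(x, y, r, c, sid=f"s{i}")
            for i, (x, y, r, c) in enumerate(
                zip(rng.uniform(1, 6, 5), rng.uniform(1, 5, 5), rng.uniform(0.5, 2, 5), rng.integers(1, 60, 5))
            )
        ]
        surf = g.kernel_density(stops, stratum="white", bandwidth_mi=2.0, grid=grid, kernel=kernel)
        sw = [(sp.x, sp.y, g.standardize_count(sp.race_counts["white"], sp.radius_mi)[0]) for sp in stops]
        expected = naive_kde(sw, grid, 2.0, kernel)
        np.testing.assert_allclose(surf.values, expected, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("kernel", ["gaussian-truncated", "quartic"])
    def test_mass_conservation(self, kernel, rng):
        """Integrated volume equals the summed weights within 1%."""
        grid = g.GridSpec(xll=0, yll=0, cell_size=0.1, ncols=200, nrows=200)
        stops = [
            stop(x, y, r, c, sid=f"s{i}")
            for i, (x, y, r, c) in enumerate(
                zip(rng.uniform(7, 13, 6), rng.uniform(7, 13, 6), rng.uniform(0.5, 2, 6), rng.integers(5, 80, 6))
            )
        ]
        surf = g.kernel_density(stops, stratum="white", bandwidth_mi=2.0, grid=grid, kernel=kernel)
        total_weight = sum(g.standardize_count(sp.race_counts["white"], sp.radius_mi)[0] for sp in stops)
        assert surf.volume() == pytest.approx(total_weight, rel=0.01)

    def test_raw_weight_mode_uses_counts(self):
        grid = g.GridSpec(xll=-5, yll=-5, cell_size=0.1, ncols=100, nrows=100)
        sp = stop(0, 0, 2.0, 40)
        raw = g.kernel_density([sp], "white", 1.0, grid, weight_mode="raw")
        std = g.kernel_density([sp], "white", 1.0, grid, weight_mode="standardized")
        assert raw.volume() == pytest.approx(40, rel=0.01)
        assert std.volume() == pytest.approx(10, rel=0.01)  # 40 / 2^2

    def test_linearity_across_strata(self, rng):
        """Race surfaces sum to the total surface cellwise (counts partition)."""
        pop = []
        for i, race in enumerate(["white"] * 80 + ["black"] * 50 + ["other"] * 20):
            x, y = rng.uniform(1, 9, 2)
            pop.append(g.UserProfile(id=f"p{i}", x=x, y=y, race=race, age=30))
        stops = g.run_route(g.Route(polyline=((0, 5), (10, 5))), pop, k=30)
        grid = g.GridSpec(xll=0, yll=0, cell_size=0.25, ncols=40, nrows=40)
        surfs = {
            r: g.kernel_density(stops, r, 2.0, grid).values for r in ("white", "black", "other", "total")
        }
        np.testing.assert_allclose(
            surfs["white"] + surfs["black"] + surfs["other"], surfs["total"], rtol=1e-12, atol=1e-12
        )

    def test_translation_equivariance(self, rng):
        grid = g.GridSpec(xll=0, yll=0, cell_size=0.2, ncols=30, nrows=30)
        stops = [stop(2.3, 3.1, 1.0, 20), stop(4.0, 2.0, 2.0, 35, sid="s1")]
        surf = g.kernel_density(stops, "white", 1.5, grid)
        dx, dy = 7.25, -3.5
        grid2 = g.GridSpec(xll=dx, yll=dy, cell_size=0.2, ncols=30, nrows=30)
        stops2 = [stop(2.3 + dx, 3.1 + dy, 1.0, 20), stop(4.0 + dx, 2.0 + dy, 2.0, 35, sid="s1")]
        surf2 = g.kernel_density(stops2, "white", 1.5, grid2)
        np.testing.assert_allclose(surf.values, surf2.values, rtol=1e-12, atol=1e-15)

    def test_narrower_bandwidth_has_higher_peak(self, rng):
        grid = g.GridSpec(xll=0, yll=0, cell_size=0.1, ncols=100, nrows=100)
        stops = [
            stop(x, y, r, c, sid=f"s{i}")
            for i, (x, y, r, c) in enumerate(
                zip(rng.uniform(2, 8, 8), rng.uniform(2, 8, 8), rng.uniform(0.3, 2, 8), rng.integers(1, 50, 8))
            )
        ]
        m1 = np.nanmax(g.kernel_density(stops, "white", 1.0, grid).values)
        m2 = np.nanmax(g.kernel_density(stops, "white", 2.0, grid).values)
        assert m1 >= m2

    def test_region_mask_sets_nodata_outside(self, square_region):
        grid = g.GridSpec(xll=-2, yll=-2, cell_size=0.5, ncols=28, nrows=28)
        surf = g.kernel_density([stop(5, 5, 1.0, 10)], "white", 1.0, grid, region=square_region)
        assert np.isnan(surf.values[0, 0])  # corner cell is outside the square
        assert not np.isnan(surf.values[grid.cell_of(5, 5)])

    def test_bad_parameters_rejected(self):
        grid = g.GridSpec(xll=0, yll=0, cell_size=1, ncols=5, nrows=5)
        with pytest.raises(InvalidParameterError):
            g.kernel_density([], "white", 0.0, grid)
        with pytest.raises(InvalidParameterError):
            g.kernel_density([], "white", 1.0, grid, kernel="epanechnikov")
        with pytest.raises(InvalidParameterError):
            g.kernel_density([], "white", 1.0, grid, weight_mode="weird")


class TestPerPointSummary:
    def unit_stops(self, counts):
        r = 1 / math.sqrt(math.pi)  # per-sq-mi density == count
        return [stop(float(i), 0.0, r, c, sid=f"s{i}") for i, c in enumerate(counts)]

    def test_simple_order_statistics(self):
        s = g.per_point_density_summary(self.unit_stops([1, 2, 3]), "white")
        assert s["mean"] == pytest.approx(2)
        assert s["median"] == pytest.approx(2)
        assert (s["min"], s["max"]) == (pytest.approx(1), pytest.approx(3))

    def test_right_skew_flags_mean_above_median(self):
        s = g.per_point_density_summary(self.unit_stops([1, 1, 100]), "white")
        assert s["median"] == pytest.approx(1)
        assert s["mean"] == pytest.approx(34)
        assert s["mean"] > s["median"]

    def test_clustered_scenario_is_right_skewed(self, demo_pipeline):
        s = g.per_point_density_summary(demo_pipeline["stops"])
        assert s["median"] < s["mean"]

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            g.per_point_density_summary([])


class TestAscRoundtrip:
    def test_roundtrip_preserves_values_and_nodata(self, tmp_path):
        grid = g.GridSpec(xll=-1.5, yll=2.0, cell_size=0.25, ncols=6, nrows=4)
        values = np.arange(24, dtype=float).reshape(4, 6) / 7.0
        values[1, 2] = np.nan
        surf = g.DensitySurface(grid=grid, values=values)
        p1 = tmp_path / "a.asc"
        g.write_asc(surf, p1)
        grid2, values2 = g.read_asc(p1)
        assert grid2 == grid
        # %g serialization keeps 6 significant digits
        np.testing.assert_allclose(values2, values, rtol=1e-5)
        assert np.isnan(values2[1, 2])
        p2 = tmp_path / "b.asc"
        g.write_asc(g.DensitySurface(grid=grid2, values=values2), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\nnrows 2\nbogus 1\n")
        with pytest.raises(ParseError, match="line 3"):
            g.read_asc(p)
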