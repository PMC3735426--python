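import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

import streetmorph as sm
from streetmorph.geo_morphometrics import (
    LAND_USE_CLASSES,
    MorphometricsError,
    lum_from_shares,
)

from hypothesis import given, settings, strategies as st_


def straight_graph(length=3000.0):
    return sm.build_segment_graph([[(1000.0, 0.0), (1000.0 + length, 0.0)]])


class TestNetworkBuffer:
    def test_straight_segment_closed_form_area(self):
        g = straight_graph()
        hw = 50.0
        buf = sm.network_buffer(g, (2500.0, 0.0), radius=1000.0, half_width=hw)
        assert buf.reached_length() == pytest.approx(2000.0, abs=1e-6)
        expected = 2000.0 * 2 * hw + math.pi * hw**2
        assert buf.area == pytest.approx(expected, rel=0.01)

    def test_tiny_radius_degenerates_to_disc(self):
        g = straight_graph()
        buf = sm.network_buffer(g, (2500.0, 10.0), radius=0.001, half_width=25.0)
        assert buf.area == pytest.approx(math.pi * 25.0**2, rel=0.01)
        assert buf.polygon.contains(Point(buf.access_point))

    def test_reached_edges_monotone_in_radius(self, small_town):
        g = small_town.graph
        origin = tuple(small_town.dwelling_points[0])
        b500 = sm.network_buffer(g, origin, 500.0)
        b1000 = sm.network_buffer(g, origin, 1000.0)
        for sid, ivs in b500.reached_edges.items():
            assert sid in b1000.reached_edges
            for lo, hi in ivs:
                assert any(
                    lo >= lo2 - 1e-9 and hi <= hi2 + 1e-9
                    for lo2, hi2 in b1000.reached_edges[sid]
                )
        assert b1000.area >= b500.area

    def test_area_monotone_in_half_width(self):
        g = straight_graph()
        a1 = sm.network_buffer(g, (2500.0, 0.0), 800.0, half_width=25.0).area
        a2 = sm.network_buffer(g, (2500.0, 0.0), 800.0, half_width=50.0).area
        assert a2 > a1

    def test_origin_too_far_errors_with_id(self):
        g = straight_graph()
        with pytest.raises(MorphometricsError, match="D77"):
            sm.network_buffer(
                g, (2500.0, 500.0), 1000.0, snap_distance=200.0, dwelling_id="D77"
            )


class TestLandUseMix:
    def _buffer_over(self, poly=None):
        g = straight_graph()
        buf = sm.network_buffer(g, (2500.0, 0.0), 1000.0)
        if poly is not None:
            # rectangular catchment so parcel strips intersect exactly equally
            buf.polygon = poly
            buf.area = poly.area
        return buf

    def test_equal_shares_give_one(self):
        buf = self._buffer_over(box(1500.0, -50.0, 3500.0, 50.0))
        x0, y0, x1, y1 = buf.polygon.bounds
        w = (x1 - x0) / 5
        parcels = sm.ParcelLayer(
            polygons=[box(x0 + k * w, y0 - 10, x0 + (k + 1) * w, y1 + 10) for k in range(5)],
            classes=list(LAND_USE_CLASSES),
        )
        assert sm.land_use_mix(buf, parcels) == pytest.approx(1.0, abs=1e-9)

    def test_single_class_gives_zero(self):
        buf = self._buffer_over(None)
        x0, y0, x1, y1 = buf.polygon.bounds
        parcels = sm.ParcelLayer(
            polygons=[box(x0 - 10, y0 - 10, x1 + 10, y1 + 10)],
            classes=["retail"],
        )
        assert sm.land_use_mix(buf, parcels) == pytest.approx(0.0, abs=1e-12)

    def test_half_half_matches_hand_formula(self):
        buf = self._buffer_over(box(1500.0, -50.0, 3500.0, 50.0))
        x0, y0, x1, y1 = buf.polygon.bounds
        xm = (x0 + x1) / 2
        parcels = sm.ParcelLayer(
            polygons=[box(x0 - 10, y0 - 10, xm, y1 + 10), box(xm, y0 - 10, x1 + 10, y1 + 10)],
            classes=["residential", "retail"],
        )
        # buffer is symmetric about its centre, so the two shares are equal
        assert sm.land_use_mix(buf, parcels) == pytest.approx(
            math.log(2) / math.log(5), abs=1e-6
        )

    def test_no_classified_land_errors(self):
        buf = self._buffer_over(None)
        parcels = sm.ParcelLayer(
            polygons=[box(90000, 90000, 90010, 90010)], classes=["retail"]
        )
        with pytest.raises(MorphometricsError, match="no classified land"):
            sm.land_use_mix(buf, parcels)

    @given(
        shares=st_.lists(
            st_.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=5, max_size=5
        ).filter(lambda s: sum(s) > 0)
    )
    @settings(max_examples=100, deadline=None)
    def test_shares_entropy_properties(self, shares):
        v = lum_from_shares(shares)
        assert -1e-12 <= v <= 1.0 + 1e-12
        # scale invariance
        assert lum_from_shares([s * 3.7 for s in shares]) == pytest.approx(v, abs=1e-9)
        nonzero = [s for s in shares if s > 0]
        if len(nonzero) == 1:
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_maximised_only_at_equal_shares(self):
        assert lum_from_shares([1, 1, 1, 1, 1]) == pytest.approx(1.0)
        assert lum_from_shares([1.2, 1, 1, 1, 1]) < 1.0


class TestDensities:
    def _unit_buffer(self):
        # buffer whose polygon area is exactly 1 km^2: use a square zone
        g = straight_graph()
        buf = sm.network_buffer(g, (2500.0, 0.0), 1000.0)
        buf.polygon = box(0.0, 0.0, 1000.0, 1000.0)
        buf.area = buf.polygon.area
        return buf

    def test_ten_points_in_unit_area(self):
        buf = self._unit_buffer()
        pts = [(100.0 * k + 50.0, 500.0) for k in range(10)]
        assert sm.destination_density(buf, pts) == pytest.approx(10.0)

    def test_empty_is_zero(self):
        buf = self._unit_buffer()
        assert sm.destination_density(buf, []) == 0.0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(13)
        buf = self._unit_buffer()
        pts = rng.uniform(-200, 1200, size=(37, 2))
        dens = sm.destination_density(buf, [tuple(p) for p in pts])
        brute = sum(1 for p in pts if buf.polygon.contains(Point(p)))
        assert dens == pytest.approx(brute / 1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(14)
        buf = self._unit_buffer()
        pts = rng.uniform(0, 1000, size=(25, 2))
        d1 = sm.destination_density(buf, [tuple(p) for p in pts])
        shift = np.array([5000.0, -3000.0])
        buf2 = self._unit_buffer()
        from shapely import affinity

        buf2.polygon = affinity.translate(buf2.polygon, *shift)
        buf2.area = buf2.polygon.area
        d2 = sm.destination_density(buf2, [tuple(p + shift) for p in pts])
        assert d1 == pytest.approx(d2)

    def test_per_category_map(self):
        buf = self._unit_buffer()
        out = sm.destination_density(buf, {"bus_stops": [(10.0, 10.0)], "retail": []})
        assert out == {"bus_stops": pytest.approx(1.0), "retail": 0.0}


class TestDwellingDensity:
    def test_isolated_dwelling_counts_itself(self):
        assert sm.dwelling_centred_density([(1000.0, 0.0)], (1000.0, 0.0)) == 1

    def test_threshold_at_30m(self):
        focal = (1000.0, 0.0)
        pts = [focal, (1010.0, 0.0), (1020.0, 0.0), (1029.0, 0.0), (1031.0, 0.0)]
        assert sm.dwelling_centred_density(pts, focal) == 4

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 200, size=(200, 2))
        for k in (0, 50, 199):
            focal = tuple(pts[k])
            brute = sum(1 for p in pts if math.dist(p, focal) <= 30.0)
            assert sm.dwelling_centred_density(pts, focal) == brute


class TestPlotExposure:
    def _house(self):
        return box(1000.0, 0.0, 1008.0, 8.0)

    def test_one_exposed_face(self):
        road = box(1000.0, -6.0, 1008.0, -1.0)
        assert sm.plot_exposure(self._house(), [road]) == "1"

    def test_corner_plot_two_plus(self):
        roads = [box(1000.0, -6.0, 1008.0, -1.0), box(1009.0, 0.0, 1014.0, 8.0)]
        assert sm.plot_exposure(self._house(), roads) == "2+"

    def test_landlocked_zero(self):
        road = box(1050.0, 0.0, 1060.0, 8.0)
        assert sm.plot_exposure(self._house(), [road]) == "0"

    def test_degenerate_footprint_errors(self):
        degenerate = Polygon([(0, 0), (1, 1), (2, 2)])
        with pytest.raises(MorphometricsError, match="degenerate"):
            sm.plot_exposure(degenerate, [box(0, 0, 1, 1)])


class TestZonalStat:
    def test_constant_raster(self):
        r = sm.RasterGrid(x_ll=0, y_ll=0, cell_size=10, values=np.full((20, 20), 3.5))
        zone = box(20, 20, 180, 180)
        assert sm.zonal_stat(r, zone, "mean") == pytest.approx(3.5)
        assert sm.zonal_stat(r, zone, "sd") == pytest.approx(0.0)

    def test_four_cells_hand_computation(self):
        r = sm.RasterGrid(
            x_ll=0, y_ll=0, cell_size=10, values=np.array([[1.0, 2.0], [3.0, 4.0]])
        )
        zone = box(-5, -5, 25, 25)
        assert sm.zonal_stat(r, zone, "mean") == pytest.approx(2.5)
        assert sm.zonal_stat(r, zone, "sd") == pytest.approx(math.sqrt(1.25))

    def test_matches_exhaustive_cell_centre_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            nrows, ncols = rng.integers(20, 100, size=2)
            vals = rng.uniform(-5, 5, size=(nrows, ncols))
            vals[rng.random(vals.shape) < 0.05] = -9999.0
            r = sm.RasterGrid(x_ll=0, y_ll=0, cell_size=7.0, values=vals, nodata=-9999.0)
            cx, cy = rng.uniform(0, ncols * 7), rng.uniform(0, nrows * 7)
            zone = Point(cx, cy).buffer(rng.uniform(30, 200))
            picked = []
            for row in range(nrows):
                for col in range(ncols):
                    x = (col + 0.5) * 7.0
                    y = (nrows - row - 0.5) * 7.0
                    if vals[row, col] != -9999.0 and zone.contains(Point(x, y)):
                        picked.append(vals[row, col])
            if not picked:
                with pytest.raises(MorphometricsError):
                    sm.zonal_stat(r, zone, "mean")
                continue
            assert sm.zonal_stat(r, zone, "mean") == pytest.approx(np.mean(picked))
            assert sm.zonal_stat(r, zone, "sd") == pytest.approx(np.std(picked))

    def test_no_valid_cells_errors(self):
        r = sm.RasterGrid(x_ll=0, y_ll=0, cell_size=10, values=np.full((5, 5), -9999.0))
        with pytest.raises(MorphometricsError):
            sm.zonal_stat(r, box(0, 0, 50, 50), "mean")

    def test_ascii_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        r = sm.RasterGrid(
            x_ll=123.5, y_ll=-40.25, cell_size=12.5,
            values=rng.uniform(0, 9, size=(8, 11)),
        )
        path = tmp_path / "grid.asc"
        r.to_ascii(path)
        r2 = sm.RasterGrid.from_ascii(path)
        assert r2.cell_size == r.cell_size
        assert r2.x_ll == r.x_ll and r2.y_ll == r.y_ll
        np.testing.assert_allclose(r2.values, r.values, rtol=1e-9)


class TestDwellingBattery:
    def test_full_battery_columns_and_ranges(self, small_town):
        morph = small_town.respondent_morphometrics
        from streetmorph.geo_morphometrics import BUILT_ENV_COLUMNS, NATURAL_ENV_COLUMNS

        for col in (*BUILT_ENV_COLUMNS, *NATURAL_ENV_COLUMNS):
            assert col in morph.columns
        assert morph["Land use mix"].between(0, 1).all()
        assert (morph["Dwelling centred density (within 30 m radius)"] >= 1).all()
        assert morph["Mean NDVI"].between(-1, 1).all()
        assert (morph["Neighbourhood slope variability"] >= 0).all()
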