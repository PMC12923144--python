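import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from marisdm import ranges
from marisdm.d3os import SpeciesProfile
from marisdm.grid import Grid, Raster, haversine_km, mask_to_polygons

from conftest import make_table


def all_ocean_raster(extent=(-30, 30, -30, 30), resolution=1.0):
    lon0, lon1, lat0, lat1 = extent
    nlon = int((lon1 - lon0) / resolution)
    nlat = int((lat1 - lat0) / resolution)
    grid = Grid(lon0, lat0, resolution, nlon, nlat)
    return Raster(grid, np.ones(grid.shape))


class TestBuildFromErm:
    def test_br_is_one_degree_buffer(self):
        ocean = all_ocean_raster()
        rs = ranges.build_from_erm(box(0, 0, 10, 10), ocean)
        assert rs.br.bounds == pytest.approx((-1, -1, 11, 11))

    def test_pr_is_ten_degree_buffer(self):
        ocean = all_ocean_raster()
        rs = ranges.build_from_erm(box(0, 0, 10, 10), ocean)
        assert rs.pr.bounds == pytest.approx((-10, -10, 20, 20))

    def test_land_cropped_from_both(self, world):
        erm = box(world.grid.lon_min + 2, -5, world.grid.lon_max - 2, 5)
        rs = ranges.build_from_erm(erm, world.ocean)
        land = mask_to_polygons(world.land_mask, world.grid)
        assert rs.br.intersection(land).area < 1e-9
        assert rs.pr.intersection(land).area < 1e-9

    def test_empty_erm_rejected(self, world):
        with pytest.raises(ranges.RangeConstructionError):
            ranges.build_from_erm(shapely.Polygon(), world.ocean)

    def test_basin_confinement(self):
        # two ocean basins split by a meridional landmass; an ERM in the
        # western basin must not leak into the eastern one
        grid = Grid(0, 0, 1.0, 30, 20)
        vals = np.ones(grid.shape)
        vals[:, 14:16] = np.nan  # land wall at lon 14-16
        ocean = Raster(grid, vals)
        rs = ranges.build_from_erm(box(2, 2, 8, 8), ocean)
        east = box(16, 0, 30, 20)
        assert rs.pr.intersection(east).area < 1e-9


class TestBoundingBox:
    def test_extremes(self):
        records = make_table(
            [{"lon": 5.0, "lat": 5.0}, {"lon": 8.0, "lat": 2.0}]
        )
        assert ranges.bounding_box_from_occurrences(records).bounds == (5, 2, 8, 5)

    def test_erroneous_records_excluded(self):
        records = make_table(
            [{"lon": 5.0, "lat": 5.0}, {"lon": 100.0, "lat": 80.0, "flag": 0.0}]
        )
        assert ranges.bounding_box_from_occurrences(records).bounds == (5, 5, 5, 5) or \
            ranges.bounding_box_from_occurrences(records).is_empty

    def test_single_record_inflated(self):
        records = make_table([{"lon": 5.0, "lat": 5.0}])
        bb = ranges.bounding_box_from_occurrences(records, min_size=0.5)
        assert bb.area > 0
        assert bb.contains(shapely.Point(5, 5))

    def test_no_valid_records_errors(self):
        with pytest.raises(ranges.RangeConstructionError):
            ranges.bounding_box_from_occurrences(make_table([{"flag": 0.0}]))

    def test_merge_boxes_takes_extremes(self):
        merged = ranges.merge_boxes([box(0, 0, 5, 5), box(3, -2, 8, 4)])
        assert merged.bounds == (0, -2, 8, 5)


class TestThinning:
    @pytest.mark.parametrize(
        "n, expected",
        [(800, None), (1000, None), (1001, 20.0), (2000, 20.0), (5000, 20.0), (6000, 30.0)],
    )
    def test_distance_rule(self, n, expected):
        assert ranges.thinning_distance_km(n) == expected

    def test_small_set_unchanged(self):
        records = make_table([{"lon": float(i)} for i in range(10)])
        out = ranges.spatial_thin(records, seed=0)
        pd.testing.assert_frame_equal(out, records)

    def test_close_pair_reduced_to_one(self):
        # ~5 km apart at the equator; 20 km thinning keeps exactly one
        records = make_table([{"lon": 0.0}, {"lon": 0.045}])
        records["lat"] = 0.0
        out = ranges.spatial_thin(records, seed=0, distance_km=20.0)
        assert len(out) == 1

    def test_minimum_distance_property_brute_force(self, clean_records):
        out = ranges.spatial_thin(clean_records, seed=3, distance_km=100.0)
        lon = out["lon"].to_numpy()
        lat = out["lat"].to_numpy()
        for i in range(len(out)):
            d = haversine_km(lon[i], lat[i], lon[i + 1 :], lat[i + 1 :])
            assert (d >= 100.0 - 1e-6).all()

    def test_seed_determinism(self, clean_records):
        a = ranges.spatial_thin(clean_records, seed=5, distance_km=50.0)
        b = ranges.spatial_thin(clean_records, seed=5, distance_km=50.0)
        pd.testing.assert_frame_equal(a, b)


class TestShareFilter:
    def test_per_province_shares(self):
        # counts 50/30/2: C holds 2/82 = 2.4% <= 3.3% and is dropped
        shares = {"A": 50 / 82, "B": 30 / 82, "C": 2 / 82}
        kept = ranges._filter_by_share(shares, 0.033, "per_unit")
        assert sorted(kept) == ["A", "B"]

    def test_share_exactly_at_threshold_dropped(self):
        shares = {"A": 0.933, "B": 0.033, "C": 0.034}
        kept = ranges._filter_by_share(shares, 0.033, "per_unit")
        assert sorted(kept) == ["A", "C"]  # strict >

    def test_cumulative_mode_drops_smallest_tail(self):
        shares = {"A": 0.90, "B": 0.08, "C": 0.015, "D": 0.005}
        kept = ranges._filter_by_share(shares, 0.033, "cumulative")
        assert sorted(kept) == ["A", "B"]  # D+C = 2% <= 3.3% dropped together

    def test_retained_mass_bound(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 200, size=12)
        shares = {f"p{i}": c / counts.sum() for i, c in enumerate(counts)}
        kept = ranges._filter_by_share(shares, 0.033, "per_unit")
        dropped = len(shares) - len(kept)
        assert sum(shares[k] for k in kept) > 1 - dropped * 0.033


class TestDeriveRange:
    def _profile(self, label):
        from marisdm.d3os import classify_bottom

        p = SpeciesProfile("t1", label)
        p.bottom_class = classify_bottom(label)
        return p

    def test_pelagic_range_drops_sparse_provinces(self, world, clean_records):
        rs = ranges.derive_range(
            clean_records, self._profile("pelagic"), world.partition, world.ocean
        )
        assert rs.provenance == "derived"
        assert not rs.br.is_empty
        # provinces holding almost no occurrences are excluded pre-buffer
        lon = clean_records["lon"].to_numpy()
        lat = clean_records["lat"].to_numpy()
        for pid, poly in world.partition.provinces.items():
            share = np.mean(shapely.contains_xy(poly, lon, lat))
            if share == 0.0:
                # at most the 1-degree BR buffer may reach into it
                reach = rs.br.intersection(poly.buffer(-1.01))
                assert reach.area < 1e-9

    def test_benthic_range_is_layer_province_intersection(self, world, clean_records):
        rs = ranges.derive_range(
            clean_records, self._profile("demersal"), world.partition, world.ocean
        )
        assert not rs.br.is_empty
        assert rs.br_area_km2 <= rs.pr_area_km2 + 1e-6

    def test_all_filtered_out_suggests_relaxation(self, world, clean_records):
        with pytest.raises(ranges.RangeConstructionError, match="share_threshold"):
            ranges.derive_range(
                clean_records,
                self._profile("pelagic"),
                world.partition,
                world.ocean,
                share_threshold=1.0,
            )


class TestReflag:
    def test_partition_of_records(self, world, clean_records, erm):
        rs = ranges.build_from_erm(erm, world.ocean)
        out = ranges.reflag_by_range(clean_records, rs)
        n1 = (out["flag"] == 1.0).sum()
        n0 = (out["flag"] == 0.0).sum()
        assert n1 + n0 == len(out)
        assert out["flag"].isna().sum() == 0

    def test_inside_br_valid_outside_erroneous(self, world, erm):
        rs = ranges.build_from_erm(erm, world.ocean)
        c = rs.br.representative_point()
        records = make_table(
            [
                {"lon": c.x, "lat": c.y},
                {"lon": world.grid.lon_min + 0.1, "lat": world.grid.lat_max - 0.1},
            ]
        )
        out = ranges.reflag_by_range(records, rs)
        assert out["flag"].tolist() == [1.0, 0.0]

    def test_previously_valid_point_outside_br_demoted(self, world, erm):
        rs = ranges.build_from_erm(erm, world.ocean)
        records = make_table(
            [{"lon": world.grid.lon_min + 0.1, "lat": world.grid.lat_max - 0.1, "flag": 1.0}]
        )
        assert ranges.reflag_by_range(records, rs)["flag"].iloc[0] == 0.0

    def test_land_point_erroneous(self, world, erm):
        rs = ranges.build_from_erm(erm, world.ocean)
        lon2d, lat2d = world.grid.center_mesh()
        r, c = np.argwhere(world.land_mask)[0]
        records = make_table([{"lon": lon2d[r, c], "lat": lat2d[r, c]}])
        assert ranges.reflag_by_range(records, rs)["flag"].iloc[0] == 0.0


def test_geojson_roundtrip(tmp_path, erm):
    path = tmp_path / "r.geojson"
    ranges.write_geojson({"erm": erm}, path)
    back = ranges.read_geojson(path)
    assert back["erm"].equals(erm) or back["erm"].symmetric_difference(erm).area < 1e-9
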