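"""Biogeographical (BR) and potential (PR) range construction.

A species' BR is where it is currently known to occur — an expert range map
(ERM) when one exists, otherwise a data-driven construction from occurrence
records intersected with biogeographic province and depth-zone partitions.
The PR admits plausible future shifts by widening the BR. Both are built by
degree-buffering the source polygon (1 deg for BR, 10 deg for PR, literal in
lon/lat space), clipping to the ocean basin(s) the source touches, and
cropping out all land. Occurrence flags are then refreshed against the BR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

from .grid import EARTH_RADIUS_KM, Raster, mask_to_polygons, rasterize, spherical_area_km2

BR_BUFFER_DEG = 1.0
PR_BUFFER_DEG = 10.0
PROVINCE_SHARE_THRESHOLD = 0.033
ARCTIC_SHARE_THRESHOLD = 0.005

#: spatial-thinning rule: (max n, thinning distance km); None = no thinning
THINNING_RULE = [(1000, None), (5000, 20.0), (np.inf, 30.0)]


class RangeConstructionError(RuntimeError):
    pass


@dataclass
class RangeSet:
    """BR and PR polygons for one taxon, with spherical areas in km^2."""

    taxon_id: str
    br: shapely.Geometry
    pr: shapely.Geometry
    provenance: str  # "erm" or "derived"

    @property
    def br_area_km2(self) -> float:
        return spherical_area_km2(self.br)

    @property
    def pr_area_km2(self) -> float:
        return spherical_area_km2(self.pr)


@dataclass
class BioPartition:
    """Biogeographic provinces and sea-floor depth zones.

    ``provinces`` maps province id -> polygon (pairwise interior-disjoint);
    ``depth_zones`` maps zone name (coastal_upper_bathyal/bathyal/abyssal/
    hadal) -> polygon; ``arctic_units`` optionally subdivides the province
    named by ``arctic_province_id``.
    """

    provinces: dict[str, shapely.Geometry]
    depth_zones: dict[str, shapely.Geometry]
    arctic_units: dict[str, shapely.Geometry] = field(default_factory=dict)
    arctic_province_id: str | None = None

    @property
    def coastal_zone(self) -> shapely.Geometry:
        return self.depth_zones["coastal_upper_bathyal"]


def _valid(records: pd.DataFrame) -> pd.DataFrame:
    return records.loc[records["flag"] != 0.0]


def _square_buffer(geometry, distance: float):
    # literal lon/lat buffering; mitred joins + square caps keep rectangles
    # rectangular, matching a per-axis degree expansion
    return geometry.buffer(distance, cap_style="square", join_style="mitre")


def basin_polygon(ocean: Raster, seed_geometry) -> shapely.Geometry:
    """Union of the connected ocean components the seed geometry touches."""
    mask = ocean.mask
    labels, n = ndimage.label(mask)
    seed_cells = rasterize(seed_geometry, ocean.grid) & mask
    touched = np.unique(labels[seed_cells])
    touched = touched[touched > 0]
    if touched.size == 0:
        # fall back to components intersecting the geometry's footprint
        inter = np.zeros_like(mask)
        minx, miny, maxx, maxy = seed_geometry.bounds
        lon2d, lat2d = ocean.grid.center_mesh()
        inter = (lon2d >= minx) & (lon2d <= maxx) & (lat2d >= miny) & (lat2d <= maxy)
        touched = np.unique(labels[inter & mask])
        touched = touched[touched > 0]
    if touched.size == 0:
        raise RangeConstructionError("range geometry touches no ocean basin")
    return mask_to_polygons(np.isin(labels, touched), ocean.grid)


def _buffer_and_mask(pre_range, ocean: Raster, taxon_id: str, provenance: str) -> RangeSet:
    basin = basin_polygon(ocean, pre_range)
    br = _square_buffer(pre_range, BR_BUFFER_DEG).intersection(basin)
    pr = _square_buffer(pre_range, PR_BUFFER_DEG).intersection(basin)
    if br.is_empty:
        raise RangeConstructionError("biogeographical range is empty after masking")
    return RangeSet(taxon_id=taxon_id, br=br, pr=pr, provenance=provenance)


def build_from_erm(erm, ocean: Raster, taxon_id: str = "") -> RangeSet:
    """BR/PR from an expert range map.

    BR = (ERM + 1 deg) and PR = (ERM + 10 deg), both clipped to the connected
    ocean components the ERM intersects (which also removes all land).
    Multiple maps for one accepted name must be unioned beforehand.
    """
    if erm is None or erm.is_empty:
        raise RangeConstructionError("empty expert range map")
    if not rasterize(erm, ocean.grid)[ocean.mask].any() and not erm.intersects(
        mask_to_polygons(ocean.mask, ocean.grid)
    ):
        raise RangeConstructionError("expert range map lies entirely on land")
    return _buffer_and_mask(erm, ocean, taxon_id, "erm")


def bounding_box_from_occurrences(records: pd.DataFrame, min_size: float = 0.0):
    """Axis-aligned box over the surviving (non-erroneous) records.

    A degenerate (point or line) box is inflated by ``min_size`` degrees per
    side so it remains valid geometry.
    """
    valid = _valid(records)
    if len(valid) == 0:
        raise RangeConstructionError("no valid occurrence records for bounding box")
    lon = valid["lon"].to_numpy(float)
    lat = valid["lat"].to_numpy(float)
    minx, maxx = lon.min(), lon.max()
    miny, maxy = lat.min(), lat.max()
    if min_size > 0:
        if maxx - minx < min_size:
            minx, maxx = minx - min_size / 2, maxx + min_size / 2
        if maxy - miny < min_size:
            miny, maxy = miny - min_size / 2, maxy + min_size / 2
    return box(minx, miny, maxx, maxy)


def merge_boxes(boxes):
    """Merge bounding boxes by the most extreme coordinates."""
    bounds = np.array([b.bounds for b in boxes])
    return box(bounds[:, 0].min(), bounds[:, 1].min(), bounds[:, 2].max(), bounds[:, 3].max())


def thinning_distance_km(n_records: int) -> float | None:
    """Thinning distance by dataset size: none <=1000, 20 km <=5000, else 30 km."""
    for cutoff, dist in THINNING_RULE:
        if n_records <= cutoff:
            return dist
    raise AssertionError("unreachable")


def spatial_thin(records: pd.DataFrame, seed: int, distance_km: float | None = "auto"):
    """Greedy great-circle thinning over a seed-shuffled record order.

    No surviving pair is closer than the thinning distance; the distance
    follows :func:`thinning_distance_km` unless given explicitly. Selection
    is deterministic under the seed.
    """
    if distance_km == "auto":
        distance_km = thinning_distance_km(len(records))
    if distance_km is None or len(records) <= 1:
        return records.copy()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    lon = np.radians(records["lon"].to_numpy(float))
    lat = np.radians(records["lat"].to_numpy(float))
    xyz = np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )
    # chord length equivalent to the great-circle thinning distance
    chord = 2.0 * np.sin(distance_km / (2.0 * EARTH_RADIUS_KM))
    tree = cKDTree(xyz)
    removed = np.zeros(len(records), dtype=bool)
    kept = np.zeros(len(records), dtype=bool)
    for i in order:
        if removed[i]:
            continue
        kept[i] = True
        for j in tree.query_ball_point(xyz[i], chord):
            if j != i:
                removed[j] = True
    return records.iloc[np.flatnonzero(kept)].copy()


def _shares(records: pd.DataFrame, geoms: dict) -> dict[str, float]:
    lon = records["lon"].to_numpy(float)
    lat = records["lat"].to_numpy(float)
    n = len(records)
    return {
        key: float(np.sum(shapely.contains_xy(g, lon, lat))) / n
        for key, g in geoms.items()
    }


def _filter_by_share(shares: dict[str, float], threshold: float, mode: str) -> list[str]:
    if mode == "per_unit":
        return [k for k, s in shares.items() if s > threshold]
    if mode == "cumulative":
        # drop the smallest units while their cumulative share stays <= threshold
        ordered = sorted(shares, key=shares.get)
        cum, dropped = 0.0, set()
        for k in ordered:
            if cum + shares[k] <= threshold:
                cum += shares[k]
                dropped.add(k)
            else:
                break
        return [k for k in shares if k not in dropped]
    raise ValueError(f"unknown share-filter mode {mode!r}")


def derive_range(
    records: pd.DataFrame,
    profile,
    partition: BioPartition,
    ocean: Raster,
    share_threshold: float = PROVINCE_SHARE_THRESHOLD,
    share_mode: str = "per_unit",
) -> RangeSet:
    """BR/PR for a species without an expert range map.

    Pelagic species: provinces intersecting the occurrence bounding box,
    cropped to the coastal zone for pelagic-neritic species, keeping
    provinces holding more than 3.3% of occurrences. Benthic/demersal
    species: the intersection of depth layers and provinces each holding
    more than 3.3% (reef-associated restricted to the coastal zone). Within
    the Arctic province, sub-units below a 0.5% share are removed. The
    result is then buffered/masked exactly as an expert map would be.

    ``records`` are expected to be cleaned, bounding-box filtered and
    spatially thinned already.
    """
    valid = _valid(records)
    if len(valid) == 0:
        raise RangeConstructionError("no valid occurrence records")
    bbox = bounding_box_from_occurrences(valid, min_size=ocean.grid.resolution)

    candidates = {
        pid: g for pid, g in partition.provinces.items() if g.intersects(bbox)
    }
    if not candidates:
        raise RangeConstructionError("no province intersects the occurrence bounding box")

    pelagic = profile.bottom_class == "pelagic"
    label = str(profile.habitat_label).strip().lower()
    if pelagic:
        if label == "pelagic-neritic":
            candidates = {
                pid: g.intersection(partition.coastal_zone)
                for pid, g in candidates.items()
            }
            candidates = {pid: g for pid, g in candidates.items() if not g.is_empty}
        shares = _shares(valid, candidates)
        kept = _filter_by_share(shares, share_threshold, share_mode)
        if not kept:
            raise RangeConstructionError(
                "all provinces fall at or below the share threshold; "
                "consider relaxing share_threshold"
            )
        pre_range = unary_union([candidates[k] for k in kept])
    else:
        layer_shares = _shares(valid, partition.depth_zones)
        kept_layers = _filter_by_share(layer_shares, share_threshold, share_mode)
        prov_shares = _shares(valid, candidates)
        kept_provs = _filter_by_share(prov_shares, share_threshold, share_mode)
        if not kept_layers or not kept_provs:
            raise RangeConstructionError(
                "depth-layer/province filtering removed everything; "
                "consider relaxing share_threshold"
            )
        pre_range = unary_union([partition.depth_zones[k] for k in kept_layers]).intersection(
            unary_union([candidates[k] for k in kept_provs])
        )
        if label == "reef-associated":
            pre_range = pre_range.intersection(partition.coastal_zone)
        if pre_range.is_empty:
            raise RangeConstructionError("depth-layer/province intersection is empty")

    if partition.arctic_units and partition.arctic_province_id in partition.provinces:
        arctic = partition.provinces[partition.arctic_province_id]
        if pre_range.intersects(arctic):
            unit_shares = _shares(valid, partition.arctic_units)
            kept_units = [
                k for k, s in unit_shares.items() if s > ARCTIC_SHARE_THRESHOLD
            ]
            refined = unary_union(
                [partition.arctic_units[k] for k in kept_units]
            ) if kept_units else shapely.Polygon()
            pre_range = pre_range.difference(arctic).union(
                pre_range.intersection(arctic).intersection(refined)
            )

    return _buffer_and_mask(pre_range, ocean, profile.taxon_id, "derived")


def reflag_by_range(records: pd.DataFrame, range_set: RangeSet) -> pd.DataFrame:
    """Set flag=1 inside the BR and flag=0 outside.

    The BR excludes land, so land records come out erroneous automatically.
    Records already flagged erroneous stay erroneous.
    """
    out = records.copy()
    inside = shapely.contains_xy(
        range_set.br, out["lon"].to_numpy(float), out["lat"].to_numpy(float)
    )
    already_bad = out["flag"].to_numpy() == 0.0
    out["flag"] = np.where(inside & ~already_bad, 1.0, 0.0)
    return out


def write_geojson(geometries: dict, path) -> None:
    """Write named geometries as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}
        for name, geom in geometries.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    return {
        feat["properties"].get("name", str(i)): shape(feat["geometry"])
        for i, feat in enumerate(data["features"])
    }
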