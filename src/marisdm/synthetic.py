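"""Synthetic ocean worlds with known ground truth.

Every pipeline stage can be exercised end-to-end on a generated world: a
rectangular lon/lat domain with a continent along its eastern edge, a shelf
that deepens offshore, smooth environmental gradients (latitudinal
temperature plus seeded noise, covarying oxygen, near-coast productivity),
spatially uniform future warming deltas, latitudinal biogeographic
provinces, bathymetry-derived depth zones, and species with known
truncated-Gaussian niches from which error-injected occurrence tables are
drawn. Regenerating with the same seed is bit-identical.

The default future temperature deltas (+0.86 / +1.51 / +2.89 deg C by the
2090s for the low/moderate/high-emission scenarios, roughly halved by the
2050s) follow the projected global mean SST rises of the SSP1-2.6, SSP2-4.5
and SSP5-8.5 scenario families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .envgrid import EnvStack
from .grid import Grid, Raster, mask_to_polygons
from .ranges import BioPartition

#: end-century mean warming by scenario (deg C); mid-century scales by 0.55
SCENARIO_WARMING = {"ssp126": 0.86, "ssp245": 1.51, "ssp585": 2.89}
PERIOD_SCALE = {"2050s": 0.55, "2090s": 1.0}

DEPTH_ZONE_BREAKS = [
    ("coastal_upper_bathyal", 0.0, 800.0),
    ("bathyal", 800.0, 3500.0),
    ("abyssal", 3500.0, 6500.0),
    ("hadal", 6500.0, np.inf),
]

#: default error-injection rates for sampled occurrence tables
DEFAULT_ERROR_PROFILE = {
    "land": 0.05,
    "zero_zero": 0.02,
    "duplicate": 0.05,
    "stray": 0.05,
    "missing_date": 0.10,
}


@dataclass
class SyntheticWorld:
    grid: Grid
    land_mask: np.ndarray = field(repr=False)
    bathymetry: Raster = field(repr=False)
    present: EnvStack = field(repr=False)
    partition: BioPartition = field(repr=False)
    deltas: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def ocean_mask(self) -> np.ndarray:
        return ~self.land_mask

    @property
    def ocean(self) -> Raster:
        """Ocean indicator raster (1 on ocean, NaN on land)."""
        vals = np.where(self.ocean_mask, 1.0, np.nan)
        return Raster(self.grid, vals)

    def future(self, scenario: str, period: str = "2090s") -> EnvStack:
        """Present stack plus spatially uniform per-layer deltas."""
        scale = PERIOD_SCALE[period] * SCENARIO_WARMING[scenario] / SCENARIO_WARMING["ssp585"]
        layers = {}
        for name, arr in self.present.layers.items():
            delta = self.deltas.get(name, 0.0) * scale
            layers[name] = arr + delta
        return EnvStack(
            grid=self.grid,
            layers=layers,
            period=period,
            scenario=scenario,
            stratum=self.present.stratum,
        )


@dataclass
class TrueSpecies:
    """A species with a known product-Gaussian niche over the environment."""

    taxon_id: str
    habitat_label: str
    niche: dict[str, tuple[float, float]]  # variable -> (centre, breadth sd)
    depth_min: float | None = None
    depth_max: float | None = None
    range_cutoff: float = 0.5

    def suitability(self, stack: EnvStack) -> Raster:
        """True suitability in [0, 1] per ocean cell (Gaussian product)."""
        s = np.ones(stack.grid.shape)
        for var, (centre, breadth) in self.niche.items():
            z = (stack.layers[var] - centre) / breadth
            s = s * np.exp(-0.5 * z**2)
        s = np.where(stack.ocean_mask, s, np.nan)
        return Raster(stack.grid, s)

    def true_range_mask(self, stack: EnvStack) -> np.ndarray:
        s = self.suitability(stack)
        return np.where(np.isfinite(s.values), s.values >= self.range_cutoff, False)


def _smooth_noise(rng, shape, sigma=3.0, amplitude=1.0):
    return amplitude * ndimage.gaussian_filter(rng.standard_normal(shape), sigma)


def make_world(
    extent: tuple[float, float, float, float] = (0.0, 40.0, -30.0, 30.0),
    resolution: float = 0.5,
    n_provinces: int = 4,
    deltas: dict[str, float] | None = None,
    seed: int = 0,
    land_fraction: float = 0.15,
) -> SyntheticWorld:
    """Build a synthetic world on the given lon/lat extent.

    A continent occupies roughly ``land_fraction`` of the domain along the
    eastern edge (with a seeded, wiggly coastline); the sea floor deepens
    with distance from the coast; temperature follows a latitudinal gradient
    plus smooth noise; provinces are latitudinal bands; depth zones are cut
    from the bathymetry at 800/3500/6500 m.
    """
    lon0, lon1, lat0, lat1 = extent
    if lon1 <= lon0 or lat1 <= lat0:
        raise ValueError(f"degenerate extent {extent}")
    nlon = int(round((lon1 - lon0) / resolution))
    nlat = int(round((lat1 - lat0) / resolution))
    if nlon < 4 or nlat < 4:
        raise ValueError("extent too small for the requested resolution")
    grid = Grid(lon0, lat0, resolution, nlon, nlat)
    rng = np.random.default_rng(seed)

    lon2d, lat2d = grid.center_mesh()
    # wiggly eastern coastline
    coast_lon = lon1 - land_fraction * (lon1 - lon0)
    wiggle = _smooth_noise(rng, (nlat,), sigma=4.0, amplitude=0.04 * (lon1 - lon0))
    land_mask = lon2d > (coast_lon + wiggle[:, None])

    # bathymetry: deepens with distance from the coast, shallow shelf first
    dist_cells = ndimage.distance_transform_edt(~land_mask)
    dist_deg = dist_cells * resolution
    depth = 15.0 + 90.0 * dist_deg + 12.0 * dist_deg**2
    depth = np.where(land_mask, np.nan, np.minimum(depth, 7500.0))
    bathymetry = Raster(grid, depth)

    # environmental layers (surface stratum)
    temperature = 28.0 - 0.4 * np.abs(lat2d) + _smooth_noise(rng, grid.shape, 3.0, 0.6)
    oxygen = 320.0 - 4.5 * temperature + _smooth_noise(rng, grid.shape, 3.0, 5.0)
    ph = 8.15 - 0.004 * np.abs(lat2d) + _smooth_noise(rng, grid.shape, 3.0, 0.01)
    productivity = 2.0 + 18.0 * np.exp(-dist_deg / 4.0) + np.abs(
        _smooth_noise(rng, grid.shape, 3.0, 0.4)
    )
    salinity = 35.0 + 0.02 * lat2d + _smooth_noise(rng, grid.shape, 3.0, 0.15)
    velocity = np.abs(0.15 + _smooth_noise(rng, grid.shape, 3.0, 0.08))

    ocean = ~land_mask
    layers = {
        "dissolved_oxygen": np.where(ocean, oxygen, np.nan),
        "temperature": np.where(ocean, temperature, np.nan),
        "ph": np.where(ocean, ph, np.nan),
        "primary_productivity": np.where(ocean, productivity, np.nan),
        "salinity": np.where(ocean, salinity, np.nan),
        "water_velocity": np.where(ocean, velocity, np.nan),
    }
    present = EnvStack(grid=grid, layers=layers, period="2000s", scenario="present",
                       stratum="surface")

    # provinces: latitudinal bands spanning the full domain
    from shapely.geometry import box as shapely_box

    provinces = {}
    band = (lat1 - lat0) / n_provinces
    for i in range(n_provinces):
        provinces[f"province_{i}"] = shapely_box(
            lon0, lat0 + i * band, lon1, lat0 + (i + 1) * band
        )

    depth_zones = {}
    for name, lo, hi in DEPTH_ZONE_BREAKS:
        mask = ocean & (depth >= lo) & (depth < hi)
        if mask.any():
            depth_zones[name] = mask_to_polygons(mask, grid)
    partition = BioPartition(provinces=provinces, depth_zones=depth_zones)

    if deltas is None:
        deltas = {"temperature": SCENARIO_WARMING["ssp585"]}

    return SyntheticWorld(
        grid=grid,
        land_mask=land_mask,
        bathymetry=bathymetry,
        present=present,
        partition=partition,
        deltas=deltas,
        seed=seed,
    )


def make_species(
    world: SyntheticWorld,
    taxon_id: str = "sp1",
    habitat_label: str = "pelagic",
    centre_lat: float = 10.0,
    breadths: dict[str, float] | None = None,
    depth_range: tuple[float, float] | None = None,
    range_cutoff: float = 0.5,
) -> TrueSpecies:
    """A species whose niche is centred on the conditions at ``centre_lat``.

    The niche is a Gaussian product over temperature and salinity with the
    given breadths (defaults: 3 deg C, 1.5 psu).
    """
    breadths = breadths or {"temperature": 3.0, "salinity": 1.5}
    lat_row = int(
        np.clip(
            (centre_lat - world.grid.lat_min) / world.grid.resolution,
            0,
            world.grid.nlat - 1,
        )
    )
    niche = {}
    for var, breadth in breadths.items():
        row = world.present.layers[var][lat_row]
        niche[var] = (float(np.nanmean(row)), breadth)
    dmin, dmax = (depth_range if depth_range is not None else (None, None))
    return TrueSpecies(
        taxon_id=taxon_id,
        habitat_label=habitat_label,
        niche=niche,
        depth_min=dmin,
        depth_max=dmax,
        range_cutoff=range_cutoff,
    )


def sample_occurrences(
    world: SyntheticWorld,
    species: TrueSpecies,
    n: int,
    seed: int,
    error_profile: dict[str, float] | None = None,
    source: str = "gbif",
) -> pd.DataFrame:
    """Draw an error-injected raw occurrence table for a species.

    Clean presences are drawn from ocean cells with probability proportional
    to the true suitability and jittered within the cell. Errors are injected
    on top at the profile's rates: points on land, points at (0, 0), exact
    duplicates of clean rows, out-of-range strays (ocean cells far outside
    the true range), and missing collection dates. Ground truth is recorded
    in ``is_error`` / ``error_kind`` columns for test assertions.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    profile = dict(DEFAULT_ERROR_PROFILE if error_profile is None else error_profile)
    rng = np.random.default_rng(seed)
    grid = world.grid
    suit = species.suitability(world.present).values
    flat = np.nan_to_num(suit, nan=0.0).ravel()
    if flat.sum() == 0:
        raise ValueError("species has zero suitability everywhere")
    p = flat / flat.sum()

    def _cells_to_points(idx):
        rows, cols = np.unravel_index(idx, grid.shape)
        jit = rng.uniform(-0.5, 0.5, size=(len(idx), 2)) * grid.resolution
        lon = grid.lon_centers()[cols] + jit[:, 0]
        lat = grid.lat_centers()[rows] + jit[:, 1]
        return lon, lat

    idx = rng.choice(flat.size, size=n, replace=True, p=p)
    lon, lat = _cells_to_points(idx)
    years = rng.integers(1990, 2024, size=n).astype(float)
    months = rng.integers(1, 13, size=n).astype(float)

    base = pd.DataFrame(
        {
            "taxon_id": species.taxon_id,
            "lon": lon,
            "lat": lat,
            "year": years,
            "month": months,
            "basis_of_record": rng.choice(["observation", "specimen"], size=n),
            "source": source,
            "original_flags": [[] for _ in range(n)],
            "flag": np.nan,
            "is_error": False,
            "error_kind": "",
        }
    )

    extras = []

    def _n_of(kind):
        return int(rng.binomial(n, profile.get(kind, 0.0)))

    # land points
    land_idx = np.flatnonzero(world.land_mask.ravel())
    k = _n_of("land")
    if k and land_idx.size:
        pick = rng.choice(land_idx, size=k)
        llon, llat = _cells_to_points(pick)
        extras.append(_error_rows(base, species, llon, llat, rng, "land"))

    # (0,0) points
    k = _n_of("zero_zero")
    if k:
        extras.append(
            _error_rows(base, species, np.zeros(k), np.zeros(k), rng, "zero_zero")
        )

    # out-of-range strays: ocean cells well outside the true range (beyond
    # the 1-degree buffer a derived range would add), so downstream
    # re-flagging can catch them
    true_range = species.true_range_mask(world.present)
    dilate_cells = max(1, int(np.ceil(2.0 / grid.resolution)))
    near_range = ndimage.binary_dilation(true_range, iterations=dilate_cells)
    stray_ok = (world.ocean_mask & ~near_range).ravel()
    stray_idx = np.flatnonzero(stray_ok)
    k = _n_of("stray")
    if k and stray_idx.size:
        pick = rng.choice(stray_idx, size=k)
        slon, slat = _cells_to_points(pick)
        extras.append(_error_rows(base, species, slon, slat, rng, "stray"))

    # exact duplicates of clean rows
    k = _n_of("duplicate")
    if k:
        dup = base.sample(n=k, replace=True, random_state=int(rng.integers(2**31)))
        dup = dup.copy()
        dup["is_error"] = True
        dup["error_kind"] = "duplicate"
        extras.append(dup)

    out = pd.concat([base, *extras], ignore_index=True)

    # missing dates on a random subset (not an error, a completeness gap)
    k = _n_of("missing_date")
    if k:
        rows = rng.choice(len(out), size=min(k, len(out)), replace=False)
        out.loc[rows, ["year", "month"]] = np.nan

    return out.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def _error_rows(base, species, lon, lat, rng, kind):
    k = len(lon)
    return pd.DataFrame(
        {
            "taxon_id": species.taxon_id,
            "lon": lon,
            "lat": lat,
            "year": rng.integers(1990, 2024, size=k).astype(float),
            "month": rng.integers(1, 13, size=k).astype(float),
            "basis_of_record": "observation",
            "source": base["source"].iloc[0] if len(base) else "gbif",
            "original_flags": [[] for _ in range(k)],
            "flag": np.nan,
            "is_error": True,
            "error_kind": kind,
        }
    )


def make_erm(
    species: TrueSpecies,
    world: SyntheticWorld,
    simplify_tolerance: float = 0.0,
    erode_deg: float = 0.0,
):
    """Polygonize the species' true range into a synthetic expert range map.

    ``erode_deg`` shrinks the polygon to mimic an expert map that
    under-covers the realized range; ``simplify_tolerance`` coarsens the
    outline. Built from ocean cells only, so it never touches land.
    """
    mask = species.true_range_mask(world.present)
    if not mask.any():
        raise ValueError("species has an empty true range")
    poly = mask_to_polygons(mask, world.grid)
    if erode_deg > 0:
        eroded = poly.buffer(-erode_deg)
        if not eroded.is_empty:
            poly = eroded
    if simplify_tolerance > 0:
        poly = poly.simplify(simplify_tolerance)
    return poly
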