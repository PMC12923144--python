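"""Environmental raster stacks: resolution choice, regridding, binning,
environmental-space thinning, and range-map pseudo-occurrences.

A stack is a set of named layers (dissolved_oxygen, temperature, ph,
primary_productivity, salinity, water_velocity, depth) sharing one grid and
one ocean mask, tagged with a period (2000s/2050s/2090s), a climate scenario
(present or an SSP) and the vertical stratum (surface or benthic) it
describes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grid import Grid, Raster, rasterize

RESOLUTIONS = (0.05, 0.1, 0.2)

#: default per-layer bin sizes used to define "unique environments"
DEFAULT_BIN_SIZES = {
    "dissolved_oxygen": 10.0,
    "temperature": 0.05,
    "ph": 0.1,
    "primary_productivity": 0.5,
    "salinity": 0.1,
    "water_velocity": 0.02,
    "depth": 5.0,
}

PSEUDO_OCC_CAP = 1000
PSEUDO_OCC_FRACTION = 0.4


class GenerationError(RuntimeError):
    pass


@dataclass
class EnvStack:
    """Named environmental layers on a shared grid.

    All layers must share shape and missing-value (ocean) mask; NaN cells are
    land or out-of-domain.
    """

    grid: Grid
    layers: dict[str, np.ndarray] = field(repr=False)
    period: str = "2000s"
    scenario: str = "present"
    stratum: str = "surface"

    def __post_init__(self):
        shapes = {name: arr.shape for name, arr in self.layers.items()}
        if any(s != self.grid.shape for s in shapes.values()):
            raise ValueError(f"layer shapes {shapes} do not match grid {self.grid.shape}")
        masks = [np.isfinite(a) for a in self.layers.values()]
        if masks and not all(np.array_equal(masks[0], m) for m in masks[1:]):
            raise ValueError("layers disagree on the ocean mask")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def ocean_mask(self) -> np.ndarray:
        first = next(iter(self.layers.values()))
        return np.isfinite(first)

    def raster(self, name: str) -> Raster:
        return Raster(self.grid, self.layers[name])

    def sample(self, lon, lat) -> pd.DataFrame:
        """Per-point environment values, one column per layer."""
        return pd.DataFrame(
            {name: self.raster(name).sample(lon, lat) for name in self.layers}
        )

    def table(self) -> pd.DataFrame:
        """Ocean cells as rows (columns = layers), in row-major cell order."""
        mask = self.ocean_mask
        return pd.DataFrame(
            {name: arr[mask] for name, arr in self.layers.items()}
        )


def choose_resolution(region_cell_count: int, global_cell_count: int) -> float:
    """Working resolution from the modelled share of global ocean cells.

    <= 1/3 of ocean cells -> 0.05 deg; (1/3, 2/3] -> 0.1 deg; > 2/3 -> 0.2 deg.
    """
    if global_cell_count <= 0:
        raise ValueError("global cell count must be positive")
    if region_cell_count > global_cell_count:
        raise ValueError("region cannot exceed the global ocean")
    p = region_cell_count / global_cell_count
    if p <= 1 / 3:
        return 0.05
    if p <= 2 / 3:
        return 0.1
    return 0.2


def _aggregate(values: np.ndarray, factor: int) -> np.ndarray:
    nlat, nlon = values.shape
    if nlat % factor or nlon % factor:
        raise ValueError("grid shape not divisible by aggregation factor")
    blocks = values.reshape(nlat // factor, factor, nlon // factor, factor)
    counts = np.isfinite(blocks).sum(axis=(1, 3))
    sums = np.nansum(np.nan_to_num(blocks, nan=0.0), axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def _disaggregate(values: np.ndarray, factor: int) -> np.ndarray:
    # bilinear interpolation between coarse cell centres; edges held at the
    # nearest centre value so the output covers the full extent
    nlat, nlon = values.shape
    filled = values.copy()
    coarse_mask = np.isfinite(values)
    if not coarse_mask.all():
        # fill land for interpolation; re-mask afterwards
        filled[~coarse_mask] = np.nanmean(values) if coarse_mask.any() else 0.0
    yc = (np.arange(nlat) + 0.5) * factor
    xc = (np.arange(nlon) + 0.5) * factor
    interp = RegularGridInterpolator(
        (yc, xc), filled, method="linear", bounds_error=False, fill_value=None
    )
    yf = np.arange(nlat * factor) + 0.5
    xf = np.arange(nlon * factor) + 0.5
    yy, xx = np.meshgrid(yf, xf, indexing="ij")
    # clamp to the centre span: constant extrapolation at the edges
    pts = np.column_stack(
        [np.clip(yy.ravel(), yc[0], yc[-1]), np.clip(xx.ravel(), xc[0], xc[-1])]
    )
    fine = interp(pts).reshape(nlat * factor, nlon * factor)
    fine_mask = np.repeat(np.repeat(coarse_mask, factor, 0), factor, 1)
    fine[~fine_mask] = np.nan
    return fine


def regrid(stack: EnvStack, target_resolution: float) -> EnvStack:
    """Aggregate (block mean over ocean cells) or disaggregate (bilinear).

    The target must be an integer multiple or divisor of the source
    resolution; the missing-value mask is propagated block-wise.
    """
    src = stack.grid.resolution
    if np.isclose(src, target_resolution):
        return stack
    ratio = target_resolution / src
    if ratio > 1:
        factor = int(round(ratio))
        if not np.isclose(ratio, factor):
            raise ValueError(f"non-integral aggregation factor {ratio}")
        layers = {n: _aggregate(a, factor) for n, a in stack.layers.items()}
        nlat, nlon = stack.grid.shape
        grid = Grid(
            stack.grid.lon_min,
            stack.grid.lat_min,
            target_resolution,
            nlon // factor,
            nlat // factor,
        )
    else:
        factor = int(round(1 / ratio))
        if not np.isclose(1 / ratio, factor):
            raise ValueError(f"non-integral disaggregation factor {1 / ratio}")
        layers = {n: _disaggregate(a, factor) for n, a in stack.layers.items()}
        nlat, nlon = stack.grid.shape
        grid = Grid(
            stack.grid.lon_min,
            stack.grid.lat_min,
            target_resolution,
            nlon * factor,
            nlat * factor,
        )
    out = replace(stack, grid=grid, layers=layers)
    return out


def snap(values, bin_size: float, mode: str = "nearest"):
    """Snap values to multiples of ``bin_size`` (nearest by default)."""
    values = np.asarray(values, dtype=float)
    if mode == "nearest":
        return np.round(values / bin_size) * bin_size
    if mode == "floor":
        return np.floor(values / bin_size) * bin_size
    raise ValueError(f"unknown snapping mode {mode!r}")


def bin_environment(
    stack: EnvStack,
    bin_sizes: dict[str, float] | None = None,
    mode: str = "nearest",
) -> Raster:
    """Integer raster of 'unique environment' ids.

    Every layer value is snapped to the nearest multiple of its bin size and
    cells with identical snapped tuples share an id. Land cells are NaN.
    """
    bin_sizes = dict(DEFAULT_BIN_SIZES if bin_sizes is None else bin_sizes)
    missing = [n for n in stack.layers if n not in bin_sizes]
    if missing:
        raise KeyError(f"no bin size configured for layer(s): {missing}")
    mask = stack.ocean_mask
    snapped = np.column_stack(
        [snap(stack.layers[n][mask], bin_sizes[n], mode) for n in stack.names]
    )
    _, inverse = np.unique(snapped, axis=0, return_inverse=True)
    keys = np.full(stack.grid.shape, np.nan)
    keys[mask] = inverse
    return Raster(stack.grid, keys)


def count_unique_environments(stack: EnvStack, bin_sizes=None) -> int:
    keys = bin_environment(stack, bin_sizes)
    return int(np.unique(keys.values[np.isfinite(keys.values)]).size)


def env_thin(records: pd.DataFrame, env_keys: Raster, seed: int) -> pd.DataFrame:
    """Keep exactly one record per unique environment, chosen at random.

    Every record must fall on an ocean cell of the key raster; the set of
    represented environments is unchanged by construction.
    """
    keys = env_keys.sample(records["lon"].to_numpy(float), records["lat"].to_numpy(float))
    off = np.flatnonzero(~np.isfinite(keys))
    if off.size:
        raise ValueError(
            f"records off the environmental grid at rows {off.tolist()[:10]}"
        )
    rng = np.random.default_rng(seed)
    keep = []
    order = records.reset_index(drop=True)
    for _, idx in pd.Series(np.arange(len(order))).groupby(keys):
        keep.append(rng.choice(idx.to_numpy()))
    return order.iloc[np.sort(keep)].copy()


def generate_pseudo_occurrences(
    erm,
    bathymetry: Raster,
    depth_range: tuple[float, float] | None,
    seed: int,
    taxon_id: str = "",
    exclude_lonlat: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample pseudo-occurrence points inside an expert range map.

    Candidate cells are those whose centre lies inside the range polygon and
    (when a depth range is known) whose sea-floor depth falls within it. The
    sample size is min(1000, floor(0.4 * number of candidate cells)), drawn
    without replacement; cells holding a real occurrence are excluded so the
    generated points only add information. Records are tagged with
    ``basis_of_record='erm_generated'``.
    """
    inside = rasterize(erm, bathymetry.grid)
    candidates = inside & bathymetry.mask
    if depth_range is not None:
        lo, hi = depth_range
        candidates &= (bathymetry.values >= lo) & (bathymetry.values <= hi)
    if exclude_lonlat is not None and len(exclude_lonlat):
        r, c = bathymetry.grid.index_of(exclude_lonlat[:, 0], exclude_lonlat[:, 1])
        ok = (r >= 0) & (c >= 0)
        candidates[r[ok], c[ok]] = False
    rows, cols = np.nonzero(candidates)
    n_candidates = rows.size
    if n_candidates == 0:
        raise GenerationError("no candidate cells inside the range map")
    n = min(PSEUDO_OCC_CAP, int(np.floor(PSEUDO_OCC_FRACTION * n_candidates)))
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_candidates, size=n, replace=False)
    lons = bathymetry.grid.lon_centers()[cols[pick]]
    lats = bathymetry.grid.lat_centers()[rows[pick]]
    return pd.DataFrame(
        {
            "taxon_id": taxon_id,
            "lon": lons,
            "lat": lats,
            "year": np.nan,
            "month": np.nan,
            "basis_of_record": "erm_generated",
            "source": "synthetic",
            "original_flags": [[] for _ in range(n)],
            "flag": 1.0,
        }
    )
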