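"""Projection of the fitted ensemble onto environmental stacks, clamping
masks, binarization, climate-change indices and richness stacking.

Change indices compare binarized present and future suitability inside the
potential range: invasion cells are suitable in the future but not now,
extinction cells the reverse; both are expressed as a percentage of the
PR's spherical area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envgrid import EnvStack
from .ensemble import EnsembleResult
from .grid import Raster, masked_area_km2, rasterize


class ProjectionError(ValueError):
    pass


@dataclass
class ProjectionProduct:
    """Per-cell ensemble products for one scenario/period, masked to the PR."""

    hsi: Raster
    committee: Raster
    cv: Raster
    clamping: Raster
    scenario: str
    period: str


@dataclass
class ChangeIndices:
    invasion: Raster  # 1 where the species appears
    extinction: Raster  # 1 where it disappears
    percent_area_gained: float
    percent_area_lost: float
    area_gained_km2: float
    area_lost_km2: float


def project(ensemble: EnsembleResult, stack: EnvStack, pr) -> ProjectionProduct:
    """Ensemble mean / committee / CV / clamping rasters over the PR."""
    missing = [v for v in ensemble.variables if v not in stack.layers]
    if missing:
        raise ProjectionError(f"stack is missing modelled layer(s): {missing}")
    domain = rasterize(pr, stack.grid) & stack.ocean_mask
    rows, cols = np.nonzero(domain)
    X = pd.DataFrame(
        {v: stack.layers[v][rows, cols] for v in ensemble.variables}
    )
    table = ensemble.predict_table(X)

    def _fill(series) -> Raster:
        out = np.full(stack.grid.shape, np.nan)
        out[rows, cols] = series
        return Raster(stack.grid, out)

    clamp_counts = np.zeros(len(rows))
    for v in ensemble.variables:
        lo = ensemble.calibration_ranges.loc[v, "min"]
        hi = ensemble.calibration_ranges.loc[v, "max"]
        vals = stack.layers[v][rows, cols]
        clamp_counts += (vals < lo) | (vals > hi)

    return ProjectionProduct(
        hsi=_fill(table["hsi"].to_numpy()),
        committee=_fill(table["committee"].to_numpy()),
        cv=_fill(table["cv"].to_numpy()),
        clamping=_fill(clamp_counts),
        scenario=stack.scenario,
        period=stack.period,
    )


def clamping_mask(stack: EnvStack, calibration_ranges) -> Raster:
    """Per-cell count of variables outside their calibration range."""
    counts = np.zeros(stack.grid.shape)
    for v in calibration_ranges.index:
        if v not in stack.layers:
            raise ProjectionError(f"stack is missing layer {v!r}")
        lo, hi = calibration_ranges.loc[v, "min"], calibration_ranges.loc[v, "max"]
        vals = stack.layers[v]
        counts += np.where(np.isfinite(vals), (vals < lo) | (vals > hi), 0)
    counts = np.where(stack.ocean_mask, counts, np.nan)
    return Raster(stack.grid, counts)


def binarize(hsi: Raster, threshold: float) -> Raster:
    """Presence (1) where HSI >= threshold, absence (0) elsewhere on-mask."""
    if not (0 < threshold < 1):
        raise ProjectionError("threshold must lie strictly inside (0, 1)")
    vals = np.where(hsi.mask, (hsi.values >= threshold).astype(float), np.nan)
    return Raster(hsi.grid, vals)


def change_indices(binary_present: Raster, binary_future: Raster, pr) -> ChangeIndices:
    """Invasion/extinction rasters and the % of PR area gained and lost."""
    if not binary_present.grid.compatible(binary_future.grid):
        raise ProjectionError("present and future rasters are on different grids")
    grid = binary_present.grid
    domain = rasterize(pr, grid) & binary_present.mask & binary_future.mask
    pres = binary_present.values == 1
    fut = binary_future.values == 1
    inv = domain & fut & ~pres
    ext = domain & pres & ~fut
    pr_area = masked_area_km2(domain, grid)
    gained = masked_area_km2(inv, grid)
    lost = masked_area_km2(ext, grid)

    def _to_raster(mask):
        vals = np.where(domain, mask.astype(float), np.nan)
        return Raster(grid, vals)

    return ChangeIndices(
        invasion=_to_raster(inv),
        extinction=_to_raster(ext),
        percent_area_gained=100.0 * gained / pr_area if pr_area else 0.0,
        percent_area_lost=100.0 * lost / pr_area if pr_area else 0.0,
        area_gained_km2=gained,
        area_lost_km2=lost,
    )


def stack_richness(binary_maps: list[Raster], normalized: bool = False) -> Raster:
    """Per-cell species richness (sum of presences; optionally / max)."""
    if not binary_maps:
        raise ProjectionError("no species maps to stack")
    grid = binary_maps[0].grid
    for r in binary_maps[1:]:
        if not grid.compatible(r.grid):
            raise ProjectionError("richness stacking requires a shared grid")
    total = np.zeros(grid.shape)
    any_data = np.zeros(grid.shape, dtype=bool)
    for r in binary_maps:
        total += np.where(r.mask, r.values, 0.0)
        any_data |= r.mask
    total = np.where(any_data, total, np.nan)
    if normalized:
        peak = np.nanmax(total)
        if peak > 0:
            total = total / peak
    return Raster(grid, total)


def resample_max(raster: Raster, factor: int) -> Raster:
    """Coarsen by taking the per-block maximum (for cross-dataset comparison)."""
    from .grid import Grid

    nlat, nlon = raster.grid.shape
    if nlat % factor or nlon % factor:
        raise ProjectionError("grid shape not divisible by the resampling factor")
    blocks = raster.values.reshape(nlat // factor, factor, nlon // factor, factor)
    with np.errstate(invalid="ignore"):
        coarse = np.nanmax(np.nan_to_num(blocks, nan=-np.inf), axis=(1, 3))
    coarse[~np.isfinite(coarse)] = np.nan
    g = raster.grid
    grid = Grid(g.lon_min, g.lat_min, g.resolution * factor, nlon // factor, nlat // factor)
    return Raster(grid, coarse)
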