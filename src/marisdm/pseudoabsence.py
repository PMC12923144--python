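"""Pseudo-absence generation inside the potential range.

Presence-only data need artificial absences for discrimination-based model
fitting. Two habitat-appropriate strategies are used:

* pelagic species — the surface range envelope (SRE): per-variable
  [2.5th, 97.5th] percentile bounds of the presence environments; candidate
  absence cells are those where **all** variables fall outside their bounds
  (relaxed to "any variable outside" only when too few such cells exist);
* benthic/demersal species — disk sampling: cells whose great-circle
  distance to the nearest presence lies between 80 and 1000 km.

All candidates are ocean cells inside the potential range; sampling is
uniform without replacement and seed-deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .envgrid import EnvStack
from .grid import EARTH_RADIUS_KM, Raster, rasterize

logger = logging.getLogger(__name__)

SRE_PERCENTILES = (2.5, 97.5)
DISK_MIN_KM = 80.0
DISK_MAX_KM = 1000.0


class PseudoAbsenceError(RuntimeError):
    pass


@dataclass
class Envelope:
    """Per-variable [P2.5, P97.5] bounds of the presence environments."""

    lower: pd.Series
    upper: pd.Series

    @property
    def variables(self) -> list[str]:
        return list(self.lower.index)

    def outside(self, env: pd.DataFrame) -> pd.DataFrame:
        """Boolean frame: True where a value falls outside its bounds."""
        lo = self.lower.reindex(env.columns)
        hi = self.upper.reindex(env.columns)
        return (env < lo) | (env > hi)


def fit_envelope(presence_env: pd.DataFrame) -> Envelope:
    """Fit the surface range envelope with linear-interpolation percentiles."""
    if len(presence_env) < 2:
        raise PseudoAbsenceError("need at least 2 presences to fit an envelope")
    lower = presence_env.quantile(SRE_PERCENTILES[0] / 100, interpolation="linear")
    upper = presence_env.quantile(SRE_PERCENTILES[1] / 100, interpolation="linear")
    degenerate = lower.index[(lower == upper)].tolist()
    if degenerate:
        logger.warning("degenerate envelope bounds for variable(s): %s", degenerate)
    return Envelope(lower=lower, upper=upper)


def _pr_ocean_cells(stack: EnvStack, pr) -> tuple[np.ndarray, np.ndarray]:
    mask = rasterize(pr, stack.grid) & stack.ocean_mask
    rows, cols = np.nonzero(mask)
    return rows, cols


def _cells_to_frame(stack: EnvStack, rows, cols) -> pd.DataFrame:
    lons = stack.grid.lon_centers()[cols]
    lats = stack.grid.lat_centers()[rows]
    out = pd.DataFrame({"lon": lons, "lat": lats})
    for name in stack.names:
        out[name] = stack.layers[name][rows, cols]
    out["role"] = "pseudo_absence"
    return out


def sample_pa_sre(
    stack: EnvStack,
    envelope: Envelope,
    pr,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """SRE pseudo-absences: all variables outside the envelope, inside PR.

    When fewer than ``n`` strict cells exist the rule relaxes to "at least
    one variable outside", with a warning; failing even that is an error.
    """
    rows, cols = _pr_ocean_cells(stack, pr)
    if rows.size == 0:
        raise PseudoAbsenceError("potential range contains no ocean cells")
    env = pd.DataFrame(
        {name: stack.layers[name][rows, cols] for name in envelope.variables}
    )
    outside = envelope.outside(env)
    strict = outside.all(axis=1).to_numpy()
    eligible = np.flatnonzero(strict)
    relaxed = False
    if eligible.size < n:
        relaxed = True
        eligible = np.flatnonzero(outside.any(axis=1).to_numpy())
        logger.warning(
            "only %d cells have every variable outside the envelope; "
            "relaxing to any-variable-outside (%d cells)",
            strict.sum(),
            eligible.size,
        )
    if eligible.size == 0:
        raise PseudoAbsenceError("no environmentally eligible cells inside the PR")
    rng = np.random.default_rng(seed)
    pick = rng.choice(eligible, size=min(n, eligible.size), replace=False)
    out = _cells_to_frame(stack, rows[pick], cols[pick])
    out.attrs["sre_relaxed"] = relaxed
    return out


def sample_pa_disk(
    presences: pd.DataFrame,
    stack: EnvStack,
    pr,
    n: int,
    seed: int,
    min_km: float = DISK_MIN_KM,
    max_km: float = DISK_MAX_KM,
) -> pd.DataFrame:
    """Disk pseudo-absences: 80-1000 km from the nearest presence, inside PR."""
    if len(presences) == 0:
        raise PseudoAbsenceError("need at least one presence")
    rows, cols = _pr_ocean_cells(stack, pr)
    if rows.size == 0:
        raise PseudoAbsenceError("potential range contains no ocean cells")
    cell_lon = stack.grid.lon_centers()[cols]
    cell_lat = stack.grid.lat_centers()[rows]

    def _xyz(lon, lat):
        lon, lat = np.radians(lon), np.radians(lat)
        return np.column_stack(
            [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
        )

    tree = cKDTree(_xyz(presences["lon"].to_numpy(float), presences["lat"].to_numpy(float)))
    chord, _ = tree.query(_xyz(cell_lon, cell_lat), k=1)
    dist_km = 2 * EARTH_RADIUS_KM * np.arcsin(np.clip(chord / 2, 0, 1))
    eligible = np.flatnonzero((dist_km >= min_km) & (dist_km <= max_km))
    if eligible.size == 0:
        raise PseudoAbsenceError(
            f"no ocean cell in the PR lies {min_km}-{max_km} km from a presence"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(eligible, size=min(n, eligible.size), replace=False)
    return _cells_to_frame(stack, rows[pick], cols[pick])


def generate(
    profile,
    presences: pd.DataFrame,
    stack: EnvStack,
    pr,
    seed: int,
    n: int | None = None,
) -> pd.DataFrame:
    """Habitat-appropriate pseudo-absences; n defaults to the presence count."""
    n = len(presences) if n is None else n
    if profile.bottom_class == "pelagic":
        env = stack.sample(
            presences["lon"].to_numpy(float), presences["lat"].to_numpy(float)
        ).dropna()
        envelope = fit_envelope(env)
        return sample_pa_sre(stack, envelope, pr, n, seed)
    return sample_pa_disk(presences, stack, pr, n, seed)
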