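"""Three-axis habitat classification for marine species.

Each species is placed along three spatial descriptors:

* **distance to bottom** — pelagic / demersal / benthic, mapped from the
  habitat label used by trait databases;
* **distance to coast** — neritic / oceanic / generalist, from the share of
  cleaned occurrences falling in the coastal (0–800 m) zone;
* **distance to surface** — membership in depth zones: the pelagic water
  column is split at 200 m and 1000 m (epipelagic / mesopelagic /
  bathypelagic), the sea floor at 800 / 3500 / 6500 m (coastal & upper
  bathyal / bathyal / abyssal / hadal).

Zone bounds are treated as closed intervals, so a depth range touching a
boundary exactly counts as overlapping both zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

#: habitat-label -> bottom class (case-insensitive lookup)
BOTTOM_CLASS = {
    "pelagic": "pelagic",
    "pelagic-oceanic": "pelagic",
    "bathypelagic": "pelagic",
    "pelagic-neritic": "pelagic",
    "demersal": "demersal",
    "benthopelagic": "demersal",
    "bathydemersal": "demersal",
    "benthic": "benthic",
    "reef-associated": "benthic",
}

#: (name, lower, upper) in metres; upper None = unbounded
PELAGIC_ZONES = [
    ("epipelagic", 0.0, 200.0),
    ("mesopelagic", 200.0, 1000.0),
    ("bathypelagic", 1000.0, None),
]
BENTHIC_ZONES = [
    ("coastal_upper_bathyal", 0.0, 800.0),
    ("bathyal", 800.0, 3500.0),
    ("abyssal", 3500.0, 6500.0),
    ("hadal", 6500.0, None),
]

PELAGIC_DEPTH_BUFFER_M = 30.0
COASTAL_SHARE = 0.90
OCCURRENCE_ZONE_SHARE = 0.10


class ClassificationError(ValueError):
    pass


@dataclass
class SpeciesProfile:
    """Habitat traits plus the derived three-axis classes for one species."""

    taxon_id: str
    habitat_label: str
    depth_min: float | None = None
    depth_max: float | None = None
    bottom_class: str | None = None
    coast_class: str | None = None
    vertical_classes: set[str] = field(default_factory=set)

    @property
    def has_depth_range(self) -> bool:
        return (
            self.depth_min is not None
            and self.depth_max is not None
            and np.isfinite(self.depth_min)
            and np.isfinite(self.depth_max)
        )


def classify_bottom(habitat_label: str) -> str:
    """Map a trait-database habitat label to pelagic/demersal/benthic."""
    if habitat_label is None or (isinstance(habitat_label, float) and np.isnan(habitat_label)):
        raise ClassificationError("missing habitat label")
    key = str(habitat_label).strip().lower()
    try:
        return BOTTOM_CLASS[key]
    except KeyError:
        raise ClassificationError(f"unknown habitat label: {habitat_label!r}") from None


def classify_coast(records: pd.DataFrame, coastal_zone) -> str:
    """Neritic / oceanic / generalist from the coastal share of occurrences.

    ``coastal_zone`` is the 0–800 m depth-zone geometry; the share uses only
    records not flagged erroneous. Both the 90% (neritic) and the symmetric
    10% (oceanic) cut are inclusive.
    """
    valid = records.loc[records["flag"] != 0.0]
    if len(valid) == 0:
        raise ClassificationError("no valid occurrence records")
    inside = shapely.contains_xy(
        coastal_zone, valid["lon"].to_numpy(float), valid["lat"].to_numpy(float)
    )
    p = float(np.mean(inside))
    eps = 1e-12  # boundary cuts are inclusive; guard float representation
    if p >= COASTAL_SHARE - eps:
        return "neritic"
    if p <= (1.0 - COASTAL_SHARE) + eps:
        return "oceanic"
    return "generalist"


def _overlapping_zones(zones, lo: float, hi: float) -> set[str]:
    # closed-interval overlap: touching a boundary counts
    out = set()
    for name, zlo, zhi in zones:
        if (zhi is None or lo <= zhi) and hi >= zlo:
            out.add(name)
    return out


def classify_vertical(
    profile: SpeciesProfile,
    records: pd.DataFrame | None = None,
    bathymetry=None,
) -> set[str]:
    """Depth-zone membership for a species with an assigned bottom class.

    Pelagic species: the trait depth range, buffered by 30 m and floored at
    0, is intersected with the pelagic zones. Benthic/demersal species use
    their (unbuffered) depth range against the sea-floor zones; lacking a
    depth range, zones holding more than 10% of valid occurrences (sea-floor
    depth sampled from ``bathymetry``) are returned.
    """
    if profile.bottom_class is None:
        raise ClassificationError("bottom_class must be assigned first")

    if profile.bottom_class == "pelagic":
        if not profile.has_depth_range:
            return _zones_from_records(PELAGIC_ZONES, records, bathymetry)
        lo = max(0.0, profile.depth_min - PELAGIC_DEPTH_BUFFER_M)
        hi = profile.depth_max + PELAGIC_DEPTH_BUFFER_M
        return _overlapping_zones(PELAGIC_ZONES, lo, hi)

    if profile.has_depth_range:
        return _overlapping_zones(BENTHIC_ZONES, profile.depth_min, profile.depth_max)
    return _zones_from_records(BENTHIC_ZONES, records, bathymetry)


def _zones_from_records(zones, records, bathymetry) -> set[str]:
    if records is None or bathymetry is None:
        raise ClassificationError(
            "no depth range and no occurrences/bathymetry to fall back on"
        )
    valid = records.loc[records["flag"] != 0.0]
    if len(valid) == 0:
        raise ClassificationError("no valid occurrence records")
    depths = bathymetry.sample(valid["lon"].to_numpy(float), valid["lat"].to_numpy(float))
    depths = depths[np.isfinite(depths)]
    if depths.size == 0:
        raise ClassificationError("no occurrence falls on a bathymetry cell")
    out = set()
    for name, zlo, zhi in zones:
        share = np.mean((depths >= zlo) & ((zhi is None) | (depths <= (zhi or np.inf))))
        if share > OCCURRENCE_ZONE_SHARE:
            out.add(name)
    if not out:
        raise ClassificationError("no depth zone holds more than 10% of records")
    return out


def classify_species(
    profile: SpeciesProfile,
    records: pd.DataFrame,
    coastal_zone,
    bathymetry=None,
) -> SpeciesProfile:
    """Run all three classifiers and return the completed profile."""
    profile.bottom_class = classify_bottom(profile.habitat_label)
    profile.coast_class = classify_coast(records, coastal_zone)
    profile.vertical_classes = classify_vertical(profile, records, bathymetry)
    return profile


def read_trait_table(path) -> list[SpeciesProfile]:
    """Read a trait CSV (taxon_id, habitat_label, depth_min, depth_max)."""
    df = pd.read_csv(path, dtype={"taxon_id": str})
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            SpeciesProfile(
                taxon_id=row["taxon_id"],
                habitat_label=row["habitat_label"],
                depth_min=None if pd.isna(row.get("depth_min")) else float(row["depth_min"]),
                depth_max=None if pd.isna(row.get("depth_max")) else float(row["depth_max"]),
            )
        )
    return profiles
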