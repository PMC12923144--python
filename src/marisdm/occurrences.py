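"""Occurrence-table harmonization: flag unification, coordinate cleaning,
deduplication.

Occurrence tables are pandas DataFrames with the columns

=================  =======================================================
taxon_id           stable identifier string
lon, lat           decimal degrees (WGS84)
year, month        collection date, nullable integers
basis_of_record    one of {observation, specimen, erm_generated, other,
                   missing}
source             one of {aquamaps, obis, gbif, synthetic}
original_flags     list of source-specific flag strings (may be empty)
flag               ternary quality flag: 1.0 valid, 0.0 erroneous,
                   NaN unflagged
=================  =======================================================

The quality scheme is binary-with-blank: source databases that already carry
a binary flag (AquaMaps-style) pass it through; databases with a richer flag
vocabulary (OBIS-style) are mapped so that only flags indicating a physically
impossible location mark a record erroneous, while soft flags (depth
anomalies, missing depth) are kept in ``original_flags`` without forcing a
verdict; flag-less sources (GBIF-style) stay blank throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KNOWN_SOURCES = frozenset({"aquamaps", "obis", "gbif", "synthetic"})

#: OBIS-style flags that mark a record erroneous (configurable per call).
DEFAULT_ERRONEOUS_FLAGS = frozenset(
    {"on_land", "no_coords", "zero_coords", "implausible_location"}
)

OCC_COLUMNS = [
    "taxon_id",
    "lon",
    "lat",
    "year",
    "month",
    "basis_of_record",
    "source",
    "original_flags",
    "flag",
]


class UnknownSourceError(ValueError):
    pass


def _as_flag_list(value):
    if isinstance(value, (list, tuple)):
        return list(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    if isinstance(value, str):
        return [f for f in value.split(";") if f]
    raise TypeError(f"cannot interpret original_flags value {value!r}")


def empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in OCC_COLUMNS})


def standardize_flags(
    records: pd.DataFrame,
    erroneous_flags: frozenset[str] = DEFAULT_ERRONEOUS_FLAGS,
) -> pd.DataFrame:
    """Unify per-source quality flags into the ternary scheme.

    * aquamaps / synthetic: the existing binary flag is adopted as-is.
    * obis: any flag in ``erroneous_flags`` -> flag 0; soft flags are kept in
      ``original_flags`` and the ternary flag stays blank.
    * gbif: flag always blank.
    """
    unknown = set(records["source"]) - KNOWN_SOURCES
    if unknown:
        raise UnknownSourceError(f"unknown occurrence source(s): {sorted(unknown)}")

    out = records.copy()
    out["original_flags"] = out["original_flags"].map(_as_flag_list)

    flags = np.full(len(out), np.nan)
    for i, (_, rec) in enumerate(out.iterrows()):
        src = rec["source"]
        if src in ("aquamaps", "synthetic"):
            flags[i] = rec["flag"] if pd.notna(rec["flag"]) else np.nan
        elif src == "obis":
            if any(f in erroneous_flags for f in rec["original_flags"]):
                flags[i] = 0.0
            # soft flags remain in original_flags; ternary flag stays blank
        elif src == "gbif":
            flags[i] = np.nan
    out["flag"] = flags
    return out


def clean_coordinates(records: pd.DataFrame) -> pd.DataFrame:
    """Round coordinates to 4 decimals, drop (0,0) and out-of-bounds points.

    Rounding is round-half-even (numpy's default), so values differing only
    at the 5th decimal may snap to the even neighbour. Removals are logged,
    never raised.
    """
    out = records.copy()
    out["lon"] = np.round(out["lon"].astype(float), 4)
    out["lat"] = np.round(out["lat"].astype(float), 4)

    zero = (out["lon"] == 0.0) & (out["lat"] == 0.0)
    oob = (
        (out["lon"] < -180) | (out["lon"] > 180) | (out["lat"] < -90) | (out["lat"] > 90)
    )
    dropped = int(zero.sum()), int((oob & ~zero).sum())
    if any(dropped):
        logger.info(
            "clean_coordinates: removed %d (0,0) records and %d out-of-bounds records",
            *dropped,
        )
    return out.loc[~(zero | oob)].copy()


_SOURCE_PRIORITY = {"aquamaps": 0, "obis": 1, "gbif": 2, "synthetic": 3}


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per (taxon_id, lon, lat, year, month) group.

    The survivor is the most complete record: completeness = has-flag +
    has-basis-of-record, ties broken by source priority (aquamaps > obis >
    gbif), then first-seen order. Missing year/month group as their own key.
    """
    if records.empty:
        return records.copy()
    out = records.copy()
    out["_completeness"] = out["flag"].notna().astype(int) + (
        out["basis_of_record"].notna()
        & ~out["basis_of_record"].isin(["missing"])
    ).astype(int)
    out["_priority"] = out["source"].map(_SOURCE_PRIORITY).fillna(9)
    out["_order"] = np.arange(len(out))

    key_cols = ["taxon_id", "lon", "lat", "year", "month"]
    out = out.sort_values(
        ["_completeness", "_priority", "_order"],
        ascending=[False, True, True],
        kind="stable",
    )
    out = out.drop_duplicates(subset=key_cols, keep="first")
    out = out.sort_values("_order").drop(columns=["_completeness", "_priority", "_order"])
    return out


def harmonize(records: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """standardize_flags -> clean_coordinates -> deduplicate."""
    return deduplicate(clean_coordinates(standardize_flags(records, **kwargs)))


def read_csv(path) -> pd.DataFrame:
    """Read an occurrence CSV (columns taxon_id, lon, lat, year, month,
    basisOfRecord, source, original_flags semicolon-joined, GOODOCC)."""
    df = pd.read_csv(path, dtype={"taxon_id": str})
    df = df.rename(
        columns={"basisOfRecord": "basis_of_record", "GOODOCC": "flag"}
    )
    for col in OCC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["original_flags"] = df["original_flags"].map(_as_flag_list)
    df["year"] = pd.to_numeric(df["year"], errors="coerce")
    df["month"] = pd.to_numeric(df["month"], errors="coerce")
    return df[OCC_COLUMNS + [c for c in df.columns if c not in OCC_COLUMNS]]


def write_csv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["original_flags"] = out["original_flags"].map(
        lambda v: ";".join(_as_flag_list(v))
    )
    out = out.rename(columns={"basis_of_record": "basisOfRecord", "flag": "GOODOCC"})
    out["GOODOCC"] = out["GOODOCC"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out.to_csv(path, index=False)
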