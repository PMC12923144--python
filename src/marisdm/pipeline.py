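"""Per-species workflow orchestration.

``run_species`` sequences the full chain — flag harmonization, coordinate
cleaning, habitat classification, range construction, spatial thinning,
range-based re-flagging, training-set assembly (environmental thinning,
pseudo-occurrences, pseudo-absences), ensemble fitting, projection and
change indices — from a single config object whose defaults carry every
numeric rule of the method (thresholds, buffers, distances, percentiles,
prevalence, TSS gate, bin sizes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import d3os, envgrid, occurrences, projection, pseudoabsence, ranges
from .ensemble import (
    ALGORITHMS,
    DEFAULT_PREVALENCE,
    TSS_GATE,
    TrainingSet,
    fit_ensemble,
)
from .envgrid import DEFAULT_BIN_SIZES
from .synthetic import SyntheticWorld, TrueSpecies


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")


@dataclass
class PipelineConfig:
    """All tunable rules of the workflow, defaulting to the method's values."""

    coastal_share: float = d3os.COASTAL_SHARE  # 0.90
    province_share_threshold: float = ranges.PROVINCE_SHARE_THRESHOLD  # 0.033
    arctic_share_threshold: float = ranges.ARCTIC_SHARE_THRESHOLD  # 0.005
    br_buffer_deg: float = ranges.BR_BUFFER_DEG  # 1
    pr_buffer_deg: float = ranges.PR_BUFFER_DEG  # 10
    sre_percentiles: tuple[float, float] = pseudoabsence.SRE_PERCENTILES  # (2.5, 97.5)
    disk_min_km: float = pseudoabsence.DISK_MIN_KM  # 80
    disk_max_km: float = pseudoabsence.DISK_MAX_KM  # 1000
    prevalence: float = DEFAULT_PREVALENCE  # 0.7
    tss_gate: float = TSS_GATE  # 0.6
    bin_sizes: dict = field(default_factory=lambda: dict(DEFAULT_BIN_SIZES))
    algorithms: tuple = ALGORITHMS
    scenarios: tuple = ("ssp126", "ssp245", "ssp585")
    periods: tuple = ("2050s", "2090s")
    seed: int = 0

    def diff_report(self) -> dict:
        """Fields that deviate from the method defaults."""
        defaults = PipelineConfig()
        out = {}
        for f in dataclasses.fields(self):
            a, b = getattr(self, f.name), getattr(defaults, f.name)
            if a != b:
                out[f.name] = {"value": a, "default": b}
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_species(
    config: PipelineConfig,
    records: pd.DataFrame,
    profile: d3os.SpeciesProfile,
    world: SyntheticWorld,
    erm=None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full per-species workflow and return a manifest.

    ``records`` is a raw occurrence table; ``erm`` an optional expert range
    polygon. Intermediates are written under ``out_dir`` when given. The
    manifest records per-stage status, record counts, the flag ledger
    (verified / erroneous / unflagged shares), retained-run metrics and the
    change indices per scenario/period.
    """
    manifest: dict = {
        "taxon_id": profile.taxon_id,
        "seed": config.seed,
        "stages": {},
        "config_diff": config.diff_report(),
        "files": [],
    }
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "config.json").write_text(json.dumps(config.to_dict(), default=str))
        manifest["files"].append("config.json")

    def _save(df: pd.DataFrame, name: str):
        if out_path is not None:
            occurrences.write_csv(df.drop(columns=["is_error", "error_kind"],
                                          errors="ignore"), out_path / name)
            manifest["files"].append(name)

    def _stage(name):
        manifest["stages"][name] = "complete"

    # 1. clean
    try:
        clean = occurrences.harmonize(records)
    except Exception as exc:
        raise StageError("clean", "harmonize_failed", str(exc)) from exc
    _save(clean, "occ_clean.csv")
    _stage("clean")
    manifest["n_clean"] = int(len(clean))

    # 2. habitat classification
    try:
        profile.bottom_class = d3os.classify_bottom(profile.habitat_label)
        profile.coast_class = d3os.classify_coast(clean, world.partition.coastal_zone)
        profile.vertical_classes = d3os.classify_vertical(
            profile, clean, world.bathymetry
        )
    except d3os.ClassificationError as exc:
        raise StageError("d3os", "classification_failed", str(exc)) from exc
    _stage("d3os")
    manifest["d3os"] = {
        "bottom": profile.bottom_class,
        "coast": profile.coast_class,
        "vertical": sorted(profile.vertical_classes),
    }

    # 3. spatial thinning (before deriving a range, as for unmapped species)
    thinned = ranges.spatial_thin(clean, seed=config.seed)
    _stage("thin")
    manifest["n_thinned"] = int(len(thinned))

    # 4. range construction + re-flagging
    try:
        if erm is not None:
            range_set = ranges.build_from_erm(erm, world.ocean, profile.taxon_id)
        else:
            range_set = ranges.derive_range(
                thinned,
                profile,
                world.partition,
                world.ocean,
                share_threshold=config.province_share_threshold,
            )
    except ranges.RangeConstructionError as exc:
        raise StageError("range", "construction_failed", str(exc)) from exc
    flagged = ranges.reflag_by_range(clean, range_set)
    _save(flagged, "occ_flagged.csv")
    _stage("range")
    manifest["range"] = {
        "provenance": range_set.provenance,
        "br_area_km2": range_set.br_area_km2,
        "pr_area_km2": range_set.pr_area_km2,
    }
    total = len(flagged)
    manifest["flag_ledger"] = {
        "verified": float((flagged["flag"] == 1.0).mean()) if total else 0.0,
        "erroneous": float((flagged["flag"] == 0.0).mean()) if total else 0.0,
        "unflagged": float(flagged["flag"].isna().mean()) if total else 0.0,
    }

    # 5. training presences: verified records, pseudo-occurrences if sparse,
    #    then one record per unique environment
    presences = flagged.loc[flagged["flag"] == 1.0].copy()
    if erm is not None and len(presences) < 1000:
        depth_range = (
            (profile.depth_min, profile.depth_max) if profile.has_depth_range else None
        )
        try:
            pseudo = envgrid.generate_pseudo_occurrences(
                erm,
                world.bathymetry,
                depth_range,
                seed=config.seed + 1,
                taxon_id=profile.taxon_id,
                exclude_lonlat=presences[["lon", "lat"]].to_numpy(float),
            )
        except envgrid.GenerationError as exc:
            raise StageError("pseudo_occurrence", "generation_failed", str(exc)) from exc
        presences = pd.concat([presences, pseudo], ignore_index=True)
    env_keys = envgrid.bin_environment(world.present, config.bin_sizes)
    on_grid = np.isfinite(
        env_keys.sample(presences["lon"].to_numpy(float), presences["lat"].to_numpy(float))
    )
    presences = presences.loc[on_grid]
    presences = envgrid.env_thin(presences, env_keys, seed=config.seed + 2)
    _save(presences, "presences.csv")
    _stage("training_presences")
    manifest["n_presences"] = int(len(presences))

    # 6. pseudo-absences
    try:
        pas = pseudoabsence.generate(
            profile, presences, world.present, range_set.pr, seed=config.seed + 3
        )
    except pseudoabsence.PseudoAbsenceError as exc:
        raise StageError("pseudo_absence", "generation_failed", str(exc)) from exc
    _stage("pseudo_absence")
    manifest["n_pseudo_absences"] = int(len(pas))

    # 7. ensemble
    pres_env = world.present.sample(
        presences["lon"].to_numpy(float), presences["lat"].to_numpy(float)
    )
    pa_env = pas[world.present.names]
    X = pd.concat([pres_env, pa_env], ignore_index=True).dropna()
    y = np.concatenate([np.ones(len(pres_env)), np.zeros(len(pa_env))])[X.index]
    training = TrainingSet(X=X.reset_index(drop=True), y=y, prevalence=config.prevalence)
    n_unique = envgrid.count_unique_environments(world.present, config.bin_sizes)
    ensemble = fit_ensemble(
        training,
        n_unique_env=n_unique,
        seed=config.seed + 4,
        algorithms=config.algorithms,
        tss_gate=config.tss_gate,
    )
    _stage("ensemble")
    ledger = ensemble.run_ledger()
    if out_path is not None:
        ledger.to_csv(out_path / "run_ledger.csv", index=False)
        manifest["files"].append("run_ledger.csv")
    manifest["ensemble"] = {
        "n_runs": int(len(ledger)),
        "n_retained": int(ledger["retained"].sum()),
        "mean_retained_tss": float(
            ledger.loc[ledger["retained"], "tss"].mean()
        ),
    }

    # 8. projection + change indices
    threshold = ensemble.ensemble_threshold(training)
    present_proj = projection.project(ensemble, world.present, range_set.pr)
    present_bin = projection.binarize(present_proj.hsi, threshold)
    manifest["threshold"] = float(threshold)
    changes = {}
    for scenario in config.scenarios:
        for period in config.periods:
            fut = world.future(scenario, period)
            proj = projection.project(ensemble, fut, range_set.pr)
            fut_bin = projection.binarize(proj.hsi, threshold)
            idx = projection.change_indices(present_bin, fut_bin, range_set.pr)
            changes[f"{scenario}_{period}"] = {
                "percent_gained": idx.percent_area_gained,
                "percent_lost": idx.percent_area_lost,
            }
    _stage("project")
    _stage("change")
    manifest["change"] = changes

    if out_path is not None:
        (out_path / "manifest.json").write_text(json.dumps(manifest, default=str, indent=2))
    return manifest
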