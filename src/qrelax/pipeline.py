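"""Study orchestration: simulate -> fit -> orientation -> regional -> stats.

``run_study`` reproduces the longitudinal analysis on a study directory (as
written by :func:`qrelax.phantom.generate_study`, or assembled by hand with
the same manifest layout): per-day R2* and fiber-angle maps, condition
average and difference maps, orientation profiles with per-day anisotropy,
the region x condition comparison table with the stats battery, hemispheric
contrast, iron-change annotation and the sensitivity re-run that drops the
migraine-free days immediately after an attack.

Map computation (``compute_maps``) and statistics (``analyse_maps``) are
separate stages so the quantitative maps can be produced blind to the
condition labels; ``run_study`` simply chains them.  All intermediates are
written to disk (NIfTI / CSV) so each stage is individually inspectable,
and every CSV is written with a fixed float format so repeated runs with
the same seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .relaxometry import MultiEchoSeries, fit_r2star, average_maps, delta_map, R2StarMap
from .diffusion import DiffusionSeries, fit_tensor, fiber_angle, fractional_anisotropy
from .orientation import bin_r2star_by_angle, condition_profiles, anisotropy
from .regional import (
    LabelVolume,
    regional_means,
    condition_table,
    sensitivity_exclude,
    hemispheric_contrast,
    annotate_iron,
    IronCalibration,
)

__all__ = ["StudyConfig", "StudyResult", "compute_maps", "analyse_maps", "run_study"]

CSV_FLOAT_FORMAT = "%.6g"


@dataclass
class StudyConfig:
    """Configuration of one analysis run."""

    study_dir: str
    out_dir: str
    method: str = "loglinear"  # R2* fitter
    b0_direction: tuple[float, float, float] | None = None  # default: manifest
    wm_label_ids: list[int] | None = None  # default: manifest
    min_count: int = 50  # voxels per orientation bin
    fa_threshold: float = 0.1  # exclude near-isotropic voxels from pooling
    alpha: float = 0.05
    iron_slope: float = 0.27  # 1/s per mg/kg
    sensitivity_exclude_days: list[int] | None = None  # default: day after each attack
    write_maps: bool = True
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class StudyResult:
    """In-memory bundle of everything ``run_study`` writes to disk."""

    config: StudyConfig
    manifest: dict
    r2_maps: dict  # day -> R2StarMap
    theta_maps: dict  # day -> FiberAngleMap
    mean_maps: dict  # condition -> R2StarMap
    delta: object  # DeltaMap
    per_day_values: list  # RegionDayValue
    table: pd.DataFrame
    table_sensitivity: pd.DataFrame
    contrast: pd.DataFrame
    orientation: object  # ConditionOrientationSummary
    anisotropy_per_day: pd.DataFrame
    excluded_days: list = field(default_factory=list)


def _day_conditions(manifest: dict) -> dict[int, str]:
    return {int(d["day"]): d["condition"] for d in manifest["days"]}


def default_sensitivity_exclusion(manifest: dict) -> list[int]:
    """Migraine-free days immediately following a migraine day."""
    conds = _day_conditions(manifest)
    out = []
    for day, cond in sorted(conds.items()):
        if cond == "migraine" and conds.get(day + 1) == "migraine-free":
            out.append(day + 1)
    return out


def compute_maps(config: StudyConfig):
    """Stage 1 (condition-blind): per-day R2*, fiber-angle and FA maps."""
    study = Path(config.study_dir)
    manifest = qio.load_manifest(study)
    echo_times = np.asarray(manifest["echo_times_ms"], dtype=float)
    b0 = tuple(config.b0_direction or manifest.get("b0_direction", (0.0, 0.0, 1.0)))
    bvals, bvecs = qio.load_bvals_bvecs(study / manifest["bvals"], study / manifest["bvecs"])

    missing = [d["day"] for d in manifest["days"]
               if not ((study / d["gre"]).exists() and (study / d["dwi"]).exists())]
    if missing and not config.allow_missing:
        raise FileNotFoundError(f"missing day data for days {missing}")

    out = Path(config.out_dir)
    maps_dir = out / "maps"
    if config.write_maps:
        maps_dir.mkdir(parents=True, exist_ok=True)

    r2_maps, theta_maps, fa_maps = {}, {}, {}
    for entry in manifest["days"]:
        day = int(entry["day"])
        if day in missing:
            continue
        gre = qio.load_volume(study / entry["gre"])
        series = MultiEchoSeries(gre, echo_times)
        r2_maps[day] = fit_r2star(series, method=config.method)

        dwi = qio.load_volume(study / entry["dwi"])
        tensors = fit_tensor(DiffusionSeries(dwi, bvals, bvecs))
        theta_maps[day] = fiber_angle(tensors, b0)
        fa_maps[day] = fractional_anisotropy(tensors)

        if config.write_maps:
            vs = float(manifest.get("voxel_size_mm", 1.0))
            qio.save_volume(maps_dir / f"r2star_day{day:02d}.nii.gz",
                            np.nan_to_num(r2_maps[day].r2star), vs)
            qio.save_volume(maps_dir / f"theta_day{day:02d}.nii.gz",
                            np.nan_to_num(theta_maps[day].theta, nan=-1.0), vs)
            qio.save_volume(maps_dir / f"fa_day{day:02d}.nii.gz",
                            np.nan_to_num(fa_maps[day]), vs)
    return manifest, r2_maps, theta_maps, fa_maps


def analyse_maps(config: StudyConfig, manifest, r2_maps, theta_maps, fa_maps) -> StudyResult:
    """Stage 2 (unblinded): condition averages, orientation and regional stats."""
    study = Path(config.study_dir)
    out = Path(config.out_dir)
    tables_dir = out / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    vs = float(manifest.get("voxel_size_mm", 1.0))

    labels_arr = qio.load_volume(study / manifest["labels"]).astype(np.int32)
    lut = qio.load_lut(study / manifest["lut"])
    labels = LabelVolume(labels_arr, lut)
    day_conditions = {d: c for d, c in _day_conditions(manifest).items() if d in r2_maps}

    # condition-average and difference maps
    mean_maps = {}
    for cond in ("migraine-free", "migraine"):
        days = [d for d, c in day_conditions.items() if c == cond]
        if not days:
            raise ValueError(f"no usable day with condition {cond!r}")
        mean_maps[cond] = average_maps([r2_maps[d] for d in days])
    delta = delta_map(mean_maps["migraine-free"], mean_maps["migraine"])
    if config.write_maps:
        maps_dir = out / "maps"
        maps_dir.mkdir(parents=True, exist_ok=True)
        qio.save_volume(maps_dir / "r2star_mean_free.nii.gz",
                        np.nan_to_num(mean_maps["migraine-free"].r2star), vs)
        qio.save_volume(maps_dir / "r2star_mean_migraine.nii.gz",
                        np.nan_to_num(mean_maps["migraine"].r2star), vs)
        qio.save_volume(maps_dir / "delta_r2star_abs.nii.gz",
                        np.nan_to_num(delta.delta_abs), vs)
        qio.save_volume(maps_dir / "delta_r2star_pct.nii.gz",
                        np.nan_to_num(delta.delta_pct), vs)

    # orientation profiles per day and hemisphere
    wm_ids = config.wm_label_ids or manifest.get("wm_label_ids")
    if not wm_ids:
        raise ValueError("no white-matter label ids configured")
    hemi_of = {lid: lut[lid][1] for lid in wm_ids}
    day_profiles = []
    profile_rows = []
    for day in sorted(r2_maps):
        for hemi in sorted(set(hemi_of.values())):
            ids = [lid for lid in wm_ids if hemi_of[lid] == hemi]
            wm_mask = np.isin(labels_arr, ids)
            if config.fa_threshold > 0:
                wm_mask = wm_mask & (np.nan_to_num(fa_maps[day]) >= config.fa_threshold)
            prof = bin_r2star_by_angle(
                r2_maps[day], theta_maps[day], wm_mask,
                min_count=config.min_count, hemisphere=hemi, tag=str(day),
            )
            day_profiles.append(prof)
            for k in range(prof.bin_count.size):
                profile_rows.append(
                    {
                        "day": day,
                        "condition": day_conditions[day],
                        "hemisphere": hemi,
                        "bin_lo": prof.bin_edges[k],
                        "bin_hi": prof.bin_edges[k + 1],
                        "mean_r2star": prof.bin_mean_r2star[k],
                        "count": prof.bin_count[k],
                    }
                )
    orient = condition_profiles(day_profiles, day_conditions)
    aniso_df = pd.DataFrame(orient.per_day_anisotropy).sort_values(
        ["day", "hemisphere"]).reset_index(drop=True)

    # regional aggregation and condition stats (day = sampling unit)
    per_day_values = []
    for day in sorted(r2_maps):
        per_day_values.extend(
            regional_means(r2_maps[day], labels, day, day_conditions[day])
        )
    cal = IronCalibration(config.iron_slope)
    table = annotate_iron(condition_table(per_day_values, alpha=config.alpha), cal)
    contrast = hemispheric_contrast(table)

    excl = config.sensitivity_exclude_days
    if excl is None:
        excl = default_sensitivity_exclusion(manifest)
    excl = [d for d in excl if d in day_conditions]
    table_sens = annotate_iron(
        sensitivity_exclude(per_day_values, excl, alpha=config.alpha), cal
    ) if excl else table.copy()

    # reports (fixed float format -> byte-identical reruns)
    def write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(tables_dir / name, index=False, float_format=CSV_FLOAT_FORMAT)

    write(pd.DataFrame(
        [
            {
                "region": v.region, "hemisphere": v.hemisphere,
                "day": v.day_index, "condition": v.condition,
                "mean_r2star": v.mean_r2star, "voxel_count": v.voxel_count,
            }
            for v in per_day_values
        ]), "per_day_regional.csv")
    write(table, "condition_table.csv")
    write(table_sens, "condition_table_sensitivity.csv")
    write(contrast, "hemispheric_contrast.csv")
    write(pd.DataFrame(profile_rows), "orientation_profiles_per_day.csv")

    cond_rows = []
    for (cond, hemi), prof in sorted(orient.profiles.items()):
        for k in range(prof.bin_count.size):
            cond_rows.append(
                {
                    "condition": cond, "hemisphere": hemi,
                    "bin_lo": prof.bin_edges[k], "bin_hi": prof.bin_edges[k + 1],
                    "mean_r2star": prof.bin_mean_r2star[k],
                    "count": prof.bin_count[k],
                }
            )
    write(pd.DataFrame(cond_rows), "orientation_profiles_condition.csv")
    write(aniso_df, "anisotropy_per_day.csv")

    aniso_summary = []
    for hemi, change in sorted(orient.relative_change_pct.items()):
        res_free = anisotropy(orient.profiles[("migraine-free", hemi)])
        res_mig = anisotropy(orient.profiles[("migraine", hemi)])
        aniso_summary.append(
            {
                "hemisphere": hemi,
                "anisotropy_free_profile": res_free.anisotropy,
                "anisotropy_migraine_profile": res_mig.anisotropy,
                "relative_change_pct_per_day": change,
            }
        )
    write(pd.DataFrame(aniso_summary), "anisotropy_summary.csv")

    run_log = {
        "config": {
            "study_dir": str(config.study_dir),
            "method": config.method,
            "min_count": config.min_count,
            "fa_threshold": config.fa_threshold,
            "alpha": config.alpha,
            "iron_slope": config.iron_slope,
            "sensitivity_excluded_days": excl,
            "b0_direction": list(config.b0_direction
                                 or manifest.get("b0_direction", (0, 0, 1))),
        },
        "seed": manifest.get("seed"),
        "n_days": len(day_conditions),
        "n_migraine_days": sum(c == "migraine" for c in day_conditions.values()),
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=True)

    return StudyResult(
        config=config, manifest=manifest, r2_maps=r2_maps, theta_maps=theta_maps,
        mean_maps=mean_maps, delta=delta, per_day_values=per_day_values,
        table=table, table_sensitivity=table_sens, contrast=contrast,
        orientation=orient, anisotropy_per_day=aniso_df, excluded_days=excl,
    )


def run_study(config: StudyConfig) -> StudyResult:
    """Full pipeline: map computation (blind) followed by condition analysis."""
    manifest, r2_maps, theta_maps, fa_maps = compute_maps(config)
    return analyse_maps(config, manifest, r2_maps, theta_maps, fa_maps)
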