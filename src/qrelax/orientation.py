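"""Orientation-dependent R2* profiles and the anisotropy index.

White-matter R2* depends on the angle theta between the local fiber axis and
the scanner's main field B0 (myelinated fibers and fiber-parallel vessels are
the dominant sources).  Pooling all white-matter voxels into 18 five-degree
angle bins gives the orientation profile R2*(theta); its dynamic range is
summarised by the anisotropy index

    anisotropy = (R2*_max - R2*_min) / (R2*_max + R2*_min)

taken over the defined bin means.  For the generative model
R2*(theta) = a + b sin^2(theta) this index converges to b / (2a + b) as noise
vanishes, which makes it an easily checkable statistic.

The index is computed on raw bin means (no smoothing); an optional
least-squares fit of the a + b sin^2 model is provided as a cross-check.
Profiles are computed per day and per hemisphere, then averaged by condition;
per-day anisotropy values feed the condition statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relaxometry import R2StarMap
from .diffusion import FiberAngleMap

__all__ = [
    "BIN_EDGES",
    "N_BINS",
    "OrientationProfile",
    "AnisotropyResult",
    "bin_r2star_by_angle",
    "anisotropy",
    "condition_profiles",
    "fit_sin2_model",
]

N_BINS = 18
BIN_EDGES = np.arange(0.0, 91.0, 5.0)  # 0, 5, ..., 90


@dataclass
class OrientationProfile:
    """Mean R2* per 5-degree fiber-angle bin, with voxel counts.

    ``bin_mean_r2star`` is NaN for bins with fewer than ``min_count`` voxels.
    """

    bin_edges: np.ndarray
    bin_mean_r2star: np.ndarray
    bin_count: np.ndarray
    hemisphere: str = "both"
    tag: str = ""
    min_count: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_mean_r2star = np.asarray(self.bin_mean_r2star, dtype=float)
        self.bin_count = np.asarray(self.bin_count, dtype=int)
        if self.bin_edges.size != self.bin_mean_r2star.size + 1:
            raise ValueError("bin_edges must have one more entry than bin means")
        if self.bin_count.size != self.bin_mean_r2star.size:
            raise ValueError("bin_count and bin means must align")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.bin_mean_r2star)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class AnisotropyResult:
    r2star_max: float
    r2star_min: float
    anisotropy: float

    @property
    def percent(self) -> float:
        return 100.0 * self.anisotropy


def bin_r2star_by_angle(
    r2map: R2StarMap,
    angles: FiberAngleMap,
    wm_mask: np.ndarray,
    min_count: int = 50,
    hemisphere: str = "both",
    tag: str = "",
) -> OrientationProfile:
    """Pool white-matter voxels into 5-degree fiber-angle bins.

    A voxel with angle theta goes to bin floor(theta / 5); theta = 90 goes to
    the last bin (bins are half-open [lo, hi) with the final bin closed).
    Bins with fewer than ``min_count`` valid voxels are undefined (NaN mean).
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if r2map.grid_shape != angles.theta.shape or wm_mask.shape != r2map.grid_shape:
        raise ValueError("r2 map, angle map and mask must share one grid")
    if not wm_mask.any():
        raise ValueError("white-matter mask is empty")

    use = wm_mask & r2map.valid & angles.valid & np.isfinite(angles.theta)
    theta = angles.theta[use]
    values = r2map.r2star[use]

    idx = np.minimum(np.floor(theta / 5.0).astype(int), N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS)
    sums = np.bincount(idx, weights=values, minlength=N_BINS)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    means = np.where(counts >= max(min_count, 1), means, np.nan)
    if not np.isfinite(means).any():
        raise ValueError("all orientation bins are undefined (too few voxels)")
    return OrientationProfile(BIN_EDGES.copy(), means, counts,
                              hemisphere=hemisphere, tag=tag, min_count=min_count)


def anisotropy(profile: OrientationProfile) -> AnisotropyResult:
    """Anisotropy index (max - min) / (max + min) over defined bin means."""
    vals = profile.bin_mean_r2star[profile.defined]
    if vals.size < 2:
        raise ValueError("need at least two defined bins for the anisotropy index")
    hi = float(vals.max())
    lo = float(vals.min())
    return AnisotropyResult(hi, lo, (hi - lo) / (hi + lo))


def fit_sin2_model(profile: OrientationProfile) -> tuple[float, float]:
    """Least-squares fit of mean = a + b sin^2(theta_center) to defined bins.

    Cross-check for the raw-bin anisotropy; returns (a, b).
    """
    ok = profile.defined
    if ok.sum() < 2:
        raise ValueError("need at least two defined bins to fit the sin^2 model")
    x = np.sin(np.radians(profile.bin_centers[ok])) ** 2
    y = profile.bin_mean_r2star[ok]
    b, a = np.polyfit(x, y, 1)
    return float(a), float(b)


@dataclass
class ConditionOrientationSummary:
    """Condition-averaged profiles and per-day anisotropy bookkeeping."""

    profiles: dict  # (condition, hemisphere) -> OrientationProfile
    per_day_anisotropy: list = field(default_factory=list)  # dicts: day, condition, hemisphere, anisotropy
    relative_change_pct: dict = field(default_factory=dict)  # hemisphere -> %


def condition_profiles(day_profiles, day_conditions) -> ConditionOrientationSummary:
    """Average per-day profiles by condition and track per-day anisotropy.

    Parameters
    ----------
    day_profiles
        List of OrientationProfile, one per (day, hemisphere); each profile's
        ``tag`` must be the day index as a string.
    day_conditions
        Mapping day index (int) -> condition string.

    The condition profile is the unweighted mean of daily bin means (a bin is
    defined when defined on every contributing day).  The relative condition
    change per hemisphere is 100 * (mean_aniso_migraine - mean_aniso_free) /
    mean_aniso_free, computed from per-day anisotropy values.
    """
    conditions = set(day_conditions.values())
    if not {"migraine-free", "migraine"} <= conditions:
        raise ValueError("need at least one day per condition")

    by_key: dict[tuple[str, str], list[OrientationProfile]] = {}
    per_day = []
    for prof in day_profiles:
        day = int(prof.tag)
        cond = day_conditions[day]
        by_key.setdefault((cond, prof.hemisphere), []).append(prof)
        res = anisotropy(prof)
        per_day.append(
            {
                "day": day,
                "condition": cond,
                "hemisphere": prof.hemisphere,
                "anisotropy": res.anisotropy,
                "r2star_max": res.r2star_max,
                "r2star_min": res.r2star_min,
            }
        )

    profiles = {}
    for (cond, hemi), profs in by_key.items():
        means = np.vstack([p.bin_mean_r2star for p in profs])
        counts = np.vstack([p.bin_count for p in profs])
        mean = means.mean(axis=0)  # NaN-propagating: defined iff defined on all days
        profiles[(cond, hemi)] = OrientationProfile(
            profs[0].bin_edges.copy(), mean, counts.sum(axis=0),
            hemisphere=hemi, tag=cond, min_count=profs[0].min_count,
        )

    rel = {}
    hemis = {p.hemisphere for p in day_profiles}
    for hemi in hemis:
        free = [d["anisotropy"] for d in per_day
                if d["hemisphere"] == hemi and d["condition"] == "migraine-free"]
        mig = [d["anisotropy"] for d in per_day
               if d["hemisphere"] == hemi and d["condition"] == "migraine"]
        if free and mig:
            mf = float(np.mean(free))
            rel[hemi] = 100.0 * (float(np.mean(mig)) - mf) / mf
    return ConditionOrientationSummary(profiles, per_day, rel)
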