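"""Synthetic study generator: labelled anatomy + daily multi-echo GRE / DWI.

The phantom emulates a 21-day single-subject quantitative-MRI study with two
migraine days (days 12 and 16 by default).  It is a stylised two-hemisphere
block layout — left/right copies of a subset of deep-gray regions embedded in
a cerebral white-matter slab — with no attempt at realistic cortical
geometry.  Ground truth is fully known, so downstream fits can be checked
against it:

* Gray-matter regions carry a per-(region, hemisphere, condition) R2*.
* White-matter voxels follow the orientation model
  R2*(theta) = a + b sin^2(theta), with (a, b) per hemisphere and condition
  and theta the angle of the local fiber axis to B0 (fixed to the third
  image axis, the scanner z convention).  The fiber field is a smooth
  hemisphere-specific fan sweeping 0-90 degrees along y so that every
  5-degree orientation bin is populated.
* A per-(region, hemisphere, day) Gaussian offset (``day_jitter_sd``)
  emulates physiological day-to-day fluctuation; the condition-level truth
  (without jitter) is kept separately for exact-contrast checks.
* Signals: mono-exponential multi-echo decay S(TE) = S0 exp(-R2* TE) and
  single-tensor diffusion attenuation S = S0 exp(-b g^T D g), both under
  Rician magnitude noise (independent Gaussian noise of SD ``noise_sigma``
  on two quadrature channels, then the modulus).

Everything is deterministic given the spec's seed; per-day noise streams are
derived from (seed, day).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

try:  # nibabel only needed for on-disk studies
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "RegionBox",
    "build_ground_truth",
    "simulate_multiecho",
    "simulate_dwi",
    "generate_study",
    "isotropic_directions",
    "wm_r2star",
    "DEFAULT_ECHO_TIMES_MS",
    "DEFAULT_DAY_SCHEDULE",
]

# printed multi-echo GRE protocol (ms)
DEFAULT_ECHO_TIMES_MS = (4.92, 9.84, 14.7, 19.6, 24.6, 29.51)

CONDITIONS = ("migraine-free", "migraine")


def _default_schedule() -> list[str]:
    sched = ["migraine-free"] * 21
    sched[11] = "migraine"  # day 12 (1-based)
    sched[15] = "migraine"  # day 16
    return sched


DEFAULT_DAY_SCHEDULE = tuple(_default_schedule())


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned box extent of one labelled region (half-open slices)."""

    name: str
    hemisphere: str
    tissue: str  # "gm" | "wm"
    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.x), slice(*self.y), slice(*self.z))


def _default_layout(grid=(48, 48, 48)) -> dict[int, RegionBox]:
    """Two mirrored hemispheres: a WM slab with embedded deep-gray boxes.

    Label ids follow the FreeSurfer subcortical convention (2/41 cerebral
    WM, 10/49 thalamus, 11/50 caudate, 12/51 putamen, 28/60 ventral DC).
    """
    nx = grid[0]
    half = nx // 2
    lay: dict[int, RegionBox] = {}

    def hemi_boxes(x0: int, hemi: str, wm_id: int, ids: tuple[int, int, int, int]):
        lay[wm_id] = RegionBox("Cerebral-white-matter", hemi, "wm",
                               (x0 + 2, x0 + half - 2), (4, 44), (4, 44))
        th, cd, pu, vd = ids
        lay[th] = RegionBox("Thalamus", hemi, "gm", (x0 + 4, x0 + 10), (8, 14), (8, 14))
        lay[cd] = RegionBox("Caudate", hemi, "gm", (x0 + 4, x0 + 10), (20, 26), (20, 26))
        lay[pu] = RegionBox("Putamen", hemi, "gm", (x0 + 12, x0 + 18), (8, 14), (28, 34))
        lay[vd] = RegionBox("Ventral-DC", hemi, "gm", (x0 + 12, x0 + 18), (30, 36), (10, 16))

    hemi_boxes(0, "left", 2, (10, 11, 12, 28))
    hemi_boxes(half, "right", 41, (49, 50, 51, 60))
    return lay


def _default_gm_r2star() -> dict[tuple[str, str, str], float]:
    """Baseline (migraine-free) means and migraine-day values, in 1/s."""
    base = {
        ("Thalamus", "left"): (20.6, 0.0),
        ("Thalamus", "right"): (20.7, -0.3),
        ("Caudate", "left"): (20.6, +1.0),
        ("Caudate", "right"): (20.8, -1.1),
        ("Putamen", "left"): (23.3, -0.3),
        ("Putamen", "right"): (22.5, +0.4),
        ("Ventral-DC", "left"): (23.0, +1.3),
        ("Ventral-DC", "right"): (22.0, -1.0),
    }
    out = {}
    for (name, hemi), (free, shift) in base.items():
        out[(name, hemi, "migraine-free")] = free
        out[(name, hemi, "migraine")] = free + shift
    return out


def _default_orientation_effect() -> dict[tuple[str, str], tuple[float, float]]:
    """(a, b) of R2*(theta) = a + b sin^2(theta), per hemisphere and condition.

    Free-day values match the endpoint means of the orientation profiles
    (19.6 -> 22.1 Hz left, 19.8 -> 21.9 Hz right); on migraine days the left
    isotropic component rises by 0.4 1/s and the right anisotropic amplitude
    shrinks so that the generative anisotropy index drops by 16.6%.
    """
    return {
        ("left", "migraine-free"): (19.6, 2.5),
        ("left", "migraine"): (20.0, 2.5),
        ("right", "migraine-free"): (19.8, 2.1),
        ("right", "migraine"): (19.8, 1.737),
    }


@dataclass
class PhantomSpec:
    """Full generative description of a synthetic study."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 2.0  # mm
    region_layout: dict[int, RegionBox] = field(default_factory=_default_layout)
    true_r2star_by_region_condition: dict[tuple[str, str, str], float] = field(
        default_factory=_default_gm_r2star
    )
    orientation_effect: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_orientation_effect
    )
    s0_by_region: dict[str, float] = field(
        default_factory=lambda: {"Cerebral-white-matter": 900.0, "default": 1000.0}
    )
    wm_fiber_field: str = "fan-y"
    noise_sigma: float = 10.0
    day_jitter_sd: float = 0.25  # physiological day-to-day fluctuation, 1/s
    day_schedule: tuple[str, ...] = DEFAULT_DAY_SCHEDULE
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    diffusivities: tuple[float, float, float] = (1.7e-3, 0.3e-3, 0.3e-3)  # mm^2/s
    iso_diffusivity: float = 0.8e-3  # non-WM tissue
    n_directions: int = 30
    n_b0: int = 3
    bvalue: float = 1000.0  # s/mm^2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.day_schedule) < 3:
            raise ValueError("day_schedule needs at least 3 days")
        conds = set(self.day_schedule)
        if not conds <= set(CONDITIONS):
            raise ValueError(f"unknown conditions in schedule: {conds - set(CONDITIONS)}")
        if len(conds) < 2:
            raise ValueError("day_schedule needs at least one day of each condition")
        if self.noise_sigma < 0 or self.day_jitter_sd < 0:
            raise ValueError("noise levels must be non-negative")
        for key, val in self.true_r2star_by_region_condition.items():
            if val <= 0:
                raise ValueError(f"R2* must be positive (got {val} for {key})")
        for key, (a, b) in self.orientation_effect.items():
            if a <= 0 or b < 0:
                raise ValueError(f"orientation effect needs a > 0, b >= 0 (got {key})")
        layout_regions = {(r.name, r.hemisphere) for r in self.region_layout.values()}
        for name, hemi, _cond in self.true_r2star_by_region_condition:
            if (name, hemi) not in layout_regions:
                raise ValueError(f"region ({name}, {hemi}) not present in region_layout")
        lam = self.diffusivities
        if not (lam[0] >= lam[1] >= lam[2] > 0):
            raise ValueError("diffusivities must satisfy l1 >= l2 >= l3 > 0")

    @property
    def conditions(self) -> list[str]:
        return list(self.day_schedule)

    @property
    def n_days(self) -> int:
        return len(self.day_schedule)

    def s0_for(self, region: str) -> float:
        return self.s0_by_region.get(region, self.s0_by_region.get("default", 1000.0))

    @property
    def lut(self) -> dict[int, tuple[str, str]]:
        return {lid: (box.name, box.hemisphere) for lid, box in self.region_layout.items()}


def wm_r2star(spec: PhantomSpec, theta_deg, hemisphere: str, condition: str):
    """White-matter R2*(theta) = a + b sin^2(theta) for a hemisphere/condition."""
    a, b = spec.orientation_effect[(hemisphere, condition)]
    s = np.sin(np.radians(theta_deg))
    return a + b * s * s


@dataclass
class GroundTruth:
    """Everything the analysis is supposed to recover."""

    spec: PhantomSpec
    label_volume: np.ndarray
    s0_volume: np.ndarray
    fiber_direction_volume: np.ndarray  # (x, y, z, 3); zero outside WM
    theta_true: np.ndarray  # degrees, NaN outside WM
    r2star_by_condition: dict[str, np.ndarray]  # condition-level truth, no jitter
    r2star_per_day: list[np.ndarray]  # with day jitter applied

    @property
    def wm_mask(self) -> np.ndarray:
        wm_ids = [lid for lid, box in self.spec.region_layout.items() if box.tissue == "wm"]
        return np.isin(self.label_volume, wm_ids)

    def day_condition(self, day: int) -> str:
        return self.spec.day_schedule[day - 1]


def _check_overlaps(layout: dict[int, RegionBox]) -> None:
    """GM boxes may carve the WM slab but must not overlap each other."""
    gm = [(lid, box) for lid, box in layout.items() if box.tissue == "gm"]
    for i in range(len(gm)):
        for j in range(i + 1, len(gm)):
            (la, a), (lb, b) = gm[i], gm[j]
            if (a.x[0] < b.x[1] and b.x[0] < a.x[1]
                    and a.y[0] < b.y[1] and b.y[0] < a.y[1]
                    and a.z[0] < b.z[1] and b.z[0] < a.z[1]):
                raise ValueError(
                    f"overlapping region extents: labels {la} ({a.name}/{a.hemisphere})"
                    f" and {lb} ({b.name}/{b.hemisphere})"
                )


def build_ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Materialise labels, S0, fiber field and true R2* volumes from a spec.

    Deterministic given the spec (day jitter uses the spec's seed).  The WM
    fiber fan sweeps theta linearly over [0, 90] degrees along the y axis;
    the fiber axis lies in the x-z plane (mirrored between hemispheres) and
    B0 is the third image axis.
    """
    _check_overlaps(spec.region_layout)
    shape = spec.grid_shape
    labels = np.zeros(shape, dtype=np.int32)
    # paint WM slabs first, then carve GM boxes
    for tissue in ("wm", "gm"):
        for lid, box in spec.region_layout.items():
            if box.tissue == tissue:
                labels[box.slices()] = lid

    s0 = np.zeros(shape)
    for lid, box in spec.region_layout.items():
        s0[labels == lid] = spec.s0_for(box.name)

    # fiber fan: theta depends linearly on y inside each WM box
    fibers = np.zeros(shape + (3,))
    theta_true = np.full(shape, np.nan)
    for lid, box in spec.region_layout.items():
        if box.tissue != "wm":
            continue
        sl = box.slices()
        sel = labels[sl] == lid
        ys = np.arange(box.y[0], box.y[1])
        span = max(box.y[1] - 1 - box.y[0], 1)
        theta_y = 90.0 * (ys - box.y[0]) / span  # [0, 90] inclusive
        tgrid = np.broadcast_to(
            theta_y[None, :, None],
            (box.x[1] - box.x[0], ys.size, box.z[1] - box.z[0]),
        )
        sign = 1.0 if box.hemisphere == "left" else -1.0
        rad = np.radians(tgrid)
        dirs = np.stack(
            [sign * np.sin(rad), np.zeros_like(rad), np.cos(rad)], axis=-1
        )
        block_theta = theta_true[sl]
        block_theta[sel] = tgrid[sel]
        theta_true[sl] = block_theta
        block_dir = fibers[sl]
        block_dir[sel] = dirs[sel]
        fibers[sl] = block_dir

    # condition-level truth (no jitter)
    r2_cond: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        vol = np.zeros(shape)
        for lid, box in spec.region_layout.items():
            sel = labels == lid
            if box.tissue == "gm":
                vol[sel] = spec.true_r2star_by_region_condition[
                    (box.name, box.hemisphere, cond)
                ]
            else:
                vol[sel] = wm_r2star(spec, theta_true[sel], box.hemisphere, cond)
        r2_cond[cond] = vol

    # per-day truth = condition truth + per-(region, day) physiological jitter
    rng = np.random.default_rng([spec.seed, 7])
    jitter = rng.normal(
        0.0, spec.day_jitter_sd, size=(len(spec.region_layout), spec.n_days)
    ) if spec.day_jitter_sd > 0 else np.zeros((len(spec.region_layout), spec.n_days))
    label_ids = sorted(spec.region_layout)
    per_day = []
    for d in range(spec.n_days):
        vol = r2_cond[spec.day_schedule[d]].copy()
        for k, lid in enumerate(label_ids):
            vol[labels == lid] += jitter[k, d]
        per_day.append(vol)

    return GroundTruth(spec, labels, s0, fibers, theta_true, r2_cond, per_day)


def _rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return noiseless.copy()
    n1 = rng.normal(0.0, sigma, noiseless.shape)
    n2 = rng.normal(0.0, sigma, noiseless.shape)
    return np.sqrt((noiseless + n1) ** 2 + n2**2)


def simulate_multiecho(
    gt: GroundTruth,
    echo_times=DEFAULT_ECHO_TIMES_MS,
    noise_sigma: float | None = None,
    seed: int | None = None,
    day: int = 1,
) -> np.ndarray:
    """Simulate a 4D multi-echo magnitude volume for one study day.

    S(TE) = S0 exp(-R2* TE) with TE in ms, R2* in 1/s; Rician magnitude
    noise of SD ``noise_sigma`` (defaults to the spec's).  ``day`` is
    1-based; the noise stream is derived from (seed, day).
    """
    te = np.asarray(echo_times, dtype=float)
    if np.any(te < 0):
        raise ValueError("echo times must be non-negative")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo_times must be strictly increasing")
    sigma = gt.spec.noise_sigma if noise_sigma is None else noise_sigma
    seed = gt.spec.seed if seed is None else seed
    r2 = gt.r2star_per_day[day - 1]
    clean = gt.s0_volume[..., None] * np.exp(-r2[..., None] * te[None, None, None, :] * 1e-3)
    rng = np.random.default_rng([seed, day, 0])
    return _rician(clean, sigma, rng)


def isotropic_directions(n: int) -> np.ndarray:
    """n approximately isotropically distributed unit vectors (Fibonacci hemisphere).

    Deterministic; directions live on the upper hemisphere, which is
    sufficient for diffusion encoding (the signal is antipodally symmetric).
    """
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    phi = 2 * np.pi * i / golden
    z = (i + 0.5) / n  # upper hemisphere
    r = np.sqrt(1 - z**2)
    g = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def default_bvals_bvecs(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.concatenate([np.zeros(spec.n_b0), np.full(spec.n_directions, spec.bvalue)])
    bvecs = np.vstack([np.zeros((spec.n_b0, 3)), isotropic_directions(spec.n_directions)])
    return bvals, bvecs


def simulate_dwi(
    gt: GroundTruth,
    bvals: np.ndarray | None = None,
    bvecs: np.ndarray | None = None,
    diffusivities: tuple[float, float, float] | None = None,
    noise_sigma: float | None = None,
    seed: int | None = None,
    day: int = 1,
) -> np.ndarray:
    """Simulate a 4D DWI magnitude volume: S = S0 exp(-b g^T D g) + Rician noise.

    WM voxels carry an axially-oriented tensor with eigenvalues
    ``diffusivities`` along the local fiber axis; other tissue is isotropic
    with the spec's ``iso_diffusivity``.
    """
    spec = gt.spec
    if bvals is None or bvecs is None:
        bvals, bvecs = default_bvals_bvecs(spec)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("bvecs for b > 0 volumes must be unit vectors")
    lam = np.asarray(diffusivities if diffusivities is not None else spec.diffusivities)
    if not (lam[0] >= lam[1] >= lam[2] > 0):
        raise ValueError("diffusivities must satisfy l1 >= l2 >= l3 > 0")
    sigma = spec.noise_sigma if noise_sigma is None else noise_sigma
    seed = spec.seed if seed is None else seed

    shape = spec.grid_shape
    nvol = bvals.size
    quad = np.zeros(shape + (nvol,))  # g^T D g per voxel and volume

    wm = gt.wm_mask
    tissue = (gt.label_volume > 0) & ~wm
    if wm.any():
        d1 = gt.fiber_direction_volume[wm]  # (N, 3)
        # complete a right-handed local frame around the fiber axis
        ref = np.where(np.abs(d1[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]])
        e2 = np.cross(d1, ref)
        e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
        e3 = np.cross(d1, e2)
        c1 = d1 @ bvecs.T  # (N, nvol)
        c2 = e2 @ bvecs.T
        c3 = e3 @ bvecs.T
        quad[wm] = lam[0] * c1**2 + lam[1] * c2**2 + lam[2] * c3**2
    quad[tissue] = spec.iso_diffusivity * (np.linalg.norm(bvecs, axis=1) ** 2)[None, :]

    clean = gt.s0_volume[..., None] * np.exp(-bvals[None, None, None, :] * quad)
    rng = np.random.default_rng([seed, day, 1])
    return _rician(clean, sigma, rng)


def _save_nifti(path: Path, data: np.ndarray, voxel_size: float) -> None:
    if nib is None:  # pragma: no cover
        raise ImportError("nibabel is required to write NIfTI files")
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.to_filename(str(path))


def generate_study(spec: PhantomSpec, out_dir, write_truth: bool = False) -> dict:
    """Write a full study to disk and return (and save) its manifest.

    Layout: per-day GRE/DWI 4D NIfTI under ``days/``, a shared label volume,
    lookup table (TSV: id, name, hemisphere), FSL-style bvals/bvecs, and a
    ``manifest.yaml`` listing day index, condition and file paths.  Noise is
    fresh per day (streams derived from seed + day index); calling twice
    with the same spec produces bit-identical volumes.
    """
    out = Path(out_dir)
    (out / "days").mkdir(parents=True, exist_ok=True)
    gt = build_ground_truth(spec)

    labels_path = out / "labels.nii.gz"
    if nib is None:  # pragma: no cover
        raise ImportError("nibabel is required to write NIfTI files")
    nib.Nifti1Image(gt.label_volume.astype(np.int16),
                    np.diag([spec.voxel_size] * 3 + [1.0])).to_filename(str(labels_path))

    lut_path = out / "lut.tsv"
    with open(lut_path, "w") as fh:
        fh.write("id\tname\themisphere\n")
        for lid in sorted(spec.region_layout):
            box = spec.region_layout[lid]
            fh.write(f"{lid}\t{box.name}\t{box.hemisphere}\n")

    bvals, bvecs = default_bvals_bvecs(spec)
    np.savetxt(out / "bvals", bvals[None, :], fmt="%g")
    np.savetxt(out / "bvecs", bvecs.T, fmt="%.8f")

    days = []
    for d in range(1, spec.n_days + 1):
        gre = simulate_multiecho(gt, day=d)
        dwi = simulate_dwi(gt, bvals=bvals, bvecs=bvecs, day=d)
        gre_path = out / "days" / f"gre_day{d:02d}.nii.gz"
        dwi_path = out / "days" / f"dwi_day{d:02d}.nii.gz"
        _save_nifti(gre_path, gre, spec.voxel_size)
        _save_nifti(dwi_path, dwi, spec.voxel_size)
        days.append(
            {
                "day": d,
                "condition": spec.day_schedule[d - 1],
                "gre": str(gre_path.relative_to(out)),
                "dwi": str(dwi_path.relative_to(out)),
            }
        )

    if write_truth:
        (out / "truth").mkdir(exist_ok=True)
        for cond, vol in gt.r2star_by_condition.items():
            _save_nifti(out / "truth" / f"r2star_{cond}.nii.gz", vol, spec.voxel_size)
        _save_nifti(out / "truth" / "theta.nii.gz",
                    np.nan_to_num(gt.theta_true, nan=-1.0), spec.voxel_size)

    manifest = {
        "seed": spec.seed,
        "voxel_size_mm": spec.voxel_size,
        "echo_times_ms": [float(t) for t in DEFAULT_ECHO_TIMES_MS],
        "b0_direction": [float(v) for v in spec.b0_direction],
        "labels": "labels.nii.gz",
        "lut": "lut.tsv",
        "bvals": "bvals",
        "bvecs": "bvecs",
        "wm_label_ids": sorted(
            lid for lid, box in spec.region_layout.items() if box.tissue == "wm"
        ),
        "days": days,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
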