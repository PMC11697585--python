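"""Diffusion tensor fitting and fiber-angle-to-B0 maps.

A single symmetric 3x3 tensor D is fitted per voxel by ordinary least squares
on ln(S/S0) against the six tensor design components
b * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz), where S0 is the geometric
mean of the b=0 volumes.  The fiber angle theta is the angle between the
principal eigenvector e1 and the main field direction B0, folded to
[0, 90] degrees by taking |e1 . B0| (e1 and -e1 describe the same fiber).

Voxels with near-degenerate tensors (FA below a threshold, default 0.1) keep
a defined theta but are flagged so that orientation pooling can exclude them:
the principal axis of an isotropic tensor carries no directional meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiffusionSeries",
    "TensorField",
    "FiberAngleMap",
    "fit_tensor",
    "fiber_angle",
    "fractional_anisotropy",
]


@dataclass
class DiffusionSeries:
    """4D DWI magnitude data with FSL-style bvals/bvecs."""

    data: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, volume)")
        n = self.data.shape[3]
        if self.bvals.shape != (n,) or self.bvecs.shape != (n, 3):
            raise ValueError("bvals/bvecs counts must match the number of volumes")
        dw = self.bvals > 0
        if dw.sum() < 6:
            raise ValueError("need at least 6 diffusion-weighted directions")
        if (~dw).sum() < 1:
            raise ValueError("need at least one b=0 volume")
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("bvecs for b>0 volumes must be unit vectors")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match spatial grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class TensorField:
    """Per-voxel eigensystem of the diffusion tensor.

    ``eigenvalues``: (x, y, z, 3) in mm^2/s, sorted descending.
    ``eigenvectors``: (x, y, z, 3, 3); column ``[..., :, i]`` is the
    eigenvector of ``eigenvalues[..., i]``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    valid: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.valid.shape

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigenvectors[..., :, 0]


@dataclass
class FiberAngleMap:
    """Angle of the principal diffusion axis to B0, degrees in [0, 90]."""

    theta: np.ndarray
    valid: np.ndarray


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    g = bvecs
    return bvals[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(series: DiffusionSeries) -> TensorField:
    """OLS diffusion-tensor fit with eigen-decomposition per voxel.

    The b=0 reference is the geometric mean of all b=0 volumes.  Raises if
    the diffusion directions are collinear (rank-deficient design).
    """
    dw = series.bvals > 0
    design = _design_matrix(series.bvals[dw], series.bvecs[dw])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("diffusion directions are collinear: rank-deficient design")
    pinv = np.linalg.pinv(design)

    mask = (
        series.mask
        if series.mask is not None
        else np.ones(series.grid_shape, dtype=bool)
    )
    flat = series.data[mask]  # (N, V)
    b0 = flat[:, ~dw]
    dwi = flat[:, dw]
    positive = np.all(flat > 0, axis=1) & np.all(np.isfinite(flat), axis=1)

    n = flat.shape[0]
    evals = np.full((n, 3), np.nan)
    evecs = np.full((n, 3, 3), np.nan)

    if positive.any():
        s0 = np.exp(np.log(b0[positive]).mean(axis=1))  # geometric mean
        y = -(np.log(dwi[positive]) - np.log(s0)[:, None])  # (Np, Ndw)
        d6 = y @ pinv.T  # (Np, 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
        t = np.empty((d6.shape[0], 3, 3))
        t[:, 0, 0] = d6[:, 0]
        t[:, 1, 1] = d6[:, 1]
        t[:, 2, 2] = d6[:, 2]
        t[:, 0, 1] = t[:, 1, 0] = d6[:, 3]
        t[:, 0, 2] = t[:, 2, 0] = d6[:, 4]
        t[:, 1, 2] = t[:, 2, 1] = d6[:, 5]
        w, v = np.linalg.eigh(t)  # ascending
        evals[positive] = w[:, ::-1]
        evecs[positive] = v[:, :, ::-1]

    shape = series.grid_shape
    out_w = np.full(shape + (3,), np.nan)
    out_v = np.full(shape + (3, 3), np.nan)
    out_valid = np.zeros(shape, dtype=bool)
    out_w[mask] = evals
    out_v[mask] = evecs
    out_valid[mask] = positive
    return TensorField(out_w, out_v, out_valid)


def fractional_anisotropy(tf: TensorField) -> np.ndarray:
    """FA of the fitted tensor; NaN where invalid."""
    w = tf.eigenvalues
    md = w.mean(axis=-1, keepdims=True)
    num = ((w - md) ** 2).sum(axis=-1)
    den = (w**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(tf.valid & (den > 0), fa, np.nan)


def fiber_angle(tf: TensorField, b0_direction=(0.0, 0.0, 1.0)) -> FiberAngleMap:
    """Angle between the principal eigenvector and B0, folded to [0, 90] deg.

    Antipodal symmetric: e1 and -e1 give the same angle.
    """
    b0 = np.asarray(b0_direction, dtype=float)
    if abs(np.linalg.norm(b0) - 1.0) > 1e-6:
        raise ValueError("b0_direction must be a unit vector")
    e1 = tf.principal_direction
    cosang = np.abs(np.tensordot(e1, b0, axes=([-1], [0])))
    theta = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    theta = np.where(tf.valid, theta, np.nan)
    return FiberAngleMap(theta, tf.valid.copy())
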