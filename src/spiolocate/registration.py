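"""Alignment of the baseline scan to the contrast scan.

The baseline (pre-injection / ground-truth) dataset is always the moving
image — it is warped onto the contrast dataset so that the volumes carrying
the labeled cells are never interpolated.  Rigid alignment maximises
normalized mutual information with a multi-resolution direction-set
(Powell) search; an optional demons-style diffusion-regularized refinement
handles residual non-rigid motion.  Transforms recovered from magnitude
images are applied to the phase data through the complex representation, so
wrapped phase is never directly interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .core import (
    MaskVolume,
    MultiEchoDataset,
    ScalarVolume,
    ValidationError,
    wrap_to_pi,
)

__all__ = [
    "RigidTransform",
    "DeformationField",
    "RegistrationError",
    "normalized_mutual_information",
    "register_rigid",
    "register_nonrigid",
    "resample",
    "resample_dataset",
]


class RegistrationError(RuntimeError):
    """Optimization failed to improve on the identity alignment."""


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (Euler xyz, degrees) about ``center`` followed by translation.

    Maps moving-space points into fixed space: ``x' = R (x - c) + c + t``
    (all in mm).  The identity has all-zero parameters.
    """

    rotation: tuple = (0.0, 0.0, 0.0)
    translation: tuple = (0.0, 0.0, 0.0)
    center: tuple = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation, degrees=True).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center)
        return (self.matrix @ (p - c).T).T + c + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        R = self.matrix.T
        rot = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        # x = R^T (x' - c - t) + c  ==  R^T (x - c) + c + t_inv
        t_inv = -R @ np.asarray(self.translation)
        return RigidTransform(tuple(rot), tuple(t_inv), self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        R = self.matrix @ other.matrix
        c = np.asarray(self.center)
        co = np.asarray(other.center)
        # self(other(x)) = R x + const; recentre on self.center
        const = (
            self.matrix @ (other.matrix @ (-co) + co + np.asarray(other.translation) - c)
            + c
            + np.asarray(self.translation)
        )
        rot = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        t = const - (R @ (-c) + c)
        return RigidTransform(tuple(rot), tuple(t), self.center)


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) sampled on the fixed grid.

    The warped moving image at fixed-grid point ``x`` is
    ``moving(x + displacement(x))``; a zero field is the identity.
    """

    displacement: np.ndarray  # (nx, ny, nz, 3), mm
    voxel_size: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def jacobian_determinant(self) -> np.ndarray:
        vs = np.asarray(self.voxel_size)
        J = np.empty(self.displacement.shape[:3] + (3, 3))
        for comp in range(3):
            grads = np.gradient(self.displacement[..., comp], *vs)
            for ax in range(3):
                J[..., comp, ax] = grads[ax]
        J += np.eye(3)
        return np.linalg.det(J)


def _order(mode: str) -> int:
    if mode in ("trilinear", "linear"):
        return 1
    if mode in ("nearest", "nn"):
        return 0
    raise ValidationError(f"unknown interpolation mode '{mode}'")


def _resample_array(
    data: np.ndarray, vol: ScalarVolume, transform, mode: str, cval: float
) -> np.ndarray:
    order = _order(mode)
    if isinstance(transform, RigidTransform):
        S = np.diag(vol.voxel_size)
        Sinv = np.diag(1.0 / np.asarray(vol.voxel_size))
        Rinv = transform.matrix.T
        origin = np.asarray(vol.origin)
        c = np.asarray(transform.center)
        t = np.asarray(transform.translation)
        M = Sinv @ Rinv @ S
        off = Sinv @ (Rinv @ (origin - c - t) + c - origin)
        # snap numerical epsilon so grid-aligned transforms stay exact
        M = np.where(np.abs(M - np.round(M)) < 1e-9, np.round(M), M)
        off = np.where(np.abs(off - np.round(off)) < 1e-9, np.round(off), off)
        return ndimage.affine_transform(
            data, M, offset=off, order=order, mode="constant", cval=cval, prefilter=False
        )
    if isinstance(transform, DeformationField):
        vs = np.asarray(vol.voxel_size)
        idx = np.indices(data.shape, dtype=float)
        coords = [
            idx[ax] + transform.displacement[..., ax] / vs[ax] for ax in range(3)
        ]
        return ndimage.map_coordinates(
            data, coords, order=order, mode="constant", cval=cval, prefilter=False
        )
    raise ValidationError(f"unsupported transform type {type(transform)!r}")


def resample(volume, transform, mode: str = "trilinear", fill: float = 0.0):
    """Resample a scalar or mask volume under a rigid or deformable transform.

    The output grid is the input grid; ``out(x) = in(T^-1(x))`` for rigid
    transforms, ``out(x) = in(x + d(x))`` for deformation fields.
    Out-of-field voxels receive ``fill``.
    """
    if isinstance(volume, MaskVolume):
        res = _resample_array(volume.data.astype(np.float32), volume, transform, "nearest", 0.0)
        return volume.like(res > 0.5)
    res = _resample_array(volume.data, volume, transform, mode, fill)
    return volume.like(res)


def resample_dataset(dataset: MultiEchoDataset, transform, mode: str = "trilinear") -> MultiEchoDataset:
    """Resample every echo of a dataset in the complex representation.

    Magnitude and phase are recombined into a complex image, real and
    imaginary parts are interpolated, and magnitude / wrapped phase are
    re-extracted, so 2-pi discontinuities are never interpolated across.
    """
    mags, phases = [], []
    for e in range(dataset.protocol.n_echoes):
        cplx = dataset.complex_echo(e)
        ref = dataset.magnitude[e]
        re = _resample_array(cplx.real, ref, transform, mode, 0.0)
        im = _resample_array(cplx.imag, ref, transform, mode, 0.0)
        mags.append(ref.like(np.hypot(re, im)))
        phases.append(ref.like(wrap_to_pi(np.arctan2(im, re))))
    return MultiEchoDataset(dataset.protocol, mags, phases, dataset.role)


def normalized_mutual_information(a: ScalarVolume | np.ndarray, b, bins: int = 32) -> float:
    """Studholme normalized mutual information, ``(H(A)+H(B)) / H(A,B)``.

    Computed from the ``bins`` x ``bins`` joint histogram; ranges over
    ``[1, 2]`` with 2 attained by perfectly (monotonically) related images.
    """
    if bins < 2:
        raise ValidationError("bins must be >= 2")
    da = (a.data if isinstance(a, ScalarVolume) else np.asarray(a)).ravel()
    db = (b.data if isinstance(b, ScalarVolume) else np.asarray(b)).ravel()
    if da.shape != db.shape:
        raise ValidationError("volumes must share one grid")
    valid = np.isfinite(da) & np.isfinite(db)  # NaN marks out-of-field voxels
    da, db = da[valid], db[valid]
    if da.size == 0 or np.ptp(da) == 0 or np.ptp(db) == 0:
        raise ValidationError("constant image has degenerate (zero) entropy")
    hist, _, _ = np.histogram2d(da, db, bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def _entropy(p):
        p = p[p > 0]
        return -np.sum(p * np.log(p))

    hxy = _entropy(pxy.ravel())
    if hxy == 0:
        raise ValidationError("degenerate joint entropy")
    return float((_entropy(px) + _entropy(py)) / hxy)


def _downsample(vol: ScalarVolume, factor: int) -> ScalarVolume:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.data, sigma=factor / 2.0)
    data = sm[::factor, ::factor, ::factor]
    vs = tuple(v * factor for v in vol.voxel_size)
    return ScalarVolume(data, vs, vol.origin)


def register_rigid(
    moving: ScalarVolume,
    fixed: ScalarVolume,
    bins: int = 32,
    levels=(4, 2, 1),
    center: tuple | None = None,
) -> RigidTransform:
    """Recover the rigid transform mapping ``moving`` into ``fixed`` space.

    Maximizes NMI by a derivative-free direction-set (Powell) search over
    the six rigid parameters across a coarse-to-fine resolution pyramid.
    """
    if moving.shape != fixed.shape:
        raise ValidationError("moving and fixed must share one grid")
    if center is None:
        center = tuple(
            np.asarray(fixed.origin)
            + (np.asarray(fixed.shape) - 1) / 2.0 * np.asarray(fixed.voxel_size)
        )
    params = np.zeros(6)
    for factor in levels:
        mov_l = _downsample(moving, factor)
        fix_l = _downsample(fixed, factor)

        def neg_nmi(p):
            t = RigidTransform(tuple(p[:3]), tuple(p[3:]), center)
            # NaN fill marks out-of-field voxels; NMI runs on the overlap only
            warped = resample(mov_l, t, fill=np.nan)
            return -normalized_mutual_information(warped, fix_l, bins)

        res = minimize(
            neg_nmi,
            params,
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 60},
        )
        params = res.x
    final = RigidTransform(tuple(params[:3]), tuple(params[3:]), center)
    nmi_identity = normalized_mutual_information(moving, fixed, bins)
    nmi_final = normalized_mutual_information(
        resample(moving, final, fill=np.nan), fixed, bins
    )
    if nmi_final + 1e-3 < nmi_identity:
        raise RegistrationError(
            f"no NMI improvement over identity ({nmi_final:.4f} < {nmi_identity:.4f})"
        )
    if nmi_final < nmi_identity:
        # already aligned: interpolation loss makes any motion score worse
        return RigidTransform(center=center)
    return final


def register_nonrigid(
    moving: ScalarVolume,
    fixed: ScalarVolume,
    init: RigidTransform | None = None,
    levels=(4, 2),
    iterations: int = 30,
    smooth_sigma: float = 1.5,
    max_step: float = 0.4,
) -> DeformationField:
    """Demons-style diffusion-regularized refinement after rigid alignment.

    Returns the total deformation (including the rigid part) on the fixed
    grid.  The per-iteration update is capped at ``max_step`` voxels and the
    field is Gaussian-smoothed, which keeps the Jacobian determinant
    positive.  Off by default in the phantom pipeline.
    """
    if init is None:
        init = RigidTransform(center=tuple(np.zeros(3)))
    mov0 = resample(moving, init)
    vs = np.asarray(fixed.voxel_size)

    u = None  # displacement in voxels on current level grid
    prev_factor = None
    for factor in levels:
        fix_l = _downsample(fixed, factor)
        mov_l = _downsample(mov0, factor)
        if u is None:
            u = np.zeros(fix_l.shape + (3,))
        else:
            scale = prev_factor / factor
            u = np.stack(
                [
                    ndimage.zoom(u[..., ax], np.asarray(fix_l.shape) / np.asarray(u.shape[:3]), order=1)
                    for ax in range(3)
                ],
                axis=-1,
            ) * scale
        f = fix_l.data
        idx = np.indices(f.shape, dtype=float)
        for _ in range(iterations):
            coords = [idx[ax] + u[..., ax] for ax in range(3)]
            m = ndimage.map_coordinates(mov_l.data, coords, order=1, mode="nearest")
            diff = f - m
            grads = np.gradient(m)
            g2 = sum(g * g for g in grads)
            denom = g2 + diff**2 + 1e-6 * np.max(np.abs(f)) ** 2
            step = np.stack([diff * g / denom for g in grads], axis=-1)
            norm = np.linalg.norm(step, axis=-1, keepdims=True)
            step = np.where(norm > max_step, step / np.maximum(norm, 1e-12) * max_step, step)
            u = u + step
            for ax in range(3):
                u[..., ax] = ndimage.gaussian_filter(u[..., ax], smooth_sigma)
        prev_factor = factor

    if prev_factor != 1:
        u = np.stack(
            [
                ndimage.zoom(u[..., ax], np.asarray(fixed.shape) / np.asarray(u.shape[:3]), order=1)
                for ax in range(3)
            ],
            axis=-1,
        ) * prev_factor
    disp_demons_mm = u * vs  # voxels -> mm on fixed grid

    # compose with the rigid part: moving(T^-1(x + u_mm(x)))
    nx, ny, nz = fixed.shape
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in (nx, ny, nz)], indexing="ij"), axis=-1)
    x_mm = np.asarray(fixed.origin) + grid * vs
    target = x_mm + disp_demons_mm
    inv = init.inverse()
    total = inv.apply(target.reshape(-1, 3)).reshape(target.shape) - x_mm
    return DeformationField(total, fixed.voxel_size, fixed.origin)
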