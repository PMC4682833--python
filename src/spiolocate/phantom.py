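"""Synthetic multi-echo GRE datasets of agarose block phantoms with SPIO inlays.

The simulator replaces the scanner: it builds a ground-truth iron oxide
concentration volume from a geometric phantom description, derives the
susceptibility-induced phase by convolution with the unit magnetic dipole
kernel, applies mono-exponential T2* decay, and adds complex Gaussian noise,
yielding paired baseline / contrast datasets with full ground truth.

Signal model per voxel and echo time TE::

    S(TE) = PD * exp(-(R2*_bg + r * c) * TE) * exp(i * (phi0 + 2*pi*df*TE + phi_dip(TE)))

with ``c`` the local iron oxide concentration (uM), ``r`` the relaxivity
(1/s/uM), ``df`` a smooth background off-resonance field (Hz), and
``phi_dip`` the dipole-convolution phase of the susceptibility distribution.
Complex Gaussian noise makes the stored magnitude Rician-distributed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .core import (
    AcquisitionProtocol,
    DatasetRole,
    MaskVolume,
    MultiEchoDataset,
    ScalarVolume,
    ValidationError,
    wrap_to_pi,
)
from .config import PhantomConfig, ProtocolConfig

__all__ = [
    "InlaySpec",
    "LowDensityRegion",
    "PhantomSpec",
    "PhantomTruth",
    "NoiseSpec",
    "ContrastModel",
    "GAMMA_RAD_PER_S_T",
    "FE2O3_MOLAR_MASS",
    "CELLS_TO_UM_TABLE",
    "cells_to_concentration",
    "build_phantom_truth",
    "dipole_phase_field",
    "tissue_maps",
    "background_fields",
    "synthesize_dataset",
    "apply_rigid_misalignment",
    "protocol_from_config",
    "build_block_phantom_spec",
    "build_invivo_like_spec",
]

#: Proton gyromagnetic ratio, rad / s / T.
GAMMA_RAD_PER_S_T = 2.6752218744e8

#: Molar mass of Fe2O3, g/mol.
FE2O3_MOLAR_MASS = 159.69

#: Dilution-series correspondence between labeled-cell density (cells/mm^3)
#: and iron oxide concentration (uM Fe2O3) used for phantom fabrication.
CELLS_TO_UM_TABLE = ((30.0, 19.0), (60.0, 38.0), (120.0, 78.0), (240.0, 156.0), (480.0, 313.0))


@dataclass(frozen=True)
class InlaySpec:
    """A cylindrical labeled-cell compartment (axis along z)."""

    center: tuple  # mm
    radius: float  # mm
    height: float  # mm
    cell_density: float  # cells / mm^3
    iron_concentration: float  # uM Fe2O3

    def __post_init__(self):
        if self.radius <= 0 or self.height <= 0:
            raise ValidationError("inlay radius and height must be positive")
        if self.cell_density < 0:
            raise ValidationError("cell_density must be >= 0")


@dataclass(frozen=True)
class LowDensityRegion:
    """A spherical low-proton-density confounder (air / bone analog)."""

    center: tuple  # mm
    radius: float  # mm
    pd_multiplier: float = 0.05
    r2star: Optional[float] = None  # override, 1/s


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of a block phantom inside the imaging FOV."""

    block_size: tuple  # mm
    block_center: tuple  # mm
    inlays: tuple = ()
    background_r2star: float = 25.0  # 1/s
    background_proton_density: float = 100.0  # a.u.
    low_density_regions: tuple = ()
    background_texture_amplitude: float = 0.0  # fraction of background PD
    texture_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "inlays", tuple(self.inlays))
        object.__setattr__(self, "low_density_regions", tuple(self.low_density_regions))
        half = np.asarray(self.block_size) / 2.0
        c0 = np.asarray(self.block_center)
        for inlay in self.inlays:
            c = np.asarray(inlay.center)
            lo, hi = c0 - half, c0 + half
            if (
                c[0] - inlay.radius < lo[0] - 1e-9
                or c[0] + inlay.radius > hi[0] + 1e-9
                or c[1] - inlay.radius < lo[1] - 1e-9
                or c[1] + inlay.radius > hi[1] + 1e-9
                or c[2] - inlay.height / 2 < lo[2] - 1e-9
                or c[2] + inlay.height / 2 > hi[2] + 1e-9
            ):
                raise ValidationError(f"inlay at {inlay.center} lies outside the block")
        for i, a in enumerate(self.inlays):
            for b in self.inlays[i + 1 :]:
                d_xy = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                dz = abs(a.center[2] - b.center[2])
                if d_xy < a.radius + b.radius and dz < (a.height + b.height) / 2:
                    raise ValidationError("inlays must be pairwise disjoint")


@dataclass
class PhantomTruth:
    """Ground truth: concentration volume and integer inlay labels."""

    concentration: ScalarVolume  # uM
    inlay_labels: np.ndarray  # int volume, 0 = background, i = spec.inlays[i-1]
    positive_mask: MaskVolume

    def __post_init__(self):
        if not np.array_equal(self.positive_mask.data, self.concentration.data > 0):
            raise ValidationError("positive_mask must equal concentration > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Complex-noise level (fraction of background magnitude at TE1) and seed."""

    complex_noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.complex_noise_sigma < 0:
            raise ValidationError("noise sigma must be >= 0")


@dataclass(frozen=True)
class ContrastModel:
    """Conversion constants between cells, iron load, R2* and susceptibility."""

    r2star_relaxivity: float = 1.0  # 1/s per uM
    susceptibility_per_concentration: float = 3.0e-3  # ppm per uM
    per_cell_iron_load: float = 90.0  # pg per cell

    def __post_init__(self):
        if self.r2star_relaxivity <= 0:
            raise ValidationError("relaxivity must be positive")


def cells_to_concentration(
    cell_density: float, model: ContrastModel | None = None, mode: str = "lookup"
) -> float:
    """Convert a labeled-cell density (cells/mm^3) to uM Fe2O3.

    The default ``lookup`` mode linearly interpolates (and extrapolates) the
    fabrication dilution-series pairs in :data:`CELLS_TO_UM_TABLE`.  The
    ``analytic`` mode is approximate: it computes pg Fe2O3 per mm^3 from the
    per-cell iron load and divides by the molar mass; it does not exactly
    reproduce the fabrication pairs (30 cells/mm^3 gives ~16.9 uM, not 19 uM).
    """
    if cell_density < 0:
        raise ValidationError("cell_density must be >= 0")
    if mode == "analytic":
        model = model or ContrastModel()
        pg_per_mm3 = cell_density * model.per_cell_iron_load
        # pg/mm^3 == ug/cm^3 == ug/ml; /M gives umol/l == uM
        return pg_per_mm3 / FE2O3_MOLAR_MASS
    if mode != "lookup":
        raise ValidationError(f"unknown mode '{mode}' (use 'lookup' or 'analytic')")
    if cell_density == 0:
        return 0.0
    xs = np.array([p[0] for p in CELLS_TO_UM_TABLE])
    ys = np.array([p[1] for p in CELLS_TO_UM_TABLE])
    if cell_density <= xs[0]:
        slope = ys[0] / xs[0]  # through the origin below the table
        return float(slope * cell_density)
    if cell_density >= xs[-1]:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + slope * (cell_density - xs[-1]))
    return float(np.interp(cell_density, xs, ys))


def _grid_coords(protocol: AcquisitionProtocol, origin=(0.0, 0.0, 0.0)):
    nx, ny, nz = protocol.matrix_size
    vx, vy, vz = protocol.voxel_size
    x = origin[0] + np.arange(nx) * vx
    y = origin[1] + np.arange(ny) * vy
    z = origin[2] + np.arange(nz) * vz
    return np.meshgrid(x, y, z, indexing="ij")


def build_phantom_truth(
    spec: PhantomSpec, protocol: AcquisitionProtocol, supersample: int = 3
) -> PhantomTruth:
    """Rasterize the phantom geometry onto the protocol grid.

    A voxel belongs to an inlay when at least 50% of its volume (estimated on
    a ``supersample``^3 sub-grid) lies inside the cylinder; the concentration
    map is piecewise constant.
    """
    nx, ny, nz = protocol.matrix_size
    vx, vy, vz = protocol.voxel_size
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    conc = np.zeros((nx, ny, nz), dtype=np.float64)

    # sub-voxel offsets (voxel centred at index * voxel_size)
    ss = supersample
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    for idx, inlay in enumerate(spec.inlays, start=1):
        cx, cy, cz = inlay.center
        ilo = max(0, int(np.floor((cx - inlay.radius) / vx - 1)))
        ihi = min(nx, int(np.ceil((cx + inlay.radius) / vx + 1)) + 1)
        jlo = max(0, int(np.floor((cy - inlay.radius) / vy - 1)))
        jhi = min(ny, int(np.ceil((cy + inlay.radius) / vy + 1)) + 1)
        klo = max(0, int(np.floor((cz - inlay.height / 2) / vz - 1)))
        khi = min(nz, int(np.ceil((cz + inlay.height / 2) / vz + 1)) + 1)
        xs = (np.arange(ilo, ihi)[:, None] + offs[None, :]).ravel() * vx
        ys = (np.arange(jlo, jhi)[:, None] + offs[None, :]).ravel() * vy
        zs = (np.arange(klo, khi)[:, None] + offs[None, :]).ravel() * vz
        X2 = (xs[:, None, None] - cx) ** 2
        Y2 = (ys[None, :, None] - cy) ** 2
        Z_in = np.abs(zs - cz) <= inlay.height / 2
        inside = (X2 + Y2 <= inlay.radius**2) & Z_in[None, None, :]
        # fold supersampling axes back onto voxels
        inside = inside.reshape(ihi - ilo, ss, jhi - jlo, ss, khi - klo, ss)
        occupancy = inside.mean(axis=(1, 3, 5))
        sel = occupancy >= 0.5
        labels[ilo:ihi, jlo:jhi, klo:khi][sel] = idx
        conc[ilo:ihi, jlo:jhi, klo:khi][sel] = inlay.iron_concentration

    vol = ScalarVolume(conc, protocol.voxel_size)
    mask = MaskVolume(conc > 0, protocol.voxel_size)
    return PhantomTruth(vol, labels, mask)


def dipole_phase_field(
    truth: PhantomTruth,
    model: ContrastModel,
    protocol: AcquisitionProtocol,
    te: float,
) -> ScalarVolume:
    """Susceptibility-induced phase (radians) at echo time ``te`` (ms).

    The concentration map is scaled to a dimensionless susceptibility map,
    convolved with the unit dipole kernel (Fourier-domain
    ``1/3 - kz^2 / |k|^2`` with the k = 0 term zeroed, kz along B0), and
    multiplied by gamma * B0 * TE.  The result is linear in both the
    concentration and TE.
    """
    if te <= 0:
        raise ValidationError("te must be positive")
    chi = truth.concentration.data * model.susceptibility_per_concentration * 1e-6
    nx, ny, nz = chi.shape
    kx = np.fft.fftfreq(nx, d=protocol.voxel_size[0])
    ky = np.fft.fftfreq(ny, d=protocol.voxel_size[1])
    kz = np.fft.fftfreq(nz, d=protocol.voxel_size[2])
    KX, KY, KZ = np.meshgrid(kx, ky, kz, indexing="ij")
    k2 = KX**2 + KY**2 + KZ**2
    bx, by, bz = protocol.b0_direction
    kb = KX * bx + KY * by + KZ * bz
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = 1.0 / 3.0 - kb**2 / k2
    kernel[0, 0, 0] = 0.0
    field_rel = np.fft.ifftn(kernel * np.fft.fftn(chi)).real
    phase = GAMMA_RAD_PER_S_T * protocol.field_strength * field_rel * (te * 1e-3)
    return truth.concentration.like(phase)


def tissue_maps(spec: PhantomSpec, protocol: AcquisitionProtocol):
    """Proton-density and background-R2* volumes implied by the phantom spec."""
    X, Y, Z = _grid_coords(protocol)
    half = np.asarray(spec.block_size) / 2.0
    c0 = np.asarray(spec.block_center)
    # partial-volume block boundary: per-axis overlap fraction of each voxel
    # with the box, so sub-voxel phantom positions are faithfully rendered
    vs = np.asarray(protocol.voxel_size)
    frac = np.ones_like(X)
    for axis, coords in enumerate((X, Y, Z)):
        frac = frac * np.clip((half[axis] - np.abs(coords - c0[axis])) / vs[axis] + 0.5, 0.0, 1.0)
    pd = spec.background_proton_density * frac
    r2s = np.full(pd.shape, spec.background_r2star)
    if spec.background_texture_amplitude > 0:
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(spec.texture_seed)
        tex = gaussian_filter(rng.standard_normal(pd.shape), sigma=4.0)
        tex /= max(np.abs(tex).max(), 1e-12)
        pd = pd * (1.0 + spec.background_texture_amplitude * tex)
        r2s = r2s * (1.0 + 0.5 * spec.background_texture_amplitude * tex)
    for reg in spec.low_density_regions:
        d2 = (X - reg.center[0]) ** 2 + (Y - reg.center[1]) ** 2 + (Z - reg.center[2]) ** 2
        sel = d2 <= reg.radius**2
        pd[sel] *= reg.pd_multiplier
        if reg.r2star is not None:
            r2s[sel] = reg.r2star
    vs = protocol.voxel_size
    return ScalarVolume(pd, vs), ScalarVolume(r2s, vs)


def background_fields(spec: PhantomSpec, protocol: AcquisitionProtocol, seed: int):
    """Smooth background off-resonance (Hz) and RF phase offset (rad) maps.

    Low-order polynomial fields with seeded coefficients; shared by the
    baseline and contrast scans of one phantom (same shim state).
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 2])
    X, Y, Z = _grid_coords(protocol)
    fov = np.asarray(protocol.fov)
    Xn = X / fov[0] - 0.5
    Yn = Y / fov[1] - 0.5
    Zn = Z / fov[2] - 0.5
    lin = rng.uniform(-150.0, 150.0, size=3)
    quad = rng.uniform(-50.0, 50.0, size=3)
    df = lin[0] * Xn + lin[1] * Yn + lin[2] * Zn
    df += quad[0] * Xn * Yn + quad[1] * Yn * Zn + quad[2] * (Zn**2 - 1.0 / 12.0)
    p0 = rng.uniform(-0.3, 0.3) + rng.uniform(-0.3, 0.3) * Yn
    vs = protocol.voxel_size
    return ScalarVolume(df, vs), ScalarVolume(p0 + np.zeros_like(df), vs)


def synthesize_dataset(
    truth: PhantomTruth,
    spec: PhantomSpec,
    model: ContrastModel,
    protocol: AcquisitionProtocol,
    noise: NoiseSpec,
):
    """Simulate the (baseline, contrast) dataset pair for one phantom.

    The contrast scan carries the dipole phase and the accelerated T2* decay
    of the concentration map; the baseline is generated identically with zero
    concentration and an independently seeded noise draw.
    """
    pd, r2s_bg = tissue_maps(spec, protocol)
    df, phi0 = background_fields(spec, protocol, noise.seed)
    te1_s = protocol.echo_times_s[0]
    sigma = noise.complex_noise_sigma * spec.background_proton_density * math.exp(
        -spec.background_r2star * te1_s
    )

    datasets = {}
    for role, conc_vol, sub in (
        (DatasetRole.BASELINE, None, 1),
        (DatasetRole.CONTRAST, truth.concentration, 0),
    ):
        rng = np.random.default_rng([int(noise.seed) & 0x7FFFFFFF, sub])
        mags, phases = [], []
        for te_ms, te_s in zip(protocol.echo_times, protocol.echo_times_s):
            r2s = r2s_bg.data.copy()
            phase = phi0.data + 2.0 * np.pi * df.data * te_s
            if conc_vol is not None:
                r2s = r2s + model.r2star_relaxivity * conc_vol.data
                phase = phase + dipole_phase_field(truth, model, protocol, te_ms).data
            signal = pd.data * np.exp(-r2s * te_s) * np.exp(1j * phase)
            if sigma > 0:
                signal = signal + sigma * (
                    rng.standard_normal(signal.shape) + 1j * rng.standard_normal(signal.shape)
                )
            mags.append(pd.like(np.abs(signal)))
            phases.append(pd.like(wrap_to_pi(np.angle(signal))))
        datasets[role] = MultiEchoDataset(protocol, mags, phases, role)
    return datasets[DatasetRole.BASELINE], datasets[DatasetRole.CONTRAST]


def apply_rigid_misalignment(dataset: MultiEchoDataset, transform) -> MultiEchoDataset:
    """Resample every echo of a dataset under a rigid transform.

    Resampling acts on the complex representation (re/im) and the phase is
    re-extracted afterwards, so wrapped-phase discontinuities are never
    interpolated across.
    """
    from .registration import resample_dataset

    return resample_dataset(dataset, transform)


def protocol_from_config(cfg: ProtocolConfig) -> AcquisitionProtocol:
    return AcquisitionProtocol(
        echo_times=cfg.echo_times,
        repetition_time=cfg.repetition_time,
        flip_angle=cfg.flip_angle,
        field_strength=cfg.field_strength,
        voxel_size=cfg.voxel_size,
        matrix_size=cfg.matrix_size,
        b0_direction=cfg.b0_direction,
    )


def build_block_phantom_spec(
    phantom_cfg: PhantomConfig, protocol: AcquisitionProtocol
) -> PhantomSpec:
    """The default agarose block phantom: five cylindrical inlays in a 2:1
    dilution series (480 down to 30 cells/mm^3) evenly spaced along the long
    axis of the block."""
    fov = np.asarray(protocol.fov)
    margin = phantom_cfg.block_margin
    block_size = tuple(fov - 2 * margin)
    center = tuple(fov / 2.0)
    n = len(phantom_cfg.cell_densities)
    r = phantom_cfg.inlay_radius
    clearance = 1.2  # mm of agarose between every compartment and a block face
    y_lo = margin + r + clearance
    y_hi = fov[1] - margin - r - clearance
    y_centers = np.linspace(y_lo, y_hi, n) if n > 1 else [fov[1] / 2.0]
    inlays = []
    for i, dens in enumerate(phantom_cfg.cell_densities):
        y = y_centers[i]
        inlays.append(
            InlaySpec(
                center=(fov[0] / 2.0, float(y), fov[2] / 2.0),
                radius=phantom_cfg.inlay_radius,
                height=phantom_cfg.inlay_height,
                cell_density=float(dens),
                iron_concentration=cells_to_concentration(float(dens)),
            )
        )
    return PhantomSpec(
        block_size=block_size,
        block_center=center,
        inlays=tuple(inlays),
        background_r2star=phantom_cfg.background_r2star,
        background_proton_density=phantom_cfg.background_proton_density,
    )


def build_invivo_like_spec(
    seed: int, protocol: AcquisitionProtocol | None = None
) -> PhantomSpec:
    """An in-vivo-like phantom: heterogeneous background, at least two
    low-proton-density confounder regions (air / bone analogs) without iron,
    and two labeled-cell inlays in opposite half-spaces (the two injections).
    """
    if protocol is None:
        protocol = protocol_from_config(ProtocolConfig())
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    fov = np.asarray(protocol.fov)
    margin = 1.6
    block_size = tuple(fov - 2 * margin)
    center = tuple(fov / 2.0)
    jitter = lambda s: float(rng.uniform(-s, s))

    inlays = (
        InlaySpec(
            center=(fov[0] / 2 + jitter(1.0), fov[1] * 0.25 + jitter(2.0), fov[2] / 2),
            radius=2.8,
            height=4.8,
            cell_density=240.0,
            iron_concentration=cells_to_concentration(240.0),
        ),
        InlaySpec(
            center=(fov[0] / 2 + jitter(1.0), fov[1] * 0.75 + jitter(2.0), fov[2] / 2),
            radius=2.8,
            height=4.8,
            cell_density=480.0,
            iron_concentration=cells_to_concentration(480.0),
        ),
    )
    confounders = (
        LowDensityRegion(
            center=(fov[0] * 0.3 + jitter(1.0), fov[1] * 0.45 + jitter(2.0), fov[2] / 2),
            radius=2.4,
            pd_multiplier=0.05,
            r2star=80.0,
        ),
        LowDensityRegion(
            center=(fov[0] * 0.7 + jitter(1.0), fov[1] * 0.58 + jitter(2.0), fov[2] / 2),
            radius=2.0,
            pd_multiplier=0.08,
            r2star=60.0,
        ),
    )
    return PhantomSpec(
        block_size=block_size,
        block_center=center,
        inlays=inlays,
        background_r2star=28.0,
        background_proton_density=100.0,
        low_density_regions=confounders,
        background_texture_amplitude=0.15,
        texture_seed=int(seed) & 0x7FFFFFFF,
    )
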