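"""Magnitude-derived features: signal intensity, VOI, hyper/hypo-intensity
change maps, R2* relaxometry, and the R2* -> iron oxide concentration
calibration.

R2* is fit per voxel by weighted log-linear least squares on the
mono-exponential decay ``S(TE) = S0 exp(-R2* TE)``; echoes whose magnitude
has fallen to the noise floor are excluded, and voxels left with fewer than
two usable echoes fall back to a two-echo estimate from the shortest echo
pair and are flagged low-confidence.  This is the mechanism behind the
systematic underestimation of the highest concentrations: their long-TE
signal sits below the noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import MaskVolume, MultiEchoDataset, ScalarVolume, ValidationError
from .phantom import PhantomTruth

__all__ = [
    "R2StarMap",
    "CalibrationModel",
    "signal_intensity",
    "compute_voi",
    "delta_rho",
    "fit_r2star",
    "fit_calibration",
    "concentration_from_r2star",
]


@dataclass
class R2StarMap:
    r2star: ScalarVolume  # 1/s
    fit_quality: ScalarVolume  # weighted RMS residual of the log fit
    low_confidence_mask: MaskVolume


@dataclass
class CalibrationModel:
    """Linear R2*(c) calibration: ``R2* = intercept + slope * c``.

    ``intercept_r2star`` is the background (agarose) rate in 1/s and
    ``slope_relaxivity`` the relaxivity in 1/s per uM, so the predicted
    concentration at the intercept is exactly zero.
    """

    intercept_r2star: float
    slope_relaxivity: float
    fit_points: list  # (concentration uM, regional R2* 1/s)

    def __post_init__(self):
        if self.slope_relaxivity <= 0:
            raise ValidationError("calibration slope must be positive")

    def predict_concentration(self, r2star: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, (r2star - self.intercept_r2star) / self.slope_relaxivity)


def signal_intensity(dataset: MultiEchoDataset) -> list:
    """Per-echo magnitude volumes (validated pass-through)."""
    for vol in dataset.magnitude:
        if np.any(vol.data < 0):
            raise ValidationError("magnitude must be non-negative")
    return list(dataset.magnitude)


def _fcm_two_class(features: np.ndarray, m: float = 2.0, iters: int = 60, tol: float = 1e-5):
    """Two-class fuzzy c-means on (n_samples, n_features); returns memberships
    of the higher-intensity class."""
    n = features.shape[0]
    rng_lo, rng_hi = np.percentile(features[:, 0], [5, 95])
    centers = np.array(
        [[rng_lo] * features.shape[1], [rng_hi] * features.shape[1]], dtype=float
    )
    u = None
    for _ in range(iters):
        d2 = ((features[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = 1.0 / d2  # m = 2 -> exponent 1
        u_new = inv / inv.sum(axis=1, keepdims=True)
        w = u_new**m
        centers_new = (w.T @ features) / w.sum(axis=0)[:, None]
        if u is not None and np.max(np.abs(u_new - u)) < tol:
            u = u_new
            centers = centers_new
            break
        u, centers = u_new, centers_new
    hi = int(np.argmax(centers[:, 0]))
    return u[:, hi]


def compute_voi(
    magnitude_first_echo: ScalarVolume, membership_threshold: float = 0.5
) -> MaskVolume:
    """Object mask (phantom / animal, excluding air) of the first-echo image.

    Spatial fuzzy c-means with two classes on an (intensity, neighborhood
    mean) feature pair, automated threshold on the object-class membership,
    then largest connected component and hole filling, so signal voids from
    SPIO inlays inside the object are retained.
    """
    data = magnitude_first_echo.data
    if data.size == 0 or np.ptp(data) == 0:
        raise ValidationError("VOI segmentation needs a non-constant volume")
    neigh = ndimage.uniform_filter(data, size=3)
    feats = np.stack([data.ravel(), neigh.ravel()], axis=1)
    membership = _fcm_two_class(feats).reshape(data.shape)
    mask = membership >= membership_threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValidationError("VOI segmentation found no object")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    # closing seals pinholes so interior signal voids stay enclosed holes
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3)))
    mask = ndimage.binary_fill_holes(mask)
    return MaskVolume(mask, magnitude_first_echo.voxel_size, magnitude_first_echo.origin)


def delta_rho(contrast: MultiEchoDataset, baseline_registered: MultiEchoDataset) -> list:
    """Per-echo voxelwise absolute magnitude change versus the registered
    baseline (hyper- and hypo-intensities fold into one non-negative map)."""
    if tuple(contrast.protocol.echo_times) != tuple(baseline_registered.protocol.echo_times):
        raise ValidationError("echo times of contrast and baseline differ")
    if contrast.shape != baseline_registered.shape:
        raise ValidationError("datasets must share one grid")
    return [
        c.like(np.abs(c.data - b.data))
        for c, b in zip(contrast.magnitude, baseline_registered.magnitude)
    ]


def fit_r2star(dataset: MultiEchoDataset, noise_floor: float = 0.0) -> R2StarMap:
    """Voxelwise mono-exponential R2* fit across echo times.

    Weighted least squares on log-magnitude with squared-magnitude weights
    (the correct first-order weighting for log-transformed Rician data at
    moderate SNR).  Echoes at or below ``noise_floor`` are excluded; voxels
    with fewer than two usable echoes take the two-echo estimate from the
    first echo pair and are flagged in ``low_confidence_mask``, as are voxels
    whose fitted rate was negative and clamped to zero.
    """
    n_echo = dataset.protocol.n_echoes
    if n_echo < 2:
        raise ValidationError("R2* fitting needs at least 2 echoes")
    te = dataset.protocol.echo_times_s  # seconds
    mags = np.stack([v.data for v in dataset.magnitude], axis=-1)
    shape = mags.shape[:-1]
    safe = np.maximum(mags, 1e-12)
    logm = np.log(safe)

    usable = mags > noise_floor
    n_usable = usable.sum(axis=-1)
    low_conf = n_usable < n_echo  # any echo fell below the floor

    w = np.where(usable, safe**2, 0.0)
    # fall back to the first two echoes where fewer than 2 echoes are usable
    fallback = n_usable < 2
    if np.any(fallback):
        w[fallback] = 0.0
        w[fallback, 0] = safe[fallback, 0] ** 2
        w[fallback, 1] = safe[fallback, 1] ** 2

    sw = w.sum(axis=-1)
    swt = (w * te).sum(axis=-1)
    swtt = (w * te * te).sum(axis=-1)
    swy = (w * logm).sum(axis=-1)
    swty = (w * te * logm).sum(axis=-1)
    denom = sw * swtt - swt**2
    denom = np.where(denom <= 0, np.nan, denom)
    slope = (sw * swty - swt * swy) / denom
    intercept = (swy - slope * swt) / sw
    r2s = -slope
    nan_fit = ~np.isfinite(r2s)
    with np.errstate(invalid="ignore"):
        negative = np.where(nan_fit, False, r2s < 0)
    r2s = np.where(nan_fit, 0.0, np.maximum(r2s, 0.0))
    low_conf = low_conf | nan_fit | negative

    resid = logm - (intercept[..., None] + slope[..., None] * te)
    resid = np.where(np.isnan(resid), 0.0, resid)
    quality = np.sqrt((w * resid**2).sum(axis=-1) / np.maximum(sw, 1e-300))

    ref = dataset.magnitude[0]
    return R2StarMap(
        r2star=ref.like(r2s),
        fit_quality=ref.like(quality),
        low_confidence_mask=MaskVolume(low_conf, ref.voxel_size, ref.origin),
    )


def fit_calibration(
    r2star_map: R2StarMap,
    truth: PhantomTruth,
    mask: MaskVolume | None = None,
) -> CalibrationModel:
    """Fit the linear R2*(concentration) calibration from the phantom inlays.

    Uses the median R2* per inlay region (robust to edge partial volume)
    plus the background point (0, median background R2*); background voxels
    are restricted to ``mask`` (e.g. the VOI) when given.
    """
    r2s = r2star_map.r2star.data
    labels = truth.inlay_labels
    concs, rates = [], []
    bg = labels == 0
    if mask is not None:
        bg = bg & mask.data
    if np.any(bg):
        concs.append(0.0)
        rates.append(float(np.median(r2s[bg])))
    for lab in range(1, labels.max() + 1):
        sel = labels == lab
        if not np.any(sel):
            continue
        concs.append(float(np.median(truth.concentration.data[sel])))
        rates.append(float(np.median(r2s[sel])))
    nonzero = sorted({c for c in concs if c > 0})
    if len(nonzero) < 2:
        raise ValidationError("calibration needs >= 2 distinct nonzero concentrations")
    slope, intercept = np.polyfit(concs, rates, 1)
    return CalibrationModel(
        intercept_r2star=float(intercept),
        slope_relaxivity=float(slope),
        fit_points=list(zip(concs, rates)),
    )


def concentration_from_r2star(
    r2star_map: R2StarMap, calibration: CalibrationModel
) -> ScalarVolume:
    """Voxelwise concentration estimate ``max(0, (R2* - b) / a)`` in uM.

    Low-confidence voxels carry the estimate; the flag travels separately in
    ``r2star_map.low_confidence_mask``.
    """
    return r2star_map.r2star.like(
        calibration.predict_concentration(r2star_map.r2star.data)
    )
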