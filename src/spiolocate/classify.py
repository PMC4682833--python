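"""Voxel-wise C-SVC classification of the multiparametric feature stack.

Thirteen feature channels per voxel — per-echo signal intensity, per-echo
magnitude change versus baseline, R2*, per-echo baseline-subtracted unwrapped
phase, the unreliable-phase indicator, the short-range perturbation s and the
propagation rate p — are standardized (median / MAD over the VOI) and fed to
a C-support-vector classifier with an RBF kernel.  The regularization C and
kernel sharpness gamma are self-tuned by stratified five-fold cross
validation over a log grid; the pre-trained model (with its scalers)
transfers to independently acquired scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import MaskVolume, ScalarVolume, ValidationError

__all__ = [
    "FeatureStack",
    "TrainingSet",
    "SvmModel",
    "LocalizationResult",
    "CHANNEL_ORDER",
    "assemble_features",
    "sample_training_set",
    "rbf_kernel",
    "train_svm",
    "predict_voxels",
    "build_localization_result",
]

#: Canonical channel ordering for a 3-echo protocol.
CHANNEL_ORDER = (
    "rho_e1", "rho_e2", "rho_e3",
    "drho_e1", "drho_e2", "drho_e3",
    "r2star",
    "phi_e1", "phi_e2", "phi_e3",
    "unreliable_phi",
    "s", "p",
)

#: Channels zeroed (imputed to the standardized centre) at unreliable voxels.
PHASE_CHANNELS = ("phi_e1", "phi_e2", "phi_e3", "s", "p")


@dataclass
class FeatureStack:
    """Standardized per-voxel feature channels on one grid."""

    channels: dict  # name -> ScalarVolume (standardized)
    voi: MaskVolume
    channel_scalers: dict  # name -> (location, scale) of the raw channel

    @property
    def names(self) -> tuple:
        return tuple(self.channels)

    def matrix(self, indices: np.ndarray | None = None) -> np.ndarray:
        """(n_voxels, n_channels) design matrix over VOI (or given flat indices)."""
        if indices is None:
            indices = np.flatnonzero(self.voi.data.ravel())
        cols = [self.channels[name].data.ravel()[indices] for name in self.channels]
        return np.stack(cols, axis=1)

    def raw_matrix(self, indices: np.ndarray, scalers: dict | None = None) -> np.ndarray:
        """Design matrix re-standardized with foreign ``scalers`` (model transfer)."""
        if scalers is None:
            return self.matrix(indices)
        if tuple(scalers) != tuple(self.channels):
            raise ValidationError("channel mismatch between stack and model")
        cols = []
        for name in self.channels:
            loc, scale = self.channel_scalers[name]
            raw = self.channels[name].data.ravel()[indices] * scale + loc
            mloc, mscale = scalers[name]
            cols.append((raw - mloc) / mscale)
        return np.stack(cols, axis=1)


@dataclass
class TrainingSet:
    features: np.ndarray  # (n, n_channels)
    labels: np.ndarray  # bool, True = containing labeled cells
    voxel_indices: np.ndarray  # flat indices into the grid
    channel_names: tuple
    fraction: float
    seed: int


@dataclass
class SvmModel:
    """Trained C-SVC with its CV record and the training-stack scalers."""

    svc: SVC
    C: float
    gamma: float
    cv_table: dict  # (C, gamma) -> CV accuracy
    channel_names: tuple
    channel_scalers: dict
    n_support: tuple = ()


@dataclass
class LocalizationResult:
    """Binary positive-voxel map and the masked concentration map (uM)."""

    positives: MaskVolume
    concentration: ScalarVolume


def _robust_scaler(values: np.ndarray) -> tuple:
    loc = float(np.median(values))
    mad = float(np.median(np.abs(values - loc)))
    scale = 1.4826 * mad
    if scale <= 0:
        sd = float(values.std())
        scale = sd if sd > 0 else 1.0
    return loc, scale


def assemble_features(
    rho: list,
    drho: list,
    r2star: ScalarVolume,
    phi_diff: list,
    unreliable: MaskVolume,
    s_map: ScalarVolume,
    p_map: ScalarVolume,
    voi: MaskVolume,
) -> FeatureStack:
    """Stack, standardize (median/MAD over the VOI) and impute the channels.

    Voxels flagged unreliable keep an indicator channel set to 1 and have
    their phase-derived channels imputed to 0, the standardized centre, so
    every VOI voxel still receives a classification.
    """
    raw = {}
    for i, vol in enumerate(rho, 1):
        raw[f"rho_e{i}"] = vol
    for i, vol in enumerate(drho, 1):
        raw[f"drho_e{i}"] = vol
    raw["r2star"] = r2star
    for i, vol in enumerate(phi_diff, 1):
        raw[f"phi_e{i}"] = vol
    raw["unreliable_phi"] = ScalarVolume(
        unreliable.data.astype(float), unreliable.voxel_size, unreliable.origin
    )
    raw["s"] = s_map
    raw["p"] = p_map

    ref = voi
    for name, vol in raw.items():
        if vol.shape != ref.shape:
            raise ValidationError(f"channel {name}: grid mismatch")

    inside = voi.data
    unrel = unreliable.data & inside
    channels, scalers = {}, {}
    for name, vol in raw.items():
        if name == "unreliable_phi":
            loc, scale = 0.0, 1.0
            std = vol.data.astype(float)
        else:
            loc, scale = _robust_scaler(vol.data[inside])
            std = (vol.data - loc) / scale
        if name in PHASE_CHANNELS:
            std = np.where(unrel, 0.0, std)
        channels[name] = vol.like(np.where(inside, std, 0.0))
        scalers[name] = (loc, scale)
    return FeatureStack(channels=channels, voi=voi, channel_scalers=scalers)


def sample_training_set(
    stack: FeatureStack,
    truth_labels: MaskVolume,
    fraction: float = 0.15,
    seed: int = 0,
    stratified: bool = False,
) -> TrainingSet:
    """Random subsample of VOI voxels with labels from the phantom truth.

    Emulates manual labeling of a random voxel subset from a-priori knowledge
    of the inlay geometry.  ``stratified`` keeps the VOI class ratio exactly
    (within rounding); both classes must end up present.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    voi_idx = np.flatnonzero(stack.voi.data.ravel())
    labels_all = truth_labels.data.ravel()[voi_idx]
    n = max(1, round(fraction * voi_idx.size))
    for attempt in range(2):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, attempt])
        if stratified:
            pos = np.flatnonzero(labels_all)
            neg = np.flatnonzero(~labels_all)
            n_pos = max(1, round(n * pos.size / labels_all.size))
            take = np.concatenate(
                [
                    rng.choice(pos, size=min(n_pos, pos.size), replace=False),
                    rng.choice(neg, size=min(n - n_pos, neg.size), replace=False),
                ]
            )
        else:
            take = rng.choice(labels_all.size, size=n, replace=False)
        take.sort()
        lab = labels_all[take]
        if lab.any() and not lab.all():
            idx = voi_idx[take]
            return TrainingSet(
                features=stack.matrix(idx),
                labels=lab,
                voxel_indices=idx,
                channel_names=stack.names,
                fraction=fraction,
                seed=seed,
            )
    raise ValidationError("a class is absent from the training sample (after resampling once)")


def rbf_kernel(x_i: np.ndarray, x_j: np.ndarray, gamma: float) -> float:
    """RBF kernel ``exp(-gamma * ||x_i - x_j||^2)``, in (0, 1]."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValidationError("feature vectors must have equal dimension")
    if gamma <= 0:
        raise ValidationError("gamma must be positive")
    return float(np.exp(-gamma * np.sum((x_i - x_j) ** 2)))


def train_svm(
    training: TrainingSet,
    c_grid=(0.125, 0.5, 2.0, 8.0, 32.0, 128.0, 512.0),
    gamma_grid=(2.0**-9, 2.0**-7, 2.0**-5, 2.0**-3, 0.5, 2.0, 8.0),
    cv_folds: int = 5,
    cv_max_samples: int | None = 2500,
    seed: int = 0,
) -> SvmModel:
    """Grid-search (C, gamma) by stratified five-fold CV, refit on all data.

    Class-weighted misclassification penalties compensate the background /
    inlay imbalance.  Ties are broken toward the smallest gamma, then the
    smallest C (the smoother boundary).  When the training sample exceeds
    ``cv_max_samples`` the CV search runs on a seeded stratified subsample;
    the selected point is refit on the full sample.
    """
    X, y = training.features, training.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    if len(c_grid) == 0 or len(gamma_grid) == 0:
        raise ValidationError("hyperparameter grid must be nonempty")

    X_cv, y_cv = X, y
    if cv_max_samples is not None and X.shape[0] > cv_max_samples:
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 17])
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        n_pos = max(cv_folds, round(cv_max_samples * pos.size / y.size))
        n_neg = cv_max_samples - n_pos
        take = np.concatenate(
            [
                rng.choice(pos, size=min(n_pos, pos.size), replace=False),
                rng.choice(neg, size=min(n_neg, neg.size), replace=False),
            ]
        )
        take.sort()
        X_cv, y_cv = X[take], y[take]

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=int(seed) & 0x7FFFFFFF)
    splits = list(skf.split(X_cv, y_cv))
    cv_table = {}
    best = None
    for gamma in sorted(gamma_grid):
        for C in sorted(c_grid):
            correct = 0
            for tr, te in splits:
                svc = SVC(C=C, gamma=gamma, kernel="rbf", class_weight="balanced", cache_size=200)
                svc.fit(X_cv[tr], y_cv[tr])
                correct += int((svc.predict(X_cv[te]) == y_cv[te]).sum())
            acc = correct / y_cv.size
            cv_table[(C, gamma)] = acc
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)

    _, C_sel, gamma_sel = best
    svc = SVC(C=C_sel, gamma=gamma_sel, kernel="rbf", class_weight="balanced", cache_size=500)
    svc.fit(X, y)
    return SvmModel(
        svc=svc,
        C=C_sel,
        gamma=gamma_sel,
        cv_table=cv_table,
        channel_names=training.channel_names,
        channel_scalers={},
        n_support=tuple(int(v) for v in svc.n_support_),
    )


def predict_voxels(stack: FeatureStack, model: SvmModel, chunk: int = 65536) -> MaskVolume:
    """Classify every VOI voxel; voxels outside the VOI are negative.

    When the model carries scalers from its training stack, the channels are
    re-standardized with those scalers so a pre-trained model transfers to an
    independently acquired scan.
    """
    if model.channel_names != stack.names:
        raise ValidationError(
            f"channel mismatch: model {model.channel_names} vs stack {stack.names}"
        )
    voi_idx = np.flatnonzero(stack.voi.data.ravel())
    out = np.zeros(stack.voi.data.size, dtype=bool)
    scalers = model.channel_scalers or None
    for start in range(0, voi_idx.size, chunk):
        idx = voi_idx[start : start + chunk]
        X = stack.raw_matrix(idx, scalers)
        out[idx] = model.svc.predict(X).astype(bool)
    return stack.voi.like(out.reshape(stack.voi.data.shape))


def build_localization_result(
    positives: MaskVolume, concentration: ScalarVolume
) -> LocalizationResult:
    """Concentration map masked to positive voxels (exactly 0 elsewhere)."""
    if positives.shape != concentration.shape:
        raise ValidationError("positives and concentration must share one grid")
    masked = np.where(positives.data, concentration.data, 0.0)
    return LocalizationResult(positives=positives, concentration=concentration.like(masked))
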