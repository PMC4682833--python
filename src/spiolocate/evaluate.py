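"""Scoring of localization results against phantom ground truth.

Per-inlay sensitivity and specificity are computed inside an evaluation
region consisting of the inlay plus a surrounding shell of background
(default 3 voxels, 26-connectivity); detected-to-real volume ratios
attribute predicted voxels to their nearest inlay within a configurable
distance; the halo analysis quantifies how much of the false-positive set
hugs the true positive regions rather than scattering through the volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import MaskVolume, ScalarVolume, ValidationError
from .classify import LocalizationResult
from .phantom import PhantomTruth

__all__ = [
    "ConfusionCounts",
    "InlayReport",
    "EvaluationReport",
    "confusion_counts",
    "sensitivity_specificity",
    "volume_ratio",
    "attribute_positives",
    "concentration_report",
    "halo_fraction",
    "evaluate_result",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ConfusionCounts:
    true_positives: int
    false_positives: int
    true_negatives: int
    false_negatives: int
    region_id: int = 0

    @property
    def total(self) -> int:
        return (
            self.true_positives
            + self.false_positives
            + self.true_negatives
            + self.false_negatives
        )


@dataclass
class InlayReport:
    region_id: int
    concentration_true: float  # uM
    sensitivity: float
    specificity: float
    volume_ratio: float
    concentration_mean: Optional[float]  # uM over attributed positives; None if missing
    concentration_std: Optional[float]


@dataclass
class EvaluationReport:
    inlays: list  # InlayReport, ordered by region id
    mean_sensitivity: float
    mean_specificity: float
    mean_volume_ratio: float
    halo_fraction: float
    global_specificity: float  # over the whole VOI

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region": r.region_id,
                    "c_real_uM": r.concentration_true,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "vol_detected/vol_real": r.volume_ratio,
                    "c_detected_uM": r.concentration_mean,
                    "c_detected_std_uM": r.concentration_std,
                }
                for r in self.inlays
            ]
        )


def confusion_counts(
    predicted: MaskVolume, truth: MaskVolume, evaluation_region: MaskVolume
) -> ConfusionCounts:
    """Standard 2x2 voxel counts restricted to the evaluation region."""
    if predicted.shape != truth.shape or predicted.shape != evaluation_region.shape:
        raise ValidationError("masks must share one grid")
    region = evaluation_region.data
    if not region.any():
        raise ValidationError("empty evaluation region")
    p = predicted.data[region]
    t = truth.data[region]
    return ConfusionCounts(
        true_positives=int(np.sum(p & t)),
        false_positives=int(np.sum(p & ~t)),
        true_negatives=int(np.sum(~p & ~t)),
        false_negatives=int(np.sum(~p & t)),
    )


def sensitivity_specificity(counts: ConfusionCounts) -> tuple:
    """(sensitivity, specificity) = (TP/real positives, TN/real negatives).

    A side with a zero denominator is reported as ``nan``; both zero is an
    error.
    """
    pos = counts.true_positives + counts.false_negatives
    neg = counts.true_negatives + counts.false_positives
    if pos == 0 and neg == 0:
        raise ValidationError("evaluation region holds no positives and no negatives")
    sens = counts.true_positives / pos if pos > 0 else float("nan")
    spec = counts.true_negatives / neg if neg > 0 else float("nan")
    return sens, spec


def attribute_positives(
    predicted: MaskVolume, inlay_labels: np.ndarray, max_distance: float = 3.0
) -> np.ndarray:
    """Attribute each predicted-positive voxel to the nearest inlay.

    Returns an integer volume: the inlay id for positives within
    ``max_distance`` voxels of that inlay, 0 elsewhere.
    """
    if not (inlay_labels > 0).any():
        raise ValidationError("no inlay regions in the truth labels")
    dist, idx = ndimage.distance_transform_edt(inlay_labels == 0, return_indices=True)
    nearest = inlay_labels[tuple(idx)]
    attributed = np.where(predicted.data & (dist <= max_distance), nearest, 0)
    return attributed


def volume_ratio(
    predicted: MaskVolume, truth_region: MaskVolume, max_distance: float = 3.0
) -> float:
    """Detected-to-real volume ratio for one inlay region.

    Counts predicted positives within ``max_distance`` voxels of the region
    (halo voxels are attributed to the inlay that caused them) over the true
    region voxel count.
    """
    region = truth_region.data
    if not region.any():
        raise ValidationError("empty truth region")
    dist = ndimage.distance_transform_edt(~region)
    detected = int(np.sum(predicted.data & (dist <= max_distance)))
    return detected / int(region.sum())


def concentration_report(
    result: LocalizationResult, truth: PhantomTruth, max_distance: float = 3.0
) -> dict:
    """Per-inlay (mean, std) of the detected concentration in uM.

    Statistics run over predicted-positive voxels attributed to each inlay;
    an inlay with no attributed positives is reported as missing (None).
    """
    if result.positives.shape != truth.concentration.shape:
        raise ValidationError("result and truth must share one grid")
    attributed = attribute_positives(result.positives, truth.inlay_labels, max_distance)
    out = {}
    for lab in range(1, truth.inlay_labels.max() + 1):
        sel = attributed == lab
        if not sel.any():
            out[lab] = None
            continue
        vals = result.concentration.data[sel]
        out[lab] = (float(vals.mean()), float(vals.std()))
    return out


def halo_fraction(
    predicted: MaskVolume, truth: MaskVolume, shell_width: int = 2
) -> tuple:
    """Fraction of false positives lying within ``shell_width`` voxels
    (26-connectivity) of the true positive set.

    Returns ``(fraction, defined)``; with no false positives at all the
    fraction is 1.0 and ``defined`` is False.
    """
    if shell_width < 1:
        raise ValidationError("shell_width must be >= 1")
    fp = predicted.data & ~truth.data
    n_fp = int(fp.sum())
    if n_fp == 0:
        return 1.0, False
    halo = ndimage.binary_dilation(truth.data, structure=_STRUCT26, iterations=shell_width)
    in_halo = int(np.sum(fp & halo))
    return in_halo / n_fp, True


def _inlay_regions(truth: PhantomTruth, shell_width: int, voi: MaskVolume | None):
    """Evaluation region per inlay: the inlay plus a background shell."""
    labels = truth.inlay_labels
    any_inlay = labels > 0
    for lab in range(1, labels.max() + 1):
        core = labels == lab
        shell = ndimage.binary_dilation(core, structure=_STRUCT26, iterations=shell_width)
        shell = shell & ~any_inlay
        if voi is not None:
            shell = shell & voi.data
        yield lab, core, core | shell


def evaluate_result(
    result: LocalizationResult,
    truth: PhantomTruth,
    voi: MaskVolume | None = None,
    shell_width: int = 3,
    attribution_distance: float = 3.0,
) -> EvaluationReport:
    """Full per-inlay and global scoring of a localization result."""
    conc_stats = concentration_report(result, truth, attribution_distance)
    rows = []
    for lab, core, region in _inlay_regions(truth, shell_width, voi):
        counts = confusion_counts(
            result.positives,
            truth.positive_mask,
            MaskVolume(region, result.positives.voxel_size),
        )
        counts.region_id = lab
        sens, spec = sensitivity_specificity(counts)
        vr = volume_ratio(
            result.positives,
            MaskVolume(core, result.positives.voxel_size),
            attribution_distance,
        )
        stats = conc_stats.get(lab)
        rows.append(
            InlayReport(
                region_id=lab,
                concentration_true=float(np.median(truth.concentration.data[core])),
                sensitivity=sens,
                specificity=spec,
                volume_ratio=vr,
                concentration_mean=None if stats is None else stats[0],
                concentration_std=None if stats is None else stats[1],
            )
        )
    hf, _ = halo_fraction(result.positives, truth.positive_mask, 2)
    if voi is not None:
        global_counts = confusion_counts(result.positives, truth.positive_mask, voi)
        _, global_spec = sensitivity_specificity(global_counts)
    else:
        global_spec = float("nan")
    return EvaluationReport(
        inlays=rows,
        mean_sensitivity=float(np.mean([r.sensitivity for r in rows])),
        mean_specificity=float(np.mean([r.specificity for r in rows])),
        mean_volume_ratio=float(np.mean([r.volume_ratio for r in rows])),
        halo_fraction=hf,
        global_specificity=global_spec,
    )
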