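"""Run configuration shared by all pipeline stages.

The configuration is a YAML file whose keys mirror the nested models below.
Every field has a documented default, so an empty file is a valid run
configuration; unknown keys are rejected with a list of valid keys.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError as PydanticValidationError, field_validator

from .core import ValidationError

__all__ = ["RunConfig", "load_run_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ProtocolConfig(_Section):
    """Acquisition protocol of the multi-echo FLASH sequence."""

    echo_times: List[float] = [2.54, 3.78, 11.34]  # ms
    repetition_time: float = 200.0  # ms
    flip_angle: float = 25.0  # degrees
    field_strength: float = 4.7  # tesla
    voxel_size: List[float] = [0.4, 0.4, 0.4]  # mm
    matrix_size: List[int] = [48, 128, 28]
    b0_direction: List[float] = [0.0, 0.0, 1.0]

    @field_validator("echo_times")
    @classmethod
    def _tes_positive_increasing(cls, v):
        if any(t <= 0 for t in v):
            raise ValueError("echo_times must be positive")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("echo_times must be strictly increasing")
        return v


class PhantomConfig(_Section):
    """Geometry and tissue parameters of the simulated agarose block phantom."""

    kind: str = "agarose-block"  # agarose-block | invivo-like
    cell_densities: List[float] = [480.0, 240.0, 120.0, 60.0, 30.0]  # cells/mm^3
    inlay_radius: float = 3.6  # mm
    inlay_height: float = 5.6  # mm
    block_margin: float = 1.6  # mm of agarose kept clear of the FOV edge
    background_r2star: float = 25.0  # 1/s, 2% agarose
    background_proton_density: float = 100.0  # a.u.
    r2star_relaxivity: float = 1.0  # 1/s per uM Fe2O3
    susceptibility_per_concentration: float = 3.0e-3  # ppm per uM
    per_cell_iron_load: float = 90.0  # pg per cell
    noise_sigma: float = 0.05  # complex noise, fraction of background magnitude at TE1
    misalign_translation: List[float] = [0.32, -0.2, 0.12]  # mm applied to baseline
    misalign_rotation: List[float] = [0.0, 0.0, 0.4]  # degrees


class FeatureConfig(_Section):
    """Feature-extraction knobs (noise floor, band-pass, reliability)."""

    noise_floor_factor: float = 2.0  # x median air magnitude
    voi_membership_threshold: float = 0.5
    band_low_period: float = 10.0  # voxels; longest period passed
    band_high_period: float = 2.0  # voxels; shortest period passed
    s_echo_index: int = 1  # 0-based echo used for the s-map (second TE)
    unreliable_residual_tol: float = 0.15  # rad RMS
    unreliable_intercept_tol: float = 0.3  # rad
    source_threshold: float = 0.15  # rad on |s| for source localization

    @field_validator("band_high_period")
    @classmethod
    def _band_ok(cls, v):
        if v < 2.0:
            raise ValueError("band_high_period must be >= 2 voxels (Nyquist)")
        return v


class RegistrationConfig(_Section):
    enabled: bool = True
    nonrigid: bool = False
    bins: int = 32
    levels: List[int] = [4, 2, 1]  # down-sampling factors, coarse to fine


class SvmConfig(_Section):
    training_fraction: float = 0.15
    stratified: bool = False
    c_grid: List[float] = [2.0**k for k in range(-3, 10, 2)]
    gamma_grid: List[float] = [2.0**k for k in range(-9, 4, 2)]
    cv_folds: int = 5
    cv_max_samples: int = 2500  # CV-search subsample cap; final fit uses all


class EvaluationConfig(_Section):
    shell_width: int = 3  # voxels of background around each inlay
    attribution_distance: float = 3.0  # voxels, FP attribution for volume ratios


class RunConfig(_Section):
    """Top-level pipeline configuration with all defaults materialized."""

    seed: int = 0
    protocol: ProtocolConfig = ProtocolConfig()
    phantom: PhantomConfig = PhantomConfig()
    features: FeatureConfig = FeatureConfig()
    registration: RegistrationConfig = RegistrationConfig()
    svm: SvmConfig = SvmConfig()
    evaluation: EvaluationConfig = EvaluationConfig()


def load_run_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration, filling in all documented defaults.

    ``path`` may be None (all defaults).  Unknown keys raise a validation
    error naming the valid keys of the offending section.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: run config must be a mapping")
    if overrides:
        for key, val in overrides.items():
            node = data
            parts = key.split(".")
            for part in parts[:-1]:
                node = node.setdefault(part, {})
            node[parts[-1]] = val
    try:
        return RunConfig(**data)
    except PydanticValidationError as err:
        msgs = []
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"])
            if e["type"] == "extra_forbidden":
                section = e["loc"][:-1]
                model: type[_Section] = RunConfig
                for part in section:
                    model = model.model_fields[part].annotation
                valid = ", ".join(model.model_fields)
                msgs.append(f"unknown key '{loc}'; valid keys: {valid}")
            else:
                msgs.append(f"{loc}: {e['msg']}")
        raise ValidationError("; ".join(msgs)) from err
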