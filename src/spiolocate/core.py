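"""Core in-memory containers for multi-echo gradient-echo MRI data.

Conventions used throughout the package:

* voxel indices are 0-based and axis order is (x, y, z);
* world coordinates are in millimetres, voxel-centred: the centre of voxel
  ``(i, j, k)`` sits at ``origin + (i, j, k) * voxel_size``;
* the static field B0 points along ``AcquisitionProtocol.b0_direction``
  (+z by default);
* wrapped phase lives in ``[-pi, pi)`` radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "ScalarVolume",
    "MaskVolume",
    "DatasetRole",
    "MultiEchoDataset",
    "ValidationError",
    "wrap_to_pi",
]


class ValidationError(ValueError):
    """An input violated a documented contract."""


def wrap_to_pi(phase: np.ndarray) -> np.ndarray:
    """Wrap angles (radians) into ``[-pi, pi)``."""
    return np.mod(np.asarray(phase) + np.pi, 2.0 * np.pi) - np.pi


def _as_vec3(value: Sequence[float], name: str, dtype=float) -> tuple:
    arr = tuple(dtype(v) for v in value)
    if len(arr) != 3:
        raise ValidationError(f"{name} must have 3 components, got {len(arr)}")
    return arr


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Acquisition parameters of a multi-echo 3D FLASH (spoiled GRE) scan.

    Parameters
    ----------
    echo_times : sequence of float
        Echo times in milliseconds, strictly increasing, at least two.
    repetition_time : float
        TR in milliseconds.
    flip_angle : float
        Excitation flip angle in degrees.
    field_strength : float
        B0 in tesla.
    voxel_size : 3-sequence of float
        Voxel edge lengths in millimetres.
    matrix_size : 3-sequence of int
        Grid dimensions in voxels, axis order (x, y, z).
    b0_direction : 3-sequence of float
        Unit vector of the main field direction; normalised on construction.
    """

    echo_times: tuple
    repetition_time: float
    flip_angle: float
    field_strength: float
    voxel_size: tuple
    matrix_size: tuple
    b0_direction: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        tes = tuple(float(t) for t in self.echo_times)
        if len(tes) < 2:
            raise ValidationError("at least 2 echo times are required")
        if any(t <= 0 for t in tes):
            raise ValidationError("echo times must be positive")
        if any(b <= a for a, b in zip(tes, tes[1:])):
            raise ValidationError("echo times must be strictly increasing")
        object.__setattr__(self, "echo_times", tes)
        vs = _as_vec3(self.voxel_size, "voxel_size")
        if any(v <= 0 for v in vs):
            raise ValidationError("voxel_size components must be positive")
        object.__setattr__(self, "voxel_size", vs)
        ms = _as_vec3(self.matrix_size, "matrix_size", dtype=int)
        if any(m <= 0 for m in ms):
            raise ValidationError("matrix_size components must be positive")
        object.__setattr__(self, "matrix_size", ms)
        b0 = np.asarray(self.b0_direction, dtype=float)
        norm = float(np.linalg.norm(b0))
        if norm == 0:
            raise ValidationError("b0_direction must be a nonzero vector")
        object.__setattr__(self, "b0_direction", tuple(b0 / norm))
        if self.repetition_time <= 0:
            raise ValidationError("repetition_time must be positive")
        if self.field_strength <= 0:
            raise ValidationError("field_strength must be positive")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def echo_times_s(self) -> np.ndarray:
        """Echo times in seconds."""
        return np.asarray(self.echo_times) * 1e-3

    @property
    def fov(self) -> tuple:
        """Field of view in millimetres."""
        return tuple(m * v for m, v in zip(self.matrix_size, self.voxel_size))


@dataclass
class ScalarVolume:
    """A real-valued 3D volume on a regular grid.

    ``data`` has axis order (x, y, z); ``voxel_size`` and ``origin`` are in mm.
    """

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.voxel_size = _as_vec3(self.voxel_size, "voxel_size")
        self.origin = _as_vec3(self.origin, "origin")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def same_grid(self, other: "ScalarVolume | MaskVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )

    def like(self, data: np.ndarray) -> "ScalarVolume":
        """New volume with the same grid metadata."""
        return ScalarVolume(np.asarray(data), self.voxel_size, self.origin)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to mm coordinates (voxel centres)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return np.asarray(self.origin) + ijk * np.asarray(self.voxel_size)


@dataclass
class MaskVolume:
    """A boolean 3D volume sharing the :class:`ScalarVolume` grid contract."""

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValidationError(f"mask data must be 3D, got ndim={self.data.ndim}")
        self.voxel_size = _as_vec3(self.voxel_size, "voxel_size")
        self.origin = _as_vec3(self.origin, "origin")

    shape = ScalarVolume.shape
    same_grid = ScalarVolume.same_grid
    voxel_to_world = ScalarVolume.voxel_to_world

    def like(self, data: np.ndarray) -> "MaskVolume":
        return MaskVolume(np.asarray(data), self.voxel_size, self.origin)

    def count(self) -> int:
        return int(self.data.sum())


class DatasetRole(str, Enum):
    BASELINE = "baseline"
    CONTRAST = "contrast"


@dataclass
class MultiEchoDataset:
    """Paired magnitude / wrapped-phase volumes, one pair per echo time.

    Invariants (checked on construction): magnitudes are non-negative, phase
    values lie in ``[-pi, pi)``, and all per-echo volumes share one grid whose
    shape matches ``protocol.matrix_size``.
    """

    protocol: AcquisitionProtocol
    magnitude: list
    phase_wrapped: list
    role: DatasetRole = DatasetRole.CONTRAST

    def __post_init__(self):
        self.role = DatasetRole(self.role)
        n = self.protocol.n_echoes
        if len(self.magnitude) != n or len(self.phase_wrapped) != n:
            raise ValidationError(
                f"expected {n} magnitude and phase volumes, got "
                f"{len(self.magnitude)} / {len(self.phase_wrapped)}"
            )
        ref = self.magnitude[0]
        if ref.shape != tuple(self.protocol.matrix_size):
            raise ValidationError(
                f"volume shape {ref.shape} does not match protocol matrix_size "
                f"{tuple(self.protocol.matrix_size)}"
            )
        for vol in list(self.magnitude) + list(self.phase_wrapped):
            if not ref.same_grid(vol):
                raise ValidationError("per-echo volumes must share one grid")
        for vol in self.magnitude:
            if np.any(vol.data < 0):
                raise ValidationError("magnitude values must be >= 0")
        for vol in self.phase_wrapped:
            if np.any(vol.data < -np.pi) or np.any(vol.data >= np.pi):
                raise ValidationError("phase values must lie in [-pi, pi)")

    @property
    def shape(self) -> tuple:
        return self.magnitude[0].shape

    def complex_echo(self, e: int) -> np.ndarray:
        """Complex image of echo ``e`` reconstructed from magnitude and phase."""
        return self.magnitude[e].data * np.exp(1j * self.phase_wrapped[e].data)

    def with_role(self, role: DatasetRole) -> "MultiEchoDataset":
        return MultiEchoDataset(self.protocol, self.magnitude, self.phase_wrapped, role)
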