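"""Reading and writing multi-echo datasets.

A dataset on disk is a directory of per-echo NIfTI-1 volume pairs plus one
YAML manifest naming the files and the acquisition parameters.  ANALYZE 7.5
pairs (.hdr/.img) are accepted on read.  Phase may be stored either as
floating-point radians or integer-scaled (vendor style); integer-scaled phase
is rescaled into [-pi, pi) on read.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import (
    AcquisitionProtocol,
    DatasetRole,
    MultiEchoDataset,
    ScalarVolume,
    ValidationError,
)

__all__ = ["read_dataset", "write_dataset", "read_volume", "write_volume"]

MANIFEST_NAME = "manifest.yaml"


def _affine(voxel_size, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size)
    aff[:3, 3] = origin
    return aff


def write_volume(vol, path: str | Path) -> None:
    """Write a scalar or mask volume as NIfTI-1."""
    data = np.asarray(vol.data, dtype=np.float32)
    img = nib.Nifti1Image(data, _affine(vol.voxel_size, vol.origin))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a NIfTI-1 or ANALYZE volume into a :class:`ScalarVolume`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got shape {data.shape}")
    aff = img.affine
    if aff is None:
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = (0.0, 0.0, 0.0)
    else:
        voxel_size = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
        origin = tuple(float(v) for v in aff[:3, 3])
    return ScalarVolume(data, voxel_size, origin)


def _rescale_phase(data: np.ndarray, path) -> np.ndarray:
    """Bring stored phase into [-pi, pi) regardless of integer scaling.

    Float data already within range is passed through.  Integer-scaled phase
    is mapped affinely assuming a power-of-two full-scale range, e.g. signed
    12-bit data spanning [-2048, 2047] maps -2048 -> -pi and 2047 -> pi*2047/2048.
    """
    lo, hi = float(np.min(data)), float(np.max(data))
    if lo >= -np.pi and hi < np.pi:
        return data
    if hi <= np.pi and lo >= -np.pi - 1e-9:  # boundary value -pi inclusive wiggle
        return np.clip(data, -np.pi, np.nextafter(np.pi, 0))
    if lo < 0:
        # signed integer scaling: full scale is the next power of two
        full = 2.0 ** np.ceil(np.log2(max(abs(lo), hi + 1.0)))
        out = data / full * np.pi
    elif hi > np.pi:
        # unsigned scaling [0, 2^b) -> [-pi, pi)
        full = 2.0 ** np.ceil(np.log2(hi + 1.0))
        out = data / full * 2.0 * np.pi - np.pi
    else:
        raise ValidationError(f"{path}: phase value range [{lo}, {hi}] not inferable")
    if np.min(out) < -np.pi or np.max(out) >= np.pi:
        raise ValidationError(f"{path}: phase value range [{lo}, {hi}] not inferable")
    return out


def write_dataset(dataset: MultiEchoDataset, directory: str | Path) -> Path:
    """Write a dataset directory (per-echo NIfTI pairs + YAML manifest).

    Returns the manifest path.  ``read_dataset`` on the result reproduces the
    dataset to storage (float32) precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p = dataset.protocol
    echoes = []
    for e, te in enumerate(p.echo_times):
        mag_name = f"magnitude_echo{e + 1}.nii.gz"
        phs_name = f"phase_echo{e + 1}.nii.gz"
        write_volume(dataset.magnitude[e], directory / mag_name)
        write_volume(dataset.phase_wrapped[e], directory / phs_name)
        echoes.append({"echo_time": float(te), "magnitude": mag_name, "phase": phs_name})
    manifest = {
        "role": dataset.role.value,
        "repetition_time": float(p.repetition_time),
        "flip_angle": float(p.flip_angle),
        "field_strength": float(p.field_strength),
        "voxel_size": [float(v) for v in p.voxel_size],
        "matrix_size": [int(v) for v in p.matrix_size],
        "b0_direction": [float(v) for v in p.b0_direction],
        "echoes": echoes,
    }
    manifest_path = directory / MANIFEST_NAME
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_dataset(directory: str | Path, manifest_path: str | Path | None = None) -> MultiEchoDataset:
    """Read a dataset directory written by :func:`write_dataset` (or compatible).

    Echoes are reordered by ascending echo time; phase is rescaled into
    [-pi, pi) whatever the on-disk integer scaling.
    """
    directory = Path(directory)
    manifest_path = Path(manifest_path) if manifest_path else directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    echoes = manifest.get("echoes")
    if not echoes:
        raise ValidationError(f"{manifest_path}: manifest lists no echoes")
    echoes = sorted(echoes, key=lambda e: float(e["echo_time"]))

    mags, phases = [], []
    shape = None
    for entry in echoes:
        te = float(entry["echo_time"])
        for key, dest in (("magnitude", mags), ("phase", phases)):
            path = directory / entry[key]
            if not path.exists():
                # accept ANALYZE pair naming if manifest points at .img/.hdr
                raise FileNotFoundError(f"{key} file for echo TE={te} ms missing: {path}")
            vol = read_volume(path)
            if shape is None:
                shape = vol.shape
            elif vol.shape != shape:
                raise ValidationError(
                    f"{path}: dimensions {vol.shape} do not match first echo {shape}"
                )
            if key == "phase":
                vol = vol.like(_rescale_phase(vol.data, path))
            dest.append(vol)

    protocol = AcquisitionProtocol(
        echo_times=[float(e["echo_time"]) for e in echoes],
        repetition_time=float(manifest["repetition_time"]),
        flip_angle=float(manifest["flip_angle"]),
        field_strength=float(manifest.get("field_strength", 4.7)),
        voxel_size=manifest.get("voxel_size", list(mags[0].voxel_size)),
        matrix_size=manifest.get("matrix_size", list(shape)),
        b0_direction=manifest.get("b0_direction", [0.0, 0.0, 1.0]),
    )
    role = DatasetRole(manifest.get("role", "contrast"))
    return MultiEchoDataset(protocol, mags, phases, role)
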