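"""Shared fixtures: small protocols, noiseless phantoms, and one cached
transfer experiment reused by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from spiolocate.config import RunConfig
from spiolocate.core import AcquisitionProtocol
from spiolocate.pipeline import run_full_pipeline, run_transfer_experiment, simulate_phantom


def small_run_config(seed: int = 0, **kwargs) -> RunConfig:
    """A reduced phantom (3 inlays, coarse grid, 1-point SVM grid) for tests
    that exercise the pipeline mechanics rather than its statistics."""
    cfg = RunConfig(seed=seed)
    cfg.protocol.matrix_size = [32, 80, 16]
    cfg.phantom.cell_densities = [480.0, 120.0, 30.0]
    cfg.phantom.inlay_radius = 2.4
    cfg.phantom.inlay_height = 3.2
    cfg.svm.c_grid = [2.0]
    cfg.svm.gamma_grid = [0.125]
    for key, val in kwargs.items():
        section, name = key.split("__")
        setattr(getattr(cfg, section), name, val)
    return cfg


@pytest.fixture(scope="session")
def tiny_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol(
        echo_times=[2.54, 3.78, 11.34],
        repetition_time=200.0,
        flip_angle=25.0,
        field_strength=4.7,
        voxel_size=[0.4, 0.4, 0.4],
        matrix_size=[24, 24, 16],
    )


@pytest.fixture(scope="session")
def noiseless_run_cfg() -> RunConfig:
    cfg = RunConfig(seed=3)
    cfg.phantom.noise_sigma = 0.0
    return cfg


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_run_cfg):
    """(spec, truth, baseline, contrast) of the default block phantom, no noise."""
    return simulate_phantom(noiseless_run_cfg)


@pytest.fixture(scope="session")
def transfer_runs():
    """One full transfer experiment (train on A, evaluate on B) at the default
    study conditions; shared by the acceptance and end-to-end tests."""
    return run_transfer_experiment(RunConfig(seed=7), RunConfig(seed=8))


@pytest.fixture(scope="session")
def small_pipeline_run():
    """One full pipeline execution on the reduced phantom."""
    return run_full_pipeline(small_run_config(seed=11))
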