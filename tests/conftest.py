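"""Shared fixtures.

The heavy objects (designed trajectory with density weights, rasterised
phantoms) are session-scoped: trajectory design and the density-compensation
fixed point are deterministic, so sharing them across tests changes nothing
but wall time.  The "ci" protocol used throughout is the reduced-sampling
profile: 546 readouts at 55.3 kHz (553 samples each) on the same 4 mm / 60^3
geometry as the full printed protocol.
"""

from __future__ import annotations

import numpy as np
import pytest

from natsc import (AcquisitionProtocol, CohortSpec, HeadGeometry, SiteSpec,
                   StudyConfig, apply_delay_correction, build_head_phantom,
                   compute_density_weights, design_cones, grid_reconstruct,
                   simulate_kspace)
from natsc.pipeline import PROFILES


@pytest.fixture(scope="session")
def ci_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol(**PROFILES["ci"])


@pytest.fixture(scope="session")
def tiny_protocol() -> AcquisitionProtocol:
    """A deliberately coarse protocol small enough for Voronoi weights."""
    return AcquisitionProtocol(voxel_mm=12.0, n_readouts=60, readout_ms=2.0,
                               bw_full_khz=25.0, tr_ms=20.0)


@pytest.fixture(scope="session")
def ci_raw_traj(ci_protocol):
    return design_cones(ci_protocol)


@pytest.fixture(scope="session")
def ci_recon_traj(ci_protocol, ci_raw_traj):
    traj = apply_delay_correction(ci_raw_traj, ci_protocol.delay_us)
    return compute_density_weights(traj, "iterative")


@pytest.fixture(scope="session")
def head_phantom(ci_protocol):
    """Default (small-ventricle) head phantom on the 60^3 grid."""
    return build_head_phantom(voxel_mm=ci_protocol.voxel_mm,
                              grid_size=ci_protocol.grid_size)


@pytest.fixture(scope="session")
def verification_phantom(ci_protocol):
    """Large-central-ventricle phantom for exact-recovery checks."""
    return build_head_phantom(geometry=HeadGeometry.verification(),
                              voxel_mm=ci_protocol.voxel_mm,
                              grid_size=ci_protocol.grid_size)


@pytest.fixture(scope="session")
def noiseless_image(head_phantom, ci_recon_traj, ci_protocol):
    kdata = simulate_kspace(head_phantom, ci_recon_traj, ci_protocol,
                            noise_sd=0.0, relaxation=True)
    return grid_reconstruct(kdata, ci_recon_traj)


@pytest.fixture()
def tiny_cohort_config() -> StudyConfig:
    cfg = StudyConfig.from_profile("ci", seed=11)
    cfg.cohort = CohortSpec(
        n_subjects=2, seed=11,
        sites=[SiteSpec("A", 3.5e-3, 1.0, 5.0), SiteSpec("B", 7e-3, 1.05, 5.0)],
        scans_per_site={"A": [2, 2], "B": [2, 1]})
    return cfg
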