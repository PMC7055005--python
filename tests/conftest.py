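"""Shared fixtures and helpers for the ricstools test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ricstools.geometry import ScanConfig, SpeciesSpec
from ricstools.synthetic import default_box, simulate_raster_series


def n_particles_for(scan: ScanConfig, n_effective: float = 2.0) -> int:
    """Particle count giving ~n_effective molecules in the focal volume.

    The effective volume is pi^1.5 * w0^2 * wz; ~2 effective molecules
    matches a 10 nM dye at a typical one-photon confocal volume.
    """
    box = default_box(scan)
    v_eff = np.pi ** 1.5 * scan.w0 ** 2 * scan.wz
    return int(round(n_effective / v_eff * box.volume))


def simulate_single_species(D: float, scan: ScanConfig, seed: int,
                            brightness: float = 2.0,
                            n_effective: float = 2.0):
    """One diffusing species rendered through the streaming scan engine."""
    sp = SpeciesSpec(D=D, brightness=brightness,
                     n_particles=n_particles_for(scan, n_effective))
    return simulate_raster_series(sp, scan, seed=seed)[1]


@pytest.fixture(scope="session")
def tiny_scan() -> ScanConfig:
    """Small, fast scan geometry with the standard pixel clock."""
    return ScanConfig(frame_shape=(32, 32), n_frames=10)


@pytest.fixture(scope="session")
def test_scan() -> ScanConfig:
    """Mid-size geometry used for recovery checks in the suite."""
    return ScanConfig(frame_shape=(80, 80), n_frames=50)
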