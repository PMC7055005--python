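"""Shared domain containers: scan geometry, species, image series, traces, voxel grids.

All lengths are in micrometres (µm) and all times in seconds unless a field
name says otherwise.  Arrays follow the (frame|z, y, x) axis convention with
0-based indices; a continuous position ``p`` (in voxel or pixel units) lies in
voxel ``floor(p)``, i.e. voxel ``i`` spans ``[i, i+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ScanConfig",
    "SpeciesSpec",
    "ImageSeries",
    "PhotonTrace",
    "VoxelGrid",
]

#: Gaussian-beam shape factor gamma = 2**(-3/2) relating G(0,0) to 1/N.
GAMMA_3D = 2.0 ** (-1.5)


@dataclass(frozen=True)
class ScanConfig:
    """Raster-scan geometry and optics shared by the simulator and the fitters.

    Parameters
    ----------
    pixel_size:
        Pixel spacing delta_r along both scan axes, µm.
    dwell_time:
        Pixel dwell time tau_p, s.
    line_time:
        Line repetition time tau_l (includes retrace), s.
    frame_shape:
        (rows, cols) of one frame.
    n_frames:
        Number of frames in a series.
    w0:
        Lateral 1/e² beam-waist radius, µm.
    AR:
        Axial ratio wz / w0 (dimensionless).
    frame_time:
        Frame repetition time, s.  Defaults to ``rows * line_time``.
    """

    pixel_size: float = 0.02
    dwell_time: float = 8.19e-6
    line_time: float = 4.92e-3
    frame_shape: tuple[int, int] = (256, 256)
    n_frames: int = 50
    w0: float = 0.25
    AR: float = 5.0
    frame_time: Optional[float] = None

    def __post_init__(self) -> None:
        rows, cols = self.frame_shape
        if rows < 1 or cols < 1 or self.n_frames < 1:
            raise ValueError("frame_shape and n_frames must be positive")
        for name in ("pixel_size", "dwell_time", "line_time", "w0", "AR"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.line_time < cols * self.dwell_time:
            raise ValueError(
                f"line_time ({self.line_time}) shorter than cols*dwell_time "
                f"({cols * self.dwell_time})"
            )
        if self.frame_time is None:
            object.__setattr__(self, "frame_time", rows * self.line_time)
        elif self.frame_time < rows * self.line_time - 1e-12:
            raise ValueError("frame_time shorter than rows * line_time")

    @property
    def rows(self) -> int:
        return self.frame_shape[0]

    @property
    def cols(self) -> int:
        return self.frame_shape[1]

    @property
    def wz(self) -> float:
        """Axial 1/e² radius, µm (== AR * w0)."""
        return self.AR * self.w0

    @property
    def field_size(self) -> tuple[float, float]:
        """(Ly, Lx) extent of the scanned field, µm."""
        return (self.rows * self.pixel_size, self.cols * self.pixel_size)

    def pixel_times(self) -> np.ndarray:
        """Acquisition clock t(f, r, c), shape [n_frames, rows, cols], s."""
        f = np.arange(self.n_frames)[:, None, None] * self.frame_time
        r = np.arange(self.rows)[None, :, None] * self.line_time
        c = np.arange(self.cols)[None, None, :] * self.dwell_time
        return f + r + c


@dataclass
class SpeciesSpec:
    """A population of identical point emitters.

    ``brightness`` is the mean detected photon count per particle per dwell
    time with the particle at the beam centre.  ``label`` assigns the species
    to detection channel 1, channel 2, or ``"both"`` (a dual-labelled complex;
    ``brightness2`` then sets the channel-2 counts, defaulting to
    ``brightness``).  ``bound_fraction`` marks the proportion of particles
    rigidly co-moving with a partner species (the species listed immediately
    before this one); ``k_on``/``k_off`` switch that binding kinetically with
    exponential waiting times.
    """

    D: float
    brightness: float
    n_particles: int
    label: int | str = 1
    bound_fraction: float = 0.0
    brightness2: Optional[float] = None
    k_on: Optional[float] = None
    k_off: Optional[float] = None

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must lie in [0, 1]")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        for k in (self.k_on, self.k_off):
            if k is not None and k < 0:
                raise ValueError("kinetic rates must be >= 0")
        if self.label not in (1, 2, "both"):
            raise ValueError("label must be 1, 2 or 'both'")

    @property
    def kinetic(self) -> bool:
        return self.k_on is not None and self.k_off is not None


@dataclass
class ImageSeries:
    """Photon-count raster series: integer array [n_frames, rows, cols]."""

    counts: np.ndarray
    channel: int | str
    scan: ScanConfig
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (self.scan.n_frames, self.scan.rows, self.scan.cols)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match scan {expected}"
            )
        if np.issubdtype(self.counts.dtype, np.integer) and self.counts.min() < 0:
            raise ValueError("photon counts must be non-negative")


@dataclass
class PhotonTrace:
    """Binned photon-count time trace for FCS."""

    counts: np.ndarray
    bin_width: float = 1e-3
    duration: float = 10.0
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = int(round(self.duration / self.bin_width))
        if self.counts.ndim != 1 or len(self.counts) != n:
            raise ValueError(
                f"trace length {len(self.counts)} != duration/bin_width ({n})"
            )
        if self.counts.min() < 0:
            raise ValueError("photon counts must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.counts)) * self.bin_width


@dataclass
class VoxelGrid:
    """Multi-channel 3D stack with anisotropic voxel size (z, y, x) in µm."""

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = (0.15, 0.04, 0.04)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        shapes = {name: np.asarray(a).shape for name, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def voxels_to_um(self, zyx: np.ndarray) -> np.ndarray:
        return np.asarray(zyx, dtype=float) * np.asarray(self.voxel_size)
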