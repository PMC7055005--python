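"""Readers and writers binding the pipeline together.

Conventions: image data travel as multi-page TIFF with axis order
(frame|z, y, x) and channels split into separate files (raster series) or
stacked as the leading axis (3D multi-channel stacks); geometry always lives
in a sidecar YAML, never in TIFF tags; tabular results are CSV whose header
comment lines record the package version, the configuration hash and the
seed of the run.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .geometry import ImageSeries, PhotonTrace, ScanConfig, VoxelGrid

__all__ = [
    "scan_to_dict",
    "scan_from_dict",
    "write_image_series",
    "read_image_series",
    "write_stack",
    "read_stack",
    "write_fcs_trace",
    "read_fcs_trace",
    "write_table",
    "read_table",
    "config_hash",
]


def scan_to_dict(scan: ScanConfig) -> dict:
    return {
        "pixel_size": scan.pixel_size,
        "dwell_time": scan.dwell_time,
        "line_time": scan.line_time,
        "frame_shape": list(scan.frame_shape),
        "n_frames": scan.n_frames,
        "w0": scan.w0,
        "AR": scan.AR,
        "frame_time": scan.frame_time,
    }


def scan_from_dict(d: dict) -> ScanConfig:
    d = dict(d)
    if "frame_shape" in d:
        d["frame_shape"] = tuple(d["frame_shape"])
    return ScanConfig(**d)


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    payload = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_image_series(series: ImageSeries, path: str | Path,
                       sidecar: Optional[dict] = None) -> Path:
    """Write a photon-count series as multi-page TIFF plus a YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(series.counts, dtype=np.uint16))
    meta = {"scan": scan_to_dict(series.scan), "channel": series.channel,
            "rng_seed": series.rng_seed}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_image_series(path: str | Path,
                      geometry: ScanConfig | str | Path | None = None,
                      channel: int | str = 1) -> ImageSeries:
    """Load a raster series, checking the page count against the geometry.

    ``geometry`` may be a ScanConfig or a path to a YAML sidecar; when
    omitted, the sidecar next to the TIFF is used.
    """
    path = Path(path)
    if geometry is None:
        geometry = path.with_suffix(".yaml")
    seed = None
    if isinstance(geometry, (str, Path)):
        meta = yaml.safe_load(Path(geometry).read_text())
        scan = scan_from_dict(meta["scan"])
        channel = meta.get("channel", channel)
        seed = meta.get("rng_seed")
    else:
        scan = geometry
    counts = tifffile.imread(path)
    if counts.ndim == 2:
        counts = counts[None]
    if counts.shape[0] != scan.n_frames:
        raise ValueError(
            f"file holds {counts.shape[0]} frames but the geometry declares "
            f"{scan.n_frames}")
    if counts.shape[1:] != scan.frame_shape:
        raise ValueError(
            f"frame shape {counts.shape[1:]} does not match declared "
            f"{scan.frame_shape}")
    return ImageSeries(counts=counts.astype(np.int64), channel=channel,
                       scan=scan, rng_seed=seed)


def write_stack(grid: VoxelGrid, path: str | Path,
                sidecar: Optional[dict] = None) -> Path:
    """Write a multi-channel stack as a (C, Z, Y, X) TIFF plus YAML sidecar."""
    path = Path(path)
    names = list(grid.channels)
    data = np.stack([np.asarray(grid.channels[n], dtype=np.float32)
                     for n in names])
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {"channels": names, "voxel_size": list(grid.voxel_size),
            "shape": list(grid.shape)}
    meta.update(grid.meta)
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_stack(path: str | Path,
               geometry: str | Path | dict | None = None) -> VoxelGrid:
    """Load a multi-channel stack with its channel names and voxel size."""
    path = Path(path)
    if geometry is None:
        geometry = path.with_suffix(".yaml")
    meta = (yaml.safe_load(Path(geometry).read_text())
            if isinstance(geometry, (str, Path)) else dict(geometry))
    data = tifffile.imread(path)
    names = meta["channels"]
    if data.ndim == 3:
        data = data[None]
    if data.shape[0] != len(names):
        raise ValueError(
            f"file holds {data.shape[0]} channels but the sidecar declares "
            f"{len(names)} ({names})")
    declared = meta.get("shape")
    if declared is not None and list(data.shape[1:]) != list(declared):
        raise ValueError(
            f"stack shape {list(data.shape[1:])} does not match declared "
            f"{declared}")
    channels = {n: data[i].astype(float) for i, n in enumerate(names)}
    return VoxelGrid(channels=channels,
                     voxel_size=tuple(meta.get("voxel_size", (0.15, 0.04, 0.04))),
                     meta={k: v for k, v in meta.items()
                           if k not in ("channels", "voxel_size", "shape")})


def write_fcs_trace(trace: PhotonTrace, path: str | Path) -> Path:
    """Two-column CSV (time_s, counts)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "counts": trace.counts})
    df.to_csv(path, index=False)
    return path


def read_fcs_trace(path: str | Path) -> PhotonTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    bin_width = float(np.median(np.diff(t)))
    return PhotonTrace(counts=df["counts"].to_numpy(),
                       bin_width=bin_width,
                       duration=len(df) * bin_width)


def write_table(df: pd.DataFrame, path: str | Path,
                config: Optional[dict] = None,
                seed: Optional[int] = None) -> Path:
    """Write a result CSV with provenance header comments."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# ricstools {__version__}\n")
    if config is not None:
        buf.write(f"# config_hash {config_hash(config)}\n")
    if seed is not None:
        buf.write(f"# seed {seed}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
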