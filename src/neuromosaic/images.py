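"""3D grey-level volumes with isotropic voxel size.

Intensity is in arbitrary units (tomographic grey levels track electron
density but are uncalibrated). Volumes are stored z, y, x like a stack of
TIFF pages; voxel centres sit at ``origin + (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .geometry import Box3D

__all__ = ["VolumeImage", "read_volume", "write_volume"]


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid plus its physical voxel size in μm."""

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be a non-empty 3D array")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def box(self) -> Box3D:
        """Physical bounding box of the grid, axes ordered (x, y, z)."""
        extent = np.array(self.data.shape[::-1], dtype=float) * self.voxel_size
        return Box3D(self.origin, self.origin + extent)

    def voxel_volume(self) -> float:
        return self.voxel_size ** 3

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional (z, y, x) array indices to physical (x, y, z) μm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        xyz = idx[:, ::-1]
        return self.origin + (xyz + 0.5) * self.voxel_size


def read_volume(path, voxel_size: float, origin=(0.0, 0.0, 0.0)) -> VolumeImage:
    """Read a multipage TIFF (or a directory of per-slice TIFFs) as a volume.

    ``voxel_size`` (μm, isotropic) is metadata the file format does not
    carry reliably, so it must be supplied by the caller/config.
    """
    path = Path(path)
    if path.is_dir():
        slices = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not slices:
            raise FileNotFoundError(f"no .tif/.tiff slices found in {path}")
        data = np.stack([tifffile.imread(str(p)) for p in slices], axis=0)
    else:
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
    return VolumeImage(data, voxel_size, origin=np.asarray(origin, dtype=float))


def write_volume(volume: VolumeImage, path) -> None:
    """Write the volume as a multipage 32-bit float TIFF, one page per z-slice."""
    tifffile.imwrite(str(path), volume.data.astype(np.float32))
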