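"""Core image containers: a 2D plane with an axial position, and a z-stack.

An :class:`ImagePlane` is one wide-field intensity image together with the
absolute axial position (in micrometres) at which it was acquired or
rendered.  An :class:`ImageStack` is an ordered set of planes on a strictly
increasing z grid; it is the unit of ground truth and of training data.

Stacks are stored on disk as a multi-page TIFF plus a CSV sidecar with
columns ``plane_index,z_um`` so the pairing of pixels and axial positions
survives round trips losslessly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: sentinel z value for derived planes (e.g. EDF images) that do not live at
#: a physical focal position
Z_SENTINEL = np.nan


@dataclasses.dataclass
class ImagePlane:
    pixels: np.ndarray
    z: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if min(self.pixels.shape) < 16:
            raise ValueError("plane must be at least 16x16 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")

    @property
    def shape(self):
        return self.pixels.shape


@dataclasses.dataclass
class ImageStack:
    planes: list[ImagePlane]
    z_grid: np.ndarray

    def __post_init__(self):
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        if len(self.planes) != len(self.z_grid):
            raise ValueError("planes and z_grid lengths differ")
        if len(self.z_grid) == 0:
            raise ValueError("empty stack")
        if len(self.z_grid) > 1 and not np.all(np.diff(self.z_grid) > 0):
            raise ValueError("z_grid must be strictly increasing")
        for p, z in zip(self.planes, self.z_grid):
            if p.z != z:
                raise ValueError("plane order does not match z_grid")

    def __len__(self):
        return len(self.planes)

    @property
    def shape(self):
        return (len(self.planes), *self.planes[0].shape)

    def as_array(self) -> np.ndarray:
        """(|Z|, m, n) volume array."""
        return np.stack([p.pixels for p in self.planes])

    def nearest_plane(self, z: float) -> ImagePlane:
        return self.planes[int(np.argmin(np.abs(self.z_grid - z)))]

    @classmethod
    def from_array(cls, volume: np.ndarray, z_grid) -> "ImageStack":
        z_grid = np.asarray(z_grid, dtype=float)
        planes = [ImagePlane(volume[i], float(z_grid[i]))
                  for i in range(volume.shape[0])]
        return cls(planes, z_grid)


def save_stack(stack: ImageStack, tif_path, csv_path=None) -> None:
    """Write a stack as multi-page float32 TIFF + ``plane_index,z_um`` CSV."""
    tif_path = Path(tif_path)
    if csv_path is None:
        csv_path = tif_path.with_suffix(".csv")
    tifffile.imwrite(tif_path, stack.as_array().astype(np.float32),
                     photometric="minisblack")
    pd.DataFrame({
        "plane_index": np.arange(len(stack)),
        "z_um": stack.z_grid,
    }).to_csv(csv_path, index=False)


def load_stack(tif_path, csv_path=None) -> ImageStack:
    tif_path = Path(tif_path)
    if csv_path is None:
        csv_path = tif_path.with_suffix(".csv")
    volume = tifffile.imread(tif_path)
    if volume.ndim == 2:
        volume = volume[None]
    table = pd.read_csv(csv_path).sort_values("plane_index")
    if len(table) != volume.shape[0]:
        raise ValueError("z sidecar does not match number of TIFF pages")
    return ImageStack.from_array(volume, table["z_um"].to_numpy())
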