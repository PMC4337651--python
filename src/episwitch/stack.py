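"""3D image stack container and TIFF input/output.

Stacks are stored (z, y, x) with anisotropic voxel spacing: square pixels of
``voxel_xy`` micrometers in-plane and a z step of 0.2 um by default, matching
typical widefield smFISH acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .errors import ParameterError

__all__ = ["ImageStack", "read_stack", "write_stack", "read_mask", "write_mask"]


@dataclass
class ImageStack:
    """A 3D fluorescence intensity grid with voxel spacing metadata."""

    data: np.ndarray  # (z, y, x)
    voxel_xy: float  # um
    z_step: float = 0.2  # um

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError(f"stack must be 3D (z, y, x), got shape {self.data.shape}")
        if self.voxel_xy <= 0 or self.z_step <= 0:
            raise ParameterError("voxel_xy and z_step must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("stack intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a multi-page TIFF (one page per z-slice)."""
    tifffile.imwrite(
        path,
        np.asarray(stack.data, dtype=np.float32),
        metadata={"voxel_xy_um": stack.voxel_xy, "z_step_um": stack.z_step},
    )


def read_stack(path, voxel_xy: float, z_step: float = 0.2) -> ImageStack:
    """Load a multi-page TIFF as an ImageStack; negative intensities clip to 0."""
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data=np.clip(data, 0.0, None), voxel_xy=voxel_xy, z_step=z_step)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a 2D cell-label image as 16-bit label TIFF."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ParameterError("mask must be 2D")
    if mask.max(initial=0) > np.iinfo(np.uint16).max:
        raise ParameterError("more labels than a 16-bit mask can hold")
    tifffile.imwrite(path, mask.astype(np.uint16))


def read_mask(path) -> np.ndarray:
    mask = np.asarray(tifffile.imread(path))
    if mask.ndim != 2:
        raise ParameterError(f"mask must be 2D, got shape {mask.shape}")
    return mask.astype(np.int64)
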