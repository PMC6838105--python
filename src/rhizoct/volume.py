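"""Core grid containers shared by every stage of the pipeline.

All images live on a common cubic voxel grid with an isotropic voxel size in
micrometres (µm).  Distances, diameters and decay lengths are always expressed
in µm in public interfaces; voxel units appear only inside algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrayVolume",
    "BinaryMask",
    "ThicknessMap",
    "um_to_vox",
    "vox_to_um",
]


def um_to_vox(value_um: float, voxel_size: float) -> float:
    """Convert a length in µm to voxel units."""
    return float(value_um) / float(voxel_size)


def vox_to_um(value_vox: float, voxel_size: float) -> float:
    """Convert a length in voxel units to µm."""
    return float(value_vox) * float(voxel_size)


def _check_grid(values: np.ndarray, voxel_size: float) -> None:
    if values.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={values.ndim}")
    if voxel_size <= 0:
        raise ValueError(f"voxel_size must be positive, got {voxel_size}")


@dataclass
class GrayVolume:
    """A 3D gray-value image (CT attenuation proxy).

    Parameters
    ----------
    values : ndarray
        3D integer grid, uint8 or uint16.
    voxel_size : float
        Edge length of a (cubic) voxel in µm.
    bit_depth : int
        8 or 16; declares the nominal gray range [0, 2**bit_depth - 1].
    """

    values: np.ndarray
    voxel_size: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        _check_grid(self.values, self.voxel_size)
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if min(self.values.shape) < 8:
            raise ValueError(
                f"all axis extents must be >= 8 voxels, got shape {self.values.shape}"
            )
        vmax = self.values.max(initial=0)
        if vmax > self.gray_max:
            raise ValueError(
                f"values exceed declared {self.bit_depth}-bit range (max {vmax})"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def gray_max(self) -> int:
        return (1 << self.bit_depth) - 1

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float32)

    def with_values(self, values: np.ndarray, bit_depth: int | None = None) -> "GrayVolume":
        """New volume on the same grid with replaced values."""
        return GrayVolume(
            values=values,
            voxel_size=self.voxel_size,
            bit_depth=self.bit_depth if bit_depth is None else bit_depth,
        )


@dataclass
class BinaryMask:
    """A boolean phase mask on the same grid as its source volume."""

    values: np.ndarray
    voxel_size: float
    roi: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        _check_grid(self.values, self.voxel_size)
        if self.values.dtype != bool:
            self.values = self.values.astype(bool)
        if self.roi is not None:
            self.roi = np.asarray(self.roi, dtype=bool)
            if self.roi.shape != self.values.shape:
                raise ValueError("roi must share the mask grid")
            if not self.roi.any():
                raise ValueError("roi must be non-empty")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def count(self) -> int:
        return int(np.count_nonzero(self.values))

    def volume_mm3(self) -> float:
        """Foreground volume in mm^3."""
        return self.count() * (self.voxel_size * 1e-3) ** 3


@dataclass
class ThicknessMap:
    """Per-voxel local structure diameter in µm (0 outside the structure)."""

    values: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        _check_grid(self.values, self.voxel_size)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def foreground(self) -> np.ndarray:
        return self.values > 0
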