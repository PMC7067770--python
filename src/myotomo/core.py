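"""Core containers and small shared helpers.

Axis convention used throughout the package: arrays are indexed ``(z, y, x)``
with 0-based indices; ``z`` is the stack (axial) axis, i.e. the slice index of
the reconstructed tomography stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: default voxel edge length of the reconstructed stacks, µm
DEFAULT_VOXEL_SIZE_UM = 1.625

# Connectivity codes map onto scipy's generate_binary_structure ranks:
# 6 -> faces only, 18 -> faces+edges, 26 -> faces+edges+corners.
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

#: fg/bg connectivity pairings that avoid topological paradoxes
COMPLEMENTARY_CONNECTIVITY = {(26, 6), (6, 26), (18, 18)}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """Return the 3x3x3 binary structuring element for a 3D connectivity."""
    try:
        rank = _CONNECTIVITY_RANK[int(connectivity)]
    except KeyError:
        raise ValueError(
            f"connectivity must be one of 6, 18, 26; got {connectivity!r}"
        ) from None
    return ndimage.generate_binary_structure(3, rank)


def as_bool_mask(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    """Validate a binary mask and return it as a boolean array."""
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 1, 255)).all():
        raise ValueError(f"{name} is not binary (values {uniq[:10]})")
    return arr != 0


def check_congruent(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"arrays are not congruent: shapes {sorted(shapes)}")


@dataclass
class Volume:
    """A 3D scalar intensity grid with isotropic voxel size.

    Parameters
    ----------
    data
        Intensity array of shape ``(z, y, x)``.
    voxel_size_um
        Edge length of a voxel in micrometres.
    """

    data: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D (z,y,x); got {self.data.ndim}D")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume with the same geometry but different data."""
        check_congruent(self.data, data)
        return Volume(data, self.voxel_size_um, dict(self.meta))
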