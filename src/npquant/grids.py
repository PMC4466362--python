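"""In-memory containers for 3D image stacks.

A :class:`VoxelGrid` is a single-channel 3D intensity array with physical
voxel spacing.  Axis order is (z, y, x), 0-based; a voxel's physical position
is the position of its center, with voxel (0, 0, 0) centered at
(dz/2, dy/2, dx/2) nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelGrid:
    """3D scalar intensity stack with per-axis spacing in nm.

    Attributes
    ----------
    data:
        Array of shape (nz, ny, nx), non-negative finite intensities.
    spacing_nm:
        (dz, dy, dx) physical voxel spacing in nm.
    channel:
        Role tag, e.g. ``"nanoparticle"``, ``"membrane"``, ``"lamina"``.
    """

    data: np.ndarray
    spacing_nm: tuple[float, float, float]
    channel: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing_nm = tuple(float(s) for s in self.spacing_nm)
        if len(self.spacing_nm) != 3 or any(s <= 0 for s in self.spacing_nm):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing_nm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_nm3(self) -> float:
        dz, dy, dx = self.spacing_nm
        return dz * dy * dx

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical size of the field of view along (z, y, x)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing_nm))

    def position_to_index(self, pos_nm: np.ndarray) -> np.ndarray:
        """Map physical (z, y, x) positions in nm to integer voxel indices."""
        pos = np.atleast_2d(np.asarray(pos_nm, dtype=float))
        idx = np.floor(pos / np.asarray(self.spacing_nm)).astype(int)
        return idx if np.asarray(pos_nm).ndim > 1 else idx[0]

    def index_to_position(self, idx: np.ndarray) -> np.ndarray:
        """Physical position (nm) of voxel centers for integer indices."""
        return (np.asarray(idx, dtype=float) + 0.5) * np.asarray(self.spacing_nm)

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing_nm, other.spacing_nm)
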