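"""In-memory containers for image volumes.

Coordinate convention (shared by every module in this package):

* voxel indices are 0-based with axis order ``(z, y, x)``;
* the physical position of voxel ``(i, j, k)`` is its *center*,
  ``((i + 0.5) * dz, (j + 0.5) * dy, (k + 0.5) * dx)`` in micrometres;
* anisotropy is carried in metadata and never resampled away — all
  physical distances are computed in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageVolume", "LayerVolume"]


@dataclass
class ImageVolume:
    """A 3D scalar fluorescence intensity grid with physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative intensities in arbitrary fluorescence units.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` in micrometres, each strictly positive.
    channel : str
        Channel label, e.g. ``"AT8"``, ``"GLUT1"``, ``"HuD"``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume rank must be 3, got rank {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("volume must have at least one voxel per axis")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values, got {self.voxel_size}")
        self.voxel_size = vs
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def index_to_um(self, indices: np.ndarray) -> np.ndarray:
        """Physical centers (μm) of integer voxel indices, shape (n, 3)."""
        return (np.asarray(indices, dtype=float) + 0.5) * np.asarray(self.voxel_size)

    def um_to_index(self, points_um: np.ndarray) -> np.ndarray:
        """Integer voxel index containing each physical point (μm)."""
        idx = np.floor(np.asarray(points_um, dtype=float) / np.asarray(self.voxel_size))
        return idx.astype(int)

    def as_float(self) -> "ImageVolume":
        """Return a float64 view/copy; integer input widens losslessly."""
        if self.data.dtype == np.float64:
            return self
        return ImageVolume(self.data.astype(np.float64), self.voxel_size, self.channel)


@dataclass
class LayerVolume:
    """Cortical-layer label grid: integer labels 0–6, 0 = unassigned."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"layer volume rank must be 3, got rank {self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("layer labels must be integers")
            self.labels = as_int
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() > 6:
            raise ValueError(f"layer labels must lie in 0..6, found {present}")
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be positive")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape
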