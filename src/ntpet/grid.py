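"""Minimal 3-D scalar-field container.

A :class:`Grid3D` couples a ``(nx, ny, nz)`` numpy array with its voxel
spacing in millimetres and a world-space origin.  It carries CT volumes
(Hounsfield units), PET volumes (SUV), binary masks and integer organ label
maps alike; the interpretation lives with the caller.  Axes are ordered
``(x, y, z)`` with ``z`` the axial (cranio-caudal) direction, and voxel
indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid3D", "GridError"]


class GridError(ValueError):
    """Raised for malformed or incompatible grids."""


@dataclass
class Grid3D:
    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GridError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be three positive mm values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def like(self, data: np.ndarray) -> "Grid3D":
        """New grid sharing this grid's geometry."""
        data = np.asarray(data)
        if data.shape != self.data.shape:
            raise GridError(f"shape {data.shape} does not match {self.data.shape}")
        return Grid3D(data, self.spacing, self.origin)

    def assert_congruent(self, other: "Grid3D", what: str = "grids") -> None:
        if self.shape != other.shape:
            raise GridError(f"{what}: shape mismatch {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing, rtol=1e-6, atol=1e-6):
            raise GridError(f"{what}: spacing mismatch {self.spacing} vs {other.spacing}")

    def copy(self) -> "Grid3D":
        return Grid3D(self.data.copy(), self.spacing, self.origin)
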