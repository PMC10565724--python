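"""Lattice geometry shared by every field in a simulation.

All lengths are in the model's nondimensional units (1 unit = 1 μm).
Fields are plain ``numpy`` arrays of shape ``grid.shape``; vector fields
carry a trailing axis of length 3.  The boundary convention everywhere in
this package is zero-flux (mirror closure), which conserves mass under
diffusion and lets a cell approach the box edge without artificial loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D lattice: ``shape`` voxels per axis, ``spacing`` μm per voxel.

    World coordinate of voxel ``(i, j, k)`` is ``(index + 0.5) * spacing``
    (voxel-center convention), so the physical extent per axis is
    ``shape[i] * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: float = 0.5
    boundary: str = "zero-flux"

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3:
            raise ValueError(f"shape must have 3 entries, got {shape}")
        if any(n < 8 for n in shape):
            raise ValueError(f"all shape entries must be >= 8, got {shape}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if self.boundary != "zero-flux":
            raise ValueError(f"unsupported boundary convention {self.boundary!r}")

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical box size per axis in μm."""
        return tuple(n * self.spacing for n in self.shape)

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center world coordinates along each axis."""
        return tuple(
            (np.arange(n) + 0.5) * self.spacing for n in self.shape
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center world coordinates as three broadcastable 3D arrays."""
        ax = self.axes()
        return np.meshgrid(*ax, indexing="ij", sparse=True)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)

    def zeros_vector(self) -> np.ndarray:
        return np.zeros(self.shape + (3,))

    def check_scalar(self, f: np.ndarray, name: str = "field") -> None:
        if f.shape != self.shape:
            raise ValueError(
                f"{name} has shape {f.shape}, expected grid shape {self.shape}"
            )

    def check_vector(self, v: np.ndarray, name: str = "field") -> None:
        if v.shape != self.shape + (3,):
            raise ValueError(
                f"{name} has shape {v.shape}, expected {self.shape + (3,)}"
            )
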