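"""Cartesian simulation grids.

A :class:`CartesianGrid` couples the spatial voxel lattice (cubic voxels)
with the temporal sampling of the wave solver.  The time step is tied to the
spatial step through the Courant-Friedrichs-Lewy (CFL) number
``cfl = c_max * dt / spacing``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CartesianGrid", "make_grid"]


@dataclass(frozen=True)
class CartesianGrid:
    """Uniform 3-D Cartesian grid with cubic voxels and a time axis.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    spacing : float
        Voxel edge length in metres (cubic voxels only).
    origin : tuple of float
        Physical coordinate (m) of the centre of voxel (0, 0, 0).
    dt : float
        Time step in seconds.
    nt : int
        Number of time samples.
    """

    shape: tuple[int, int, int]
    spacing: float
    dt: float
    nt: int
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three entries >= 1, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if not (self.spacing > 0):
            raise ValueError("spacing must be > 0")
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if self.nt < 2:
            raise ValueError("nt must be >= 2")

    # -- geometry helpers -------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (m) of the domain along each axis."""
        return tuple(n * self.spacing for n in self.shape)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.nt) * self.dt

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing

    def position(self, index: tuple[int, int, int]) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * self.spacing

    def nearest_index(self, position) -> tuple[int, int, int]:
        """Nearest voxel index; exact half-spacing ties break toward the
        smaller index."""
        rel = (np.asarray(position, dtype=float) - np.asarray(self.origin)) / self.spacing
        idx = np.ceil(rel - 0.5).astype(int)
        return tuple(int(i) for i in idx)

    def contains_index(self, index, margin: int = 0) -> bool:
        return all(margin <= i < n - margin for i, n in zip(index, self.shape))

    def flat_index(self, index) -> int:
        return int(np.ravel_multi_index(tuple(index), self.shape))

    def unravel(self, flat: int) -> tuple[int, int, int]:
        return tuple(int(i) for i in np.unravel_index(flat, self.shape))

    def cfl(self, c_max: float) -> float:
        return c_max * self.dt / self.spacing


def make_grid(
    shape,
    spacing: float,
    c_max: float,
    cfl: float = 0.3,
    duration: float = None,
    origin=(0.0, 0.0, 0.0),
) -> CartesianGrid:
    """Build a grid whose time step honours a CFL number.

    ``dt = cfl * spacing / c_max`` and ``nt = ceil(duration / dt) + 1`` so
    that ``dt * (nt - 1) >= duration``.

    Parameters
    ----------
    cfl : float
        Courant number in (0, 1); 0.3 is the standard stable choice for the
        k-space pseudospectral scheme.
    """
    if np.ndim(spacing) != 0:
        raise ValueError("spacing must be a scalar: only cubic voxels are supported")
    if not (0 < cfl < 1):
        raise ValueError(f"cfl must lie in (0, 1), got {cfl} (cfl >= 1 is unstable)")
    if duration is None or not (duration > 0):
        raise ValueError("duration must be > 0")
    if not (c_max > 0):
        raise ValueError("c_max must be > 0")
    dt = cfl * spacing / c_max
    n = duration / dt
    # snap to integer when duration is an exact multiple of dt up to rounding
    if abs(n - round(n)) < 1e-6 * max(1.0, abs(n)):
        n = round(n)
    nt = int(math.ceil(n)) + 1
    return CartesianGrid(shape=tuple(shape), spacing=float(spacing), dt=float(dt),
                         nt=nt, origin=tuple(origin))
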