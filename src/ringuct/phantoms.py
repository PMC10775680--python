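"""Synthetic breast-like slab phantoms.

A :class:`PhantomSpec` describes a slab-shaped outer region (ellipsoid)
immersed in water, plus a list of internal inclusions (ellipsoids or
Gaussian blobs) that perturb speed of sound, attenuation and density.
Voxelisation is deterministic: the resulting volumes are

    value(r) = water                                   outside the outer region
    value(r) = outer + sum_i inclusion_i(r)            inside the outer region

with Gaussian inclusions contributing ``delta * exp(-|r-c|^2_A / 2)`` and
ellipsoidal inclusions contributing ``delta`` inside their support (both
restricted to the outer region).  With no outer region, inclusions perturb
the water background directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import CartesianGrid
from .media import (AcousticMedium, WATER_DENSITY, WATER_SOS,
                    attenuation_db_to_np)

__all__ = ["Inclusion", "PhantomSpec", "build_phantom"]

SOFT_TISSUE_SOS_RANGE = (1350.0, 1650.0)


@dataclass(frozen=True)
class Inclusion:
    """A single phantom inclusion.

    Parameters
    ----------
    kind : 'ellipsoid' or 'gaussian'
    center : (3,) metres
    size : (3,) metres — semi-axes (ellipsoid) or per-axis sigma (gaussian)
    delta_sos, delta_density : additive perturbations (m/s, kg/m^3)
    delta_attenuation_db : additive attenuation in dB/(MHz^y cm)
    label : optional name used in error messages
    """

    kind: str
    center: tuple
    size: tuple
    delta_sos: float = 0.0
    delta_density: float = 0.0
    delta_attenuation_db: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("ellipsoid", "gaussian"):
            raise ValueError(f"unknown inclusion kind {self.kind!r}")
        object.__setattr__(self, "center", tuple(float(v) for v in np.atleast_1d(self.center)))
        size = np.atleast_1d(np.asarray(self.size, dtype=float))
        if size.size == 1:
            size = np.repeat(size, 3)
        if size.size != 3 or np.any(size <= 0):
            raise ValueError("size must be one or three positive lengths")
        object.__setattr__(self, "size", tuple(size))

    def field(self, X, Y, Z) -> np.ndarray:
        """Evaluate the (unit-delta) spatial profile on coordinate arrays."""
        sx, sy, sz = self.size
        cx, cy, cz = self.center
        q = ((X - cx) / sx) ** 2 + ((Y - cy) / sy) ** 2 + ((Z - cz) / sz) ** 2
        if self.kind == "ellipsoid":
            return (q <= 1.0).astype(float)
        return np.exp(-0.5 * q)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a slab phantom in water."""

    inclusions: tuple = ()
    outer_center: tuple = None
    outer_semiaxes: tuple = None
    outer_sos: float = WATER_SOS
    outer_density: float = WATER_DENSITY
    outer_attenuation_db: float = 0.0
    water_sos: float = WATER_SOS
    water_density: float = WATER_DENSITY
    power_law_exponent: float = 1.5
    sos_range: tuple = SOFT_TISSUE_SOS_RANGE

    def __post_init__(self):
        object.__setattr__(self, "inclusions", tuple(self.inclusions))


def _check_inside(inc: Inclusion, grid: CartesianGrid) -> None:
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape) - 1) * grid.spacing
    c = np.asarray(inc.center)
    ext = np.asarray(inc.size) * (1.0 if inc.kind == "ellipsoid" else 3.0)
    if np.any(c - ext < lo) or np.any(c + ext > hi):
        name = inc.label or f"{inc.kind} at {inc.center}"
        raise ValueError(f"inclusion {name!r} exceeds the grid bounds")


def build_phantom(spec: PhantomSpec, grid: CartesianGrid) -> AcousticMedium:
    """Voxelise a phantom specification (deterministic, no randomness)."""
    for inc in spec.inclusions:
        _check_inside(inc, grid)

    x = grid.axis_coords(0)[:, None, None]
    y = grid.axis_coords(1)[None, :, None]
    z = grid.axis_coords(2)[None, None, :]
    X, Y, Z = np.broadcast_arrays(x, y, z)

    sos = np.full(grid.shape, spec.water_sos, dtype=float)
    rho = np.full(grid.shape, spec.water_density, dtype=float)
    alpha_db = np.zeros(grid.shape, dtype=float)

    if spec.outer_semiaxes is not None:
        oc = spec.outer_center or (0.0, 0.0, 0.0)
        outer = Inclusion("ellipsoid", oc, spec.outer_semiaxes)
        mask = outer.field(X, Y, Z) > 0
        sos[mask] = spec.outer_sos
        rho[mask] = spec.outer_density
        alpha_db[mask] = spec.outer_attenuation_db
    else:
        mask = np.ones(grid.shape, dtype=bool)

    for inc in spec.inclusions:
        f = inc.field(X, Y, Z) * mask
        sos += inc.delta_sos * f
        rho += inc.delta_density * f
        alpha_db += inc.delta_attenuation_db * f

    lo, hi = spec.sos_range
    interior = sos != spec.water_sos
    if np.any((sos[interior] < lo) | (sos[interior] > hi)):
        raise ValueError(
            f"phantom SOS leaves the configured range [{lo}, {hi}] m/s; "
            "widen PhantomSpec.sos_range if intended"
        )

    return AcousticMedium.from_tissue_units(
        sos=sos, attenuation_db=alpha_db, density=rho,
        power_law_exponent=spec.power_law_exponent,
        ambient_density=spec.water_density,
    )
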