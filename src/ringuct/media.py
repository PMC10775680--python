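"""Heterogeneous acoustic media.

An :class:`AcousticMedium` holds voxelised speed of sound ``c`` (m/s),
power-law acoustic attenuation ``alpha``, mass density ``rho`` (kg/m^3) and
the power-law exponent ``y`` of the frequency dependence of the attenuation,
``alpha(f) = alpha0 * f^y``.

Attenuation units
-----------------
Internally attenuation is stored in Np/((rad/s)^y m), the natural unit of
the fractional-Laplacian lossy wave equation.  The tissue literature quotes
attenuation in dB/(MHz^y cm); use :func:`attenuation_db_to_np` /
:meth:`AcousticMedium.from_tissue_units` at the interface.

The absorption and dispersion proportionality coefficients of the lossy
wave equation are derived quantities,

    mu  = -2 * alpha * c**(y - 1)
    eta =  2 * alpha * c**y * tan(pi * y / 2)

and are recomputed on access so they always reflect the current volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcousticMedium",
    "attenuation_db_to_np",
    "attenuation_np_to_db",
    "water_medium",
    "WATER_SOS",
    "WATER_DENSITY",
]

WATER_SOS = 1500.0  # m/s
WATER_DENSITY = 1000.0  # kg/m^3

_NP_PER_DB = 1.0 / (20.0 / np.log(10.0))  # 0.1151293


def attenuation_db_to_np(alpha_db, y):
    """Convert dB/(MHz^y cm) -> Np/((rad/s)^y m)."""
    alpha_db = np.asarray(alpha_db, dtype=float)
    return alpha_db * _NP_PER_DB * 100.0 / (2.0 * np.pi * 1e6) ** np.asarray(y)


def attenuation_np_to_db(alpha_np, y):
    """Convert Np/((rad/s)^y m) -> dB/(MHz^y cm)."""
    alpha_np = np.asarray(alpha_np, dtype=float)
    return alpha_np / _NP_PER_DB / 100.0 * (2.0 * np.pi * 1e6) ** np.asarray(y)


@dataclass
class AcousticMedium:
    """Voxelised acoustic property volumes on a Cartesian grid.

    Parameters
    ----------
    sos : ndarray
        Speed of sound, m/s. Must be > 0 everywhere.
    attenuation : ndarray
        Power-law attenuation prefactor in Np/((rad/s)^y m); >= 0.
    density : ndarray
        Mass density, kg/m^3; > 0 everywhere.
    power_law_exponent : float or ndarray
        Exponent y of the attenuation power law, 0 < y < 3 and y != 1
        (the dispersion term diverges at y = 1).
    ambient_density : float
        Reference (ambient) density used to scale mass sources.
    """

    sos: np.ndarray
    attenuation: np.ndarray
    density: np.ndarray
    power_law_exponent: object = 1.5
    ambient_density: float = WATER_DENSITY

    def __post_init__(self):
        self.sos = np.asarray(self.sos, dtype=float)
        self.attenuation = np.broadcast_to(
            np.asarray(self.attenuation, dtype=float), self.sos.shape
        ).copy()
        self.density = np.broadcast_to(
            np.asarray(self.density, dtype=float), self.sos.shape
        ).copy()
        self.validate()

    def validate(self) -> None:
        if not np.all(self.sos > 0):
            raise ValueError("sos must be > 0 everywhere")
        if not np.all(self.density > 0):
            raise ValueError("density must be > 0 everywhere")
        if not np.all(self.attenuation >= 0):
            raise ValueError("attenuation must be >= 0")
        y = np.asarray(self.power_law_exponent, dtype=float)
        if not (np.all(y > 0) and np.all(y < 3)):
            raise ValueError("power_law_exponent must satisfy 0 < y < 3")
        if np.any(y == 1.0):
            raise ValueError(
                "power_law_exponent y = 1 is outside the validity of the "
                "fractional-Laplacian dispersion term (tan(pi*y/2) diverges)"
            )
        if not (self.ambient_density > 0):
            raise ValueError("ambient_density must be > 0")

    @classmethod
    def from_tissue_units(cls, sos, attenuation_db, density,
                          power_law_exponent=1.5, ambient_density=WATER_DENSITY):
        """Construct from attenuation given in dB/(MHz^y cm)."""
        alpha = attenuation_db_to_np(attenuation_db, power_law_exponent)
        return cls(sos=np.asarray(sos, float), attenuation=alpha,
                   density=np.asarray(density, float),
                   power_law_exponent=power_law_exponent,
                   ambient_density=ambient_density)

    # -- derived coefficients (recomputed on access) ----------------------
    @property
    def absorption_coeff(self) -> np.ndarray:
        """mu = -2 alpha c^{y-1} (absorption proportionality coefficient)."""
        y = np.asarray(self.power_law_exponent, dtype=float)
        return -2.0 * self.attenuation * self.sos ** (y - 1.0)

    @property
    def dispersion_coeff(self) -> np.ndarray:
        """eta = 2 alpha c^y tan(pi y / 2) (dispersion coefficient)."""
        y = np.asarray(self.power_law_exponent, dtype=float)
        return 2.0 * self.attenuation * self.sos ** y * np.tan(np.pi * y / 2.0)

    @property
    def is_lossless(self) -> bool:
        return bool(np.all(self.attenuation == 0))

    @property
    def uniform_exponent(self) -> float:
        """The single power-law exponent, erroring if it is heterogeneous."""
        y = np.asarray(self.power_law_exponent, dtype=float)
        if y.ndim == 0:
            return float(y)
        vals = np.unique(y)
        if vals.size != 1:
            raise ValueError(
                "the wave solver requires a spatially uniform power-law "
                "exponent (fractional-Laplacian powers are global wavenumber "
                "multipliers)"
            )
        return float(vals[0])

    @property
    def c_max(self) -> float:
        return float(self.sos.max())

    @property
    def c_min(self) -> float:
        return float(self.sos.min())

    def copy(self) -> "AcousticMedium":
        y = self.power_law_exponent
        y = y.copy() if isinstance(y, np.ndarray) else y
        return AcousticMedium(self.sos.copy(), self.attenuation.copy(),
                              self.density.copy(), y, self.ambient_density)


def water_medium(shape, sos=WATER_SOS, density=WATER_DENSITY,
                 power_law_exponent=1.5) -> AcousticMedium:
    """Homogeneous lossless water volume."""
    shape = tuple(shape)
    return AcousticMedium(
        sos=np.full(shape, float(sos)),
        attenuation=np.zeros(shape),
        density=np.full(shape, float(density)),
        power_law_exponent=power_law_exponent,
    )
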