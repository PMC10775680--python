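"""Excitation pulses.

The source amplitude ``x(t)`` drives the mass-source forcing of the wave
equation; physically ``x(t) = 2 * rho0 * d(v_hat)/dt`` where ``v_hat`` is
the normal velocity of the transducer front face.  The default excitation
is a Gaussian-modulated sinusoid sized so that its spectral magnitude falls
below 1% of the peak above a declared maximum frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

__all__ = ["Pulse", "tone_burst_pulse", "GridSupportWarning"]


class GridSupportWarning(UserWarning):
    """Pulse bandwidth exceeds what the target grid can support."""


@dataclass
class Pulse:
    """Band-limited source amplitude time series.

    Parameters
    ----------
    samples : ndarray
        The source amplitude x(t) (= 2 rho0 dv/dt), sampled at ``dt``.
    dt : float
        Sample interval, s.
    center_frequency, max_frequency : float
        Spectral centre and the declared band edge (magnitude <= 1% of the
        spectral peak above it), Hz.
    """

    samples: np.ndarray
    dt: float
    center_frequency: float
    max_frequency: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("pulse samples must be finite")
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def spectrum(self, n: int = None):
        """(frequencies, complex amplitude) of the one-sided spectrum."""
        n = n or max(1024, 4 * self.n_samples)
        freqs = np.fft.rfftfreq(n, self.dt)
        return freqs, sfft.rfft(self.samples, n)

    def check_grid_support(self, spacing: float, c_min: float,
                           points_per_wavelength: float = 3.0) -> float:
        """Warn when ``max_frequency`` exceeds the supported grid frequency
        ``c_min / (ppw * spacing)``; returns the supported frequency."""
        supported = c_min / (points_per_wavelength * spacing)
        if self.max_frequency > supported * (1 + 1e-9):
            warnings.warn(
                f"pulse max_frequency {self.max_frequency:.3g} Hz exceeds the "
                f"grid-supported frequency {supported:.3g} Hz "
                f"({points_per_wavelength} points per wavelength at spacing "
                f"{spacing:.3g} m, c_min {c_min:.3g} m/s)",
                GridSupportWarning,
            )
        return supported

    def padded(self, nt: int) -> np.ndarray:
        """Samples zero-padded (or truncated) to length nt."""
        out = np.zeros(nt, dtype=float)
        n = min(nt, self.n_samples)
        out[:n] = self.samples[:n]
        return out

    def scaled(self, factor: float) -> "Pulse":
        return Pulse(self.samples * factor, self.dt,
                     self.center_frequency, self.max_frequency)


def tone_burst_pulse(center_frequency: float, dt: float,
                     max_frequency: float = None, n_cycles: float = None,
                     amplitude: float = 1.0) -> Pulse:
    """Gaussian-enveloped sinusoid with a controlled spectral band edge.

    Exactly one of ``max_frequency`` or ``n_cycles`` sets the envelope
    width.  With ``max_frequency`` the Gaussian spectral envelope is sized
    so the magnitude at ``max_frequency`` is below -46 dB of the spectral
    peak (comfortably under the 1% band-edge definition).

    Returns
    -------
    Pulse
        With ``samples = amplitude * sin(2 pi f_c (t - t0)) * gauss(t)``.
    """
    if not (center_frequency > 0):
        raise ValueError("center_frequency must be > 0")
    if (max_frequency is None) == (n_cycles is None):
        raise ValueError("specify exactly one of max_frequency or n_cycles")
    if max_frequency is not None:
        if not (max_frequency > center_frequency):
            raise ValueError("max_frequency must exceed center_frequency")
        # exp(-d^2 / (2 sf^2)) = 10^(-46/20)  at  d = f_max - f_c
        sigma_f = (max_frequency - center_frequency) / np.sqrt(2.0 * 46 / 20 * np.log(10.0))
        sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
        f_max = float(max_frequency)
    else:
        if not (n_cycles > 0):
            raise ValueError("n_cycles must be > 0")
        # n_cycles measured as the FWHM of the envelope in periods
        sigma_t = n_cycles / (center_frequency * 2.3548200450309493)
        sigma_f = 1.0 / (2.0 * np.pi * sigma_t)
        f_max = float(center_frequency + np.sqrt(2.0 * 46 / 20 * np.log(10.0)) * sigma_f)
    half = 4.0 * sigma_t
    n_half = int(np.ceil(half / dt))
    t = (np.arange(2 * n_half + 1) - n_half) * dt
    samples = amplitude * np.sin(2 * np.pi * center_frequency * t) * np.exp(
        -0.5 * (t / sigma_t) ** 2
    )
    return Pulse(samples=samples, dt=float(dt),
                 center_frequency=float(center_frequency), max_frequency=f_max)
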