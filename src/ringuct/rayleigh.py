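"""Semianalytic Rayleigh-Sommerfeld reference solution.

For a baffled aperture Omega vibrating with normal velocity
``v(r', t) = vhat(t + tau(r'))`` in a homogeneous lossless medium, the
radiated pressure is

    p(r, t) = rho0 * integral_Omega  vhat_dot(t + tau(r') - |r - r'| / c0)
                                     / (2 pi |r - r'|)  dr'.

The integral is evaluated by a distributed-point-source quadrature: the
aperture is replaced by point sources with areas, lens delays and
apodization weights.  Retarded times are evaluated by band-limited (sinc)
interpolation, realised exactly in the frequency domain.  This solution is
the validation oracle for the lens-focused k-space transducer model; it is
valid only for homogeneous, lossless media.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .pulses import Pulse
from .transducer import LensProfile, TransducerElement, lens_delay

__all__ = ["ApertureQuadrature", "rs_pressure", "max_amplitude_map",
           "vhat_dot_from_pulse"]


@dataclass
class ApertureQuadrature:
    """Distributed point sources over a transducer aperture.

    Fields: point positions (Q, 3) m; areas (Q,) m^2; per-point lens
    delays (Q,) s; dimensionless weights (Q,).
    """

    points: np.ndarray
    areas: np.ndarray
    delays: np.ndarray
    weights: np.ndarray = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.areas = np.atleast_1d(np.asarray(self.areas, dtype=float))
        self.delays = np.atleast_1d(np.asarray(self.delays, dtype=float))
        if self.weights is None:
            self.weights = np.ones(len(self.areas))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        q = len(self.points)
        if not (len(self.areas) == len(self.delays) == len(self.weights) == q):
            raise ValueError("quadrature arrays must have matching lengths")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @classmethod
    def line_aperture(cls, center, height: float, lens: LensProfile,
                      n_points: int = None, min_wavelength: float = None,
                      points_per_wavelength: float = 8.0,
                      width: float = 1.0, weight_fn=None) -> "ApertureQuadrature":
        """Vertical line aperture with a lens delay profile.

        ``n_points`` may be given directly, or derived from a minimum
        wavelength at >= ``points_per_wavelength`` points per wavelength.
        ``width`` scales the per-point areas so that the total aperture
        area is ``height * width``.
        """
        if n_points is None:
            if min_wavelength is None:
                raise ValueError("give n_points or min_wavelength")
            n_points = int(np.ceil(points_per_wavelength * height / min_wavelength))
        n_points = max(2, int(n_points))
        z_rel = (np.arange(n_points) - (n_points - 1) / 2.0) * (height / n_points)
        center = np.asarray(center, dtype=float)
        pts = np.tile(center, (n_points, 1))
        pts[:, 2] += z_rel
        areas = np.full(n_points, height * width / n_points)
        delays = lens_delay(lens, z_rel)
        weights = None if weight_fn is None else np.asarray(
            [weight_fn(z) for z in z_rel], dtype=float)
        return cls(points=pts, areas=areas, delays=delays, weights=weights)

    @classmethod
    def from_element(cls, element: TransducerElement, n_points=None,
                     min_wavelength=None, points_per_wavelength=8.0,
                     width: float = 1.0) -> "ApertureQuadrature":
        return cls.line_aperture(element.center, element.height, element.lens,
                                 n_points=n_points, min_wavelength=min_wavelength,
                                 points_per_wavelength=points_per_wavelength,
                                 width=width)

    def refined(self, factor: int = 2) -> "ApertureQuadrature":
        """Quadrature with ``factor`` points per original point (line only)."""
        # subdivide each point's segment along z
        q = self.n_points
        seg = np.diff(self.points[:, 2]).mean() if q > 1 else 0.0
        new_pts, new_areas, new_delays, new_w = [], [], [], []
        for i in range(q):
            for j in range(factor):
                off = (j - (factor - 1) / 2.0) * seg / factor
                pt = self.points[i].copy()
                pt[2] += off
                new_pts.append(pt)
                new_areas.append(self.areas[i] / factor)
                new_delays.append(self.delays[i])
                new_w.append(self.weights[i])
        return ApertureQuadrature(np.array(new_pts), np.array(new_areas),
                                  np.array(new_delays), np.array(new_w))


def vhat_dot_from_pulse(pulse: Pulse, rho0: float) -> np.ndarray:
    """Recover vhat_dot = x / (2 rho0) from the stored source amplitude."""
    return pulse.samples / (2.0 * rho0)


def rs_pressure(quadrature: ApertureQuadrature, vhat_dot: np.ndarray,
                c0: float, rho0: float, field_points: np.ndarray,
                times: np.ndarray, dt: float = None,
                chunk: int = 64) -> np.ndarray:
    """Evaluate the Rayleigh-Sommerfeld pressure at field points.

    Parameters
    ----------
    vhat_dot : ndarray
        Time derivative of the face normal velocity, sampled at ``dt``.
    times : ndarray
        Uniform output sample times ``l * dt`` starting at zero; must be
        long enough to contain all retarded arrivals (no wrap-around
        protection beyond internal padding).

    Returns
    -------
    ndarray, shape (n_field_points, len(times))
    """
    field_points = np.atleast_2d(np.asarray(field_points, dtype=float))
    vhat_dot = np.asarray(vhat_dot, dtype=float)
    times = np.asarray(times, dtype=float)
    if dt is None:
        dt = times[1] - times[0]
    n_out = len(times)
    n_fft = sfft.next_fast_len(n_out + len(vhat_dot))
    freqs = sfft.rfftfreq(n_fft, dt)
    V = sfft.rfft(vhat_dot, n_fft)

    acc = np.zeros((len(field_points), len(freqs)), dtype=complex)
    for start in range(0, quadrature.n_points, chunk):
        pts = quadrature.points[start:start + chunk]
        areas = quadrature.areas[start:start + chunk]
        delays = quadrature.delays[start:start + chunk]
        weights = quadrature.weights[start:start + chunk]
        r = np.linalg.norm(field_points[:, None, :] - pts[None, :, :], axis=2)
        if np.any(r < 1e-12):
            raise ValueError(
                "field point coincides with a quadrature point (singular "
                "1/r kernel)")
        amp = (rho0 * weights * areas) / (2.0 * np.pi * r)       # (F, Q)
        phase = np.exp(-2j * np.pi * freqs[None, None, :]
                       * (r[:, :, None] / c0 - delays[None, :, None]))
        acc += np.einsum("fq,fqk->fk", amp, phase, optimize=True) * V[None, :]
    traces = sfft.irfft(acc, n=n_fft, axis=1)[:, :n_out]
    return traces


def max_amplitude_map(traces: np.ndarray, db: bool = False,
                      normalize: float = None,
                      envelope: bool = False) -> np.ndarray:
    """Per-point maximum of |p| over time.

    With ``envelope=True`` the maximum is taken over the analytic-signal
    envelope, which removes the half-sample sensitivity of the discrete
    maximum to the carrier phase.  With ``db=True`` the map is returned as
    ``20 log10(max_t |p| / max_{r,t} |p|)`` (0 dB at the global maximum);
    ``normalize`` overrides the normalisation constant.
    """
    traces = np.asarray(traces)
    if envelope:
        from scipy.signal import hilbert
        m = np.max(np.abs(hilbert(traces, axis=-1)), axis=-1)
    else:
        m = np.max(np.abs(traces), axis=-1)
    if db:
        ref = normalize if normalize is not None else m.max()
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(m / ref)
    if normalize is not None:
        return m / normalize
    return m
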