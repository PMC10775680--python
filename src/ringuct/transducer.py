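"""Elevation-focused transducer operators.

A ring-array element is a tall, thin vertical aperture behind a concave
acoustic lens.  In a geometrical-acoustics approximation the lens maps to a
spatially varying time *advance* across the element height,

    tau(z) = d(z) (1/c0 - 1/c_lens),      d(z) = (a/2) z^2 + d0,

so contributions from the (thicker-lensed) element edges lead the centre
and the element focuses in elevation.  On the simulation grid the element
is a vertical line of N voxel-height segments; transmit injects delayed
copies of the excitation at each segment, receive forms the delayed sum of
the segment pressures.  Both directions apply the advance D_{+tau}, the
discrete statement of the lens acting on outgoing and incoming wavefronts
alike; the adjoint (transpose) of either operator is the other conjugated
by time reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft

from .grids import CartesianGrid
from .pulses import Pulse
from .solver import SourceField, WaveSimResult

__all__ = [
    "LensProfile",
    "TransducerElement",
    "ChannelData",
    "lens_delay",
    "fractional_delay",
    "discretize_aperture",
    "inject",
    "inject_trace",
    "sample",
]


@dataclass(frozen=True)
class LensProfile:
    """Parabolic concave lens: thickness d(z) = (a/2) z^2 + d0.

    Parameters
    ----------
    curvature : float
        a, 1/m.
    offset : float
        d0, minimum thickness at the element mid-height, m.
    lens_sos : float
        Speed of sound inside the lens, m/s (> medium speed for a focusing
        concave lens, giving tau >= 0).
    medium_sos : float
        Speed of sound of the coupling medium, m/s.
    """

    curvature: float = 14.0          # 0.014 mm^-1
    offset: float = 0.45e-3
    lens_sos: float = 4500.0
    medium_sos: float = 1500.0

    def __post_init__(self):
        if self.lens_sos < self.medium_sos:
            raise ValueError(
                "lens_sos < medium_sos gives negative delays (defocusing lens)")
        if self.offset < 0:
            raise ValueError("lens offset (minimum thickness) must be >= 0")

    def thickness(self, z) -> np.ndarray:
        return 0.5 * self.curvature * np.asarray(z, float) ** 2 + self.offset

    def focal_length(self) -> float:
        """Paraxial elevation focal distance of the lens in the medium."""
        if self.curvature == 0 or self.lens_sos == self.medium_sos:
            return np.inf
        return self.lens_sos / (self.curvature * (self.lens_sos - self.medium_sos))


def lens_delay(lens: LensProfile, z) -> np.ndarray:
    """Time advance tau(z) (seconds) at elevation z from the element centre."""
    return lens.thickness(z) * (1.0 / lens.medium_sos - 1.0 / lens.lens_sos)


def fractional_delay(signal, tau: float, dt: float):
    """Advance a signal by an arbitrary (non-integer) multiple of dt.

    Implements the circular spectral time-shift operator
    ``D_tau: phi(t) -> phi(t + tau)`` by multiplying the DFT by
    ``exp(+2j pi f tau)`` on the symmetric frequency set.  For even-length
    signals the unpaired Nyquist bin is scaled by ``cos(2 pi f_nyq tau)``
    so that real signals stay exactly real.  The operator is unitary
    (Parseval) apart from that Nyquist contraction, and
    ``D_{-tau} D_{tau} = I`` for signals with no Nyquist content.
    """
    if not np.isfinite(tau):
        raise ValueError("delay tau must be finite")
    x = np.asarray(signal, dtype=float)
    L = x.shape[-1]
    if L < 2:
        raise ValueError("signal must have at least 2 samples")
    freqs = sfft.rfftfreq(L, dt)
    mult = np.exp(2j * np.pi * freqs * tau)
    if L % 2 == 0:
        mult[-1] = np.cos(2 * np.pi * freqs[-1] * tau)
    return sfft.irfft(sfft.rfft(x, axis=-1) * mult, n=L, axis=-1)


@dataclass
class TransducerElement:
    """A vertical line element with a lens, discretised to grid segments.

    Before :func:`discretize_aperture` only the geometric fields are set;
    afterwards ``segment_indices`` (flat voxel indices, bottom to top),
    ``segment_delays`` (s) and ``segment_weights`` are populated.
    """

    center: tuple
    height: float
    lens: LensProfile
    weights: object = None          # None (uniform) or callable weight(z)
    segment_indices: np.ndarray = None
    segment_delays: np.ndarray = None
    segment_weights: np.ndarray = None

    def __post_init__(self):
        self.center = tuple(float(v) for v in self.center)
        if not (self.height > 0):
            raise ValueError("element height must be > 0")

    @property
    def n_segments(self):
        return None if self.segment_indices is None else len(self.segment_indices)

    @property
    def is_discretized(self) -> bool:
        return self.segment_indices is not None

    def _require_discretized(self):
        if not self.is_discretized:
            raise ValueError("element must be discretised on a grid first "
                             "(call discretize_aperture)")


def discretize_aperture(element: TransducerElement, grid: CartesianGrid,
                        pml_size: int = 10) -> TransducerElement:
    """Snap an element to the grid as N consecutive vertical segments.

    The element width is neglected (high aspect ratio); the aperture is a
    vertical line of ``N = round(height / spacing)`` voxel-height segments
    snapped to the nearest grid column (ties toward the smaller index).
    Each segment's delay is the lens advance evaluated at the segment
    centre elevation relative to the element mid-height.
    """
    dx = grid.spacing
    n_seg = int(round(element.height / dx))
    if n_seg < 1:
        raise ValueError("element height is below one voxel")
    ix, iy, _ = grid.nearest_index(element.center)
    z_rel = (np.arange(n_seg) - (n_seg - 1) / 2.0) * dx
    z_abs = element.center[2] + z_rel
    iz = np.array([grid.nearest_index((element.center[0], element.center[1], z))[2]
                   for z in z_abs])
    # consecutive segments: snap the centre, then use a contiguous run
    iz = iz[0] + np.arange(n_seg)
    for k in (0, n_seg - 1):
        if not grid.contains_index((ix, iy, iz[k]), margin=pml_size):
            raise ValueError(
                f"element at {element.center} overlaps the absorbing boundary "
                f"(pml_size={pml_size}) or leaves the grid")
    flat = np.array([grid.flat_index((ix, iy, z)) for z in iz], dtype=np.int64)
    delays = lens_delay(element.lens, z_rel)
    if element.weights is None:
        w = np.ones(n_seg)
    elif callable(element.weights):
        w = np.asarray([element.weights(z) for z in z_rel], dtype=float)
    else:
        w = np.asarray(element.weights, dtype=float)
        if w.shape != (n_seg,):
            raise ValueError("weights array must have one entry per segment")
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("apodization weights must lie in [0, 1]")
    return replace(element, segment_indices=flat, segment_delays=delays,
                   segment_weights=w)


def inject(pulse: Pulse, element: TransducerElement,
           grid: CartesianGrid) -> SourceField:
    """Transmit mapping: delayed copies of the excitation on each segment.

    Segment k carries ``weight_k * D_{+tau_k} x`` where x is the pulse
    (zero-padded to the simulation length before the circular shift).
    """
    element._require_discretized()
    if abs(pulse.dt - grid.dt) > 1e-12 * grid.dt:
        raise ValueError(
            f"pulse dt {pulse.dt} != grid dt {grid.dt}: no implicit resampling")
    x = pulse.padded(grid.nt)
    src = SourceField(grid)
    for flat, tau, w in zip(element.segment_indices, element.segment_delays,
                            element.segment_weights):
        src.add_point(int(flat), w * fractional_delay(x, +tau, grid.dt))
    return src


def inject_trace(trace: np.ndarray, element: TransducerElement,
                 grid: CartesianGrid) -> SourceField:
    """Inject an arbitrary per-element time series (adjoint sources)."""
    element._require_discretized()
    trace = np.asarray(trace, dtype=float)
    if trace.shape != (grid.nt,):
        raise ValueError("trace length must equal grid.nt")
    src = SourceField(grid)
    for flat, tau, w in zip(element.segment_indices, element.segment_delays,
                            element.segment_weights):
        src.add_point(int(flat), w * fractional_delay(trace, +tau, grid.dt))
    return src


def sample(result: WaveSimResult, element: TransducerElement) -> np.ndarray:
    """Receive sampling: delayed sum of the segment pressure traces,
    ``g = sum_k weight_k * D_{+tau_k} p(r_k)``."""
    element._require_discretized()
    rows = []
    if result.record_voxels is None:
        raise ValueError("simulation result holds no recorded traces")
    lookup = {int(v): i for i, v in enumerate(result.record_voxels)}
    for flat in element.segment_indices:
        if int(flat) not in lookup:
            raise KeyError(
                f"segment voxel {int(flat)} missing from the recorded traces")
        rows.append(lookup[int(flat)])
    seg_traces = result.traces[rows]
    delayed = np.vstack([
        fractional_delay(tr, +tau, result.dt)
        for tr, tau in zip(seg_traces, element.segment_delays)
    ])
    return element.segment_weights @ delayed


@dataclass
class ChannelData:
    """Pressure traces per (emitter, receiver, time) with sampling metadata."""

    traces: np.ndarray
    dt: float
    emitter_ids: np.ndarray = None
    receiver_ids: np.ndarray = None
    ring_z: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 3:
            raise ValueError("traces must be (n_emitters, n_receivers, nt)")
        if self.emitter_ids is None:
            self.emitter_ids = np.arange(self.traces.shape[0])
        if self.receiver_ids is None:
            self.receiver_ids = np.arange(self.traces.shape[1])

    @property
    def n_emitters(self) -> int:
        return self.traces.shape[0]

    @property
    def n_receivers(self) -> int:
        return self.traces.shape[1]

    @property
    def nt(self) -> int:
        return self.traces.shape[2]

    def copy(self) -> "ChannelData":
        return ChannelData(self.traces.copy(), self.dt,
                           self.emitter_ids.copy(), self.receiver_ids.copy(),
                           self.ring_z, dict(self.metadata))
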