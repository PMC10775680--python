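"""Source-encoded full-waveform inversion (FWI) for speed of sound.

Waveform inversion with source encoding (WISE) replaces the per-emitter
misfit sum by a stochastic objective: at each iteration a random encoding
vector ``w`` (Rademacher, zero mean, identity covariance) combines all
emitters into a single super-shot,

    J_w(c) = 1/2 || g_w - Mtau H_c s_w ||^2,
    g_w = sum_i w_i g_i,   s_w = sum_i w_i s_i,

whose expectation over w equals the full (non-encoded) objective.  The SOS
gradient is assembled from one forward and one adjoint wavefield per
iteration via the adjoint-state method:

    [grad_c J]_k = (1/c_k^3) sum_{l=1}^{L-2} q_{k, L-1-l}
                   (p_{k,l-1} - 2 p_{k,l} + p_{k,l+1}) / dt,

with the adjoint field q computed by propagating the time-reversed data
residual through the (delayed) receiver mapping with the forward solver.
The expression is exact for lossless media and an approximation in
attenuating media (attenuation terms neglected).

The module exposes a statsmodels-style pairing: :class:`WaveformInversion`
is built from channel data and geometry, ``fit()`` runs the optimisation
and returns an :class:`InversionResult` with the estimate, diagnostics and
``summary()``.  :func:`reconstruct` is the two-step coarse-to-fine driver.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft

from .grids import CartesianGrid
from .media import AcousticMedium
from .pulses import Pulse
from .solver import SourceField, simulate, solver_adjoint_run
from .transducer import (ChannelData, TransducerElement, discretize_aperture,
                         fractional_delay, inject, inject_trace, sample)

__all__ = [
    "EncodingVector", "rademacher_vector", "encode", "adjoint_source",
    "sos_gradient", "rel_rmse", "InversionConfig", "WaveformInversion",
    "InversionResult", "reconstruct", "lowpass_traces",
    "combine_ring_estimates",
]


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncodingVector:
    """Signed per-emitter weights w with zero mean and identity covariance."""

    weights: np.ndarray
    seed: int = None
    distribution: str = "rademacher"

    def __post_init__(self):
        object.__setattr__(self, "weights",
                           np.asarray(self.weights, dtype=float))


def rademacher_vector(n_emitters: int, rng) -> EncodingVector:
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    w = rng.integers(0, 2, size=n_emitters) * 2.0 - 1.0
    return EncodingVector(weights=w)


def encode(per_emitter_traces: np.ndarray, w: EncodingVector) -> np.ndarray:
    """g_w = sum_i w_i g_i for traces of shape (E, R, L) -> (R, L)."""
    traces = np.asarray(per_emitter_traces)
    weights = w.weights if isinstance(w, EncodingVector) else np.asarray(w, float)
    if traces.shape[0] != len(weights):
        raise ValueError(
            f"encoding length {len(weights)} != number of emitters "
            f"{traces.shape[0]}")
    return np.tensordot(weights, traces, axes=(0, 0))


# ---------------------------------------------------------------------------
# adjoint machinery
# ---------------------------------------------------------------------------

def adjoint_source(encoded_residual: np.ndarray,
                   receivers: list, grid: CartesianGrid) -> SourceField:
    """Build the adjoint source from a per-receiver data residual.

    The residual (R, L) is time-reversed (l -> L-1-l) and injected through
    the receivers' delayed mapping operators, so each receiver's segments
    carry lens-delayed copies of its reversed residual.
    """
    residual = np.asarray(encoded_residual, dtype=float)
    if residual.ndim == 1:
        residual = residual[None, :]
    if residual.shape[0] != len(receivers):
        raise ValueError("one residual trace per receiver is required")
    eta = residual[:, ::-1]
    src = SourceField(grid)
    for j, rec in enumerate(receivers):
        src = src + inject_trace(eta[j], rec, grid)
    return src


def sos_gradient(sos: np.ndarray, forward_wavefield: np.ndarray,
                 adjoint_wavefield: np.ndarray, dt: float,
                 chunk: int = 262144) -> np.ndarray:
    """Adjoint-state SOS gradient (see module docstring for the formula).

    Both wavefields are (K, L) records on the same grid; the adjoint field
    is correlated against the second time difference of the forward field,
    read in reversed time.  The correlation sum is scaled by 2/dt^2 so the
    returned array is the exact gradient of the discrete least-squares
    objective (verified against central finite differences); the classic
    continuous-adjoint writing of the formula differs only by this
    constant, which optimisers absorb into the step size.
    """
    p = forward_wavefield
    q = adjoint_wavefield
    if p.shape != q.shape:
        raise ValueError(f"wavefield shapes differ: {p.shape} vs {q.shape}")
    K, L = p.shape
    flat_c = np.asarray(sos, dtype=float).reshape(-1)
    if flat_c.size != K:
        raise ValueError("sos volume does not match the wavefield grid")
    grad = np.zeros(K)
    for s in range(0, K, chunk):
        e = min(K, s + chunk)
        pc = p[s:e].astype(np.float64)
        d2p = pc[:, :-2] - 2.0 * pc[:, 1:-1] + pc[:, 2:]      # l = 1 .. L-2
        q_rev = q[s:e, ::-1][:, 1:L - 1].astype(np.float64)   # q_{k, L-1-l}
        grad[s:e] = np.einsum("kl,kl->k", q_rev, d2p) * (2.0 / dt ** 2)
    return (grad / flat_c ** 3).reshape(np.asarray(sos).shape)


def rel_rmse(c: np.ndarray, c_true: np.ndarray, c0: np.ndarray) -> float:
    """Relative RMSE ||c - c_true|| / ||c0 - c_true|| of a reconstruction."""
    c0 = np.broadcast_to(np.asarray(c0, float), np.asarray(c_true).shape)
    num = np.linalg.norm(np.asarray(c, float) - np.asarray(c_true, float))
    den = np.linalg.norm(c0 - np.asarray(c_true, float))
    return float(num / den)


# ---------------------------------------------------------------------------
# filtering / grid transfer helpers (coarse-to-fine driver)
# ---------------------------------------------------------------------------

def lowpass_traces(traces: np.ndarray, dt: float, cutoff: float,
                   taper_fraction: float = 0.2) -> np.ndarray:
    """Zero-phase spectral low-pass with a raised-cosine roll-off."""
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[-1]
    freqs = sfft.rfftfreq(n, dt)
    f0 = cutoff * (1.0 - taper_fraction)
    h = np.ones_like(freqs)
    ramp = (freqs > f0) & (freqs <= cutoff)
    h[ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[ramp] - f0) / (cutoff - f0)))
    h[freqs > cutoff] = 0.0
    return sfft.irfft(sfft.rfft(traces, axis=-1) * h, n=n, axis=-1)


def restrict_volume(vol: np.ndarray) -> np.ndarray:
    """2x block-average restriction (shapes must be even)."""
    s = vol.shape
    if any(n % 2 for n in s):
        raise ValueError("volume shape must be even for 2x restriction")
    return vol.reshape(s[0] // 2, 2, s[1] // 2, 2, s[2] // 2, 2).mean(axis=(1, 3, 5))


def prolong_volume(vol: np.ndarray) -> np.ndarray:
    """2x nearest-neighbour prolongation (adjoint-of-injection refinement)."""
    return np.repeat(np.repeat(np.repeat(vol, 2, axis=0), 2, axis=1), 2, axis=2)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class InversionConfig:
    """Tunables of the stochastic inversion.

    step_size is the Adam step in m/s per iteration; bounds are the
    physical SOS projection interval in m/s.
    """

    n_iterations: int = 50
    step_size: float = 2.0
    bounds: tuple = (1300.0, 1700.0)
    regularization_weight: float = 0.0
    pml_size: int = 8
    solver_dtype: object = np.float32
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1.0    # relative damping of the diagonal scaling:
    #  ~1 gives globally normalised momentum descent (quiet where the
    #  gradient is weak); << 1 approaches classic per-voxel Adam
    patience: int = 10
    seed: int = 0
    c_ref: float = None      # common k-space reference speed across iterates
    illumination_weight: float = 0.0
    # > 0 divides the gradient by (E/max(E) + w) with E the forward
    # wavefield energy per voxel: compensates source illumination so
    # poorly insonified voxels are not under-updated
    coarse_iterations: int = 0
    coarse_lowpass_fraction: float = 0.5
    verbose: bool = False


@dataclass
class InversionResult:
    """Estimates and diagnostics returned by :meth:`WaveformInversion.fit`."""

    sos: np.ndarray
    objective_history: np.ndarray
    grid: CartesianGrid
    config: InversionConfig
    n_iterations: int
    stop_reason: str = "max_iterations"
    runtime: float = 0.0
    stages: list = field(default_factory=list)

    def rel_rmse(self, c_true, c0) -> float:
        return rel_rmse(self.sos, c_true, c0)

    def summary(self) -> str:
        j = self.objective_history
        lines = [
            "Source-encoded waveform inversion for speed of sound",
            "====================================================",
            f"grid                : {self.grid.shape} @ {self.grid.spacing*1e3:.3g} mm",
            f"iterations run      : {self.n_iterations}",
            f"stop reason         : {self.stop_reason}",
            f"encoded misfit      : first {j[0]:.6g}  last {j[-1]:.6g}"
            if len(j) else "encoded misfit      : (none)",
            f"misfit reduction    : {j[-1]/j[0]:.4f} x" if len(j) > 1 and j[0] > 0
            else "misfit reduction    : n/a",
            f"SOS estimate [m/s]  : min {self.sos.min():.1f}  "
            f"mean {self.sos.mean():.1f}  max {self.sos.max():.1f}",
            f"bounds [m/s]        : {self.config.bounds}"
            f"  (at bounds: {int(np.sum((self.sos <= self.config.bounds[0]) | (self.sos >= self.config.bounds[1])))} voxels)",
            f"runtime [s]         : {self.runtime:.1f}",
        ]
        return "\n".join(lines)

    def plot_convergence(self, ax=None):  # pragma: no cover - plotting helper
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.objective_history, "o-")
        ax.set_xlabel("encoded iteration")
        ax.set_ylabel("encoded misfit J_w")
        return ax


class WaveformInversion:
    """Stochastic (source-encoded) FWI model for one ring acquisition.

    Parameters
    ----------
    data : ChannelData
        Observed traces (n_emitters, n_receivers, nt); dt must equal the
        simulation grid's dt.
    emitters, receivers : lists of TransducerElement
        Discretised (or discretisable) elements on ``grid``.
    grid : CartesianGrid
    pulse : Pulse
        The excitation used during acquisition.
    medium : AcousticMedium
        Starting model; its SOS volume is the initial guess and its
        attenuation/density volumes are held fixed (two-region heuristic).
    """

    def __init__(self, data: ChannelData, emitters, receivers,
                 grid: CartesianGrid, pulse: Pulse, medium: AcousticMedium,
                 config: InversionConfig = None):
        self.data = data
        self.grid = grid
        self.pulse = pulse
        self.config = config or InversionConfig()
        self.medium0 = medium.copy()
        if data.traces.shape[2] != grid.nt:
            raise ValueError(f"data nt {data.traces.shape[2]} != grid.nt {grid.nt}")
        if abs(data.dt - grid.dt) > 1e-12 * grid.dt:
            raise ValueError("data dt inconsistent with grid dt")
        self.emitters = [
            e if e.is_discretized else
            discretize_aperture(e, grid, pml_size=self.config.pml_size)
            for e in emitters]
        self.receivers = [
            r if r.is_discretized else
            discretize_aperture(r, grid, pml_size=self.config.pml_size)
            for r in receivers]
        if data.traces.shape[0] != len(self.emitters):
            raise ValueError("data emitter count != number of emitter elements")
        if data.traces.shape[1] != len(self.receivers):
            raise ValueError("data receiver count != number of receiver elements")
        self._rec_vox = np.unique(np.concatenate(
            [r.segment_indices for r in self.receivers]))
        # per-emitter injected segment series, reused across iterations
        self._emitter_sources = [inject(pulse, e, grid) for e in self.emitters]

    # -- forward modelling -------------------------------------------------
    def _encoded_source(self, w: EncodingVector) -> SourceField:
        src = SourceField(self.grid)
        for wi, es in zip(w.weights, self._emitter_sources):
            for k, v in es.entries.items():
                src.add_point(k, wi * v)
        return src

    def _medium_with(self, sos: np.ndarray) -> AcousticMedium:
        med = self.medium0.copy()
        med.sos = np.asarray(sos, dtype=float)
        return med

    def _sample_all(self, result) -> np.ndarray:
        return np.vstack([sample(result, r) for r in self.receivers])

    @property
    def _c_ref(self) -> float:
        return self.config.c_ref or self.config.bounds[1]

    def simulate_emitter(self, i: int, sos: np.ndarray = None) -> np.ndarray:
        """Noise-free forward data (R, nt) for one emitter."""
        med = self._medium_with(self.medium0.sos if sos is None else sos)
        res = simulate(med, self._emitter_sources[i], self.grid,
                       record_voxels=self._rec_vox,
                       pml_size=self.config.pml_size,
                       dtype=self.config.solver_dtype, c_ref=self._c_ref)
        return self._sample_all(res)

    def full_objective(self, sos: np.ndarray) -> float:
        """Non-encoded objective sum_i 1/2 ||g_i(c) - g_i_obs||^2."""
        total = 0.0
        for i in range(len(self.emitters)):
            g = self.simulate_emitter(i, sos)
            total += 0.5 * float(np.sum((g - self.data.traces[i]) ** 2))
        return total

    def _tv_gradient(self, sos: np.ndarray, eps: float = 1e-3) -> np.ndarray:
        g = np.zeros_like(sos)
        for ax in range(3):
            d = np.diff(sos, axis=ax)
            e = d / np.sqrt(d ** 2 + eps ** 2)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(0, -1)
            sl_hi[ax] = slice(1, None)
            g[tuple(sl_lo)] -= e
            g[tuple(sl_hi)] += e
        return g

    # -- optimisation ------------------------------------------------------
    def fit(self, seed: int = None, initial_sos: np.ndarray = None,
            callback=None) -> InversionResult:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        sos = np.array(initial_sos if initial_sos is not None
                       else self.medium0.sos, dtype=float)
        m = np.zeros_like(sos)
        v = np.zeros_like(sos)
        history = []
        stop = "max_iterations"
        n_run = 0
        best = np.inf
        worse = 0
        t0 = time.perf_counter()
        for it in range(cfg.n_iterations):
            w = rademacher_vector(len(self.emitters), rng)
            g_w_obs = encode(self.data.traces, w)
            src = self._encoded_source(w)
            med = self._medium_with(sos)
            fwd = simulate(med, src, self.grid, record_voxels=self._rec_vox,
                           record_full=True, pml_size=cfg.pml_size,
                           dtype=cfg.solver_dtype, c_ref=self._c_ref)
            g_sim = self._sample_all(fwd)
            residual = g_sim - g_w_obs
            j_val = 0.5 * float(np.sum(residual ** 2))
            history.append(j_val)
            n_run = it + 1
            if j_val <= 1e-12 * 0.5 * float(np.sum(g_w_obs ** 2)):
                # data already explained at numerical precision: any
                # "gradient" is rounding noise, do not walk on it
                stop = "converged: misfit at numerical precision"
                break

            adj_src = adjoint_source(residual, self.receivers, self.grid)
            adj = solver_adjoint_run(med, adj_src, self.grid,
                                     pml_size=cfg.pml_size,
                                     dtype=cfg.solver_dtype,
                                     c_ref=self._c_ref)
            grad = sos_gradient(sos, fwd.wavefield, adj.wavefield, self.grid.dt)
            if cfg.illumination_weight > 0:
                illum = np.sum(fwd.wavefield.astype(np.float64) ** 2,
                               axis=1).reshape(sos.shape)
                grad = grad / (illum / max(illum.max(), 1e-300)
                               + cfg.illumination_weight)
            if cfg.regularization_weight > 0:
                grad = grad + cfg.regularization_weight * self._tv_gradient(sos)

            # Adam with projection onto the physical bounds; eps is scaled
            # to the gradient magnitude so the update is invariant to the
            # (arbitrary) absolute scale of the traces
            m = cfg.adam_beta1 * m + (1 - cfg.adam_beta1) * grad
            v = cfg.adam_beta2 * v + (1 - cfg.adam_beta2) * grad ** 2
            mh = m / (1 - cfg.adam_beta1 ** (it + 1))
            vh = v / (1 - cfg.adam_beta2 ** (it + 1))
            denom = np.sqrt(vh)
            eps = cfg.adam_eps * max(float(denom.max()), 1e-300)
            sos = sos - cfg.step_size * mh / (denom + eps)
            np.clip(sos, cfg.bounds[0], cfg.bounds[1], out=sos)

            if callback is not None:
                callback(it, sos, j_val)
            if cfg.verbose:
                print(f"iter {it:3d}  J_w = {j_val:.6g}")
            # divergence guard on the smoothed objective: the encoded
            # misfit fluctuates across encoding draws by design, so only a
            # sustained rise of the moving average counts
            window = np.mean(history[-5:])
            if window < best:
                best = window
                worse = 0
            elif window > 2.0 * best:
                worse += 1
                if worse >= cfg.patience:
                    stop = ("smoothed objective grew beyond twice its best "
                            f"value for {cfg.patience} consecutive "
                            "iterations (divergence guard)")
                    break
            else:
                worse = 0
            if not np.isfinite(j_val):
                stop = "non-finite objective (divergence)"
                break
        return InversionResult(sos=sos, objective_history=np.asarray(history),
                               grid=self.grid, config=cfg, n_iterations=n_run,
                               stop_reason=stop,
                               runtime=time.perf_counter() - t0)


def combine_ring_estimates(volumes, weights=None) -> np.ndarray:
    """Combine coarse SOS estimates from several ring elevations.

    Multi-ring acquisitions give one coarse reconstruction per elevation;
    the fine-grid initial guess is their (optionally weighted) voxelwise
    average.  ``weights`` may be per-volume scalars or per-volume weight
    volumes (e.g. vertical sensitivity profiles broadcast over the grid).
    """
    volumes = [np.asarray(v, dtype=float) for v in volumes]
    if not volumes:
        raise ValueError("at least one volume is required")
    if weights is None:
        weights = [np.ones_like(volumes[0])] * len(volumes)
    weights = [np.broadcast_to(np.asarray(w, dtype=float),
                               volumes[0].shape) for w in weights]
    if len(weights) != len(volumes):
        raise ValueError("one weight (volume) per estimate is required")
    num = sum(w * v for w, v in zip(weights, volumes))
    den = sum(weights)
    if np.any(den <= 0):
        raise ValueError("combined weights must be positive everywhere")
    return num / den


# ---------------------------------------------------------------------------
# two-step coarse-to-fine driver
# ---------------------------------------------------------------------------

def _coarsen_problem(data: ChannelData, emitters, receivers,
                     grid: CartesianGrid, pulse: Pulse,
                     medium: AcousticMedium, cutoff: float,
                     pml_size: int):
    """Restrict the whole problem by a factor of two in space and time."""
    if any(n % 2 for n in grid.shape):
        raise ValueError("coarse stage needs an even grid shape")
    # drop a trailing time sample if needed so the step count halves evenly
    nt_even = ((grid.nt - 1) // 2) * 2 + 1
    cgrid = CartesianGrid(shape=tuple(n // 2 for n in grid.shape),
                          spacing=grid.spacing * 2, dt=grid.dt * 2,
                          nt=(nt_even - 1) // 2 + 1, origin=grid.origin)
    lp = lowpass_traces(data.traces, data.dt, cutoff)[:, :, :nt_even:2]
    cdata = ChannelData(lp, dt=data.dt * 2, emitter_ids=data.emitter_ids,
                        receiver_ids=data.receiver_ids, ring_z=data.ring_z)
    cpulse = Pulse(lowpass_traces(pulse.samples, pulse.dt, cutoff)[::2],
                   dt=pulse.dt * 2, center_frequency=pulse.center_frequency,
                   max_frequency=min(pulse.max_frequency, cutoff))
    y = medium.power_law_exponent
    cmed = AcousticMedium(
        sos=restrict_volume(medium.sos),
        attenuation=restrict_volume(medium.attenuation),
        density=restrict_volume(medium.density),
        power_law_exponent=(restrict_volume(y) if isinstance(y, np.ndarray)
                            and np.ndim(y) == 3 else y),
        ambient_density=medium.ambient_density)
    half_pml = max(2, pml_size // 2)
    cem = [discretize_aperture(replace(e, segment_indices=None,
                                       segment_delays=None,
                                       segment_weights=None), cgrid,
                               pml_size=half_pml) for e in emitters]
    crec = [discretize_aperture(replace(r, segment_indices=None,
                                        segment_delays=None,
                                        segment_weights=None), cgrid,
                                pml_size=half_pml) for r in receivers]
    return cdata, cem, crec, cgrid, cpulse, cmed, half_pml


def reconstruct(observed: ChannelData, emitters, receivers,
                grid: CartesianGrid, pulse: Pulse, medium0: AcousticMedium,
                config: InversionConfig = None, seed: int = None) -> InversionResult:
    """Two-step coarse-to-fine source-encoded FWI driver.

    Step 1 (optional, ``config.coarse_iterations > 0``): invert low-passed,
    time-decimated data on a 2x coarser grid starting from the supplied
    (typically homogeneous water) model.  Step 2: prolong the coarse SOS
    estimate to the fine grid and refine with the full-band data.
    """
    config = config or InversionConfig()
    stages = []
    initial = None
    if config.coarse_iterations > 0:
        cutoff = config.coarse_lowpass_fraction * pulse.max_frequency
        cdata, cem, crec, cgrid, cpulse, cmed, cpml = _coarsen_problem(
            observed, emitters, receivers, grid, pulse, medium0, cutoff,
            config.pml_size)
        ccfg = replace(config, n_iterations=config.coarse_iterations,
                       coarse_iterations=0, pml_size=cpml)
        cmodel = WaveformInversion(cdata, cem, crec, cgrid, cpulse, cmed,
                                   config=ccfg)
        cres = cmodel.fit(seed=seed)
        stages.append(cres)
        initial = prolong_volume(cres.sos)
    model = WaveformInversion(observed, emitters, receivers, grid, pulse,
                              medium0, config=replace(config,
                                                      coarse_iterations=0))
    res = model.fit(seed=None if seed is None else seed + 1,
                    initial_sos=initial)
    res.stages = stages
    return res
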