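"""Desk-scale reference studies.

The full-size validation and imaging experiments (metre-scale grids,
128 x 1024 channels) are cluster jobs; the studies here reproduce the same
physics in configurations sized for a single CPU:

* :func:`lens_validation_study` — k-space simulation of a lens-focused
  line emitter in homogeneous water versus the Rayleigh-Sommerfeld
  semianalytic solution; reports the maximum normalised difference of the
  focal-plane maximum-amplitude maps (the oracle-agreement statistic).
* :func:`sensitivity_fwhm_study` — vertical sensitivity profile of a
  diametrically opposed focused pair and its full width at half maximum.
* :func:`make_recovery_problem` / :func:`run_recovery_study` — a
  64 x 64 x 32 single-inclusion phantom imaged by a 16-emitter /
  64-receiver ring, reconstructed by source-encoded FWI; optionally with a
  deliberately distorted (10% overestimated) lens curvature in the
  reconstruction operators to probe robustness to transducer model error.

All geometric ratios (lens f-number, band edge at three points per
wavelength, pulse max/centre frequency ratio of 1.75) mirror the full-size
system.
"""

from __future__ import annotations

import numpy as np

from .fwi import (InversionConfig, WaveformInversion, rel_rmse)
from .grids import CartesianGrid, make_grid
from .media import water_medium
from .phantoms import Inclusion, PhantomSpec, build_phantom
from .pulses import tone_burst_pulse
from .rayleigh import ApertureQuadrature, max_amplitude_map, rs_pressure
from .sensitivity import profile_fwhm, sensitivity_map
from .solver import simulate, source_time_correction
from .transducer import (ChannelData, LensProfile, TransducerElement,
                         discretize_aperture, inject, sample)

__all__ = [
    "lens_validation_study",
    "sensitivity_fwhm_study",
    "make_recovery_problem",
    "run_recovery_study",
]

C0 = 1500.0
RHO0 = 1000.0


def lens_validation_study(fast: bool = False, pml_size: int = 12,
                          dtype=np.float32) -> dict:
    """Lens-focused emitter versus the Rayleigh-Sommerfeld oracle.

    A 10 mm line emitter with a parabolic lens (elevation focal length
    40 mm, f-number 4 — the full-size lens scaled) radiates a 0.75 MHz
    centre / 1.25 MHz band-edge pulse into homogeneous water sampled at
    0.4 mm (three points per wavelength at the band edge, CFL 0.3).
    Maximum-amplitude maps over the vertical plane through the element
    axis are compared pointwise, normalised by the on-axis semianalytic
    maximum; the maximum normalised difference is reported in percent.

    ``fast=True`` shrinks the domain and map for smoke testing; the
    reported statistic is then looser but the protocol is identical.
    """
    dx = 0.4e-3
    if fast:
        shape = (128, 48, 64)
        origin = (-6.4e-3, -9.6e-3, -12.8e-3)
        x_map = (12e-3, 36e-3)
        z_half = 6e-3
        t_end = 36e-6
    else:
        shape = (192, 72, 96)
        origin = (-6.4e-3, -14.4e-3, -19.2e-3)
        x_map = (20e-3, 56e-3)
        z_half = 12e-3
        t_end = 50e-6
    grid = make_grid(shape, dx, c_max=C0, cfl=0.3, duration=t_end,
                     origin=origin)
    pulse = tone_burst_pulse(0.75e6, grid.dt, max_frequency=1.25e6)

    height = 10.0e-3                      # 25 voxel segments (odd: exact snap)
    focal = 40.0e-3
    lens = LensProfile(curvature=4500.0 / (focal * (4500.0 - C0)),
                       offset=0.45e-3, lens_sos=4500.0, medium_sos=C0)
    element = discretize_aperture(
        TransducerElement(center=(0.0, 0.0, 0.0), height=height, lens=lens),
        grid, pml_size=pml_size)

    medium = water_medium(grid.shape)
    src = source_time_correction(inject(pulse, element, grid))

    # map lattice: every second voxel over the focal plane y = 0
    ix = np.arange(*[int(round((x - origin[0]) / dx)) for x in x_map], 2)
    iz_half = int(round(z_half / dx))
    iz0 = int(round(-origin[2] / dx))
    iz = np.arange(iz0 - iz_half, iz0 + iz_half + 1, 2)
    iy0 = int(round(-origin[1] / dx))
    IX, IZ = np.meshgrid(ix, iz, indexing="ij")
    flat = np.ravel_multi_index(
        (IX.ravel(), np.full(IX.size, iy0), IZ.ravel()), grid.shape)

    res = simulate(medium, src, grid, record_voxels=flat, pml_size=pml_size,
                   dtype=dtype, smooth_sources=True)
    map_solver = max_amplitude_map(res.traces, envelope=True).reshape(IX.shape)

    quad = ApertureQuadrature.from_element(
        element, min_wavelength=C0 / pulse.max_frequency,
        points_per_wavelength=8.0)
    xs = origin[0] + ix * dx
    zs = origin[2] + iz * dx
    pts = np.column_stack([np.repeat(xs, len(zs)),
                           np.zeros(IX.size),
                           np.tile(zs, len(xs))])
    traces_rs = rs_pressure(quad, pulse.samples, C0, RHO0, pts, grid.times,
                            dt=grid.dt)
    map_oracle = max_amplitude_map(traces_rs, envelope=True).reshape(IX.shape)

    on_axis = np.argmin(np.abs(zs))
    m1 = map_solver / map_solver[:, on_axis].max()
    m0 = map_oracle / map_oracle[:, on_axis].max()
    diff = np.abs(m1 - m0)
    return {
        "value_percent": float(diff.max() * 100.0),
        "solver_map": m1, "oracle_map": m0, "xs": xs, "zs": zs,
        "n": int(np.prod(shape)),
    }


def sensitivity_fwhm_study(z_max: float = 4.8e-3, z_step: float = 0.8e-3,
                           pml_size: int = 12, cfl: float = 0.45,
                           dtype=np.float32) -> dict:
    """Vertical sensitivity FWHM of a focused emitter-receiver pair.

    Desk-scale variant of the pair-sensitivity characterisation: 0.4 mm
    voxels, a 64 mm diametrical separation, 10 mm elements whose lenses
    focus at the midpoint, a 0.6 MHz centre / 1.05 MHz band-edge pulse,
    and a Gaussian speed-of-sound target (c1 = 70 m/s, sigma = 0.8 mm)
    moved vertically through the midpoint at half the full-study lattice
    density (0.8 mm steps).  The profile is symmetric in z, so only
    z >= 0 is simulated and the width is doubled.
    """
    dx = 0.4e-3
    sep = 64e-3
    grid = make_grid((192, 64, 80), dx, c_max=C0 + 70.0, cfl=cfl,
                     duration=54e-6,
                     origin=(-38.4e-3, -12.8e-3, -16.0e-3))
    pulse = tone_burst_pulse(0.6e6, grid.dt, max_frequency=1.05e6)
    focal = sep / 2.0
    lens = LensProfile(curvature=4500.0 / (focal * (4500.0 - C0)),
                       offset=0.45e-3, lens_sos=4500.0, medium_sos=C0)
    height = 10.0e-3
    emitter = discretize_aperture(
        TransducerElement((-sep / 2, 0.0, 0.0), height, lens), grid,
        pml_size=pml_size)
    receiver = discretize_aperture(
        TransducerElement((+sep / 2, 0.0, 0.0), height, lens), grid,
        pml_size=pml_size)
    medium = water_medium(grid.shape)

    z = np.arange(0.0, z_max + z_step / 2, z_step)
    lattice = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    smap = sensitivity_map(emitter, receiver, medium, grid, pulse, lattice,
                           c1=70.0, sigma=0.8e-3, pml_size=pml_size,
                           solver_kwargs={"dtype": dtype})
    fwhm = profile_fwhm(z, smap.values, mirrored=True)
    return {"fwhm_mm": fwhm * 1e3, "z_mm": z * 1e3, "S": smap.values,
            "map": smap, "n": len(z)}


# ---------------------------------------------------------------------------
# parameter-recovery (FWI) study
# ---------------------------------------------------------------------------

def _ring_elements(n: int, radius: float, height: float, lens: LensProfile,
                   grid: CartesianGrid, pml_size: int):
    out = []
    for k in range(n):
        a = 2 * np.pi * k / n
        c = (radius * np.cos(a), radius * np.sin(a), 0.0)
        out.append(discretize_aperture(
            TransducerElement(c, height, lens), grid, pml_size=pml_size))
    return out


def make_recovery_problem(n_emitters: int = 16, n_receivers: int = 64,
                          pml_size: int = 8, distorted_lens: bool = False,
                          dtype=np.float32, observed: ChannelData = None):
    """Build the 64 x 64 x 32 single-inclusion ring imaging problem.

    Returns a dict with observed ChannelData (noise-free), the element
    lists used for reconstruction (optionally with a lens whose curvature
    is overestimated by 10%), grid, pulse, starting medium (homogeneous
    water), the true SOS volume and the inclusion support mask.
    """
    dx = 0.8e-3
    grid = make_grid((64, 64, 32), dx, c_max=1540.0, cfl=0.4,
                     duration=34e-6,
                     origin=(-25.6e-3, -25.6e-3, -12.8e-3))
    pulse = tone_burst_pulse(0.30e6, grid.dt, max_frequency=0.625e6)
    radius = 16e-3
    height = 5.6e-3                       # 7 voxel segments
    focal = radius
    a_true = 4500.0 / (focal * (4500.0 - C0))
    lens_true = LensProfile(curvature=a_true, offset=0.45e-3,
                            lens_sos=4500.0, medium_sos=C0)

    spec = PhantomSpec(inclusions=(
        Inclusion("ellipsoid", center=(3e-3, -2e-3, 0.0),
                  size=(6e-3, 5e-3, 4e-3), delta_sos=40.0,
                  label="recovery-inclusion"),
    ))
    true_medium = build_phantom(spec, grid)
    c_true = true_medium.sos.copy()
    mask = c_true > C0 + 1.0

    emitters = _ring_elements(n_emitters, radius, height, lens_true, grid,
                              pml_size)
    receivers = _ring_elements(n_receivers, radius, height, lens_true, grid,
                               pml_size)
    if observed is None:
        rec_vox = np.unique(np.concatenate(
            [r.segment_indices for r in receivers]))
        traces = np.zeros((n_emitters, n_receivers, grid.nt),
                          dtype=np.float64)
        for i, em in enumerate(emitters):
            res = simulate(true_medium, inject(pulse, em, grid), grid,
                           record_voxels=rec_vox, pml_size=pml_size,
                           dtype=dtype, c_ref=1540.0)
            traces[i] = np.vstack([sample(res, r) for r in receivers])
        observed = ChannelData(traces, dt=grid.dt)

    if distorted_lens:
        lens_rec = LensProfile(curvature=1.1 * a_true, offset=0.45e-3,
                               lens_sos=4500.0, medium_sos=C0)
        emitters = _ring_elements(n_emitters, radius, height, lens_rec, grid,
                                  pml_size)
        receivers = _ring_elements(n_receivers, radius, height, lens_rec,
                                   grid, pml_size)

    medium0 = water_medium(grid.shape)
    return {
        "observed": observed, "emitters": emitters, "receivers": receivers,
        "grid": grid, "pulse": pulse, "medium0": medium0,
        "c_true": c_true, "c0": np.full(grid.shape, C0),
        "inclusion_mask": mask,
    }


def run_recovery_study(seed: int = 0, n_iterations: int = 50,
                       distorted_lens: bool = False, step_size: float = 10.0,
                       problem: dict = None) -> dict:
    """Source-encoded FWI parameter recovery on the ring phantom."""
    prob = problem or make_recovery_problem(distorted_lens=distorted_lens)
    cfg = InversionConfig(n_iterations=n_iterations, step_size=step_size,
                          pml_size=8, seed=seed, c_ref=1540.0)
    model = WaveformInversion(prob["observed"], prob["emitters"],
                              prob["receivers"], prob["grid"], prob["pulse"],
                              prob["medium0"], config=cfg)
    result = model.fit(seed=seed)
    rr = rel_rmse(result.sos, prob["c_true"], prob["c0"])
    mask = prob["inclusion_mask"]
    incl_mean = float(result.sos[mask].mean())
    incl_true = float(prob["c_true"][mask].mean())
    return {
        "result": result, "rel_rmse": rr,
        "inclusion_mean": incl_mean, "inclusion_true": incl_true,
        "inclusion_mean_error": abs(incl_mean - incl_true),
        "problem": prob,
    }
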