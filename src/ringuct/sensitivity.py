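"""Sensitivity maps of focused emitter-receiver pairs.

The sensitivity of a pair to a point-like speed-of-sound perturbation at
location r is quantified as the normalised energy of the change in the
received trace,

    S(r) = int (p_r(t) - p_0(t))^2 dt / int p_0(t)^2 dt,

where p_0 is the trace for the homogeneous background and p_r the trace
after inserting a small Gaussian SOS target at r.  The map visualises the
thin region near the elevation focus that a pair effectively interrogates;
one forward simulation is needed per target location (time integrals use
the trapezoid rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import CartesianGrid
from .media import AcousticMedium
from .pulses import Pulse
from .solver import simulate
from .transducer import TransducerElement, inject, sample

__all__ = ["SensitivityMap", "gaussian_target", "sensitivity_map",
           "profile_fwhm"]


def gaussian_target(medium: AcousticMedium, grid: CartesianGrid, r,
                    c1: float = 70.0, sigma: float = 0.8e-3,
                    pml_size: int = 10) -> AcousticMedium:
    """Insert a Gaussian SOS perturbation: c(r') += c1 exp(-|r'-r|^2/2 sigma^2).

    Other acoustic properties are untouched.  Raises if the target centre
    lies in the absorbing boundary.
    """
    idx = grid.nearest_index(r)
    if not grid.contains_index(idx, margin=pml_size):
        raise ValueError(
            f"target centre {tuple(r)} lies inside the absorbing boundary")
    out = medium.copy()
    if c1 == 0.0:
        return out
    x = grid.axis_coords(0)[:, None, None]
    y = grid.axis_coords(1)[None, :, None]
    z = grid.axis_coords(2)[None, None, :]
    r = np.asarray(r, dtype=float)
    q = (x - r[0]) ** 2 + (y - r[1]) ** 2 + (z - r[2]) ** 2
    out.sos = out.sos + c1 * np.exp(-q / (2.0 * sigma ** 2))
    return out


@dataclass
class SensitivityMap:
    """S(r) samples on a target lattice, with the pair configuration."""

    positions: np.ndarray        # (P, 3)
    values: np.ndarray           # (P,)
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))

    def vertical_profile(self, atol: float = 1e-9):
        """(z, S) along the vertical line through the first lattice column."""
        ref = self.positions[0, :2]
        mask = np.all(np.abs(self.positions[:, :2] - ref) < atol, axis=1)
        z = self.positions[mask, 2]
        order = np.argsort(z)
        return z[order], self.values[mask][order]

    def plot(self, ax=None):  # pragma: no cover - thin plotting helper
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        z, s = self.vertical_profile()
        ax.plot(z * 1e3, s, "o-")
        ax.set_xlabel("elevation z [mm]")
        ax.set_ylabel("S(r)")
        return ax


def sensitivity_map(emitter: TransducerElement, receiver: TransducerElement,
                    medium: AcousticMedium, grid: CartesianGrid, pulse: Pulse,
                    target_lattice, c1: float = 70.0, sigma: float = 0.8e-3,
                    baseline_trace: np.ndarray = None, pml_size: int = 10,
                    solver_kwargs: dict = None) -> SensitivityMap:
    """Compute S on a lattice of target positions (one simulation each)."""
    target_lattice = np.atleast_2d(np.asarray(target_lattice, dtype=float))
    solver_kwargs = dict(solver_kwargs or {})
    solver_kwargs.setdefault("pml_size", pml_size)
    # all runs must share the k-space reference speed: otherwise the
    # baseline and perturbed propagators differ numerically everywhere and
    # the difference-energy statistic picks that up
    solver_kwargs.setdefault("c_ref", medium.c_max + max(c1, 0.0))
    src = inject(pulse, emitter, grid)
    rec_vox = receiver.segment_indices

    if target_lattice.size == 0:
        return SensitivityMap(np.zeros((0, 3)), np.zeros(0),
                              {"c1": c1, "sigma": sigma})

    if baseline_trace is None:
        res0 = simulate(medium, src, grid, record_voxels=rec_vox,
                        **solver_kwargs)
        baseline_trace = sample(res0, receiver)
    p0 = np.asarray(baseline_trace, dtype=float)
    denom = np.trapezoid(p0 ** 2, dx=grid.dt)
    if denom <= 0:
        raise ValueError("baseline trace has zero energy; the pair records "
                         "no signal on this grid/time horizon")

    values = np.zeros(len(target_lattice))
    for i, r in enumerate(target_lattice):
        med_r = gaussian_target(medium, grid, r, c1=c1, sigma=sigma,
                                pml_size=pml_size)
        res = simulate(med_r, src, grid, record_voxels=rec_vox,
                       **solver_kwargs)
        pr = sample(res, receiver)
        values[i] = np.trapezoid((pr - p0) ** 2, dx=grid.dt) / denom

    return SensitivityMap(target_lattice, values,
                          {"c1": c1, "sigma": sigma,
                           "emitter": tuple(emitter.center),
                           "receiver": tuple(receiver.center)})


def profile_fwhm(z: np.ndarray, s: np.ndarray, mirrored: bool = False) -> float:
    """Full width at half maximum of a sampled profile (linear interpolation).

    With ``mirrored=True`` the profile is the non-negative half of an even
    function (z >= 0) and the width is twice the half-width.
    """
    z = np.asarray(z, dtype=float)
    s = np.asarray(s, dtype=float)
    order = np.argsort(z)
    z, s = z[order], s[order]
    peak = s.max()
    half = peak / 2.0
    i_pk = int(np.argmax(s))

    def _cross(zs, ss):
        """First downward half crossing walking away from the peak."""
        for a in range(len(ss) - 1):
            if ss[a] >= half > ss[a + 1]:
                f = (ss[a] - half) / (ss[a] - ss[a + 1])
                return zs[a] + f * (zs[a + 1] - zs[a])
        raise ValueError("profile does not fall below half maximum; "
                         "extend the lattice")

    right = _cross(z[i_pk:], s[i_pk:])
    if mirrored:
        return 2.0 * abs(right - z[i_pk])
    left = _cross(z[i_pk::-1], s[i_pk::-1])
    return float(right - left)
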