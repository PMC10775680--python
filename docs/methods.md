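# Methods

This note documents the numerical methods implemented in `ringuct`, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic studies do and do not demonstrate.

## Wave model and solver

The acoustic model is the lossy second-order wave equation for pressure
`p(r, t)` in a heterogeneous medium described by speed of sound `c(r)`,
density `ρ(r)`, power-law attenuation prefactor `α(r)` and power-law
exponent `y`:

    (1/c²) p_tt − ρ ∇·(1/ρ)∇p + L ∇²p = s,
    L = μ ∂_t (−∇²)^{y/2−1} + η (−∇²)^{(y−1)/2},
    μ = −2αc^{y−1},   η = 2αc^y tan(πy/2).

The fractional Laplacians realise power-law frequency-dependent absorption
`a(ω) = α ω^y` together with the dispersion required by causality
(Kramers–Kronig). Attenuation is stored internally in Np/((rad/s)^y·m);
the constructor `AcousticMedium.from_tissue_units` accepts the tissue
convention dB/(MHz^y·cm). `y` must satisfy 0 < y < 3, y ≠ 1, and must be
spatially uniform for the solver (the fractional powers are global
wavenumber multipliers; the same restriction applies in comparable
pseudospectral codes).

The solver integrates the equivalent first-order system (particle
velocity / split acoustic density / pressure) with leapfrog time
staggering. Spatial derivatives are spectral with the k-space correction
`κ = sinc(c_ref |k| Δt / 2)`, `c_ref = max(c)` by default; for homogeneous
media this makes the discrete dispersion relation exact (`2 − 4 sin²(c|k|Δt/2)
= 2 cos(c|k|Δt)`) at any CFL ≤ 1, which the single-mode test verifies to
machine precision. The grids are unstaggered in space: the spectral
derivative operators are then exactly antisymmetric, so acoustic
reciprocity and the adjoint dot-product identity hold to rounding error —
a property the inversion machinery relies on. Forcing is a mass source:
the per-voxel forcing series `x(t)` (the right-hand side of the
second-order equation) is integrated once in time to a mass rate and added
to the split density.

**Boundaries.** A split-field PML (default 10–12 voxels, quartic
absorption ramp, strength `pml_alpha·c_ref/Δx` with `pml_alpha = 2`)
absorbs outgoing waves; `pml_size=0` gives periodic boundaries, used by
the operator-level property tests (energy conservation, adjoint identity).

**Numerical accuracy of sources.** Two effects matter when absolute field
accuracy against analytic solutions is required:

1. A raw voxel delta carries wavenumber content to the corner of the
   wavenumber cube; its sharp truncation radiates a weak spurious coherent
   arrival (∼10% of the direct wave at 10–20 wavelengths in our
   measurements). `simulate(..., smooth_sources=True)` band-limits the
   injected source in k-space with a separable window that is exactly 1 up
   to 0.70 of Nyquist (all propagating content of a 3-points-per-wavelength
   pulse is untouched) and rolls off as cos⁴ to zero at 0.95 of Nyquist.
2. The leapfrog source coupling scales the continuous response by
   `1/(sinc(ωΔt)·sinc(ωΔt/2))` (resonant-mode coupling and rectangle-rule
   integration of the mass rate; the phases of the two factors cancel, so
   there is no net latency). `source_time_correction` applies the
   zero-phase inverse filter.

With both enabled the point-source field matches the analytic spherical
wave to a few parts in 10⁴ in-band, and the lens-focused validation study
(below) reaches 0.085% of the focal maximum. Both corrections are optional
and off by default: inversion studies use the same (uncorrected) operators
for data generation and reconstruction, so the corrections cancel there.
Maximum-amplitude maps are evaluated on the analytic-signal envelope, which
removes the ±2% half-sample aliasing of a discrete max over a carrier; the
identical metric is applied to solver and oracle.

**Absorption accuracy.** The plane-wave attenuation follows `α ω^y` with
two small deviations: an O(Δt) bias (−1.5% at CFL 0.3, −0.3% at CFL 0.075
in our measurements) and a genuine second-order absorption×dispersion
cross term of the fractional-Laplacian model itself, ≈ −2% at a total path
attenuation of 0.8 Np and proportional to α. The attenuation test
therefore uses a small α (0.33 Np over the measured path) and CFL 0.15.

**A consistency rule.** Any statistic built from the *difference* of two
simulations (sensitivity maps, FWI residuals) must run both simulations
with the same `c_ref`: tying `c_ref` to each medium's own maximum changes
the discrete propagator everywhere and leaks numerical differences into
the physical signal. `sensitivity_map` and `WaveformInversion` pin a
common `c_ref` automatically.

## Lens-focused transducer operators

A ring-array element is a flat element of height `H` (default 18 mm)
behind a concave parabolic lens `d(z) = (a/2)z² + d0` (defaults
`a = 0.014 mm⁻¹`, `d0 = 0.45 mm`, `c_lens = 4500 m/s`). In the
geometrical-acoustics approximation the lens maps to the elevation time
advance `τ(z) = d(z)(1/c0 − 1/c_lens)` — thicker lens at the element edges
→ edges lead → elevation focusing with paraxial focal length
`F = c_lens/(a(c_lens − c0))` ≈ 107 mm at the defaults. The constant
`τ(0) = d0(1/c0 − 1/c_lens)` (0.2 µs) is retained as-is; it shifts every
trace equally.

On the grid the element width is neglected (high aspect ratio) and the
aperture becomes `N = round(H/Δx)` consecutive voxel segments on the
nearest column (exact half-spacing ties snap toward the smaller index).
Segment delays are evaluated at segment-centre elevation. Transmit injects
`w_k · D_{+τ_k} x` on segment k; receive forms `g = Σ_k w_k D_{+τ_k} p_k`.
`D_τ` is the FFT fractional delay `φ(t) → φ(t+τ)` (multiplier
`exp(+2πi f τ)` under numpy's transform convention; for even lengths the
unpaired Nyquist bin is scaled by `cos(2π f_N τ)` to keep real signals
real, so exact-unitarity tests use odd lengths). Apodization weights
default to 1; a `weights` callable hooks in lens-loss models.

Both transmit and receive *advance* by +τ — that is the physics of the
lens acting on outgoing and incoming wavefronts alike, and it makes
acoustic reciprocity exact. Note the transmit mapping is therefore *not*
the literal matrix transpose of the receive sampling; the two are
transposes conjugated by time reversal (`injectᵀ = T ∘ sample ∘ T`), which
is precisely the identity the adjoint-state formulation uses, and the form
in which the adjointness property is tested.

## Rayleigh–Sommerfeld oracle

For homogeneous lossless media the radiated field of a baffled aperture
with normal velocity `v̂(t + τ(r'))` is

    p(r,t) = ρ0 ∬_Ω v̂̇(t + τ(r') − |r−r'|/c0) / (2π|r−r'|) dr'.

The integral is evaluated by distributed point sources (≥ 8 per minimum
wavelength along the line aperture; refinement changes focal pressures by
< 0.05%), with retarded times applied as exact phase shifts in the
frequency domain (band-limited interpolation). The oracle is independent
of the solver code path and is only valid for homogeneous lossless media.

## Validation study (solver vs oracle)

The full-size validation (metre-scale grid, 18 mm element, 2 MHz) is a
cluster job; the packaged study uses a geometry chosen a priori to
preserve the governing ratios: 10 mm aperture (25 segments — odd, so the
element snaps to the grid without a half-voxel offset), elevation focal
length 40 mm, 0.75 MHz centre / 1.25 MHz band edge (the full-size
f_max/f_c = 1.75 and exactly 3 points per wavelength on 0.4 mm voxels),
CFL 0.3, 12-voxel PML. Maximum-envelope maps over the vertical plane
through the element axis (x ∈ [20, 56] mm, z ∈ [−12, 12] mm, 0.8 mm
sampling) are each normalised by their on-axis maximum and compared
pointwise; the packaged run measures a maximum difference of **0.085%**
(the test asserts < 0.1%). Separating the error sources: substituting the
25-segment quadrature into the oracle changes its map by only 0.09%, i.e.
aperture discretisation is not the limiter at this scale.

## Sensitivity maps

`S(r) = ∫(p_r − p_0)²dt / ∫p_0²dt` (trapezoid rule) with a Gaussian SOS
target `c(r') = c0 + c1·exp(−|r'−r|²/2σ²)`, defaults `c1 = 70 m/s`,
`σ = 0.8 mm` (peak 1570 m/s). One forward simulation per lattice point;
S is quadratic in `c1` in the Born regime. The desk-scale width study uses
0.4 mm voxels, a 64 mm diametrical separation with lenses focused at the
midpoint (F/H = 3.2, chosen a priori from the sinc⁴ two-way aperture
pattern convolved with the target — ≈ 0.63·λF/H, predicting a width of
roughly 5 mm; the packaged run measures 4.6 mm), a 0.6 MHz
pulse, CFL 0.45 (homogeneous background; the k-space correction keeps the
scheme accurate there), and half the full-study lattice density (0.8 mm
vertical steps, z ≥ 0 only — the profile is symmetric, verified separately
— with the width doubled from the half profile and the half-maximum
crossing linearly interpolated). The full-geometry map (220 mm separation,
0.2 mm voxels, 0.4 mm lattice) uses the same `sensitivity_map` API and is
a documented cluster job.

## Source-encoded FWI

Each iteration draws a fresh Rademacher vector `w`, forms the encoded data
`g_w = Σ w_i g_i` and encoded source `s_w = Σ w_i s_i` (valid by solver
linearity), simulates once forward (wavefield stored), forms the residual,
injects its time reversal through the receivers' delayed mappings, runs
one adjoint simulation, and assembles the SOS gradient

    [∇_c J]_k ∝ (1/c_k³) Σ_l q_{k, L−1−l} (p_{k,l−1} − 2p_{k,l} + p_{k,l+1}),

the correlation of the adjoint field (read backwards) with the second time
difference of the forward field. The implementation scales this sum by
2/Δt² so the returned array is the exact gradient of the discrete
least-squares objective — verified by central finite differences to < 1%
over two decades of step size (the classic continuous-adjoint writing
differs only by this constant, which any line search or Adam step
absorbs). The expression is exact for lossless media; in attenuating media
the neglected attenuation terms make it an approximation. Time reversal
maps sample `l → L−1−l` (0-based), making double reversal the identity.

The optimiser is Adam with projection onto physical bounds
([1300, 1700] m/s). Two scale-invariance details matter: `adam_eps` is
scaled by the current `max √v̂` (an absolute eps freezes the optimiser
when traces, and hence gradients, are numerically tiny), and the
divergence guard watches a 5-iteration moving average of the encoded
misfit (individual `J_w` values fluctuate across encoding draws by
design). A fit on data generated from the starting model itself stops
immediately ("misfit at numerical precision") without walking on rounding
noise. TV regularisation is available with weight 0 by default. The
two-step coarse-to-fine driver (`reconstruct`) optionally first inverts
2× restricted data (spectral low-pass at half the pulse band edge,
time-decimated, block-averaged media, re-discretised elements) and
prolongs the result to the fine grid; multi-ring acquisitions can be
combined by averaging independent coarse reconstructions.

## Recovery study

The packaged imaging experiment is a 64×64×32 grid at 0.8 mm with a
16-emitter / 64-receiver ring of radius 16 mm, 5.6 mm elements (7
segments) focused at the ring centre, a 0.30 MHz centre / 0.625 MHz
band-edge pulse (3 points per wavelength), CFL 0.4, and one +40 m/s
ellipsoidal inclusion (6×5×4 mm semi-axes) in water; data are noise-free
and reconstruction starts from homogeneous 1500 m/s with attenuation and
density fixed (the two-region heuristic reduces to uniform water here).
Contrast-to-wavelength and aperture-to-target ratios track the full-scale
breast configuration; 50 encoded iterations with a 10 m/s step (globally
normalised momentum descent, see above). The packaged run reaches
rel-RMSE ≈ 0.46 with the inclusion mean recovered within 8 m/s; the
companion robustness run reconstructs the same data with the lens
curvature overestimated by 10% in the reconstruction operators only.

What these synthetic studies show: correctness of the coupled
forward/adjoint machinery, convergence of the encoded objective, and
graceful degradation under transducer model error. What they do not show:
performance on anatomically realistic heterogeneity (real breast phantoms
have fine-scale SOS/attenuation/density texture and a curved boundary),
robustness to measurement noise at clinical SNR (the noise model exists
and is tested, but the recovery criterion runs noise-free), cycle-skipping
behaviour at clinical frequencies, or wall-clock performance at
1280×1280×216 scale.

## Known limitations

* In-plane directivity of the elements is not modelled (width is
  neglected); electrical impulse response is not modelled.
* The lens model is geometrical acoustics: no shear-wave conversion,
  refraction, lens attenuation or impedance mismatch (an apodization hook
  accepts user weights).
* The oracle covers homogeneous lossless media only.
* Uniform power-law exponent per simulation.
* Gradients are computed for SOS only; attenuation/density are held fixed
  during inversion.
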