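"""Source encoding, adjoint sources, the SOS gradient and the inversion
model object."""

import itertools

import numpy as np
import pytest

from ringuct import (ChannelData, EncodingVector, InversionConfig,
                     LensProfile, TransducerElement, WaveformInversion,
                     adjoint_source, discretize_aperture, encode, inject,
                     make_grid, rademacher_vector, rel_rmse, sample,
                     simulate, sos_gradient, tone_burst_pulse, water_medium)
from ringuct.fwi import lowpass_traces, prolong_volume, restrict_volume
from ringuct.solver import SourceField


class TestEncoding:
    def test_one_hot_selects_emitter(self, rng):
        g = rng.normal(size=(4, 3, 32))
        w = EncodingVector(np.array([0.0, 1.0, 0.0, 0.0]))
        np.testing.assert_array_equal(encode(g, w), g[1])

    def test_sign_flip_negates_data_keeps_misfit(self, rng):
        g = rng.normal(size=(4, 3, 32))
        sim = rng.normal(size=(4, 3, 32))
        w = rademacher_vector(4, rng)
        wm = EncodingVector(-w.weights)
        np.testing.assert_allclose(encode(g, wm), -encode(g, w))
        j1 = 0.5 * np.sum((encode(sim, w) - encode(g, w)) ** 2)
        j2 = 0.5 * np.sum((encode(sim, wm) - encode(g, wm)) ** 2)
        assert j1 == pytest.approx(j2, rel=1e-12)

    def test_exhaustive_rademacher_unbiasedness(self, rng):
        """Averaging the encoded misfit over all 2^3 sign vectors equals
        the sum of per-emitter misfits (cross terms cancel exactly)."""
        g = rng.normal(size=(3, 2, 16))
        sim = rng.normal(size=(3, 2, 16))
        total = 0.0
        vectors = list(itertools.product([-1.0, 1.0], repeat=3))
        for signs in vectors:
            w = EncodingVector(np.array(signs))
            total += 0.5 * np.sum((encode(sim, w) - encode(g, w)) ** 2)
        mean_encoded = total / len(vectors)
        per_emitter = sum(0.5 * np.sum((sim[i] - g[i]) ** 2)
                          for i in range(3))
        assert mean_encoded == pytest.approx(per_emitter, rel=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="encoding length"):
            encode(rng.normal(size=(4, 3, 8)), EncodingVector(np.ones(3)))

    def test_rademacher_entries(self, rng):
        w = rademacher_vector(64, rng)
        assert set(np.unique(w.weights)) <= {-1.0, 1.0}


def _flat_receiver(grid, n_voxels=3):
    lens = LensProfile(curvature=0.0, offset=0.0, lens_sos=1500.0,
                       medium_sos=1500.0)
    el = TransducerElement((0.0, 0.0, 0.0), n_voxels * grid.spacing, lens)
    return discretize_aperture(el, grid, pml_size=0)


class TestAdjointSource:
    def _grid(self):
        return make_grid((16, 16, 16), 0.8e-3, c_max=1500.0, cfl=0.3,
                         duration=3e-6, origin=(-6.4e-3, -6.4e-3, -6.4e-3))

    def test_zero_residual_zero_source(self):
        grid = self._grid()
        rec = _flat_receiver(grid)
        src = adjoint_source(np.zeros((1, grid.nt)), [rec], grid)
        assert all(np.all(v == 0) for v in src.entries.values())

    def test_spike_lands_at_reversed_index(self):
        grid = self._grid()
        rec = _flat_receiver(grid)
        L = grid.nt
        l = 5
        residual = np.zeros((1, L))
        residual[0, l] = 1.0
        src = adjoint_source(residual, [rec], grid)
        for v in src.entries.values():
            assert np.argmax(np.abs(v)) == L - 1 - l
    def test_double_reversal_restores(self, rng):
        r = rng.normal(size=(2, 33))
        np.testing.assert_array_equal(r[:, ::-1][:, ::-1], r)


class TestSosGradient:
    def test_zero_adjoint_zero_gradient(self, rng):
        p = rng.normal(size=(27, 16))
        g = sos_gradient(np.full((3, 3, 3), 1500.0), p,
                         np.zeros_like(p), 1e-7)
        np.testing.assert_array_equal(g, 0.0)

    def test_inverse_cubed_scaling(self, rng):
        p = rng.normal(size=(27, 16))
        q = rng.normal(size=(27, 16))
        c = np.full((3, 3, 3), 1500.0)
        g1 = sos_gradient(c, p, q, 1e-7)
        g2 = sos_gradient(2.0 * c, p, q, 1e-7)
        np.testing.assert_allclose(g2, g1 / 8.0, rtol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shapes differ"):
            sos_gradient(np.full((3, 3, 3), 1500.0),
                         rng.normal(size=(27, 16)),
                         rng.normal(size=(27, 15)), 1e-7)

    def test_finite_difference_agreement(self, rng):
        """Central finite differences of the discrete misfit match the
        adjoint-state gradient within 1% for epsilon spanning two decades,
        on an 8^3 periodic grid with a heterogeneous background."""
        grid = make_grid((8, 8, 8), 1e-3, c_max=1560.0, cfl=0.3,
                         duration=12e-6)
        i = np.arange(8)
        bump = np.exp(-((i[:, None, None] - 4) ** 2
                        + (i[None, :, None] - 4) ** 2
                        + (i[None, None, :] - 4) ** 2) / 8.0)
        c_bg = 1500.0 + 15.0 * bump          # heterogeneous background
        c_true = c_bg + 20.0 * np.roll(bump, 2, axis=0)
        c_ref = 1560.0
        series = np.zeros(grid.nt)
        series[3:23] = np.hanning(20) * np.sin(np.arange(20) * 0.9)
        i_src = grid.flat_index((2, 3, 2))
        i_rec = grid.flat_index((6, 5, 6))
        src = SourceField(grid)
        src.entries[i_src] = series

        def med(c):
            m = water_medium(grid.shape)
            m.sos = np.asarray(c, float).copy()
            return m

        def forward(c, full=False):
            return simulate(med(c), src, grid, record_voxels=[i_rec],
                            record_full=full, pml_size=0, c_ref=c_ref,
                            record_dtype=np.float64)

        g_obs = forward(c_true).traces

        def objective(c):
            return 0.5 * np.sum((forward(c).traces - g_obs) ** 2)

        fwd = forward(c_bg, full=True)
        residual = fwd.traces - g_obs
        adj = SourceField(grid)
        adj.entries[i_rec] = residual[0][::-1].copy()
        q = simulate(med(c_bg), adj, grid, pml_size=0, c_ref=c_ref,
                     record_full=True, record_dtype=np.float64)
        grad = sos_gradient(c_bg, fwd.wavefield, q.wavefield, grid.dt)
        dc = rng.normal(size=grid.shape)
        directional = float(np.sum(grad * dc))
        for eps in (1e-1, 1e-2, 1e-3):
            fd = (objective(c_bg + eps * dc)
                  - objective(c_bg - eps * dc)) / (2 * eps)
            assert fd == pytest.approx(directional, rel=0.01)


class TestHelpers:
    def test_lowpass_removes_high_band(self, rng):
        dt = 1e-7
        t = np.arange(256) * dt
        # integer cycle counts keep the circular filtering exact
        lo = np.sin(2 * np.pi * 12 / (256 * dt) * t)
        hi = np.sin(2 * np.pi * 64 / (256 * dt) * t)
        out = lowpass_traces(lo + hi, dt, cutoff=1.2e6)
        np.testing.assert_allclose(out, lo, atol=1e-10)

    def test_restrict_prolong_roundtrip_constant(self):
        v = np.full((8, 8, 4), 3.0)
        np.testing.assert_array_equal(prolong_volume(restrict_volume(v)), v)

    def test_combine_ring_estimates(self, rng):
        from ringuct.fwi import combine_ring_estimates
        a = np.full((4, 4, 2), 1500.0)
        b = np.full((4, 4, 2), 1540.0)
        np.testing.assert_allclose(combine_ring_estimates([a, b]), 1520.0)
        # z-dependent weights favouring the second ring
        wz = np.zeros((4, 4, 2)); wz[..., 1] = 1.0
        out = combine_ring_estimates([a, b], [np.ones_like(a), 1 + wz])
        np.testing.assert_allclose(out[..., 0], 1520.0)
        np.testing.assert_allclose(out[..., 1], (1500 + 2 * 1540) / 3)

    def test_rel_rmse_definition(self):
        c_true = np.array([1500.0, 1540.0])
        c0 = np.array([1500.0, 1500.0])
        c = np.array([1500.0, 1520.0])
        assert rel_rmse(c, c_true, c0) == pytest.approx(0.5)


class TestWaveformInversion:
    def _problem(self):
        grid = make_grid((32, 32, 16), 0.8e-3, c_max=1540.0, cfl=0.4,
                         duration=16e-6,
                         origin=(-12.8e-3, -12.8e-3, -6.4e-3))
        pulse = tone_burst_pulse(0.3e6, grid.dt, max_frequency=0.625e6)
        lens = LensProfile(curvature=4500.0 / (8e-3 * 3000.0),
                           offset=0.45e-3, lens_sos=4500.0, medium_sos=1500.0)
        radius = 8e-3
        def elems(n):
            out = []
            for k in range(n):
                a = 2 * np.pi * k / n + 0.1
                el = TransducerElement((radius * np.cos(a),
                                        radius * np.sin(a), 0.0),
                                       2.4e-3, lens)
                out.append(discretize_aperture(el, grid, pml_size=4))
            return out
        emitters, receivers = elems(2), elems(3)
        med = water_medium(grid.shape)
        rec_vox = np.unique(np.concatenate(
            [r.segment_indices for r in receivers]))
        traces = np.zeros((2, 3, grid.nt))
        for i, em in enumerate(emitters):
            res = simulate(med, inject(pulse, em, grid), grid,
                           record_voxels=rec_vox, pml_size=4,
                           dtype=np.float32, c_ref=1700.0)
            traces[i] = np.vstack([sample(res, r) for r in receivers])
        data = ChannelData(traces, dt=grid.dt)
        return data, emitters, receivers, grid, pulse, med

    def test_self_consistent_data_converges_immediately(self):
        """Observed data generated from the starting model itself: the
        misfit sits at numerical precision and the model is not updated."""
        data, em, rec, grid, pulse, med = self._problem()
        cfg = InversionConfig(n_iterations=3, pml_size=4, solver_dtype=np.float32)
        model = WaveformInversion(data, em, rec, grid, pulse, med,
                                  config=cfg)
        result = model.fit(seed=11)
        assert "converged" in result.stop_reason
        np.testing.assert_array_equal(result.sos, med.sos)
        assert result.objective_history[0] <= \
            1e-12 * 0.5 * np.sum(data.traces ** 2) * len(em)

    def test_summary_mentions_key_quantities(self):
        data, em, rec, grid, pulse, med = self._problem()
        cfg = InversionConfig(n_iterations=1, pml_size=4,
                              solver_dtype=np.float32)
        result = WaveformInversion(data, em, rec, grid, pulse, med,
                                   config=cfg).fit(seed=1)
        text = result.summary()
        for token in ("iterations", "misfit", "SOS estimate", "bounds"):
            assert token in text

    def test_two_step_coarse_to_fine_driver(self):
        """The coarse stage inverts restricted data and hands its
        prolonged estimate to the fine stage."""
        from ringuct import reconstruct
        data, em, rec, grid, pulse, med = self._problem()
        cfg = InversionConfig(n_iterations=2, coarse_iterations=2,
                              pml_size=4, solver_dtype=np.float32,
                              step_size=1.0)
        result = reconstruct(data, em, rec, grid, pulse, med, config=cfg,
                             seed=3)
        assert len(result.stages) == 1
        assert result.stages[0].grid.shape == tuple(n // 2 for n in grid.shape)
        assert result.sos.shape == grid.shape
        assert len(result.stages[0].objective_history) >= 1
        assert len(result.objective_history) >= 1

    def test_data_shape_validation(self):
        data, em, rec, grid, pulse, med = self._problem()
        with pytest.raises(ValueError, match="emitter count"):
            WaveformInversion(data, em[:1], rec, grid, pulse, med,
                              config=InversionConfig(pml_size=4))
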