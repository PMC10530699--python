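"""Network construction and LIF/SFA dynamics."""

import numpy as np
import pytest

from rulesrnn.params import SimulationParams
from rulesrnn.network import (
    NetworkState,
    build_dale_mask,
    decide_from_voltages,
    glorot_init,
    init_network,
    init_state,
    run_trial,
    simulate_batch,
    spectral_rescale,
    srnn_step,
)


class TestInit:
    def test_glorot_bound_default_size(self, rng):
        w = glorot_init(500, 500, rng)
        b = np.sqrt(6 / 1000)
        assert np.all(np.abs(w) < b)
        assert abs(b - 0.07746) < 1e-5
        # a uniform sample actually fills the interval
        assert np.abs(w).max() > 0.95 * b

    def test_glorot_small_fans_and_determinism(self):
        w = glorot_init(1, 2, np.random.default_rng(7))
        assert w.shape == (2, 1)
        assert np.all(np.abs(w) < np.sqrt(2))
        w2 = glorot_init(1, 2, np.random.default_rng(7))
        np.testing.assert_array_equal(w, w2)

    def test_spectral_rescale_identity_and_diag(self):
        out = spectral_rescale(np.eye(5), 1.5)
        np.testing.assert_allclose(out, 1.5 * np.eye(5))
        out = spectral_rescale(np.diag([2.0, 0.5]), 1.5)
        np.testing.assert_allclose(out, np.diag([1.5, 0.375]))

    def test_spectral_rescale_random_matrix(self, rng):
        w = glorot_init(200, 200, rng)
        out = spectral_rescale(w, 1.5)
        rho = np.max(np.abs(np.linalg.eigvals(out)))
        assert abs(rho - 1.5) < 1e-9
        with pytest.raises(ValueError):
            spectral_rescale(np.zeros((3, 3)), 1.5)

    def test_dale_mask_default_values(self):
        d = build_dale_mask(500, 0.8)
        assert d.d_inh == -4.0
        assert abs(d.d_norm - np.sqrt(2000)) < 1e-12
        assert d.constraint_sum() == 0.0
        off_exc = d.D[1, 0]
        off_inh = d.D[0, 499]
        assert abs(off_exc - 1 / np.sqrt(2000)) < 1e-12
        assert abs(off_inh + 4 / np.sqrt(2000)) < 1e-12

    def test_dale_mask_structure_small(self):
        d = build_dale_mask(5, 0.8)
        assert d.n_exc == 4
        assert np.all(np.diag(d.D) == 0)
        assert np.all(d.D[:, :4][~np.eye(5, dtype=bool)[:, :4]] > 0)
        assert np.all(d.D[:4, 4] < 0)
        with pytest.raises(ValueError):
            build_dale_mask(7, 0.8)

    def test_init_network_invariants(self, rng):
        p = SimulationParams(n_rec=500)
        w = init_network(p, rng)
        assert int(w.sfa_mask.sum()) == 125
        eff = w.effective_rec()
        assert np.all(eff[:, :400] >= 0)
        assert np.all(eff[:, 400:] <= 0)
        assert np.all(np.diag(eff) == 0)
        assert np.all(w.M_rec >= 0)
        lo, hi = 0.041 * 1.8, 0.041 * 2.4
        assert np.all((w.i_base0 >= lo) & (w.i_base0 <= hi))

    def test_init_network_deterministic(self):
        p = SimulationParams(n_rec=40)
        w1 = init_network(p, np.random.default_rng(3))
        w2 = init_network(p, np.random.default_rng(3))
        np.testing.assert_array_equal(w1.M_rec, w2.M_rec)
        np.testing.assert_array_equal(w1.sfa_mask, w2.sfa_mask)

    def test_init_state(self, small_params, rng):
        w = init_network(small_params, rng)
        st = init_state(small_params, w, 8, rng)
        assert np.all((st.V >= -65) & (st.V <= -50))
        assert st.I.sum() == 0 and st.A.sum() == 0 and st.refrac.sum() == 0
        np.testing.assert_array_equal(st.I_base[:, 0], st.I_base[:, 3])


def _quiet_state(p, w, batch=1):
    """State with no baseline drive and V at rest."""
    st = init_state(p, w, batch, np.random.default_rng(0))
    st.V[:] = p.v_rest
    st.I[:] = 0.0
    st.I_base[:] = 0.0
    return st


class TestDynamics:
    def test_quiet_network_is_a_fixed_point(self, tiny_params, rng):
        p = tiny_params
        w = init_network(p, rng)
        st = _quiet_state(p, w)
        zero_in = np.zeros(5)
        for _ in range(10):
            st, s = srnn_step(st, zero_in, w, p)
            assert s.sum() == 0
        np.testing.assert_allclose(st.V, p.v_rest)
        np.testing.assert_allclose(st.I, 0.0)

    def test_adaptation_follows_closed_form_decay(self, tiny_params, rng):
        """After a single spike, A(k) = (1 - phi) * phi^(k-1)."""
        p = tiny_params
        w = init_network(p, rng)
        st = _quiet_state(p, w)
        w.M_rec[:] = 0.0          # isolate units
        st._S_prev = np.zeros((p.n_rec, 1))
        st._S_prev[0, 0] = 1.0    # unit 0 spiked at t-1
        phi = p.phi_a
        As = []
        zero_in = np.zeros(5)
        for _ in range(6):
            st, _ = srnn_step(st, zero_in, w, p)
            As.append(st.A[0, 0])
        expected = [(1 - phi) * phi**k for k in range(6)]
        np.testing.assert_allclose(As, expected, rtol=1e-12)
        assert np.all(np.diff(As) < 0)

    def test_adaptation_bounded_for_arbitrary_history(self, tiny_params, rng):
        p = tiny_params
        w = init_network(p, rng)
        A = np.zeros(4)
        r = np.random.default_rng(0)
        for _ in range(2000):
            s = (r.random(4) < 0.5).astype(float)
            A = p.phi_a * A + (1 - p.phi_a) * s
            assert np.all((A >= 0) & (A <= 1))

    def test_refractory_enforced(self, small_params, rng):
        p = small_params
        w = init_network(p, rng)
        # drive hard with strong constant cue input
        w.W_cue[:] = 5.0
        spikes_in = np.ones((1, 5, 200))
        res = simulate_batch(spikes_in, w, p, rng=np.random.default_rng(0))
        raster = res.rasters[0]
        min_isi_steps = p.n_ref_steps + 1
        for u in range(p.n_rec):
            t = np.flatnonzero(raster[u])
            if t.size > 1:
                assert np.diff(t).min() >= min_isi_steps

    def test_noise_free_runs_bit_identical(self, small_params, rng):
        p = small_params
        w = init_network(p, rng)
        spikes_in = (np.random.default_rng(1).random((2, 5, 100)) < 0.2)
        a = simulate_batch(spikes_in, w, p, rng=np.random.default_rng(9), noise=False)
        b = simulate_batch(spikes_in, w, p, rng=np.random.default_rng(9), noise=False)
        np.testing.assert_array_equal(a.rasters, b.rasters)
        np.testing.assert_array_equal(a.decoder_V, b.decoder_V)

    def test_seeded_noise_runs_bit_identical(self, small_params, rng):
        p = small_params
        w = init_network(p, rng)
        spikes_in = (np.random.default_rng(1).random((2, 5, 100)) < 0.2)
        a = simulate_batch(spikes_in, w, p, rng=np.random.default_rng(4))
        b = simulate_batch(spikes_in, w, p, rng=np.random.default_rng(4))
        np.testing.assert_array_equal(a.rasters, b.rasters)

    def test_null_network_silent(self, tiny_params, rng):
        p = tiny_params
        w = init_network(p, rng)
        w.M_rec[:] = 0
        w.i_base0[:] = 0
        rec = run_trial(np.zeros((5, 50)), w, p, noise=False,
                        rng=np.random.default_rng(0))
        assert rec.raster.sum() == 0
        np.testing.assert_allclose(rec.decoder_V, 0.0)

    def test_step_matches_batch_loop(self, small_params, rng):
        p = small_params
        w = init_network(p, rng)
        spikes_in = (np.random.default_rng(2).random((5, 60)) < 0.3).astype(float)
        st = init_state(p, w, 1, np.random.default_rng(5))
        st0 = NetworkState(V=st.V.copy(), I=st.I.copy(), A=st.A.copy(),
                           refrac=st.refrac.copy(), I_base=st.I_base.copy())
        raster_step = np.zeros((p.n_rec, 60))
        for t in range(60):
            st, s = srnn_step(st, spikes_in[:, t], w, p)
            raster_step[:, t] = s[:, 0]
        res = simulate_batch(spikes_in[None], w, p, noise=False, state=st0)
        np.testing.assert_array_equal(raster_step, res.rasters[0])


class TestDecide:
    def test_two_output_convention(self):
        # (0,1) codes left: the larger second voltage wins for left
        d = decide_from_voltages(np.array([0.1, 0.9]))
        assert d.choice == "L" and not d.tie
        d = decide_from_voltages(np.array([0.9, 0.1]))
        assert d.choice == "R"

    def test_tie_flagged_toward_output_zero(self):
        d = decide_from_voltages(np.array([0.5, 0.5]))
        assert d.index == 0 and d.tie

    def test_four_output_softmax_argmax(self):
        d = decide_from_voltages(np.array([0.1, 0.2, 1.5, 0.0]))
        assert d.index == 2 and d.choice == "audition_L"
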