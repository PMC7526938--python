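"""Adaptive EIF simulator: connectivity, rheobase, dynamics, recording."""

import numpy as np
import pytest

from semibalance import meanfield as mf, spiking as sp, synthetic


def tiny_spec(j_scale=1.0, p=1.0, n_e=3, n_i=2, n_x=2):
    return mf.PopulationSpec(
        names=["e", "i", "x"], sizes=[n_e, n_i, n_x], signs=["e", "i", "x"],
        j=np.array([[0.4, -1.0, 0.8], [0.6, -0.5, 0.7]]) * j_scale,
        p=np.full((2, 3), p))


class TestConnectivity:
    def test_dense_block_exact_counts(self):
        real = sp.sample_connectivity(tiny_spec(p=1.0), seed=0)
        # every post neuron receives from every pre neuron: out-degree of
        # each recurrent neuron equals the full recurrent count
        assert np.all(np.diff(real.out_ptr) == 5)
        assert np.all(np.diff(real.xout_ptr) == 5)

    def test_in_degree_binomial(self):
        spec = synthetic.fixture("fig1_linear", size_factor=0.1).spec
        real = sp.sample_connectivity(spec, seed=1)
        # in-degree of e1 neurons from i: Binomial(N_i, 0.1)
        n_e1, n_i = spec.sizes[0], spec.sizes[2]
        i_start = 2 * n_e1
        J = np.zeros(0)
        pre = np.repeat(np.arange(real.n_rec), np.diff(real.out_ptr))
        from_i = (pre >= i_start) & (pre < i_start + n_i)
        to_e1 = real.out_tgt < n_e1
        count = np.sum(from_i & to_e1)
        expected = 0.1 * n_i * n_e1
        sd = np.sqrt(n_e1 * n_i * 0.1 * 0.9)
        assert abs(count - expected) < 5 * sd

    def test_seed_determinism(self):
        spec = tiny_spec(p=0.5, n_e=30, n_i=20, n_x=10)
        a = sp.sample_connectivity(spec, seed=5)
        b = sp.sample_connectivity(spec, seed=5)
        c = sp.sample_connectivity(spec, seed=6)
        assert np.array_equal(a.out_tgt, b.out_tgt)
        assert not np.array_equal(a.out_tgt, c.out_tgt) or \
            not np.array_equal(a.out_ptr, c.out_ptr)

    def test_weight_value(self):
        spec = tiny_spec()
        real = sp.sample_connectivity(spec, seed=0)
        # weights stored in mV*ms: 1000 * j / sqrt(N)
        pre = np.repeat(np.arange(real.n_rec), np.diff(real.out_ptr))
        w_ei = real.out_w[(pre >= 3) & (real.out_tgt < 3)]
        assert np.allclose(w_ei, 1000.0 * -1.0 / np.sqrt(5))


class TestRheobase:
    def test_closed_form(self):
        assert sp.rheobase() == pytest.approx(16.0)

    def test_small_delta_limit(self):
        p = sp.NeuronParams(D_T=1e-6)
        assert sp.rheobase(p) == pytest.approx(p.V_T - p.E_L, abs=1e-5)

    def test_grid_maximization_agrees(self):
        p = sp.NeuronParams()
        V = np.linspace(p.E_L, p.V_T + 5, 2_000_001)
        h = (V - p.E_L) - p.D_T * np.exp((V - p.V_T) / p.D_T)
        assert abs(h.max() - sp.rheobase(p)) < 1e-6


class TestSimulate:
    def test_leak_only(self):
        spec = tiny_spec(j_scale=0.0)
        real = sp.sample_connectivity(spec, seed=0)
        # depolarize for 100 ms, then release: V relaxes back to E_L
        times = np.array([0.0, 100.0])
        vals = np.array([[10.0] * 5, [0.0] * 5])
        rec = sp.simulate(real, T_ms=400, dc_schedule=(times, vals), seed=0,
                          record_traces=[0])
        assert rec.spike_ids.size == 0
        assert rec.final_V[0] == pytest.approx(-72.0, abs=1e-3)

    def test_single_neuron_rate_fine_dt_oracle(self):
        spec = mf.PopulationSpec(names=["e"], sizes=[1], signs=["e"],
                                 j=np.zeros((1, 1)), p=np.zeros((1, 1)))
        real = sp.sample_connectivity(spec, seed=0)
        dc = np.array([1.2 * sp.rheobase()])
        r = []
        for dt in (0.05, 0.005):
            rec = sp.simulate(real, dc_mV=dc, T_ms=5000, dt_ms=dt, seed=0)
            r.append(rec.spike_ids.size / 5.0)
        assert r[0] == pytest.approx(r[1], rel=0.02)

    def test_bit_exact_reproducibility(self):
        spec = synthetic.fixture("fig1_competitive", size_factor=0.05).spec
        real = sp.sample_connectivity(spec, seed=1)
        a = sp.simulate(real, rx_Hz=np.array([15.0, 15.0]), T_ms=500, seed=3)
        b = sp.simulate(real, rx_Hz=np.array([15.0, 15.0]), T_ms=500, seed=3)
        assert np.array_equal(a.spike_ids, b.spike_ids)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_membrane_bounds(self):
        spec = synthetic.fixture("fig1_competitive", size_factor=0.05).spec
        real = sp.sample_connectivity(spec, seed=1)
        rec = sp.simulate(real, rx_Hz=np.array([15.0, 30.0]), T_ms=500,
                          seed=3, record_traces=list(range(0, 1500, 100)))
        assert rec.traces.min() >= sp.NeuronParams().V_lb - 1e-9
        assert rec.traces.max() <= sp.NeuronParams().V_th + 1e-9

    def test_negative_drive_rejected(self):
        real = sp.sample_connectivity(tiny_spec(), seed=0)
        with pytest.raises(ValueError):
            sp.simulate(real, rx_Hz=np.array([-1.0]), T_ms=10)


class TestRatesAndCurrents:
    def test_rate_definition(self):
        spec = tiny_spec(j_scale=0.0)
        real = sp.sample_connectivity(spec, seed=0)
        rec = sp.simulate(real, T_ms=2000, seed=0)
        rec.spike_ids = np.zeros(10, dtype=int)
        rec.spike_times = np.linspace(10, 1990, 10)
        assert sp.estimate_rates(rec, per="neuron")[0] == pytest.approx(5.0)
        pops = sp.estimate_rates(rec, per="population")
        per_n = sp.estimate_rates(rec, per="neuron")
        assert pops[0] == pytest.approx(per_n[:3].mean())

    def test_window_validation(self):
        real = sp.sample_connectivity(tiny_spec(j_scale=0.0), seed=0)
        rec = sp.simulate(real, T_ms=100, seed=0)
        with pytest.raises(ValueError):
            sp.estimate_rates(rec, (50.0, 20.0))

    def test_current_additivity(self):
        spec = synthetic.fixture("fig1_competitive", size_factor=0.05).spec
        real = sp.sample_connectivity(spec, seed=1)
        dc = np.full(real.n_rec, 2.0)
        rec = sp.simulate(real, rx_Hz=np.array([15.0, 15.0]), T_ms=500,
                          seed=3, dc_mV=dc, current_bin_ms=50.0)
        E, I, tot = sp.decompose_currents(rec)
        np.testing.assert_allclose(tot, E + I)
        assert np.all(E >= 0) and np.all(I <= 2.0 + 1e-12)

    def test_source_bookkeeping_no_inhibition(self):
        spec = mf.PopulationSpec(names=["e", "x"], sizes=[20, 10],
                                 signs=["e", "x"],
                                 j=np.array([[0.0, 2.0]]),
                                 p=np.array([[0.0, 0.5]]))
        real = sp.sample_connectivity(spec, seed=2)
        rec = sp.simulate(real, rx_Hz=np.array([20.0]), T_ms=500, seed=3,
                          current_bin_ms=100.0)
        E, I, _ = sp.decompose_currents(rec)
        assert np.all(I == 0) and E.mean() > 0


class TestPspAndBalance:
    def test_psp_amplitudes_within_printed_range(self):
        """Single-spike PSPs of the as-printed weight table at full size."""
        spec = synthetic.fixture("fig1_linear", j_ii=-0.375).spec
        amps = np.array(list(sp.psp_amplitudes(spec).values()))
        assert amps.min() >= 0.07 - 5e-3
        assert amps.max() <= 0.8

    def test_beta_shrinks_with_coupling(self):
        """Tighter balance (smaller |E+I|/E) at larger coupling scale.

        The coupling scale is varied through the network size at fixed
        probabilities: larger N means larger in-degree times weight.
        """
        from semibalance import analysis as an
        betas = []
        for f in (0.04, 0.16):
            spec = synthetic.fixture("fig1_linear", size_factor=f).spec
            real = sp.sample_connectivity(spec, seed=1)
            rec = sp.simulate(real, rx_Hz=np.array([0.0, 30.0]), T_ms=2000,
                              seed=2, current_bin_ms=250.0)
            E, I, _ = sp.decompose_currents(rec)
            bm = an.balance_metrics(E[:, 2:], I[:, 2:])
            betas.append(bm.beta_mean)
        assert betas[1] < betas[0]


def test_effective_currents_conductance_only():
    """Effective currents -g(V0 - E) exist only for the conductance model
    and show the same E/I sign structure as the actual currents."""
    fx = synthetic.fixture("fig1_competitive", size_factor=0.05)
    real = sp.sample_connectivity(fx.spec, seed=1)
    rec = sp.simulate(real, syn=sp.SynapseParams(model="conductance"),
                      rx_Hz=np.array([15.0, 15.0]), T_ms=500, seed=3,
                      current_bin_ms=100.0)
    E, I, tot = sp.decompose_currents(rec, effective=True)
    assert np.all(E >= 0) and np.all(I <= 0)
    np.testing.assert_allclose(tot, E + I)
    rec_cur = sp.simulate(real, rx_Hz=np.array([15.0, 15.0]), T_ms=200,
                          seed=3)
    with pytest.raises(ValueError):
        sp.decompose_currents(rec_cur, effective=True)


def test_conductance_model_matches_meanfield():
    """Conductance-based synapses reproduce the rescaled-weight prediction."""
    fx = synthetic.fixture("fig1_competitive", size_factor=2000 / 30000)
    real = sp.sample_connectivity(fx.spec, seed=1)
    net = mf.build_meanfield(fx.spec)
    sol = mf.semibalanced_rates(net, mf.external_drive(net, [15.0, 30.0]))
    rec = sp.simulate(real, syn=sp.SynapseParams(model="conductance"),
                      rx_Hz=np.array([15.0, 30.0]), T_ms=3000, seed=9)
    rates = sp.estimate_rates(rec, (500, 3000), per="population")
    assert rates[0] < 1.0  # silenced population stays silent
    assert rates[1] == pytest.approx(sol.r[1], rel=0.25)
    assert rates[2] == pytest.approx(sol.r[2], rel=0.25)
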