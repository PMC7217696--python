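import numpy as np
import pytest

from crosnet import (
    ConnectivityParams,
    GridSpec,
    NeuronParams,
    SimState,
    StimulusProtocol,
    SynapticWeights,
    apply_stimulus,
    build_connections,
    load_raster,
    run_simulation,
    save_raster,
)
from crosnet.dynamics import _per_type_vectors, step
from crosnet.topology import EXCITATORY


def _single_neuron_net():
    """Degenerate network: 2x2 grid, CE=CI=0 (no edges)."""
    return build_connections(
        GridSpec(side_length=2, frac_excitatory=0.75, seed=0),
        ConnectivityParams(CE=0, CI=0), SynapticWeights(), seed=0)


class TestStep:
    def test_activation_decay_arithmetic(self):
        """A=0.5, I=0, no input, tau_P=6, A0=0 -> A' = 0.5*(5/6)."""
        net = _single_neuron_net()
        params = NeuronParams(A0_exc=0.0)
        _, tau_P, A0, A_reset = _per_type_vectors(net, params)
        state = SimState.zeros(4)
        state.A[:] = 0.5

        class NeverSpike:
            def random(self, n):
                return np.ones(n)  # u >= p, no spikes

        W = net.connection_matrix()
        step(state, W, params, NeverSpike(), tau_P, A0, A_reset)
        exc = net.neuron_type == EXCITATORY
        assert state.A[exc] == pytest.approx(0.5 * 5 / 6)

    def test_negative_activation_never_spikes(self, rng):
        net = _single_neuron_net()
        params = NeuronParams()
        _, tau_P, A0, A_reset = _per_type_vectors(net, params)
        state = SimState.zeros(4)
        state.A[:] = -1.5
        W = net.connection_matrix()
        for _ in range(5):
            step(state, W, params, rng, tau_P, A0, A_reset)
        # with A < 0 and no drive, clamp(A) = 0: no neuron ever spikes
        assert not state.S.any()

    def test_supra_unit_activation_spikes_and_resets(self):
        net = _single_neuron_net()
        params = NeuronParams()
        _, tau_P, A0, A_reset = _per_type_vectors(net, params)
        state = SimState.zeros(4)
        state.A[:] = 3.2

        class AlwaysBelow:
            def random(self, n):
                return np.zeros(n)  # u < p whenever p > 0

        # A' = 3.2*(1-dt/tauP)+A0 stays > 1 -> p = 1 -> all spike, then reset
        step(state, net.connection_matrix(), params, AlwaysBelow(),
             tau_P, A0, A_reset)
        assert state.S.all()
        assert np.array_equal(state.A, A_reset)

    def test_nan_state_aborts(self, rng):
        net = _single_neuron_net()
        params = NeuronParams()
        _, tau_P, A0, A_reset = _per_type_vectors(net, params)
        state = SimState.zeros(4)
        state.I[0] = np.nan
        with pytest.raises(FloatingPointError):
            step(state, net.connection_matrix(), params, rng, tau_P, A0, A_reset)

    def test_decoupled_activation_decays_to_zero(self, rng):
        net = _single_neuron_net()
        params = NeuronParams(A0_exc=0.0)
        _, tau_P, A0, A_reset = _per_type_vectors(net, params)
        state = SimState.zeros(4)
        state.A[:] = 0.9
        W = net.connection_matrix()

        class NeverSpike:
            def random(self, n):
                return np.ones(n)

        for _ in range(400):
            step(state, W, params, NeverSpike(), tau_P, A0, A_reset)
        # geometric decay: slowest is the inhibitory (11/12)^400 ~ 7e-16
        assert np.all(np.abs(state.A) < 1e-12)


class TestStimulus:
    def test_non_excitatory_target_rejected(self):
        net = _single_neuron_net()
        inh = net.inhibitory_ids
        state = SimState.zeros(net.n_neurons)
        with pytest.raises(ValueError):
            apply_stimulus(state, inh[:1], 0.0085, network=net)

    def test_single_target_one_step_gain(self):
        """In a silent network the stimulated neuron's next-step spike
        probability rises by w*(1-dt/tau_I)*(1-dt/tau_P)."""
        net = _single_neuron_net()
        params = NeuronParams(A0_exc=0.0)
        _, tau_P, A0, A_reset = _per_type_vectors(net, params)
        state = SimState.zeros(net.n_neurons)
        target = net.excitatory_ids[:1]
        w = 0.0085
        apply_stimulus(state, target, w, network=net)

        class NeverSpike:
            def random(self, n):
                return np.ones(n)

        step(state, net.connection_matrix(), params, NeverSpike(),
             tau_P, A0, A_reset)
        expect = w * (1 - 1 / 9) * (1 - 1 / 6)
        assert state.A[target[0]] == pytest.approx(expect, rel=1e-12)

    def test_input_multiplier_scales_injection(self):
        w = SynapticWeights(input_multiplier=8.0)
        assert w.effective_input == pytest.approx(8 * 0.0085)

    def test_zero_targets_identical_to_unstimulated(self, small_network):
        base = run_simulation(small_network, n_steps=2000, seed=5)
        stim = run_simulation(small_network, n_steps=2000, seed=5,
                              protocol=StimulusProtocol(n_stimulated=0))
        assert np.array_equal(base.counts_exc, stim.counts_exc)
        assert np.array_equal(base.to_events(), stim.to_events())


class TestRunSimulation:
    def test_decoupled_network_effectively_silent(self):
        net = _single_neuron_net()
        r = run_simulation(net, n_steps=10_000, seed=0)
        # expected spontaneous count = A0 * n_exc * steps = 1e-6*3*1e4 = 0.03
        assert r.counts_total.sum() <= 2

    def test_identical_seeds_identical_rasters(self, small_network):
        a = run_simulation(small_network, n_steps=3000, seed=9)
        b = run_simulation(small_network, n_steps=3000, seed=9)
        assert np.array_equal(a.to_events(), b.to_events())
        assert np.array_equal(a.counts_inh, b.counts_inh)

    def test_counts_equal_typed_row_sums(self, small_network):
        r = run_simulation(small_network, n_steps=3000, seed=2)
        dense = r.to_dense()
        exc = small_network.neuron_type == EXCITATORY
        assert np.array_equal(dense[:, exc].sum(axis=1), r.counts_exc)
        assert np.array_equal(dense[:, ~exc].sum(axis=1), r.counts_inh)

    def test_firing_rate_increases_with_ce(self):
        """Mean excitatory rate grows monotonically with excitatory
        connectivity at fixed CI (short runs, several seeds)."""
        rates = []
        for ce in (25.0, 50.0, 75.0):
            per_seed = []
            for seed in range(5):
                net = build_connections(
                    GridSpec(side_length=30, seed=seed),
                    ConnectivityParams(CE=ce, CI=60.0), SynapticWeights(),
                    seed=seed)
                r = run_simulation(net, n_steps=20_000, seed=seed,
                                   record_spikes=False)
                per_seed.append(r.counts_exc[5000:].mean())
            rates.append(np.mean(per_seed))
        assert rates[0] < rates[1] < rates[2]

    def test_isi_gaps_within_range(self, small_network):
        proto = StimulusProtocol(n_stimulated=3, isi_range=(50, 150), seed=1)
        r = run_simulation(small_network, n_steps=5000, seed=1, protocol=proto)
        gaps = np.diff(np.r_[0, r.stim_times])
        assert gaps.min() >= 50 and gaps.max() <= 150

    def test_too_many_targets_rejected(self, small_network):
        proto = StimulusProtocol(n_stimulated=10_000)
        with pytest.raises(ValueError):
            run_simulation(small_network, n_steps=100, protocol=proto)

    def test_raster_round_trip(self, small_network, tmp_path):
        proto = StimulusProtocol(n_stimulated=2, isi_range=(100, 200), seed=4)
        r = run_simulation(small_network, n_steps=2000, seed=4, protocol=proto)
        path = str(tmp_path / "run.npz")
        save_raster(r, path)
        back = load_raster(path)
        assert np.array_equal(back.counts_exc, r.counts_exc)
        assert np.array_equal(back.stim_times, r.stim_times)
        assert np.array_equal(back.to_events(), r.to_events())
        assert back.config == r.config
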