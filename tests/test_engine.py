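"""Network simulation: kernels, Mg block, determinism, sparsity."""

import numpy as np
import pandas as pd
import pytest

from dgsep import config as cfg
from dgsep.engine import (
    SimulationResult,
    compute_sparsity,
    kernel_peak_time,
    kernel_peak_value,
    mg_block,
    simulate_network,
    simulate_patterns,
    synaptic_current,
)
from dgsep.experiments import build_network_from_config
from dgsep.network import delete_subtype
from dgsep.patterns import SpikePattern, generate_base_pattern

COUNTS = {"GC": 40, "BC": 8, "MC": 4, "HC": 2}
NPP = 60


def _weights(over=None):
    w = {proj: 0.0 for proj in cfg.SYNAPSE_TABLE}
    w.update(over or {})
    return w


def _net(valid_populations, weights, seed=42):
    return build_network_from_config(valid_populations, COUNTS, n_pp=NPP,
                                     seed=seed, weights=weights)


class TestKernels:
    def test_mg_block_at_zero_mv(self):
        assert mg_block(0.0) == pytest.approx(1.0 / 1.28)

    def test_mg_block_monotone_in_voltage(self):
        v = np.linspace(-90, 40, 50)
        s = mg_block(v)
        assert np.all(np.diff(s) > 0)

    def test_peak_time_matches_numeric_maximum(self):
        tr, td = 0.5, 7.0
        t = np.linspace(0, 50, 200_001)
        u = np.exp(-t / td) - np.exp(-t / tr)
        assert kernel_peak_time(tr, td) == pytest.approx(t[np.argmax(u)], abs=1e-3)
        assert kernel_peak_value(tr, td) == pytest.approx(u.max(), rel=1e-6)

    def test_synaptic_current_peak_equals_gbar_drive(self):
        # states evaluated exactly at the kernel peak: g == gbar
        tr, td, gbar, E, V = 0.5, 3.0, 2.0e-6, 0.0, -70.0
        tp = kernel_peak_time(tr, td)
        state = dict(gbar=gbar, tau_rise=tr, tau_decay=td, E_syn=E,
                     decay=np.exp(-tp / td), rise=np.exp(-tp / tr))
        I = synaptic_current(V, [state])
        assert I == pytest.approx(gbar * (E - V), rel=1e-9)
        assert I > 0  # excitatory conductance depolarizes at V < E

    def test_zero_conductance_zero_current(self):
        state = dict(gbar=0.0, tau_rise=0.5, tau_decay=3.0, E_syn=0.0,
                     decay=0.3, rise=0.1)
        assert synaptic_current(-65.0, [state]) == 0.0

    def test_nmda_scaling_applied(self):
        tp = kernel_peak_time(5.0, 50.0)
        base = dict(gbar=1e-6, tau_rise=5.0, tau_decay=50.0, E_syn=0.0,
                    decay=np.exp(-tp / 50.0), rise=np.exp(-tp / 5.0))
        plain = synaptic_current(0.0, [dict(base)])
        nmda = synaptic_current(0.0, [dict(base, nmda=True)])
        assert nmda == pytest.approx(plain / 1.28)


class TestSimulation:
    def test_zero_weights_network_is_silent(self, valid_populations, tiny_patterns):
        net = _net(valid_populations, _weights())
        res = simulate_network(net, tiny_patterns[0])
        for st in COUNTS:
            assert len(res.spikes[st]) == 0

    def test_pp_drive_time_locks_gc_spikes(self, valid_populations):
        # one strong AMPA-only afferent projection and nothing else: every
        # GC spike must trail some PP spike by the axonal delay plus the
        # fast conductance transient (NMDA is disabled here because its
        # slow decay deliberately outlasts any locking window)
        syn = {k: dict(v) for k, v in cfg.SYNAPSE_TABLE.items()}
        syn[("PP", "GC")]["nmda_ratio"] = 0.0
        from dgsep.network import build_network
        net = build_network(valid_populations, COUNTS, syn,
                            _weights({("PP", "GC"): 5e-5}), n_pp=NPP, seed=42,
                            wiring=cfg.WIRING_MODE)
        pattern = generate_base_pattern(NPP, 6.0, 1500.0, seed=3)
        res = simulate_network(net, pattern, duration_ms=1500.0)
        gc = res.spikes["GC"]
        assert len(gc) > 0
        pp_times = np.sort(np.concatenate(pattern.trains))
        delay = cfg.SYNAPSE_TABLE[("PP", "GC")]["delay"]
        for t in gc["time_ms"]:
            lags = t - delay - pp_times
            lags = lags[lags >= 0]
            assert lags.size and lags.min() < 10.0

    def test_identical_seed_bitwise_identical_rasters(self, valid_populations,
                                                      tiny_patterns):
        net = _net(valid_populations,
                   _weights({("PP", "GC"): 2e-5, ("GC", "BC"): 1e-5,
                               ("BC", "GC"): 2e-5}))
        a = simulate_network(net, tiny_patterns[0], noise_sigma=2.0, seed=5)
        b = simulate_network(net, tiny_patterns[0], noise_sigma=2.0, seed=5)
        for st in COUNTS:
            pd.testing.assert_frame_equal(a.spikes[st], b.spikes[st])

    def test_noiseless_simulation_is_pure(self, valid_populations, tiny_patterns):
        net = _net(valid_populations, _weights({("PP", "GC"): 2e-5}))
        a = simulate_network(net, tiny_patterns[0], seed=1)
        b = simulate_network(net, tiny_patterns[0], seed=99)
        for st in COUNTS:
            pd.testing.assert_frame_equal(a.spikes[st], b.spikes[st])

    def test_batched_equals_single_pattern_runs(self, valid_populations,
                                                tiny_patterns):
        net = _net(valid_populations, _weights({("PP", "GC"): 2e-5,
                                                  ("PP", "HC"): 4e-7}))
        batch = simulate_patterns(net, tiny_patterns[:3])
        for k in range(3):
            single = simulate_network(net, tiny_patterns[k])
            for st in COUNTS:
                pd.testing.assert_frame_equal(batch[k].spikes[st],
                                              single.spikes[st])

    def test_conductance_superposition(self):
        """The kernel recurrence is linear: the response to two presynaptic
        spikes equals the sum of the single-spike responses."""
        dt, tr, td = 0.1, 0.5, 3.0
        fr, fd = np.exp(-dt / tr), np.exp(-dt / td)

        def response(spike_steps, n_steps=500):
            rise = decay = 0.0
            g = np.zeros(n_steps)
            for t in range(n_steps):
                rise *= fr
                decay *= fd
                if t in spike_steps:
                    rise += 1.0
                    decay += 1.0
                g[t] = decay - rise
            return g

        combined = response({50, 180})
        summed = response({50}) + response({180})
        assert np.allclose(combined, summed, atol=1e-14)

    def test_bc_deletion_never_decreases_gc_spiking(self, valid_populations,
                                                    tiny_patterns):
        weights = {proj: float(np.mean(r)) for proj, r in cfg.WEIGHT_RANGES.items()}
        net = _net(valid_populations, weights)
        base = simulate_network(net, tiny_patterns[0])
        disinhibited = simulate_network(delete_subtype(net, "BC"), tiny_patterns[0])
        assert len(disinhibited.spikes["GC"]) >= len(base.spikes["GC"])

    def test_mismatched_pattern_size_rejected(self, valid_populations):
        net = _net(valid_populations, _weights())
        bad = generate_base_pattern(NPP + 1, 8.0, 2000.0, seed=1)
        with pytest.raises(ValueError):
            simulate_network(net, bad)


class TestSparsity:
    def _result(self, active_ids, n=10):
        spikes = {"GC": pd.DataFrame({
            "neuron_id": active_ids,
            "time_ms": [1000.0] * len(active_ids)})}
        return SimulationResult(spikes=spikes, duration=2000.0,
                                analysis_window=(500.0, 2000.0),
                                sizes={"GC": n})

    def test_all_fire_zero_sparsity(self):
        assert compute_sparsity(self._result(list(range(10))), "GC") == 0.0

    def test_none_fire_full_sparsity(self):
        assert compute_sparsity(self._result([]), "GC") == 1.0

    def test_hand_built_fraction(self):
        assert compute_sparsity(self._result([0, 3, 7]), "GC") == pytest.approx(0.7)

    def test_empty_population_rejected(self):
        res = self._result([], n=0)
        with pytest.raises(ValueError):
            compute_sparsity(res, "GC")

    def test_window_respected(self):
        res = self._result([0, 1])
        res.spikes["GC"].loc[1, "time_ms"] = 100.0  # before the window
        assert compute_sparsity(res, "GC") == pytest.approx(0.9)
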