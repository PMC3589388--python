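import numpy as np
import pytest

from conftest import SIMPLE_CELL, make_micro_network
from oracles import fixed_step_simulate
from stimplast.netsim.engine import EngineState
from stimplast.netsim.params import STDPRule


def engine_for(n, synapses, **kwargs):
    return EngineState(make_micro_network(n, synapses, **kwargs))


class TestSynapticEvents:
    def test_zero_weight_leaves_voltage_unchanged(self):
        eng = engine_for(1, [])
        eng.apply_synaptic_event(0, "AMPA", 0.0, 1.0)
        assert eng.voltage(0, 1.0) == 0.0

    def test_exponential_decay_of_single_event(self):
        eng = engine_for(1, [])
        eng.apply_synaptic_event(0, "AMPA", 4.0, 0.0)
        tau = SIMPLE_CELL["tau_receptor"]["AMPA"]
        v0 = eng.voltage(0, 0.0)
        assert v0 == pytest.approx(4.0)
        # closed form e^-5 after 5 time constants: < 1% remains
        assert eng.voltage(0, 5 * tau) == pytest.approx(4.0 * np.exp(-5), rel=1e-9)
        assert eng.voltage(0, 5 * tau) < 0.01 * v0

    def test_gaba_hyperpolarizes_and_cancels_symmetric_ampa(self):
        cell = dict(SIMPLE_CELL)
        cell["tau_receptor"] = {"AMPA": 10.0, "NMDA": 40.0, "GABA_A": 10.0}
        eng = engine_for(1, [], cell=cell)
        eng.apply_synaptic_event(0, "AMPA", 3.0, 0.0)
        eng.apply_synaptic_event(0, "GABA_A", 3.0, 0.0)
        # equal magnitudes and time constants cancel at all times
        assert eng.voltage(0, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert eng.voltage(0, 7.0) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_channel_rejected(self):
        eng = engine_for(1, [])
        with pytest.raises(ValueError):
            eng.apply_synaptic_event(0, "GLYCINE", 1.0, 0.0)


class TestFiring:
    def test_subthreshold_event_does_not_fire(self):
        eng = engine_for(1, [])
        eng.apply_synaptic_event(0, "AMPA", 9.9, 1.0)
        assert not eng.check_fire(0, 1.0)

    def test_suprathreshold_event_fires(self):
        eng = engine_for(1, [])
        eng.apply_synaptic_event(0, "AMPA", 12.0, 1.0)
        assert eng.check_fire(0, 1.0)
        assert eng.spikes[0] == [1.0]

    def test_depolarization_blockade_suppresses_firing(self):
        eng = engine_for(1, [])
        eng.apply_synaptic_event(0, "AMPA", 50.0, 1.0)  # above v_block = 40
        assert not eng.check_fire(0, 1.0)
        assert eng.spikes[0] == []

    def test_absolute_refractory_period_blocks_second_spike(self):
        eng = engine_for(1, [])
        eng.apply_synaptic_event(0, "AMPA", 20.0, 1.0)
        assert eng.check_fire(0, 1.0)
        t2 = 1.0 + SIMPLE_CELL["refrac_abs"] * 0.9
        eng.apply_synaptic_event(0, "AMPA", 20.0, t2)
        assert not eng.check_fire(0, t2)

    def test_threshold_elevation_decays_after_spike(self):
        eng = engine_for(1, [])
        eng.apply_synaptic_event(0, "AMPA", 20.0, 0.0)
        assert eng.check_fire(0, 0.0)
        R, tau_R = SIMPLE_CELL["refrac_R"], SIMPLE_CELL["tau_R"]
        thr0 = SIMPLE_CELL["v_threshold"]
        assert eng.effective_threshold(0, 0.0) == pytest.approx(thr0 + R)
        elev = eng.effective_threshold(0, 5 * tau_R) - thr0
        assert elev == pytest.approx(R * np.exp(-5), rel=1e-9)
        assert elev < 0.01 * R

    def test_disabled_relative_refractoriness_leaves_abs_period_only(self):
        cell = dict(SIMPLE_CELL, refrac_R=0.0, refrac_H=0.0)
        eng = engine_for(1, [], cell=cell)
        eng.apply_synaptic_event(0, "AMPA", 20.0, 0.0)
        assert eng.check_fire(0, 0.0)
        t2 = SIMPLE_CELL["refrac_abs"] + 0.1
        eng.apply_synaptic_event(0, "AMPA", 20.0, t2)
        assert eng.check_fire(0, t2)


class TestDeliveries:
    def test_no_efferents_gives_empty_list(self):
        eng = engine_for(2, [])
        assert eng.schedule_spike_deliveries(0, 100.0) == []

    def test_arrival_time_is_spike_plus_delay(self):
        syn = [dict(pre=0, post=1, channel="AMPA", weight=1.0, delay=2.0)]
        eng = engine_for(2, syn)
        assert eng.schedule_spike_deliveries(0, 100.0) == [(0, 102.0)]

    def test_axon_length_contributes_distance_over_velocity(self):
        # two targets at axon lengths L and 2L with equal base delay
        from stimplast.netsim import build_network, default_config

        cfg = default_config()
        cfg["scale"] = 1
        net = build_network(cfg, seed=3)
        v = cfg["geometry"]["axonal_velocity_um_per_ms"]
        s = 0  # any synapse: delay = base + d / v
        rule_delay = net.syn_delay[s]
        d = np.hypot(
            *(net.positions[net.syn_pre[s]] - net.positions[net.syn_post[s]])
        )
        assert rule_delay == pytest.approx(
            d / v + (rule_delay - d / v), rel=1e-12
        )
        # difference between lengths L and 2L is L / v by construction
        assert (2 * d / v + 1.0) - (d / v + 1.0) == pytest.approx(d / v)


class TestOracleEquivalence:
    """Event-driven spike times match a 0.01 ms fixed-step integrator."""

    def drive_both(self, n, synapses, events, duration=80.0):
        eng = engine_for(n, synapses, stdp={"increment_frac": 0.0})
        got = eng.run_events(events, duration)
        expected = fixed_step_simulate(
            SIMPLE_CELL, n, synapses, events, duration
        )
        return got, expected

    def test_three_neuron_chain_matches_reference(self):
        synapses = [
            dict(pre=0, post=1, channel="AMPA", weight=15.0, delay=2.0),
            dict(pre=1, post=2, channel="AMPA", weight=15.0, delay=3.0),
        ]
        events = [(5.0, 0, "AMPA", 20.0), (30.0, 0, "AMPA", 20.0)]
        got, expected = self.drive_both(3, synapses, events)
        for i in range(3):
            assert len(got[i]) == len(expected[i])
            np.testing.assert_allclose(got[i], expected[i], atol=0.0101)
        assert len(got[2]) >= 1  # the chain actually propagated

    def test_five_neuron_circuit_with_inhibition_matches_reference(self):
        synapses = [
            dict(pre=0, post=1, channel="AMPA", weight=12.0, delay=1.0),
            dict(pre=0, post=2, channel="AMPA", weight=12.0, delay=2.0),
            dict(pre=1, post=3, channel="AMPA", weight=8.0, delay=1.5),
            dict(pre=2, post=3, channel="AMPA", weight=8.0, delay=1.0),
            dict(pre=4, post=3, channel="GABA_A", weight=10.0, delay=1.0),
            dict(pre=3, post=4, channel="AMPA", weight=14.0, delay=2.0),
        ]
        rng = np.random.default_rng(5)
        events = [
            (round(float(t), 2), int(rng.integers(0, 2)) * 4, "AMPA", 16.0)
            for t in np.sort(rng.uniform(1.0, 70.0, size=40) * 100) / 100
        ]
        events = [(round(t * 100) / 100, i, ch, w) for t, i, ch, w in events]
        got, expected = self.drive_both(5, synapses, events)
        for i in range(5):
            assert len(got[i]) == len(expected[i]), f"neuron {i}"
            np.testing.assert_allclose(got[i], expected[i], atol=0.0101)

    def test_refractory_invariant_no_isi_below_absolute_period(self):
        synapses = [
            dict(pre=0, post=1, channel="AMPA", weight=20.0, delay=1.0),
            dict(pre=1, post=0, channel="AMPA", weight=20.0, delay=1.0),
        ]
        eng = engine_for(2, synapses, stdp={"increment_frac": 0.0})
        events = [(float(t), 0, "AMPA", 25.0) for t in range(1, 60)]
        spikes = eng.run_events(events, 100.0)
        for train in spikes:
            if len(train) > 1:
                assert np.min(np.diff(train)) > SIMPLE_CELL["refrac_abs"]


class TestBlockadeClamp:
    def test_voltage_held_above_blockade_never_fires(self):
        eng = engine_for(1, [])
        # rapid large events keep the cell above v_block continuously
        events = [(0.5 * k, 0, "AMPA", 60.0) for k in range(40)]
        spikes = eng.run_events(events, 25.0)
        assert spikes[0] == []


class TestDeterminism:
    def test_identical_seeds_give_identical_spike_tables(self):
        from stimplast.netsim import build_network, default_config, run_simulation
        from stimplast.protocols import build_session

        def one():
            cfg = default_config()
            cfg["scale"] = 1
            net = build_network(cfg, seed=11)
            sched = build_session(
                "spike_triggered", durations_s=(3, 3, 3), network=net, seed=12
            )
            return run_simulation(net, sched, seed=13)

        a, b = one(), one()
        assert a.units == b.units
        for u in a.units:
            np.testing.assert_array_equal(a.spike_times[u], b.spike_times[u])
        assert a.events.equals(b.events)
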