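"""Medium-spiny-neuron dynamics, event handling, and integrator accuracy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikeloop import _kernels
from spikeloop.neuron import (NeuronParams, NeuronState, SpikeEvent,
                              SynapseSpec, advance_neuron,
                              apply_synaptic_event, evaluate_derivatives,
                              merge_events, schedule_spike)

STEP_NS = 250_000
NS_PER_MS = 1_000_000


class TestDerivatives:
    @pytest.mark.parametrize("v,u,expected_dv,expected_du", [
        (-80.0, 0.0, 0.0, 0.0),       # down-state fixed point
        (-60.0, 0.0, -14.0, -4.0),    # k(v-vr)(v-vt)/C and a(b(v-vr)-u)
    ])
    def test_point_values(self, msn_params, v, u, expected_dv, expected_du):
        s = NeuronState(v=v, u=u)
        dv, du, dge, dgi = evaluate_derivatives(s, msn_params)
        assert dv == pytest.approx(expected_dv)
        assert du == pytest.approx(expected_du)
        assert dge == 0.0 and dgi == 0.0

    def test_conductance_terms(self, msn_params):
        s = NeuronState(v=-80.0, u=0.0, g_exc=6.0, g_inh=20.0)
        dv, du, dge, dgi = evaluate_derivatives(s, msn_params)
        # exc drives +, inh at E_inh=-110 drives - at v=-80
        assert dv == pytest.approx((-6.0 * (-80.0) - 20.0 * 30.0) / 50.0)
        assert dge == pytest.approx(-1.0)   # -g/tau = -6/6
        assert dgi == pytest.approx(-1.0)   # -20/20

    def test_literal_recovery_form(self):
        p = NeuronParams(literal_eq3=True)
        s = NeuronState(v=-60.0, u=0.0)
        _, du, _, _ = evaluate_derivatives(s, p)
        assert du == pytest.approx(0.01 * (-20.0 * -60.0))  # a(bv - u)

    def test_non_finite_state_rejected(self, msn_params):
        with pytest.raises(ValueError):
            evaluate_derivatives(NeuronState(v=np.nan), msn_params)


class TestParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            NeuronParams(C=-1.0)
        with pytest.raises(ValueError):
            NeuronParams(v_r=-20.0, v_t=-25.0)

    def test_defaults_are_msn_set(self, msn_params):
        assert (msn_params.a, msn_params.b, msn_params.c, msn_params.d) \
            == (0.01, -20.0, -55.0, 150.0)
        assert (msn_params.C, msn_params.k, msn_params.v_r, msn_params.v_t,
                msn_params.v_peak) == (50.0, 1.0, -80.0, -25.0, 40.0)
        assert (msn_params.E_exc, msn_params.E_inh, msn_params.tau_exc,
                msn_params.tau_inh) == (0.0, -110.0, 6.0, 20.0)


class TestAdvance:
    def test_down_state_is_fixed_point(self, msn_params, down_state):
        s = down_state
        for _ in range(1000):
            s, spikes = advance_neuron(s, msn_params, [])
            assert not spikes
        assert s.v == pytest.approx(-80.0, abs=1e-9)
        assert s.u == pytest.approx(0.0, abs=1e-9)

    def test_conductance_decay_closed_form(self, msn_params):
        s = NeuronState(v=-80.0, g_exc=10.0, g_inh=10.0)
        for _ in range(24):  # 6 ms
            s, _ = advance_neuron(s, msn_params, [])
        assert s.g_exc == pytest.approx(10.0 * np.exp(-1.0), rel=1e-9)
        for _ in range(400 - 24):  # out to 100 ms total
            s, _ = advance_neuron(s, msn_params, [])
        assert s.g_exc == pytest.approx(10.0 * np.exp(-100.0 / 6.0), rel=1e-6)
        assert s.g_inh == pytest.approx(10.0 * np.exp(-100.0 / 20.0), rel=1e-6)

    def test_spike_reset(self, msn_params):
        # strong excitatory drive pushes v over v_peak; Eq-6 reset applies
        y = np.array([-30.0, 0.0, 60.0, 0.0])
        ws = np.empty((6, 17))
        spk = np.empty(8)
        n = _kernels.ps_advance(y, 2.0, msn_params.as_array(), 16, 1e-10,
                                ws, spk, 0)
        assert n >= 1
        assert 0.0 < spk[0] < 2.0
        # v was reset to c and continued from there; u gained d at the spike
        assert y[0] < msn_params.v_peak
        assert y[1] > 100.0

    def test_event_splitting_applies_jump_mid_step(self, msn_params):
        s = NeuronState(v=-80.0)
        ev = SpikeEvent(delivery_time_ns=125_000, source_id=0,
                        emit_time_ns=0, kind="excitatory", weight=8.0)
        s2, _ = advance_neuron(s, msn_params, [ev])
        # conductance decayed only over the latter half step (125 us)
        assert s2.g_exc == pytest.approx(8.0 * np.exp(-0.125 / 6.0), rel=1e-9)

    def test_unsorted_events_rejected(self, msn_params, down_state):
        e1 = SpikeEvent(200_000, 0, 0, "excitatory", 1.0)
        e2 = SpikeEvent(100_000, 1, 0, "excitatory", 1.0)
        with pytest.raises(ValueError):
            advance_neuron(down_state, msn_params, [e1, e2])


@pytest.fixture(scope="module")
def driven_run(msn_params):
    rng = np.random.default_rng(7)
    t_end_ms = 1000.0
    # Poisson-ish excitatory drive (9 nS) + sparse inhibition (40 nS)
    n_exc = rng.poisson(500)
    n_inh = rng.poisson(40)
    t_ev = np.concatenate([rng.uniform(0, t_end_ms, n_exc),
                           rng.uniform(0, t_end_ms, n_inh)])
    dg = np.concatenate([np.full(n_exc, 9.0), np.full(n_inh, 40.0)])
    inh = np.concatenate([np.zeros(n_exc, bool), np.ones(n_inh, bool)])
    order = np.argsort(t_ev)
    # snap event times to the ns grid used by the PS path
    t_ev = np.round(t_ev[order] * NS_PER_MS) / NS_PER_MS
    dg, inh = dg[order], inh[order]

    p = msn_params.as_array()
    # --- PS path: 250-us global steps split at events ---
    s = NeuronState()
    ps_spikes = []
    ps_v = [s.v]
    iev = 0
    n_steps = int(t_end_ms * 4)
    for step in range(n_steps):
        t1 = (step + 1) * STEP_NS
        evs = []
        while iev < t_ev.size and t_ev[iev] * NS_PER_MS < t1:
            evs.append(SpikeEvent(
                delivery_time_ns=int(round(t_ev[iev] * NS_PER_MS)),
                source_id=iev, emit_time_ns=0,
                kind="inhibitory" if inh[iev] else "excitatory",
                weight=dg[iev]))
            iev += 1
        s, spk = advance_neuron(s, msn_params, evs)
        ps_spikes.extend(spk)
        ps_v.append(s.v)

    # --- RK4 oracle at 1-us steps ---
    y = NeuronState().as_array()
    v_trace = np.empty(int(t_end_ms * 1000) + 1)
    spk_out = np.empty(4096)
    n_spk = _kernels.rk4_reference(y, t_end_ms, 0.001, t_ev, dg,
                                   inh, p, v_trace, spk_out)
    rk_spikes = spk_out[:n_spk] * NS_PER_MS  # ns
    return (np.asarray(ps_spikes, float), rk_spikes,
            np.asarray(ps_v), v_trace)


class TestIntegratorOracle:
    """Parker-Sochacki vs 1-us fixed-step RK4 on a 1-s driven run."""

    def test_identical_spike_counts(self, driven_run):
        ps_spikes, rk_spikes, _, _ = driven_run
        assert len(ps_spikes) > 5, "drive should elicit spikes"
        assert len(ps_spikes) == len(rk_spikes)

    def test_spike_times_within_tenth_ms(self, driven_run):
        ps_spikes, rk_spikes, _, _ = driven_run
        diffs = np.abs(ps_spikes - rk_spikes) / NS_PER_MS
        assert diffs.max() < 0.1

    def test_trajectory_sup_norm_between_spikes(self, driven_run):
        ps_spikes, _, ps_v, rk_v = driven_run
        # compare at the 250-us grid, excluding +-2 ms around each spike
        # (there the tiny spike-time offset dominates the pointwise error)
        t_grid_ms = np.arange(ps_v.size) * 0.25
        rk_at_grid = rk_v[::250]
        mask = np.ones(t_grid_ms.size, bool)
        for ts in ps_spikes / NS_PER_MS:
            mask &= np.abs(t_grid_ms - ts) > 2.0
        err = np.abs(ps_v - rk_at_grid)[mask]
        assert err.max() < 0.1


class TestEvents:
    def test_apply_event_examples(self, down_state):
        s = apply_synaptic_event(down_state,
                                 SpikeEvent(0, 0, 0, "excitatory", 2.0))
        assert s.g_exc == 2.0 and s.v == down_state.v and s.u == down_state.u
        s2 = apply_synaptic_event(NeuronState(g_inh=1.0),
                                  SpikeEvent(0, 0, 0, "inhibitory", 40.0))
        assert s2.g_inh == 41.0

    def test_simultaneous_events_commute(self, down_state):
        a = SpikeEvent(0, 0, 0, "excitatory", 1.0)
        b = SpikeEvent(0, 1, 0, "excitatory", 1.0)
        s_ab = apply_synaptic_event(apply_synaptic_event(down_state, a), b)
        s_ba = apply_synaptic_event(apply_synaptic_event(down_state, b), a)
        assert s_ab.g_exc == s_ba.g_exc == 2.0

    def test_negative_weight_rejected(self, down_state):
        with pytest.raises(ValueError):
            apply_synaptic_event(down_state,
                                 SpikeEvent(0, 0, 0, "excitatory", -1.0))

    def test_schedule_spike_delay(self):
        syn = SynapseSpec(0, 1, "excitatory", 2.0, 3.0)
        evs = schedule_spike(7, 1_000_000_000, [syn])
        assert len(evs) == 1
        assert evs[0].delivery_time_ns == 1_003_000_000
        assert evs[0].source_id == 7
        assert schedule_spike(7, 0, []) == []

    def test_synapse_spec_invariants(self):
        with pytest.raises(ValueError):
            SynapseSpec(0, 1, "excitatory", -1.0, 3.0)
        with pytest.raises(ValueError):
            SynapseSpec(0, 1, "excitatory", 1.0, 0.0)

    def test_merge_examples(self):
        def ev(t, src=0):
            return SpikeEvent(t, src, 0, "excitatory", 1.0)
        merged = merge_events([[ev(10), ev(12)], [ev(11)]])
        assert [e.delivery_time_ns for e in merged] == [10, 11, 12]
        # equal timestamps: ascending source id
        merged = merge_events([[ev(5, src=3)], [ev(5, src=1)]])
        assert [e.source_id for e in merged] == [1, 3]

    def test_merge_rejects_unsorted_buffer(self):
        bad = [SpikeEvent(2, 0, 0, "excitatory", 1.0),
               SpikeEvent(1, 0, 0, "excitatory", 1.0)]
        with pytest.raises(ValueError):
            merge_events([bad])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 1000), max_size=20), max_size=6))
    def test_merge_matches_sort_oracle(self, raw):
        buffers = []
        for src, times in enumerate(raw):
            times = sorted(times)
            buffers.append([SpikeEvent(t, src, 0, "excitatory", 1.0)
                            for t in times])
        merged = merge_events(buffers)
        oracle = sorted([e for buf in buffers for e in buf],
                        key=lambda e: (e.delivery_time_ns, e.source_id))
        assert merged == oracle


class TestWinnerTakeAllSubstrate:
    def test_inhibition_suppresses_less_driven_msn(self):
        from spikeloop.engine import Engine
        from spikeloop.network import NetworkConfig, build_network
        from spikeloop.synth import TuningMap, TuningUnit

        tuning = TuningMap(units=[TuningUnit("left", ("left",)),
                                  TuningUnit("right", ("right",))])
        rates = np.array([200.0, 120.0])  # asymmetric drive

        def right_rate(inh_w):
            net = build_network(tuning,
                                net_cfg=NetworkConfig(inhibitory_weight=inh_w),
                                rng=np.random.default_rng(11))
            eng = Engine(net, lcg_seed=1)
            _, _, mt, mid = eng.advance(10_000, rates)  # 20 s
            return (mid == 1).sum() / 20.0

        suppressed = right_rate(40.0)
        free = right_rate(1e-9)
        assert suppressed < free
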