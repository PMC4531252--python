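"""Izhikevich medium spiny neurons with fast conductance-based synapses.

The medium spiny neuron (MSN) is modelled with the Izhikevich simple model

    C v' = k (v - v_r)(v - v_t) - u - g_exc (v - E_exc) - g_inh (v - E_inh)
    u'   = a (b (v - v_r) - u)

plus first-order conductance decay g' = -g/tau for each synapse class.  An
incoming synaptic event steps the matching conductance by the synapse weight.
When v reaches v_peak the neuron spikes and resets (v <- c, u <- u + d).

Integration uses the Parker-Sochacki power-series method over a 250-us global
step, split into local substeps at incoming synaptic events, which gives
spike times at nanosecond precision on the virtual clock.

Note on the recovery equation: with the MSN constant b = -20 nS the textbook
form u' = a(bv - u) has no fixed point near rest and destroys the down-state;
the canonical bistable MSN form u' = a(b(v - v_r) - u) is the default, and
``literal_eq3=True`` restores the uncorrected form for comparison.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from ._kernels import NS_PER_MS

DEFAULT_GLOBAL_STEP_NS = 250_000  # 250 us


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich MSN constants.  Defaults are the printed MSN set."""

    C: float = 50.0        # pF
    k: float = 1.0         # nS/mV
    v_r: float = -80.0     # mV
    v_t: float = -25.0     # mV
    a: float = 0.01        # 1/ms
    b: float = -20.0       # nS
    c: float = -55.0       # mV
    d: float = 150.0       # pA
    v_peak: float = 40.0   # mV
    E_exc: float = 0.0     # mV
    E_inh: float = -110.0  # mV
    tau_exc: float = 6.0   # ms
    tau_inh: float = 20.0  # ms
    literal_eq3: bool = False

    def __post_init__(self):
        if self.C <= 0 or self.tau_exc <= 0 or self.tau_inh <= 0:
            raise ValueError("C, tau_exc and tau_inh must be positive")
        if not (self.v_r < self.v_t < self.v_peak):
            raise ValueError("require v_r < v_t < v_peak")

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.k, self.v_r, self.v_t, self.a, self.b,
                         self.c, self.d, self.v_peak, self.E_exc, self.E_inh,
                         self.tau_exc, self.tau_inh,
                         1.0 if self.literal_eq3 else 0.0])


@dataclass
class NeuronState:
    """Dynamical state; t_ns is the last-updated time on the virtual clock."""

    v: float = -80.0   # mV
    u: float = 0.0     # pA
    g_exc: float = 0.0  # nS
    g_inh: float = 0.0  # nS
    t_ns: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.u, self.g_exc, self.g_inh])


@dataclass(frozen=True)
class SynapseSpec:
    """A weighted, delayed connection from a spike source onto an MSN."""

    pre_id: int
    post_id: int
    kind: str            # "excitatory" | "inhibitory"
    weight: float        # nS
    delay_ms: float
    plastic: bool = False

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("synaptic weight must be positive")
        if self.delay_ms <= 0:
            raise ValueError("synaptic delay must be positive")
        if self.kind not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")


@dataclass(frozen=True, order=True)
class SpikeEvent:
    """A scheduled synaptic event (ordering: delivery time, then source)."""

    delivery_time_ns: int
    source_id: int
    emit_time_ns: int = field(compare=False)
    kind: str = field(compare=False, default="excitatory")
    weight: float = field(compare=False, default=0.0)


def evaluate_derivatives(state: NeuronState, params: NeuronParams):
    """Right-hand sides (dv/dt mV/ms, du/dt pA/ms, dg_exc/dt, dg_inh/dt nS/ms)."""
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite neuron state")
    return _kernels.rhs(state.v, state.u, state.g_exc, state.g_inh,
                        params.as_array())


def apply_synaptic_event(state: NeuronState, event: SpikeEvent) -> NeuronState:
    """Conductance jump at the event instant; v and u are untouched."""
    if event.weight < 0:
        raise ValueError("negative synaptic weight")
    if event.kind == "inhibitory":
        return replace(state, g_inh=state.g_inh + event.weight)
    return replace(state, g_exc=state.g_exc + event.weight)


def schedule_spike(source_id: int, emit_time_ns: int,
                   outgoing: list[SynapseSpec]) -> list[SpikeEvent]:
    """One delayed event per outgoing synapse; nothing is ever dropped."""
    out = []
    for syn in outgoing:
        out.append(SpikeEvent(
            delivery_time_ns=emit_time_ns + int(round(syn.delay_ms * NS_PER_MS)),
            source_id=source_id,
            emit_time_ns=emit_time_ns,
            kind=syn.kind,
            weight=syn.weight,
        ))
    return out


def merge_events(buffers: list[list[SpikeEvent]]) -> list[SpikeEvent]:
    """Time-ordered merge of per-synapse buffers.

    Each buffer must already be time-ordered; ties are broken by ascending
    source id (the dataclass ordering).
    """
    for buf in buffers:
        for e0, e1 in zip(buf, buf[1:]):
            if e1.delivery_time_ns < e0.delivery_time_ns:
                raise ValueError("per-synapse buffer is not time-ordered")
    return list(heapq.merge(*buffers))


def advance_neuron(state: NeuronState, params: NeuronParams,
                   events: list[SpikeEvent],
                   dt_ns: int = DEFAULT_GLOBAL_STEP_NS,
                   max_order: int = 16, tol: float = 1e-10):
    """Advance one global step, splitting at event delivery times.

    events must be sorted by delivery time and lie within
    [state.t_ns, state.t_ns + dt_ns).  Returns (new_state, spike_times_ns).
    """
    t0 = state.t_ns
    te = t0 + dt_ns
    prev = t0
    for ev in events:
        if ev.delivery_time_ns < prev:
            raise ValueError("events not sorted by delivery time")
        if not (t0 <= ev.delivery_time_ns < te):
            raise ValueError("event outside the global step")
        prev = ev.delivery_time_ns

    p = params.as_array()
    y = state.as_array()
    ws = np.empty((6, max_order + 1))
    spk_buf = np.empty(64)
    spikes: list[int] = []
    t_cur = t0
    boundaries = [(ev.delivery_time_ns, ev) for ev in events] + [(te, None)]
    for t_next, ev in boundaries:
        if t_next > t_cur:
            h = (t_next - t_cur) / NS_PER_MS
            n = _kernels.ps_advance(y, h, p, max_order, tol, ws, spk_buf, 0)
            for q in range(n):
                spikes.append(t_cur + int(round(spk_buf[q] * NS_PER_MS)))
            t_cur = t_next
        if ev is not None:
            if ev.kind == "inhibitory":
                y[3] += ev.weight
            else:
                y[2] += ev.weight
    new_state = NeuronState(v=y[0], u=y[1], g_exc=y[2], g_inh=y[3], t_ns=te)
    return new_state, spikes
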