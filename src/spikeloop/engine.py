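"""Virtual-time network engine: wraps the numba chunk kernel.

The engine owns the mutable simulation state — neuron states, the LCG of
the spike synthesizer, per-neuron synaptic event buffers, eligibility
triggers and the scheduled/delivered event counters — and advances it chunk
by chunk on the 2-ms synthesizer grid.  All scheduling happens in integer
nanoseconds, so runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from ._kernels import NS_PER_MS
from .network import Network
from .neuron import NeuronParams

TICK_NS = 2_000_000          # 2-ms synthesizer / task cycle
STEP_NS = 250_000            # 250-us global neuron step
EVENT_BUFFER_CAP = 2048


class Engine:
    def __init__(self, network: Network, params: NeuronParams | None = None,
                 lcg_seed: int = 0, max_order: int = 16, tol: float = 1e-10,
                 pair_window_ms: float = 40.0):
        self.net = network
        self.params = params or NeuronParams()
        self._p = self.params.as_array()
        self.max_order = int(max_order)
        self.tol = float(tol)
        self.pair_ns = int(round(pair_window_ms * NS_PER_MS))

        n_msn = network.n_msn
        self.Y = np.zeros((n_msn, 4))
        self.Y[:, 0] = self.params.v_r          # down state (v_r, 0)
        # lcg[0]: primary synthesizer; lcg[1]: the separate stress
        # synthesizer (only consulted when extra units exist)
        self.lcg = np.array([int(lcg_seed) % _kernels.LCG_MOD,
                             (int(lcg_seed) + 1) % _kernels.LCG_MOD],
                            dtype=np.int64)
        self.ev_t = np.zeros((n_msn, EVENT_BUFFER_CAP), dtype=np.int64)
        self.ev_w = np.zeros((n_msn, EVENT_BUFFER_CAP))
        self.ev_inh = np.zeros((n_msn, EVENT_BUFFER_CAP), dtype=np.bool_)
        self.ev_src = np.zeros((n_msn, EVENT_BUFFER_CAP), dtype=np.int64)
        self.ev_n = np.zeros(n_msn, dtype=np.int64)
        self.last_pre = np.full(network.n_sources, np.iinfo(np.int64).min // 2,
                                dtype=np.int64)
        self.elig_trig = np.full(network.n_syn, np.iinfo(np.int64).min // 2,
                                 dtype=np.int64)
        self.counters = np.zeros(2, dtype=np.int64)  # scheduled, delivered

        self._ws = np.empty((6, self.max_order + 1))
        self._spk_buf = np.empty(64)
        self._sub_t = np.empty(EVENT_BUFFER_CAP, dtype=np.int64)
        self._sub_w = np.empty(EVENT_BUFFER_CAP)
        self._sub_inh = np.empty(EVENT_BUFFER_CAP, dtype=np.bool_)
        self._sub_src = np.empty(EVENT_BUFFER_CAP, dtype=np.int64)
        self._empty_t = np.empty(0, dtype=np.int64)
        self._empty_src = np.empty(0, dtype=np.int64)
        self.t_ns = 0

    @property
    def scheduled(self) -> int:
        return int(self.counters[0])

    @property
    def delivered(self) -> int:
        return int(self.counters[1])

    @property
    def pending(self) -> int:
        return int(self.ev_n.sum())

    def eligibility(self, syn_idx: np.ndarray, t_ns: int,
                    lifetime_ms: float) -> np.ndarray:
        """Binary trace vector for the given synapses at time t_ns."""
        life = int(round(lifetime_ms * NS_PER_MS))
        trig = self.elig_trig[syn_idx]
        return ((t_ns - trig) < life) & (trig <= t_ns)

    def advance(self, n_ticks: int, rates_hz: np.ndarray,
                direct: bool = True, record_cortex: bool = False,
                injected: tuple[np.ndarray, np.ndarray] | None = None):
        """Advance n_ticks 2-ms cycles; returns (cortex, msn) spike arrays.

        rates_hz is the per-unit rate vector for the current synthesizer
        mode.  With direct=False, synthesizer spikes are recorded but not
        delivered; `injected` (times_ns, source_ids) feeds externally sorted
        spikes into the synapse table instead.
        """
        p_spike = np.asarray(rates_hz, dtype=float) * (TICK_NS / 1e9)
        if np.any(p_spike >= 1.0):
            raise ValueError("rate * tick must stay below 1")
        if injected is None:
            inj_t, inj_src = self._empty_t, self._empty_src
        else:
            inj_t = np.ascontiguousarray(injected[0], dtype=np.int64)
            inj_src = np.ascontiguousarray(injected[1], dtype=np.int64)
        cap_c = p_spike.size * n_ticks + 1
        cap_m = self.net.n_msn * n_ticks * 8 + 64
        c_t = np.empty(cap_c, dtype=np.int64)
        c_id = np.empty(cap_c, dtype=np.int64)
        m_t = np.empty(cap_m, dtype=np.int64)
        m_id = np.empty(cap_m, dtype=np.int64)
        nc, nm = _kernels.run_chunk(
            self.t_ns, n_ticks, TICK_NS, STEP_NS,
            self.lcg, self.net.n_tuned_units, p_spike, direct, record_cortex,
            inj_t, inj_src, inj_t.size,
            self.Y, self._p, self.max_order, self.tol,
            self.net.syn_pre, self.net.syn_post, self.net.syn_w,
            self.net.syn_delay_ns, self.net.syn_inh,
            self.net.out_ptr, self.net.out_idx,
            self.net.plast_ptr, self.net.plast_idx,
            self.ev_t, self.ev_w, self.ev_inh, self.ev_src, self.ev_n,
            self.last_pre, self.elig_trig, self.pair_ns,
            self.counters,
            c_t, c_id, m_t, m_id,
            self._ws, self._spk_buf,
            self._sub_t, self._sub_w, self._sub_inh, self._sub_src)
        self.t_ns += n_ticks * TICK_NS
        return (c_t[:nc].copy(), c_id[:nc].copy(),
                m_t[:nm].copy(), m_id[:nm].copy())
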