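"""Network construction: flat synapse tables for the event engine.

The controller network is tiny — 18 cortical units partially wired onto two
reciprocally inhibiting MSNs — but the engine representation is general:
sources are numbered units first, then MSNs (source id = n_units + j), and
synapses live in flat arrays with a CSR index by source for event scheduling
and a CSR index by postsynaptic MSN over the plastic synapses for
eligibility bookkeeping.

Synaptic delays are drawn once at construction from the stated uniform
ranges (cortex->MSN 3-5 ms, MSN<->MSN 2.5-3 ms) with the session RNG.

The stress extension adds 150 passive MSNs and 14 high-rate units wired with
Bernoulli connectivity; they exercise the simulator but feed neither the
decoder nor the plasticity rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import NS_PER_MS
from .plasticity import PlasticityConfig
from .synth import TuningMap

N_DECODING_MSNS = 2
SIDE_INDEX = {"left": 0, "right": 1}


@dataclass(frozen=True)
class NetworkConfig:
    inhibitory_weight: float = 40.0             # nS, MSN<->MSN, non-plastic
    cortex_delay_ms: tuple[float, float] = (3.0, 5.0)
    msn_delay_ms: tuple[float, float] = (2.5, 3.0)


@dataclass(frozen=True)
class StressConfig:
    extra_msns: int = 150
    extra_units: int = 14
    extra_unit_rate_hz: float = 80.0
    p_exc: float = 0.66
    p_inh: float = 0.2
    weight: float = 2.0                          # nS, fixed for all stress synapses
    exc_delay_ms: tuple[float, float] = (3.0, 5.0)
    inh_delay_ms: tuple[float, float] = (2.5, 3.0)


@dataclass
class Network:
    n_units: int
    n_msn: int
    syn_pre: np.ndarray
    syn_post: np.ndarray
    syn_w: np.ndarray
    syn_delay_ns: np.ndarray
    syn_inh: np.ndarray
    syn_plastic: np.ndarray
    out_ptr: np.ndarray
    out_idx: np.ndarray
    plast_ptr: np.ndarray
    plast_idx: np.ndarray
    conn: np.ndarray          # (n_tuned_units, 2) bool
    n_tuned_units: int
    stress: StressConfig | None = None

    @property
    def n_sources(self) -> int:
        return self.n_units + self.n_msn

    @property
    def n_syn(self) -> int:
        return self.syn_pre.size

    def plastic_columns(self) -> list[np.ndarray]:
        """Plastic synapse indices per decoding MSN."""
        return [self.plast_idx[self.plast_ptr[j]:self.plast_ptr[j + 1]]
                for j in range(N_DECODING_MSNS)]

    def weight_matrix(self) -> np.ndarray:
        """(n_tuned_units, 2) snapshot of the plastic weights (0 = absent)."""
        w = np.zeros((self.n_tuned_units, N_DECODING_MSNS))
        for j, col in enumerate(self.plastic_columns()):
            w[self.syn_pre[col], j] = self.syn_w[col]
        return w

    def set_equal_weights(self, W: float) -> None:
        for col in self.plastic_columns():
            self.syn_w[col] = W / col.size


def _csr(keys: np.ndarray, n_keys: int, values: np.ndarray | None = None):
    order = np.argsort(keys, kind="stable")
    idx = order if values is None else values[order]
    ptr = np.zeros(n_keys + 1, dtype=np.int64)
    np.add.at(ptr, keys + 1, 1)
    np.cumsum(ptr, out=ptr)
    return ptr, idx.astype(np.int64)


def build_network(tuning: TuningMap,
                  plast_cfg: PlasticityConfig | None = None,
                  net_cfg: NetworkConfig | None = None,
                  rng: np.random.Generator | None = None,
                  stress: StressConfig | None = None) -> Network:
    """Assemble the controller network (optionally with the stress load)."""
    plast_cfg = plast_cfg or PlasticityConfig()
    net_cfg = net_cfg or NetworkConfig()
    rng = rng or np.random.default_rng()
    n_tuned = tuning.n_units
    n_units = n_tuned + (stress.extra_units if stress else 0)
    n_msn = N_DECODING_MSNS + (stress.extra_msns if stress else 0)

    pre, post, w, delay, inh, plastic = [], [], [], [], [], []
    conn = np.zeros((n_tuned, N_DECODING_MSNS), dtype=bool)

    lo, hi = net_cfg.cortex_delay_ms
    for i, unit in enumerate(tuning.units):
        for side in unit.connected_to:
            j = SIDE_INDEX[side]
            conn[i, j] = True
            pre.append(i)
            post.append(j)
            w.append(0.0)  # set below from the column totals
            delay.append(rng.uniform(lo, hi))
            inh.append(False)
            plastic.append(True)

    lo, hi = net_cfg.msn_delay_ms
    for j_from, j_to in ((0, 1), (1, 0)):
        pre.append(n_units + j_from)
        post.append(j_to)
        w.append(net_cfg.inhibitory_weight)
        delay.append(rng.uniform(lo, hi))
        inh.append(True)
        plastic.append(False)

    if stress is not None:
        elo, ehi = stress.exc_delay_ms
        ilo, ihi = stress.inh_delay_ms
        for j in range(N_DECODING_MSNS, n_msn):
            for i in range(n_units):
                if rng.random() < stress.p_exc:
                    pre.append(i)
                    post.append(j)
                    w.append(stress.weight)
                    delay.append(rng.uniform(elo, ehi))
                    inh.append(False)
                    plastic.append(False)
        for j_from in range(N_DECODING_MSNS, n_msn):
            for j_to in range(N_DECODING_MSNS, n_msn):
                if j_from != j_to and rng.random() < stress.p_inh:
                    pre.append(n_units + j_from)
                    post.append(j_to)
                    w.append(stress.weight)
                    delay.append(rng.uniform(ilo, ihi))
                    inh.append(True)
                    plastic.append(False)

    syn_pre = np.asarray(pre, dtype=np.int64)
    syn_post = np.asarray(post, dtype=np.int64)
    syn_w = np.asarray(w, dtype=np.float64)
    syn_delay_ns = np.asarray(np.round(np.asarray(delay) * NS_PER_MS),
                              dtype=np.int64)
    syn_inh = np.asarray(inh, dtype=np.bool_)
    syn_plastic = np.asarray(plastic, dtype=np.bool_)

    out_ptr, out_idx = _csr(syn_pre, n_units + n_msn)
    plast_sel = np.flatnonzero(syn_plastic)
    plast_ptr, plast_idx = _csr(syn_post[plast_sel], n_msn, plast_sel)

    net = Network(n_units=n_units, n_msn=n_msn, syn_pre=syn_pre,
                  syn_post=syn_post, syn_w=syn_w, syn_delay_ns=syn_delay_ns,
                  syn_inh=syn_inh, syn_plastic=syn_plastic,
                  out_ptr=out_ptr, out_idx=out_idx,
                  plast_ptr=plast_ptr, plast_idx=plast_idx,
                  conn=conn, n_tuned_units=n_tuned, stress=stress)
    net.set_equal_weights(plast_cfg.W)
    return net


def build_stress_network(tuning: TuningMap, stress: StressConfig,
                         seed: int,
                         plast_cfg: PlasticityConfig | None = None,
                         net_cfg: NetworkConfig | None = None) -> Network:
    """Controller network plus the 150-MSN / 14-unit stress population."""
    rng = np.random.default_rng(seed)
    return build_network(tuning, plast_cfg, net_cfg, rng, stress=stress)
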