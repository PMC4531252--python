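"""Reward-modulated STDP with binary eligibility traces.

Every 26-ms decoder tick while robot control is active, each plastic
cortico-striatal weight is updated multiplicatively,

    w_ij <- w_ij (1 + mu r e_ij),      r = (1 - Rbar_k) S,

where e_ij is a binary eligibility trace (set when MSN j fires within 40 ms
after unit i, expiring 100 ms after its trigger; a re-trigger restarts the
clock), S = +/-1 is the sensory error of the last arm movement, and Rbar_k
is the running-mean success estimate for the selected target k, updated once
per trial as Rbar <- (1 - 1/m) Rbar + R_T/m.  After each update the weight
column of every MSN is renormalized to the fixed total W (homeostatic
scaling) under the hard cap w_max = alpha W / N_j; both constraints are
enforced simultaneously by a clip-and-redistribute fixed point.

Because r carries the factor (1 - Rbar_k), learning self-terminates: once
every trial succeeds, Rbar -> 1 and the weight update vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TARGETS = ("left", "right")


@dataclass(frozen=True)
class PlasticityConfig:
    mu: float = 0.02            # learning rate per 26-ms tick
    W: float = 110.0            # fixed excitatory column total per MSN (nS)
    alpha: float = 2.0          # cap scale, w_max = alpha * W / N_j
    m: int = 3                  # reward-estimate running-mean window (trials)
    pair_window_ms: float = 40.0   # max pre->post lag that tags a synapse
    lifetime_ms: float = 100.0     # trace lifetime after its trigger

    def __post_init__(self):
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1 for the cap to be feasible")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class PlasticityState:
    """Plastic weight matrix with traces and per-target reward estimates.

    ``w`` is (n_units, n_msn); entries where ``conn`` is False are absent
    synapses and held at 0.  ``elig_trigger_ms`` holds the trigger time of
    each trace (-inf when never triggered).
    """

    w: np.ndarray
    conn: np.ndarray
    cfg: PlasticityConfig = field(default_factory=PlasticityConfig)
    elig_trigger_ms: np.ndarray = None
    R_bar: np.ndarray = None          # per target, in [0, 1]
    n_k: np.ndarray = None            # per-target trial counters

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.conn = np.asarray(self.conn, dtype=bool)
        if self.elig_trigger_ms is None:
            self.elig_trigger_ms = np.full(self.w.shape, -np.inf)
        if self.R_bar is None:
            self.R_bar = np.zeros(len(TARGETS))
        if self.n_k is None:
            self.n_k = np.zeros(len(TARGETS), dtype=int)

    @property
    def n_exc(self) -> np.ndarray:
        """N_j: number of excitatory (plastic) synapses per MSN."""
        return self.conn.sum(axis=0)

    @property
    def w_max(self) -> np.ndarray:
        return self.cfg.alpha * self.cfg.W / self.n_exc

    def eligibility(self, t_now_ms: float) -> np.ndarray:
        """Binary trace matrix at time t_now_ms."""
        trig = self.elig_trigger_ms
        active = (trig <= t_now_ms) & (t_now_ms - trig < self.cfg.lifetime_ms)
        return (active & self.conn).astype(float)

    @classmethod
    def with_equal_weights(cls, conn: np.ndarray,
                           cfg: PlasticityConfig = None) -> "PlasticityState":
        cfg = cfg or PlasticityConfig()
        conn = np.asarray(conn, dtype=bool)
        w = np.zeros(conn.shape)
        for j in range(conn.shape[1]):
            n = conn[:, j].sum()
            if n:
                w[conn[:, j], j] = cfg.W / n
        return cls(w=w, conn=conn, cfg=cfg)


def update_eligibility(state: PlasticityState,
                       pre_spikes_ms: list[np.ndarray],
                       post_spikes_ms: list[np.ndarray],
                       t_now_ms: float) -> PlasticityState:
    """Re-derive trace triggers from recent spike histories (all-to-all).

    A trace is triggered at every post spike that follows a pre spike on the
    same synapse within the pairing window; the latest qualifying post spike
    wins (a re-trigger restarts the 100-ms lifetime).
    """
    win = state.cfg.pair_window_ms
    for i, pre in enumerate(pre_spikes_ms):
        pre = np.asarray(pre, dtype=float)
        for j, post in enumerate(post_spikes_ms):
            if not state.conn[i, j]:
                continue
            trig = -np.inf
            for tp in np.asarray(post, dtype=float):
                if tp > t_now_ms:
                    continue
                lags = tp - pre
                if np.any((lags > 0) & (lags <= win)):
                    trig = max(trig, tp)
            state.elig_trigger_ms[i, j] = max(state.elig_trigger_ms[i, j], trig)
    return state


def global_reward(S: int, R_bar_k: float) -> float:
    """r = (1 - Rbar_k) S; zero once the success estimate saturates."""
    if S not in (-1, 1):
        raise ValueError("sensory error S must be -1 or +1")
    if not 0.0 <= R_bar_k <= 1.0:
        raise ValueError("R_bar must lie in [0, 1]")
    return (1.0 - R_bar_k) * S


def normalize_and_cap_column(w: np.ndarray, W: float, w_max: float) -> np.ndarray:
    """Clip-and-redistribute fixed point: sum(w) == W and all w <= w_max.

    Feasible whenever n * w_max >= W (guaranteed by alpha > 1).  Uncapped
    weights are rescaled to absorb the mass the capped ones cannot carry;
    iterating reaches the joint fixed point in at most n passes.
    """
    w = np.asarray(w, dtype=float).copy()
    n = w.size
    if n * w_max < W - 1e-9:
        raise ValueError("cap infeasible: n * w_max < W")
    capped = np.zeros(n, dtype=bool)
    for _ in range(n + 1):
        free = ~capped
        s_free = w[free].sum()
        budget = W - w_max * capped.sum()
        if s_free <= 0.0 or budget <= 0.0:
            break
        w[free] *= budget / s_free
        over = free & (w > w_max)
        if not over.any():
            break
        w[over] = w_max
        capped |= over
    return w


def normalize_and_cap(state: PlasticityState) -> PlasticityState:
    for j in range(state.w.shape[1]):
        mask = state.conn[:, j]
        if mask.any():
            state.w[mask, j] = normalize_and_cap_column(
                state.w[mask, j], state.cfg.W, state.w_max[j])
    return state


def apply_reward_update(state: PlasticityState, r: float,
                        t_now_ms: float) -> PlasticityState:
    """One 26-ms plasticity tick: multiplicative update then renormalization."""
    e = state.eligibility(t_now_ms)
    state.w[state.conn] *= (1.0 + state.cfg.mu * r * e[state.conn])
    return normalize_and_cap(state)


def update_reward_estimate(R_bar_k: float, R_T: int, m: int) -> float:
    """End-of-trial running-mean update for the selected target only."""
    if R_T not in (0, 1):
        raise ValueError("R_T must be 0 or 1")
    if m < 1:
        raise ValueError("m must be >= 1")
    return (1.0 - 1.0 / m) * R_bar_k + R_T / m
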