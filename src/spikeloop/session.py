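"""Virtual-time orchestration of the two-target reaching task.

A session is a sequence of scripted trials on one logical clock that ticks
through every cadence of the original real-time system: synthesizer spike
draws every 2 ms, neuron integration in 250-us global steps split at
synaptic events, acquisition blocks of 512 us (full-loop mode), and decoder
commands every 26 ms.

Trial lifecycle (all phases are multiples of the 2-ms grid):

    refractory (2 s, baseline activity)
      -> button press (26 ms)
      -> trial start: a target is drawn uniformly; the synthesizer switches
         to the target's activity pattern
      -> +40 ms: robot control and plasticity enable
      -> every 26 ms: bin MSN spikes over the trailing 104-ms window,
         winner-take-all action, arm step, sensory error, weight update
      -> end on correct/wrong reach or 3-s timeout; the per-target success
         estimate Rbar_k is updated and the synthesizer returns to baseline;
         the arm returns to the default position during the next refractory.

Optionally the tuning map is reversed from a configured trial onward
(reversal learning) and a passive stress population can be attached.

In ``direct`` mode synthesizer spikes become synaptic events immediately; in
``full_loop`` mode each unit drives an analog channel (inverted 100-us
pulses at 31.25 kHz) through the band-pass/upsample/detect/template-match
chain, and only the sorted spikes reach the MSNs.
"""

from __future__ import annotations

import dataclasses
import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import NS_PER_MS
from .decoder import ArmState, DecoderConfig, check_reach, decode_action, \
    sensory_error, step_arm
from .engine import Engine, TICK_NS
from .network import Network, NetworkConfig, StressConfig, build_network, \
    build_stress_network, SIDE_INDEX
from .neuron import NeuronParams
from .plasticity import PlasticityConfig, global_reward, \
    normalize_and_cap_column, update_reward_estimate
from .sorting import ChannelConfig, StreamingSorter, build_pulse_templates
from .synth import SynthMode, TuningMap

TARGETS = ("left", "right")
SAMPLE_NS = 32_000  # 31.25 kHz


@dataclass
class SessionConfig:
    seed: int = 0
    n_trials: int = 200
    reversal_at_trial: int | None = None
    max_trial_s: float = 3.0
    refractory_s: float = 2.0
    button_press_ms: float = 26.0
    mode: str = "direct"              # "direct" | "full_loop"
    lcg_seed: int | None = None       # defaults to `seed`
    record_spikes: bool = False
    pulse_amplitude: float = 1.0
    waveform_noise_sigma: float = 0.0
    neuron: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    tuning: TuningMap = field(default_factory=TuningMap)
    stress: StressConfig | None = None

    def __post_init__(self):
        if self.max_trial_s <= 0 or self.refractory_s <= 0:
            raise ValueError("durations must be positive")
        if self.reversal_at_trial is not None \
                and self.reversal_at_trial > self.n_trials:
            raise ValueError("reversal_at_trial must not exceed n_trials")
        if self.mode not in ("direct", "full_loop"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for ms in (self.button_press_ms, self.refractory_s * 1000,
                   self.max_trial_s * 1000, self.decoder.tick_ms,
                   self.decoder.enable_delay_ms):
            if abs(ms * NS_PER_MS % TICK_NS) > 1e-6:
                raise ValueError("all task cadences must sit on the 2-ms grid")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tuning"]["units"] = [
            {"ensemble": u.ensemble, "connected_to": list(u.connected_to)}
            for u in self.tuning.units]
        return d


@dataclass
class TrialRecord:
    index: int                   # 1-based
    target: str
    outcome: str                 # "correct" | "wrong" | "timeout"
    R_T: int
    duration_s: float
    n_ticks: int
    trajectory_error_pct: float
    R_bar: tuple[float, float]   # after the end-of-trial update
    reversed: bool


@dataclass
class SessionResult:
    config: SessionConfig
    records: list[TrialRecord]
    weight_snapshots: list[np.ndarray]   # at each trial start, plus final
    tick_log: list[tuple]                # (t_ns, trial, cl, cr, action, S, r, angle)
    scheduled_events: int
    delivered_events: int
    pending_events: int
    cortex_spikes: tuple[np.ndarray, np.ndarray] | None = None
    msn_spikes: tuple[np.ndarray, np.ndarray] | None = None
    sorted_spikes: tuple[np.ndarray, np.ndarray] | None = None


class _FullLoopFrontEnd:
    """Per-channel waveform synthesis + streaming spike sorting.

    One channel per synthesizer unit.  Spikes emitted during cycle k are
    rendered as analog pulses, sorted, and injected into the network at the
    start of cycle k+1; with >=3-ms synaptic delays every sorted event still
    arrives before its delivery time.
    """

    def __init__(self, n_channels: int, amplitude: float, noise_sigma: float,
                 rng: np.random.Generator):
        base = ChannelConfig()
        tpl, thr, offset = build_pulse_templates(base, amplitude)
        self.config = dataclasses.replace(base, threshold=thr)
        self.offset_ns = offset
        self.amplitude = amplitude
        self.noise_sigma = noise_sigma
        self.rng = rng
        self.sorters = [StreamingSorter([dataclasses.replace(tpl, unit_id=ch)],
                                        self.config)
                        for ch in range(n_channels)]
        self.samples_emitted = np.zeros(n_channels, dtype=np.int64)

    def process_cycle(self, t_end_ns: int, spk_t: np.ndarray,
                      spk_id: np.ndarray):
        """Render and sort this cycle's spikes; return (times, sources)."""
        from .synth import emit_waveform

        out_t, out_src = [], []
        g1 = t_end_ns // SAMPLE_NS
        for ch, sorter in enumerate(self.sorters):
            g0 = self.samples_emitted[ch]
            n = int(g1 - g0)
            if n <= 0:
                continue
            times = spk_t[spk_id == ch]
            raw = emit_waveform(times, int(g0 * SAMPLE_NS), n,
                                amplitude=self.amplitude,
                                noise_sigma=self.noise_sigma, rng=self.rng)
            for unit, ts, _wf in sorter.feed(raw):
                out_t.append(ts)
                out_src.append(unit)
            self.samples_emitted[ch] = g1
        if not out_t:
            return None
        order = np.argsort(out_t, kind="stable")
        return (np.asarray(out_t, dtype=np.int64)[order],
                np.asarray(out_src, dtype=np.int64)[order])


class _Runner:
    def __init__(self, cfg: SessionConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.net = build_network(cfg.tuning, cfg.plasticity, cfg.network,
                                 self.rng, stress=cfg.stress)
        lcg_seed = cfg.seed if cfg.lcg_seed is None else cfg.lcg_seed
        self.engine = Engine(self.net, cfg.neuron, lcg_seed=lcg_seed,
                             pair_window_ms=cfg.plasticity.pair_window_ms)
        self.plast_cols = self.net.plastic_columns()
        self.R_bar = [0.0, 0.0]
        self.n_k = [0, 0]
        self.deliv = [deque(), deque()]
        self.delay_ns = int(round(
            cfg.decoder.msn_to_decoder_delay_ms * NS_PER_MS))
        self.window_ns = int(round(cfg.decoder.window_ms * NS_PER_MS))
        self.life_ms = cfg.plasticity.lifetime_ms
        self.rates_baseline = self._rates(SynthMode("baseline"))
        self.tick_log: list[tuple] = []
        self.records: list[TrialRecord] = []
        self.snapshots: list[np.ndarray] = []
        self.spk_c: list[tuple] = []
        self.spk_m: list[tuple] = []
        self.spk_sorted: list[tuple] = []
        self.front = None
        self.pending_inj = None
        if cfg.mode == "full_loop":
            self.front = _FullLoopFrontEnd(
                self.net.n_units, cfg.pulse_amplitude,
                cfg.waveform_noise_sigma,
                np.random.default_rng(cfg.seed + 1))

    def _rates(self, mode: SynthMode) -> np.ndarray:
        r = self.cfg.tuning.rates(mode)
        if self.cfg.stress is not None:
            extra = np.full(self.cfg.stress.extra_units,
                            self.cfg.stress.extra_unit_rate_hz)
            r = np.concatenate([r, extra])
        return r

    def _advance(self, n_ticks: int, rates: np.ndarray):
        eng = self.engine
        rec = self.cfg.record_spikes
        if self.front is None:
            ct, cid, mt, mid = eng.advance(n_ticks, rates, direct=True,
                                           record_cortex=rec)
        else:
            cts, cids, mts, mids = [], [], [], []
            for _ in range(n_ticks):
                ct, cid, mt, mid = eng.advance(
                    1, rates, direct=False, record_cortex=True,
                    injected=self.pending_inj)
                inj = self.front.process_cycle(eng.t_ns, ct, cid)
                self.pending_inj = inj
                if inj is not None:
                    self.spk_sorted.append(inj)
                cts.append(ct); cids.append(cid)
                mts.append(mt); mids.append(mid)
            ct = np.concatenate(cts); cid = np.concatenate(cids)
            mt = np.concatenate(mts); mid = np.concatenate(mids)
        for t, j in zip(mt, mid):
            if j < 2:
                self.deliv[j].append(t + self.delay_ns)
        if rec:
            self.spk_c.append((ct, cid))
            self.spk_m.append((mt, mid))

    def _window_counts(self, t_ns: int) -> np.ndarray:
        counts = np.zeros(2, dtype=np.int64)
        lo = t_ns - self.window_ns
        for j in range(2):
            dq = self.deliv[j]
            while dq and dq[0] <= lo:
                dq.popleft()
            counts[j] = sum(1 for x in dq if x <= t_ns)
        return counts

    def _plasticity_tick(self, t_ns: int, r: float):
        if r == 0.0:
            return
        cfg = self.cfg.plasticity
        for col in self.plast_cols:
            e = self.engine.eligibility(col, t_ns, self.life_ms)
            w = self.net.syn_w[col] * (1.0 + cfg.mu * r * e)
            self.net.syn_w[col] = normalize_and_cap_column(
                w, cfg.W, cfg.alpha * cfg.W / col.size)

    def run(self) -> SessionResult:
        cfg = self.cfg
        dec = cfg.decoder
        press_ticks = int(round(cfg.button_press_ms * NS_PER_MS / TICK_NS))
        enable_ticks = int(round(dec.enable_delay_ms * NS_PER_MS / TICK_NS))
        refr_ticks = int(round(cfg.refractory_s * 1e9 / TICK_NS))
        tick_ticks = int(round(dec.tick_ms * NS_PER_MS / TICK_NS))
        tick_ns = tick_ticks * TICK_NS
        max_dur_ns = int(round(cfg.max_trial_s * 1e9))

        # lead-in: one refractory period of baseline activity
        self._advance(refr_ticks, self.rates_baseline)

        for trial in range(1, cfg.n_trials + 1):
            rev = (cfg.reversal_at_trial is not None
                   and trial >= cfg.reversal_at_trial)
            self.snapshots.append(self.net.weight_matrix())
            self._advance(press_ticks, self.rates_baseline)
            target = TARGETS[int(self.rng.integers(2))]
            k = SIDE_INDEX[target]
            rates_trial = self._rates(SynthMode("trial", target, rev))
            t_start = self.engine.t_ns
            self._advance(enable_ticks, rates_trial)

            arm = ArmState()
            target_angle = dec.target_angle[target]
            toward = target
            n_err = 0
            n_ticks_trial = 0
            outcome = "timeout"
            while self.engine.t_ns + tick_ns - t_start <= max_dur_ns:
                self._advance(tick_ticks, rates_trial)
                t_now = self.engine.t_ns
                counts = self._window_counts(t_now)
                action = decode_action(counts)
                prev_angle = arm.actual_angle
                arm = step_arm(arm, action, dec)
                S = sensory_error(prev_angle, arm.actual_angle, target_angle)
                r = global_reward(S, self.R_bar[k])
                self._plasticity_tick(t_now, r)
                n_ticks_trial += 1
                if action != toward:
                    n_err += 1
                self.tick_log.append((t_now, trial, int(counts[0]),
                                      int(counts[1]), action, S, r,
                                      arm.actual_angle))
                reach = check_reach(arm, target, dec)
                if reach != "none":
                    outcome = reach
                    break
            if outcome == "timeout":
                rem = (t_start + max_dur_ns - self.engine.t_ns) // TICK_NS
                if rem > 0:
                    self._advance(int(rem), rates_trial)
                duration = cfg.max_trial_s
            else:
                duration = (self.engine.t_ns - t_start) / 1e9
            R_T = 1 if outcome == "correct" else 0
            self.R_bar[k] = update_reward_estimate(self.R_bar[k], R_T,
                                                   cfg.plasticity.m)
            self.n_k[k] += 1
            traj_err = 100.0 * n_err / n_ticks_trial if n_ticks_trial else 0.0
            self.records.append(TrialRecord(
                index=trial, target=target, outcome=outcome, R_T=R_T,
                duration_s=duration, n_ticks=n_ticks_trial,
                trajectory_error_pct=traj_err,
                R_bar=(self.R_bar[0], self.R_bar[1]), reversed=rev))
            # synthesizer back to baseline; arm returns during refractory
            self._advance(refr_ticks, self.rates_baseline)
        self.snapshots.append(self.net.weight_matrix())

        def _cat(chunks):
            if not chunks:
                return None
            t = np.concatenate([c[0] for c in chunks])
            i = np.concatenate([c[1] for c in chunks])
            return t, i

        return SessionResult(
            config=cfg, records=self.records,
            weight_snapshots=self.snapshots, tick_log=self.tick_log,
            scheduled_events=self.engine.scheduled,
            delivered_events=self.engine.delivered,
            pending_events=self.engine.pending,
            cortex_spikes=_cat(self.spk_c) if cfg.record_spikes else None,
            msn_spikes=_cat(self.spk_m) if cfg.record_spikes else None,
            sorted_spikes=_cat(self.spk_sorted) if self.spk_sorted else None)


def run_session(config: SessionConfig) -> SessionResult:
    """Run one complete behavioural session (see module docstring)."""
    return _Runner(config).run()


def trial_frame(result: SessionResult) -> pd.DataFrame:
    """Per-trial records as a DataFrame (one row per trial)."""
    rows = [{
        "trial": r.index, "target": r.target, "outcome": r.outcome,
        "R_T": r.R_T, "duration_s": r.duration_s, "n_ticks": r.n_ticks,
        "trajectory_error_pct": r.trajectory_error_pct,
        "R_bar_left": r.R_bar[0], "R_bar_right": r.R_bar[1],
        "reversed": r.reversed,
    } for r in result.records]
    return pd.DataFrame(rows)


def weight_changes(result: SessionResult) -> np.ndarray:
    """Max absolute plastic-weight change across each trial (nS)."""
    snaps = result.weight_snapshots
    return np.array([np.max(np.abs(b - a))
                     for a, b in zip(snaps, snaps[1:])])


def convergence_trial(result: SessionResult, frac: float = 0.01,
                      within: int | None = None) -> int | None:
    """First trial from which every later per-trial weight change stays
    below frac * W (optionally restricted to trials < `within`)."""
    W = result.config.plasticity.W
    ch = weight_changes(result)
    if within is not None:
        ch = ch[:within - 1]
    below = ch < frac * W
    for c in range(below.size):
        if below[c:].all():
            return c + 1
    return None


def first_sustained_success(result: SessionResult, after: int = 0,
                            min_run: int = 10) -> int | None:
    """First trial index (> after) opening a run of >= min_run successes
    (a run truncated only by the session end also counts)."""
    rt = [r.R_T for r in result.records]
    n = len(rt)
    run = 0
    head = 0
    for i in range(n):
        if rt[i] == 1:
            if run == 0:
                head = i + 1
            run += 1
            if head > after and (run >= min_run or i == n - 1):
                return head
        else:
            run = 0
    return None


def initial_failures(result: SessionResult, min_run: int = 10) -> int | None:
    """Number of unsuccessful trials before sustained success sets in."""
    first = first_sustained_success(result, after=0, min_run=min_run)
    if first is None:
        return None
    return sum(1 for r in result.records[:first - 1] if r.R_T == 0)


def mean_trajectory_error(result: SessionResult, first: int,
                          last: int) -> float:
    """Mean per-trial trajectory error (%) over trials first..last inclusive."""
    vals = [r.trajectory_error_pct for r in result.records
            if first <= r.index <= last]
    return float(np.mean(vals))


def summarize_session(result: SessionResult) -> dict:
    """Session-level aggregates mirroring the per-trial learning-curve plots."""
    df = trial_frame(result)
    ch = weight_changes(result)
    out = {
        "n_trials": len(result.records),
        "success_rate": float(df["R_T"].mean()) if len(df) else float("nan"),
        "mean_duration_s": float(df["duration_s"].mean()) if len(df) else float("nan"),
        "mean_trajectory_error_pct": float(df["trajectory_error_pct"].mean())
            if len(df) else float("nan"),
        "first_trial_trajectory_error_pct":
            result.records[0].trajectory_error_pct if result.records else None,
        "convergence_trial": convergence_trial(
            result, within=result.config.reversal_at_trial),
        "first_sustained_success": first_sustained_success(result),
        "initial_failures": initial_failures(result),
        "max_weight_change_per_trial": ch.tolist(),
        "scheduled_events": result.scheduled_events,
        "delivered_events": result.delivered_events,
        "pending_events": result.pending_events,
    }
    if result.config.reversal_at_trial is not None:
        rev = result.config.reversal_at_trial
        out["reversal_at_trial"] = rev
        if any(r.index == rev for r in result.records):
            rrec = next(r for r in result.records if r.index == rev)
            out["reversal_trial_trajectory_error_pct"] = rrec.trajectory_error_pct
            out["reversal_trial_duration_s"] = rrec.duration_s
        out["reconvergence_trial"] = first_sustained_success(result, after=rev)
    return out


def run_learning_scenario(seed: int, n_trials: int = 200,
                          reversal_at_trial: int | None = 50,
                          **kwargs) -> SessionResult:
    """The reference 200-trial learning experiment with reversal at trial 50:
    naive equal weights, zero reward estimates, default tuning and rates."""
    cfg = SessionConfig(seed=seed, n_trials=n_trials,
                        reversal_at_trial=reversal_at_trial, **kwargs)
    return run_session(cfg)


def scenario_metrics(result: SessionResult) -> dict:
    """Learning-curve figures of merit for one scenario run."""
    rev = result.config.reversal_at_trial
    out = {
        "first_trial_error_pct": result.records[0].trajectory_error_pct,
        "initial_failures": initial_failures(result),
        "convergence_trial": convergence_trial(result, within=rev),
        "mean_error_120_200_pct": mean_trajectory_error(result, 120, 200),
    }
    if rev is not None:
        rrec = next(r for r in result.records if r.index == rev)
        out["reversal_trial_error_pct"] = rrec.trajectory_error_pct
        out["reversal_trial_duration_s"] = rrec.duration_s
        out["reconvergence_trial"] = first_sustained_success(result, after=rev)
    return out


def write_outputs(result: SessionResult, out_dir) -> None:
    """Delimited-text and JSON session outputs (CLI backend)."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = trial_frame(result)
    df.to_csv(out / "trials.csv", index=False)
    with open(out / "trials.json", "w") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=1)
    with open(out / "summary.json", "w") as fh:
        json.dump(summarize_session(result), fh, indent=1)
    actions = pd.DataFrame(
        result.tick_log,
        columns=["t_ns", "trial", "count_left", "count_right", "action",
                 "S", "r", "angle_deg"])
    actions.to_csv(out / "actions.csv", index=False)
    rows = []
    for trial0, snap in enumerate(result.weight_snapshots):
        ii, jj = np.nonzero(snap)
        for i, j in zip(ii, jj):
            rows.append((trial0 + 1, int(i), int(j), float(snap[i, j])))
    pd.DataFrame(rows, columns=["trial", "unit", "msn", "w_ns"]) \
        .to_csv(out / "weights.csv", index=False)
    if result.cortex_spikes is not None:
        t, i = result.cortex_spikes
        cortex = pd.DataFrame({"source_id": i, "t_ns": t,
                               "kind": "excitatory"})
        tm, im = result.msn_spikes
        msn = pd.DataFrame({"source_id": im + result.config.tuning.n_units,
                            "t_ns": tm, "kind": "inhibitory"})
        spikes = pd.concat([cortex, msn]).sort_values("t_ns")
        spikes.to_csv(out / "spikes.csv", index=False)
    import yaml

    with open(out / "session_config.yaml", "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh, sort_keys=False)
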