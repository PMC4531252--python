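"""Synthetic motor-cortex spike source (software signal synthesizer).

Replaces the hardware neural-signal synthesizer: 18 Poisson units in three
six-unit ensembles (left-tuned, right-tuned, untuned) draw one uniform
deviate per unit per 2-ms tick from a 32-bit linear congruential generator,

    x(s+1) = 1664525 x(s) + 1013904223  (mod 2^32),   x(0) = 0,

and spike when x/2^32 < rate * dt.  During a trial the ensemble tuned to the
selected target is elevated from ``baseline_rate`` to ``tuned_rate``;
reversal swaps which ensemble is elevated without touching baselines.

The synthesizer can also emit the analog channel waveforms the acquisition
chain sees: an inverted 100-us rectangular pulse per spike at 31.25 kHz,
optionally with additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import NS_PER_MS

LCG_A = _kernels.LCG_A
LCG_C = _kernels.LCG_C
LCG_MOD = _kernels.LCG_MOD

DEFAULT_TICK_NS = 2_000_000  # 2 ms
DEFAULT_FS = 31_250.0        # Hz
PULSE_US = 100.0


class LCG:
    """The 32-bit linear congruential generator of the signal synthesizer."""

    def __init__(self, seed: int = 0):
        if not 0 <= seed < LCG_MOD:
            seed = int(seed) % LCG_MOD
        self.state = int(seed)

    def next(self) -> int:
        self.state = (LCG_A * self.state + LCG_C) % LCG_MOD
        return self.state

    def uniform(self) -> float:
        """Uniform deviate in [0, 1) as x / 2^32."""
        return self.next() / LCG_MOD

    def fill(self, n: int) -> np.ndarray:
        """n successive raw 32-bit outputs (vector form of next())."""
        out = np.empty(n, dtype=np.int64)
        self.state = int(_kernels.lcg_fill(self.state, out))
        return out


def lcg_next(x: int) -> int:
    """Single LCG iteration with 32-bit wraparound."""
    return (LCG_A * x + LCG_C) % LCG_MOD


@dataclass(frozen=True)
class SynthMode:
    mode: str = "baseline"          # "baseline" | "trial"
    target: str | None = None       # "left" | "right" when mode == "trial"
    reversed: bool = False

    def __post_init__(self):
        if self.mode not in ("baseline", "trial"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "trial" and self.target not in ("left", "right"):
            raise ValueError("trial mode requires target 'left' or 'right'")


@dataclass(frozen=True)
class TuningUnit:
    ensemble: str                 # "left" | "right" | "untuned"
    connected_to: tuple[str, ...]  # subset of ("left", "right")


@dataclass
class TuningMap:
    """Per-unit directional tuning and MSN wiring.

    The default map has 18 units in three ensembles of six; in each ensemble
    four units connect to a single MSN and two to both, and the four
    single-target units split evenly between the two MSNs so that with equal
    weights the naive drive onto the two MSNs is balanced.  Cross-wired units
    (tuned one way, connected only to the opposite MSN) therefore exist in
    every ensemble.
    """

    units: list[TuningUnit] = field(default_factory=lambda: _default_units())
    baseline_rate: float = 7.0   # Hz, all units out of trial
    tuned_rate: float = 40.0     # Hz, preferred-direction units during a trial

    @property
    def n_units(self) -> int:
        return len(self.units)

    def rates(self, mode: SynthMode) -> np.ndarray:
        """Per-unit firing-rate vector (Hz) for the given synthesizer mode."""
        r = np.full(self.n_units, self.baseline_rate)
        if mode.mode == "trial":
            for i, unit in enumerate(self.units):
                ens = unit.ensemble
                if mode.reversed and ens in ("left", "right"):
                    ens = "right" if ens == "left" else "left"
                if ens == mode.target:
                    r[i] = self.tuned_rate
        return r


def _default_units() -> list[TuningUnit]:
    units = []
    for ens in ("left", "right", "untuned"):
        same = "left" if ens == "left" else "right"
        cross = "right" if ens == "left" else "left"
        if ens == "untuned":
            same, cross = "left", "right"
        units.append(TuningUnit(ens, (same,)))
        units.append(TuningUnit(ens, (cross,)))
        units.append(TuningUnit(ens, (same,)))
        units.append(TuningUnit(ens, (cross,)))
        units.append(TuningUnit(ens, ("left", "right")))
        units.append(TuningUnit(ens, ("left", "right")))
    return units


def set_mode(tuning: TuningMap, mode: SynthMode) -> np.ndarray:
    """Per-unit rate vector for a mode (functional form of TuningMap.rates)."""
    return tuning.rates(mode)


def generate_tick(rates_hz: np.ndarray, lcg: LCG,
                  dt_s: float = 0.002) -> np.ndarray:
    """One 2-ms Poisson tick: boolean spike vector, one LCG draw per unit.

    Draws are consumed in fixed unit order so that the spike stream is
    bit-reproducible for a given LCG state.
    """
    rates_hz = np.asarray(rates_hz, dtype=float)
    prob = rates_hz * dt_s
    if np.any(prob >= 1.0):
        raise ValueError("rate * dt must be < 1 for the per-tick Bernoulli draw")
    draws = lcg.fill(rates_hz.size)
    return draws < prob * LCG_MOD


def emit_waveform(spike_times_ns: np.ndarray, t0_ns: int, n_samples: int,
                  fs: float = DEFAULT_FS, amplitude: float = 1.0,
                  noise_sigma: float = 0.0,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Analog channel stream: inverted 100-us pulses on a noisy baseline.

    Sample i sits at t0_ns + i/fs; a spike at t adds -amplitude to every
    sample whose time lies in [t, t + 100 us), i.e. 3-4 samples at 31.25 kHz.
    """
    x = np.zeros(n_samples)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        x += rng.normal(0.0, noise_sigma, n_samples)
    dt_ns = 1e9 / fs
    width_ns = PULSE_US * 1000.0
    for t in np.atleast_1d(np.asarray(spike_times_ns, dtype=np.int64)):
        if t + width_ns <= t0_ns:
            continue
        i0 = int(np.ceil((t - t0_ns) / dt_ns - 1e-9))
        i1 = int(np.ceil((t + width_ns - t0_ns) / dt_ns - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, n_samples)
        if i1 > i0:
            x[i0:i1] -= amplitude
    return x
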