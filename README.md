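# spikeloop

A virtual-time, software-only simulator of a closed-loop neuroprosthetic
controller built from spiking model neurons. It is aimed at computational
neuroscientists and neural engineers who want to study reinforcement-driven
brain–machine-interface (BMI) control — decoder, plasticity rule, behavioural
paradigm and all — without real-time hardware: every cadence of the original
hard real-time system (2-ms spike synthesis, 250-µs neuron integration,
512-µs acquisition blocks, 26-ms decoder commands) runs on one deterministic
logical clock with nanosecond event resolution.

## The model

Two *medium spiny neurons* (MSNs, the bistable projection neurons of the
striatum) are simulated with the Izhikevich simple model plus fast
conductance-based synapses:

    C v' = k (v − v_r)(v − v_t) − u − η (v − E_η) − γ (v − E_γ)
    u'   = a (b (v − v_r) − u)
    η' = −η/τ_η,   γ' = −γ/τ_γ,          v ≥ v_peak ⇒ v ← c, u ← u + d

with the MSN constants a = 0.01, b = −20, c = −55 mV, d = 150, C = 50 pF,
k = 1, v_r = −80 mV, v_t = −25 mV, v_peak = 40 mV, E_η = 0, E_γ = −110 mV,
τ_η = 6 ms, τ_γ = 20 ms. Integration uses the Parker–Sochacki power-series
method over 250-µs global steps split at incoming synaptic events.

Eighteen synthetic motor-cortex units (three six-unit ensembles: left-tuned,
right-tuned, untuned) emit Poisson spikes every 2 ms from a 32-bit linear
congruential generator, x(s+1) = 1664525·x(s) + 1013904223 (mod 2³²), and are
partially wired onto the two MSNs through plastic excitatory synapses
(delays U(3, 5) ms). The MSNs inhibit each other with fixed 40-nS synapses
(delays U(2.5, 3) ms), forming a winner-take-all circuit. Every 26 ms the MSN
with the higher spike count in a trailing 104-ms window steps a 1-D virtual
arm ±1°; ties leave it stationary. Learning is reward-modulated STDP:

    Δw_ij = µ w_ij r(t) e_ij(t),    r(t) = (1 − R̄_k) S(t)

where e_ij is a binary eligibility trace (set when MSN j fires ≤ 40 ms after
unit i, lifetime 100 ms), S = ±1 says whether the last arm step moved toward
the selected target, and R̄_k is a running mean of recent success for target
k — so learning self-terminates at perfect performance. After every update
each MSN's excitatory weight column is renormalized to the fixed total
W = 110 nS under the cap w_max = α·W/N_j (homeostatic scaling).

The package also implements the acquisition chain the original system used
(4th-order Butterworth band-pass 400 Hz–8 kHz at 31.25 kHz, cubic upsampling
to 62.5 kHz, level-threshold detection, 18-sample waveforms, multivariate-
Gaussian template matching), so sessions can run either in `direct` mode
(spikes become synaptic events immediately) or `full_loop` mode (spikes are
rendered as inverted 100-µs analog pulses and must be re-sorted).

## Worked example

```python
from spikeloop.session import run_learning_scenario, scenario_metrics, trial_frame

res = run_learning_scenario(seed=3)           # 200 trials, reversal at 50
print(trial_frame(res).iloc[48:52][["trial", "target", "outcome",
                                    "duration_s", "trajectory_error_pct"]])
print(scenario_metrics(res))
```

prints (a ~5-s computation):

```
    trial target  outcome  duration_s  trajectory_error_pct
48     49  right  correct       1.028              0.000000
49     50   left    wrong       1.028            100.000000
50     51   left    wrong       1.028            100.000000
51     52   left    wrong       1.028            100.000000

{'first_trial_error_pct': 29.76, 'initial_failures': 0,
 'convergence_trial': 10, 'mean_error_120_200_pct': 4.04,
 'reversal_trial_error_pct': 100.0, 'reversal_trial_duration_s': 1.028,
 'reconvergence_trial': 60}
```

Reading this: the naive controller starts with ~30% of its 26-ms commands
not pointing at the target, reaches sustained success immediately, and its
weights stop changing by trial 10. When the tuning map is reversed at trial
50 the arm drives straight to the *wrong* target (100% trajectory error in
the minimum possible 1.028 s — 40-ms enable delay plus 38 one-degree steps);
performance collapses, the reward estimates deflate, re-learning kicks in,
and sustained success returns at trial 60, after which the converged
trajectory error settles around 4%.

A shell front end writes delimited-text logs (`actions.csv`, `spikes.csv`,
`weights.csv`, `trials.json`, `summary.json`):

```
spikeloop run --seed 2 --trials 200 --reversal-at 50 --out out/ --record-spikes
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole experiment from scratch: it executes 20 seeded 200-trial
reversal sessions with the default (naive, equal-weight) controller and
recomputes the learning-curve quantities — the LCG's first output, the mean
naive first-trial trajectory error, the first post-reversal trial's error,
the weight-convergence trial, the trial at which accuracy is regained after
reversal, and the converged trajectory error over trials 120–200 — writing
them as JSON. It takes about a minute on one CPU.
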