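# Methods

## Scope and design

`spikeloop` re-creates, in virtual time, a closed-loop neuroprosthetic
control experiment: synthetic, directionally tuned motor-cortex spike trains
drive two model medium spiny neurons (MSNs) through plastic simulated
synapses; a winner-take-all decoder converts MSN spike counts into one-degree
steps of a 1-D arm; and reward-modulated STDP learns a two-target reaching
task, including reversal learning. Real-time concerns of the original
system — interrupt scheduling, CPU pinning, jitter, serial servo control —
are out of scope by construction: all task cadences (512 µs acquisition,
2 ms synthesis/simulation task cycles, 26 ms decoding) are intervals on one
discrete-event clock with integer-nanosecond event times, so jitter is zero
and runs are bit-reproducible for a fixed seed.

## Neuron model and integration

MSNs use the Izhikevich simple model with conductance-based synapses
(parameters in the README). Two numerical points deserve note:

* **Recovery equation.** The textbook form u' = a(bv − u) has, with the MSN
  constant b = −20 nS, no fixed point near rest: the down state (v_r, 0)
  would not be stationary and the characteristic down/up-state bistability
  disappears. The canonical bistable MSN formulation
  u' = a(b(v − v_r) − u) is therefore the default; the flag
  `NeuronParams(literal_eq3=True)` restores the uncorrected form for
  comparison. Nothing else in the package depends on the choice.
* **Parker–Sochacki integration.** The polynomial right-hand sides admit
  exact power-series recurrences (Cauchy products for the quadratic and the
  conductance–voltage terms). Each 250-µs global step is split at incoming
  synaptic events; each sub-interval is expanded to adaptive order
  (default cap 16 terms) with truncation once two consecutive terms
  contribute < 1e-10 at the interval end; a non-convergent series (typical
  near the spike blow-up) halves the local step and retries. Threshold
  crossings are located by bisection on the series polynomial, giving spike
  times at nanosecond resolution, and the Eq-style reset (v ← c, u ← u + d)
  is applied mid-interval. Against a 1-µs fixed-step RK4 reference on 1-s
  driven runs the integrator produces identical spike counts, spike times
  within a few µs, and sub-0.1-mV trajectories between spikes (tested).

Event bookkeeping is conservative by contract: every scheduled synaptic
event is delivered exactly once, in (delivery-time, source-id) order;
sessions assert scheduled = delivered + in-flight.

## Synthetic cortex

Eighteen units in three ensembles (left, right, untuned) spike as Bernoulli
processes on a 2-ms tick, one LCG draw per unit per tick in fixed unit
order, with uniform deviate x/2³² from the 32-bit recurrence
x(s+1) = 1664525·x(s) + 1013904223. The stress population's 14 high-rate
units draw from a second, independently seeded LCG instance, mirroring the
original two-synthesizer hardware; this keeps the primary units' spike
streams identical with and without the stress load (tested).

**Rates.** Baseline and tuned firing rates are not printed in the source
material; the stated calibration criterion is that with W = 110 nS and
40-nS inhibition the MSN baseline rate must land in the 2–5 Hz band.
Defaults: `baseline_rate = 7 Hz` (measured MSN baseline ≈ 2.9–3.6 Hz,
mid-band; 5 Hz leaves the MSNs at ≈ 1.2 Hz, below band) and
`tuned_rate = 40 Hz` for a unit's preferred direction during a trial.
Both are configurable and were fixed once, before the learning-curve
quantities were measured.

**Wiring.** Per ensemble, four units connect to a single MSN and two to
both. The four single-target units split 2/2 between the two MSNs, so each
MSN receives N_j = 12 synapses and — crucially — the *naive* drive onto the
two MSNs is exactly balanced in every trial mode (tested). With an
unbalanced split the naive controller would be born biased toward one
target, which contradicts the ~50% naive-error observation the task is
designed around. Cross-wired units (tuned one way, connected only to the
opposite MSN) exist in both tuned ensembles. The map is config-overridable.

## Plasticity

Binary eligibility traces are all-to-all within windows: any pre spike
followed by a post spike within 40 ms sets the synapse's trace, the trace
expires 100 ms after its (latest) trigger, and a re-trigger restarts the
lifetime. The engine tracks, per unit, only the most recent pre spike —
sufficient for a binary trace under this rule. Weight updates
w ← w(1 + µ r e) run every 26-ms decoder tick while robot control is active
(enable +40 ms after trial start until trial end); inter-trial ticks leave
weights frozen. r = (1 − R̄_k)·S with S = −1 for any tick that does not move
the arm strictly toward the target (a stationary arm is "otherwise" under
the toward/otherwise rule). R̄_k updates once per trial, for the selected
target only, as a running mean with window m.

**Normalization and cap.** Rescaling a column to the fixed total W and
capping every weight at w_max = α·W/N_j can conflict if done once in either
order; the implementation iterates clip-and-redistribute to the joint fixed
point, equivalent to w' = min(c·w, w_max) with a single scale c solving
Σ min(c·w, w_max) = W (feasible since α > 1; tested against a bisection
oracle). Defaults α = 2, m = 3: neither value is printed in the source
material; m = 3 lets R̄ climb from 0 to ≈ 1 over a handful of successful
trials, and α = 2 leaves the cap slack at the equal-weight start.

## Decoder and plant

Spike counts use a trailing 104-ms window of MSN spikes delivered to the
decoder with a 3-ms transmission delay; the first command is issued one
26-ms tick after control enable. Targets sit at ±38° from the default
position — not printed in the source; chosen so the ideal reach
(40 ms + 38 ticks × 26 ms = 1.028 s) matches the reported ~1-s converged
trial length — with a 0.5° (half-step) reach tolerance. An optional
single-pole 60-ms lag models arm inertia and is off by default so that the
kinematics of the core experiment are deterministic.

## Acquisition chain (full-loop mode)

Each unit drives one analog channel: an inverted 100-µs rectangular pulse
per spike at 31.25 kHz (3–4 samples), optional additive Gaussian noise. The
sorter applies a causal 4th-order Butterworth band-pass (400 Hz–8 kHz) with
state persisting across 512-µs blocks, factor-2 cubic upsampling for
alignment, negative-going level-threshold detection with an 18-sample
capture window (6 pre / 12 post the crossing — the placement is a package
choice; only the 18-sample span is given), timestamping at the upsampled
waveform minimum, and maximum-likelihood template matching under a
multivariate Gaussian per unit (d = 18). Likelihoods are evaluated in the
log domain — the linear-scale density underflows easily at d = 18 — with
acceptance thresholds compared on the same scale; argmax ties break toward
the lowest unit id. Sample covariances from degenerate waveform sets are
regularized with 1e-6·trace(Σ)/d on the diagonal. Templates for the
synthesizer's pulse channels are built programmatically (the stand-in for
GUI waveform picking) from 60 detected calibration pulses; units sharing a
channel are calibrated with the channel's common threshold so window
alignment matches run-time detection.

With noiseless pulses and exact templates, a full-loop baseline run
reproduces the direct-mode event stream spike for spike, shifted by one
fixed alignment offset (64 µs; tested). Once trials close the loop, a
single displaced trial end changes the synthesizer schedule, so cross-mode
equality is only asserted on open-loop (baseline) segments.

## What the synthetic world does and does not establish

The generator emulates stationary Poisson tuning with a static map; real
motor cortex exhibits co-adaptation, non-Poisson statistics, correlated
noise, and electrode nonstationarities, none of which are modelled. A green
learning-curve test therefore establishes that the controller — decoder,
plasticity and paradigm as specified — solves this stated world, not that
it would perform identically in vivo.

Quantitatively, the virtual experiment reproduces the qualitative learning
arc: balanced ~30–50% naive behaviour, rapid acquisition, self-terminating
weight change, total collapse on reversal (100% error in exactly the
minimum 1.028-s reach onto the wrong target), recovery, and a low converged
trajectory error (~2.5% across seeds vs the reported ~5.9%). Two printed
single-run figures are *not* matched under the documented defaults: the
mean naive first-trial error settles near 33% rather than ~50% (with R̄ = 0
the within-trial reinforcement already corrects wrong-heading runs inside
trial 1), and the weights stop changing by ≈ trial 9 rather than ≈ 40
(weight change is proportional to 1 − R̄, which saturates within a few
successful trials at m = 3). Both quantities are strongly controlled by the
unprinted tuned rate, α and m; the defaults were fixed before measurement
and deliberately not tuned toward the published numbers.

## Degenerate inputs and numerical conventions

Times are integer nanoseconds end to end; dynamics run in float64
ms/mV/nS/pA. Simultaneous synaptic events merge in ascending source-id
order (additive, hence order-invariant for the state). Zero-rate units
never consume spikes but still consume their LCG draw, keeping streams
aligned across modes. Sessions with n_trials = 0 run only the baseline
lead-in (one refractory period) and leave weights untouched. All module
configurations validate their invariants at construction (grid alignment of
cadences, v_r < v_t < v_peak, α > 1, window = 4 ticks, positive durations).
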