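"""Acquisition-side spike sorting chain.

Mirrors the signal path of an extracellular recording front end: a causal
4th-order Butterworth band-pass (400 Hz - 8 kHz) applied to 31.25-kHz channel
data, factor-2 cubic upsampling to 62.5 kHz for alignment, negative-going
level-threshold detection with an 18-sample capture window (6 pre / 12 post),
timestamping at the waveform's lowest peak, and classification by maximum
multivariate-Gaussian likelihood

    p(x | C_i) = (2 pi)^(-d/2) |Sigma_i|^(-1/2)
                 exp[-1/2 (x - mu_i)^T Sigma_i^-1 (x - mu_i)],   d = 18.

Likelihoods are evaluated in the log domain (at d = 18 the raw density
underflows easily); acceptance thresholds are compared on the same scale.
A spike whose best likelihood falls below the winning unit's threshold is
discarded as an interfering signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ChannelConfig:
    fs_in: float = 31_250.0
    fs_up: float = 62_500.0
    band: tuple[float, float] = (400.0, 8000.0)
    filter_order: int = 4          # overall band-pass order
    threshold: float = -0.5        # signal units, negative-going
    waveform_len: int = 18         # samples at fs_in (576 us span)
    pre_samples: int = 6           # capture placement around the crossing
    post_samples: int = 12

    def __post_init__(self):
        if self.waveform_len != self.pre_samples + self.post_samples:
            raise ValueError("waveform_len must equal pre + post samples")


def butter_coeffs(config: ChannelConfig):
    return signal.butter(config.filter_order // 2, config.band,
                         btype="bandpass", fs=config.fs_in)


def filter_bandpass(x: np.ndarray, config: ChannelConfig) -> np.ndarray:
    """Causal band-pass from rest (use StreamingFilter for block streams)."""
    b, a = butter_coeffs(config)
    return signal.lfilter(b, a, np.asarray(x, dtype=float))


class StreamingFilter:
    """Causal Butterworth filter whose state persists across blocks."""

    def __init__(self, config: ChannelConfig):
        self._b, self._a = butter_coeffs(config)
        self._zi = np.zeros(max(len(self._a), len(self._b)) - 1)

    def process(self, x: np.ndarray) -> np.ndarray:
        y, self._zi = signal.lfilter(self._b, self._a,
                                     np.asarray(x, dtype=float), zi=self._zi)
        return y


def upsample_cubic(x: np.ndarray) -> np.ndarray:
    """Factor-2 upsampling by cubic interpolation.

    Output sample 2i equals input sample i exactly; odd samples are the
    piecewise-cubic values at the midpoints.  Output length is 2n - 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples for cubic interpolation")
    grid = np.arange(n)
    cs = CubicSpline(grid, x)
    out = np.empty(2 * n - 1)
    out[0::2] = x
    out[1::2] = cs(grid[:-1] + 0.5)
    return out


def detect_and_extract(x: np.ndarray, config: ChannelConfig,
                       t0_ns: int = 0) -> list[tuple[np.ndarray, int]]:
    """Threshold detection on a filtered stream.

    A negative-going crossing of config.threshold opens an 18-sample capture
    window (pre/post around the crossing); the spike is timestamped at the
    minimum of the upsampled trace inside the window, and further crossings
    are locked out until the window completes.  Partial windows at either
    end of the stream are discarded.
    """
    x = np.asarray(x, dtype=float)
    thr = config.threshold
    dt_up_ns = 1e9 / config.fs_up
    out = []
    i = 1
    n = x.size
    while i < n:
        if x[i] <= thr < x[i - 1]:
            lo = i - config.pre_samples
            hi = i + config.post_samples
            if lo < 0:
                i += 1
                continue
            if hi > n:
                break  # truncated window at stream end
            wf = x[lo:hi].copy()
            xu = upsample_cubic(wf)
            k = int(np.argmin(xu))
            ts = t0_ns + int(round((2 * lo + k) * dt_up_ns))
            out.append((wf, ts))
            i = hi
        else:
            i += 1
    return out


@dataclass
class SpikeTemplate:
    """Single-unit template: sample mean/covariance of 60 chosen waveforms."""

    unit_id: int
    mean: np.ndarray
    cov: np.ndarray
    cov_inverse: np.ndarray = None
    log_sqrt_det: float = None
    prob_threshold: float | None = None   # linear scale; None accepts all
    regularized: bool = False

    @property
    def sqrt_det(self) -> float:
        return float(np.exp(self.log_sqrt_det))

    @property
    def log_prob_threshold(self) -> float:
        if self.prob_threshold is None or self.prob_threshold <= 0:
            return -np.inf
        return float(np.log(self.prob_threshold))


def build_template(waveforms: np.ndarray, unit_id: int = 0,
                   prob_threshold: float | None = None) -> SpikeTemplate:
    """Mean, covariance and their cached derived quantities.

    The inverse and sqrt-determinant are evaluated once here, as the sorter
    applies the likelihood to every detected spike.  A singular sample
    covariance (e.g. identical waveforms) is regularized by adding
    1e-6 * trace(Sigma)/d to the diagonal.
    """
    W = np.asarray(waveforms, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need at least 2 waveforms of equal length")
    d = W.shape[1]
    mean = W.mean(axis=0)
    cov = np.cov(W, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    regularized = False
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eps = 1e-6 * max(np.trace(cov), 1.0) / d
        cov = cov + eps * np.eye(d)
        regularized = True
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:  # still not PD after regularization: fall back harder
        cov = cov + 1e-6 * np.eye(d)
        sign, logdet = np.linalg.slogdet(cov)
        regularized = True
    return SpikeTemplate(unit_id=unit_id, mean=mean, cov=cov,
                         cov_inverse=np.linalg.inv(cov),
                         log_sqrt_det=0.5 * float(logdet),
                         prob_threshold=prob_threshold,
                         regularized=regularized)


def log_likelihood(x: np.ndarray, template: SpikeTemplate) -> float:
    """log p(x | C_i) of the multivariate-Gaussian unit model."""
    x = np.asarray(x, dtype=float)
    if x.shape != template.mean.shape:
        raise ValueError("waveform dimension does not match the template")
    dxv = x - template.mean
    maha = float(dxv @ template.cov_inverse @ dxv)
    d = x.size
    return -0.5 * d * LOG_2PI - template.log_sqrt_det - 0.5 * maha


def likelihood(x: np.ndarray, template: SpikeTemplate) -> float:
    """Direct (linear-scale) density; underflows to 0 for distant x at d=18."""
    return float(np.exp(log_likelihood(x, template)))


def classify_waveform(x: np.ndarray,
                      templates: list[SpikeTemplate]) -> int | None:
    """Highest-likelihood unit, or None (discard) below its threshold.

    Ties are broken toward the lowest unit id, making the result invariant
    to the ordering of the template list.
    """
    if not templates:
        raise ValueError("template list is empty")
    best = None
    for tpl in sorted(templates, key=lambda t: t.unit_id):
        ll = log_likelihood(x, tpl)
        if best is None or ll > best[0]:
            best = (ll, tpl)
    ll, tpl = best
    if ll < tpl.log_prob_threshold:
        return None
    return tpl.unit_id


class StreamingSorter:
    """Block-streaming detection + classification for one channel.

    Emulates the 512-us acquisition cadence: raw sample blocks of any length
    are filtered with persistent state, buffered, and scanned for threshold
    crossings whose capture window is complete.  Crossings whose window is
    still pending stay queued for the next block.
    """

    def __init__(self, templates: list[SpikeTemplate], config: ChannelConfig,
                 t0_ns: int = 0):
        self.templates = templates
        self.config = config
        self.t0_ns = t0_ns
        self._filt = StreamingFilter(config)
        self._buf = np.empty(0)
        self._start = 0          # absolute input-sample index of _buf[0]
        self._cursor = 1         # absolute index of next candidate crossing
        self.n_detected = 0
        self.n_discarded = 0

    def feed(self, x: np.ndarray) -> list[tuple[int, int, np.ndarray]]:
        """Consume one raw block; return completed (unit_id, t_ns, waveform)."""
        cfg = self.config
        y = self._filt.process(x)
        self._buf = np.concatenate([self._buf, y])
        out = []
        dt_up_ns = 1e9 / cfg.fs_up
        end = self._start + self._buf.size
        while self._cursor < end:
            i = self._cursor
            rel = i - self._start
            if rel < 1:
                self._cursor = self._start + 1
                continue
            if not (self._buf[rel] <= cfg.threshold < self._buf[rel - 1]):
                self._cursor += 1
                continue
            lo = i - cfg.pre_samples
            hi = i + cfg.post_samples
            if lo < 0:
                self._cursor += 1
                continue
            if hi > end:
                break  # wait for the rest of the window
            wf = self._buf[lo - self._start: hi - self._start].copy()
            xu = upsample_cubic(wf)
            k = int(np.argmin(xu))
            ts = self.t0_ns + int(round((2 * lo + k) * dt_up_ns))
            self.n_detected += 1
            unit = classify_waveform(wf, self.templates)
            if unit is None:
                self.n_discarded += 1
            else:
                out.append((unit, ts, wf))
            self._cursor = hi
        # trim the buffer, keeping enough history for a pending window
        keep_from = max(self._cursor - cfg.pre_samples - 2, self._start)
        if keep_from > self._start + 4096:
            self._buf = self._buf[keep_from - self._start:]
            self._start = keep_from
        return out


def build_pulse_templates(config: ChannelConfig, amplitude: float,
                          n_waveforms: int = 60, unit_id: int = 0,
                          noise_sigma: float = 0.0,
                          rng: np.random.Generator | None = None,
                          threshold: float | None = None):
    """Template + detection threshold for a synthesizer pulse channel.

    Plays a train of inverted 100-us pulses through the filter chain, sets
    the threshold at half the filtered pulse trough (unless a shared channel
    threshold is given), and builds the unit template from the detected
    waveforms — the programmatic equivalent of picking waveforms in an
    acquisition GUI.  Returns (template, threshold, mean_offset_ns) where
    mean_offset_ns is the fixed lag between a pulse onset and its assigned
    timestamp.  When several units share a channel, build all their
    templates with the channel's common threshold so that window alignment
    matches the run-time detection.
    """
    from .synth import emit_waveform

    fs = config.fs_in
    spacing_ns = int(10e6)                     # 10 ms between pulses
    warmup_ns = int(20e6)
    times = warmup_ns + spacing_ns * np.arange(n_waveforms)
    n_samples = int((times[-1] + spacing_ns) * fs / 1e9)
    raw = emit_waveform(times, 0, n_samples, fs=fs, amplitude=amplitude,
                        noise_sigma=noise_sigma, rng=rng)
    filt = filter_bandpass(raw, config)
    trough = float(filt.min())
    threshold = 0.5 * trough if threshold is None else threshold
    cfg = ChannelConfig(fs_in=config.fs_in, fs_up=config.fs_up,
                        band=config.band, filter_order=config.filter_order,
                        threshold=threshold,
                        waveform_len=config.waveform_len,
                        pre_samples=config.pre_samples,
                        post_samples=config.post_samples)
    hits = detect_and_extract(filt, cfg)
    if len(hits) < 2:
        raise RuntimeError("pulse calibration detected too few waveforms")
    wfs = np.array([wf for wf, _ in hits])
    stamps = np.array([ts for _, ts in hits], dtype=np.int64)
    offsets = []
    for ts in stamps:
        k = np.searchsorted(times, ts) - 1
        if 0 <= k < len(times):
            offsets.append(ts - times[k])
    tpl = build_template(wfs, unit_id=unit_id)
    return tpl, threshold, int(np.mean(offsets))
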