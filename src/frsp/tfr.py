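"""Wavelet time-frequency decomposition and fixation-locked spectral perturbation.

The decomposition convolves each channel with a bank of Hanning-tapered
3-cycle complex sinusoidal wavelets (constant cycle count across frequencies,
3-70 Hz by default) and squares the magnitude. The fixation-related spectral
perturbation (FRSP) is the dB log ratio of post-event power to the mean power
in a pre-event baseline window, averaged over trials: the fixation-locked
analogue of the event-related spectral perturbation (ERSP).

Each kernel is normalized so that a unit-amplitude sinusoid at its centre
frequency yields unit power; the FRSP is invariant to that choice (and to any
rescaling of the raw signal), since it is a power *ratio*.

Wavelet edges: a frequency-f kernel spans round(3 fs / f) samples, so power
estimates within half a kernel of an epoch edge mix in zero padding. Epoched
mode marks those samples invalid in a per-(frequency, time) mask; continuous
mode convolves the full recording first and carries no interior mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy.signal import windows


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet bank: frequency grid (Hz), cycles per wavelet, sampling rate."""

    freqs: np.ndarray = field(default_factory=lambda: np.arange(3.0, 71.0))
    n_cycles: float = 3.0
    fs: float = 500.0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if freqs.ndim != 1 or len(freqs) == 0:
            raise ValueError("freqs must be a non-empty 1-D grid")
        if freqs.min() <= 0 or freqs.max() >= self.fs / 2:
            raise ValueError("frequencies must lie in (0, fs/2)")

    def kernel_length(self, f: float) -> int:
        """Nominal kernel length round(n_cycles * fs / f); odd-adjusted."""
        n = int(round(self.n_cycles * self.fs / f))
        return n if n % 2 == 1 else n + 1


DEFAULT_WAVELETS = WaveletSpec()


def build_wavelet(f: float, spec: WaveletSpec) -> np.ndarray:
    """Complex Hann-tapered wavelet at frequency ``f``.

    kernel(t) = Hann(L) * exp(i 2 pi f t), L = round(n_cycles fs / f) samples
    (odd-adjusted so the peak sits on a sample), normalized so a
    unit-amplitude sinusoid at f yields unit power.
    """
    if not 0 < f < spec.fs / 2:
        raise ValueError("frequency must lie in (0, fs/2)")
    L = spec.kernel_length(f)
    n = np.arange(L) - L // 2
    w = windows.hann(L, sym=True)
    kernel = w * np.exp(2j * np.pi * f * n / spec.fs)
    return kernel / (w.sum() / 2.0)


@dataclass
class TFDecomposition:
    """Power over (trials x) channels x frequencies x times, with validity mask."""

    power: np.ndarray  # (n_trials, n_ch, n_freqs, n_times) or (n_ch, n_freqs, n_times)
    freqs: np.ndarray  # Hz
    times: np.ndarray  # ms relative to the locking event (or recording start)
    mask: np.ndarray  # (n_freqs, n_times) bool, True where the full kernel fits
    fs: float
    ch_names: tuple[str, ...] | None = None

    @property
    def epoched(self) -> bool:
        return self.power.ndim == 4


@dataclass
class FRSPResult:
    """Baseline-normalized dB power change per channel/frequency/time."""

    db: np.ndarray  # (n_ch, n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    mask: np.ndarray
    baseline_ms: tuple[float, float]
    scheme: str
    ch_names: tuple[str, ...] | None = None
    condition: str | None = None
    subject: int | None = None


def _tf_epoched(
    x: np.ndarray, spec: WaveletSpec, decim: int, max_chunk_bytes: int
) -> tuple[np.ndarray, np.ndarray]:
    n_trials, n_ch, n_t = x.shape
    freqs = spec.freqs
    lengths = [spec.kernel_length(f) for f in freqs]
    nfft = sfft.next_fast_len(n_t + max(lengths) - 1)
    kernels_f = np.stack(
        [sfft.fft(build_wavelet(f, spec), nfft).astype(np.complex64) for f in freqs]
    )
    t_idx = np.arange(0, n_t, decim)

    power = np.empty((n_trials, n_ch, len(freqs), len(t_idx)), dtype=np.float32)
    # chunk trials so the complex spectra stay within a modest footprint
    per_trial = n_ch * nfft * 8  # complex64 bytes
    chunk = max(1, min(n_trials, max_chunk_bytes // max(per_trial, 1)))
    for lo in range(0, n_trials, chunk):
        hi = min(lo + chunk, n_trials)
        X = sfft.fft(x[lo:hi].astype(np.complex64), nfft, axis=-1, workers=1)
        for fi, (L, Kf) in enumerate(zip(lengths, kernels_f)):
            y = sfft.ifft(X * Kf, axis=-1, workers=1)
            seg = y[..., L // 2 + t_idx]
            power[lo:hi, :, fi, :] = (seg.real**2 + seg.imag**2)
    mask = np.zeros((len(freqs), len(t_idx)), dtype=bool)
    for fi, L in enumerate(lengths):
        half = L // 2
        mask[fi] = (t_idx >= half) & (t_idx <= n_t - 1 - half)
    return power, mask


def tf_transform(
    signal: np.ndarray,
    spec: WaveletSpec = DEFAULT_WAVELETS,
    mode: str = "epoched",
    times_ms: np.ndarray | None = None,
    decim: int = 1,
    ch_names: tuple[str, ...] | None = None,
    max_chunk_bytes: int = 64_000_000,
) -> TFDecomposition:
    """Wavelet power of an epoched array (trials, channels, times) or a
    continuous recording (channels, times).

    ``decim`` keeps every decim-th output time column (power is computed at
    full temporal resolution; only the output grid is thinned). In epoched
    mode, samples within half a kernel of the epoch edges are masked invalid;
    continuous mode masks only the recording's own edges.
    """
    x = np.asarray(signal)
    if np.isnan(x).any():
        raise ValueError("signal contains NaN samples")
    if mode not in ("epoched", "continuous"):
        raise ValueError("mode must be 'epoched' or 'continuous'")
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("signal must be (trials, channels, times) or (channels, times)")
    n_t = x.shape[-1]
    max_len = max(spec.kernel_length(f) for f in spec.freqs)
    if mode == "epoched" and n_t < max_len:
        warnings.warn(
            "epoch shorter than the longest kernel: validity mask will be "
            "empty at the lowest frequencies",
            stacklevel=2,
        )

    power, mask = _tf_epoched(x, spec, decim, max_chunk_bytes)
    if squeeze:
        power = power[0]

    t_idx = np.arange(0, n_t, decim)
    if times_ms is None:
        times = t_idx * 1000.0 / spec.fs
    else:
        times = np.asarray(times_ms, dtype=float)[t_idx]
    return TFDecomposition(
        power=power, freqs=spec.freqs.copy(), times=times, mask=mask,
        fs=spec.fs, ch_names=ch_names,
    )


def epoch_by_events(
    data: np.ndarray,
    fs: float,
    event_samples: np.ndarray,
    window_ms: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slice (channels, times) data into event-locked epochs.

    Windows are half-open [t0, t1) in ms relative to each event onset, sliced
    at sample resolution with the event sample on the post-event side. Events
    whose window does not fit inside the recording are dropped (their count is
    reported through the returned keep mask).

    Returns (epochs (n_kept, n_ch, n_samp), times_ms, kept_mask).
    """
    data = np.asarray(data)
    event_samples = np.asarray(event_samples, dtype=int)
    t0, t1 = window_ms
    s0 = int(round(t0 * fs / 1000.0))
    s1 = int(round(t1 * fs / 1000.0))
    if s1 <= s0:
        raise ValueError("empty epoch window")
    n_t = data.shape[-1]
    keep = (event_samples + s0 >= 0) & (event_samples + s1 <= n_t)
    kept = event_samples[keep]
    if len(kept) == 0:
        raise ValueError("no events with a full window inside the recording")
    if (~keep).any():
        warnings.warn(f"dropped {int((~keep).sum())} event(s) at recording edges",
                      stacklevel=2)
    epochs = np.stack([data[:, ev + s0 : ev + s1] for ev in kept])
    times = (np.arange(s0, s1) * 1000.0 / fs)
    return epochs, times, keep


def epoch_power(
    tf: TFDecomposition,
    event_samples: np.ndarray,
    window_ms: tuple[float, float],
    decim: int = 1,
) -> TFDecomposition:
    """Slice a continuous power decomposition into event-locked power epochs.

    This is the continuous-mode pipeline: the convolution has already seen
    the whole recording, so no interior validity masking applies — only
    events whose window (plus half the longest kernel) does not fit inside
    the recording are dropped. Columns are the decimated time grid of the
    continuous transform; event onsets are mapped to the nearest column.
    """
    if tf.epoched:
        raise ValueError("epoch_power expects a continuous decomposition")
    t0, t1 = window_ms
    s0 = int(round(t0 * tf.fs / 1000.0))
    s1 = int(round(t1 * tf.fs / 1000.0))
    n_cols = tf.power.shape[-1]
    ncols_epoch = max((s1 - s0) // decim, 1)
    margin = int(np.flatnonzero(tf.mask.all(axis=0))[0]) if tf.mask.all(axis=0).any() else 0

    epochs, kept = [], []
    for ev in np.asarray(event_samples, dtype=int):
        c0 = int(round((ev + s0) / decim))
        if c0 < margin or c0 + ncols_epoch > n_cols - margin:
            continue
        epochs.append(tf.power[:, :, c0 : c0 + ncols_epoch])
        kept.append(ev)
    if not epochs:
        raise ValueError("no events with a full window inside the recording")
    if len(kept) < len(event_samples):
        warnings.warn(
            f"dropped {len(event_samples) - len(kept)} event(s) at recording edges",
            stacklevel=2,
        )
    times = (np.arange(ncols_epoch) * decim + s0) * 1000.0 / tf.fs
    mask = np.ones((len(tf.freqs), ncols_epoch), dtype=bool)
    return TFDecomposition(
        power=np.stack(epochs), freqs=tf.freqs.copy(), times=times, mask=mask,
        fs=tf.fs, ch_names=tf.ch_names,
    )


def baseline_normalize(
    tf: TFDecomposition,
    baseline_ms: tuple[float, float] = (-1000.0, 0.0),
    scheme: str = "trial_mean",
    condition: str | None = None,
    subject: int | None = None,
) -> FRSPResult:
    """Convert trial power to baseline-relative dB change.

    trial_mean (default): average power over trials first, then divide by the
    mean baseline power and take 10 log10. single_trial: divide each trial by
    its own baseline mean, convert to dB, then average the dB values.

    The baseline average uses, per frequency, the intersection of the
    baseline window with the validity mask (low frequencies lose their
    outermost baseline samples to wavelet edge effects).
    """
    if scheme not in ("trial_mean", "single_trial"):
        raise ValueError("scheme must be 'trial_mean' or 'single_trial'")
    if not tf.epoched:
        raise ValueError("baseline_normalize expects an epoched decomposition")
    t0, t1 = baseline_ms
    in_base = (tf.times >= t0) & (tf.times < t1)
    if not in_base.any():
        raise ValueError("baseline window contains no time samples")

    P = tf.power.astype(np.float64)  # (trials, ch, f, t)
    n_f = len(tf.freqs)
    base_cols = [np.flatnonzero(in_base & tf.mask[fi]) for fi in range(n_f)]
    if any(len(c) == 0 for c in base_cols):
        bad = [float(tf.freqs[i]) for i, c in enumerate(base_cols) if len(c) == 0]
        raise ValueError(f"baseline window entirely invalid at frequencies {bad}")

    if scheme == "trial_mean":
        Pm = P.mean(axis=0)  # (ch, f, t)
        B = np.stack([Pm[:, fi, c].mean(axis=-1) for fi, c in enumerate(base_cols)], axis=1)
        if (B <= 0).any():
            raise ValueError("zero baseline power: degenerate input")
        db = 10.0 * np.log10(Pm / B[..., None])
    else:
        B = np.stack(
            [P[:, :, fi, c].mean(axis=-1) for fi, c in enumerate(base_cols)], axis=2
        )  # (trials, ch, f)
        if (B <= 0).any():
            raise ValueError("zero baseline power: degenerate input")
        db = (10.0 * np.log10(P / B[..., None])).mean(axis=0)

    return FRSPResult(
        db=db, freqs=tf.freqs, times=tf.times, mask=tf.mask,
        baseline_ms=(float(t0), float(t1)), scheme=scheme,
        ch_names=tf.ch_names, condition=condition, subject=subject,
    )
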