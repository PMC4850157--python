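"""Synthetic 64-channel, 500 Hz EEG aligned to simulated reading scanpaths.

Background activity is 1/f^chi noise per channel (plus a 10 Hz idle rhythm at
posterior sites). Experimental effects are *induced* power changes: the
band-limited component of the ongoing signal is multiplied by a smooth gain
envelope around matching events, then recombined with the band-stop
remainder — no additive evoked transient, so the fixation-locked dB measure
sees a pure ongoing-power modulation.

Default effect templates mirror the three effects the analysis is built to
detect:

* lower-beta (13-18 Hz) desynchronization, -1 dB, 0-300 ms after fixating a
  semantically unrelated target in an ordered sentence (ORD_SEM);
* theta (4-7 Hz) synchronization, +1 dB, 300-900 ms after sentence onset for
  ordered sentences (both parieto-occipital clusters);
* gamma (31-55 Hz) linear ramp 0 -> +1 dB over 0-1800 ms after sentence onset
  for ordered sentences (right parieto-occipital and central clusters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import signal as ssig

from .montage import DEFAULT_MONTAGE, MontageSpec, is_posterior
from .reading import StimulusQuadruple, TrialRecord

EVENT_SENTENCE_ONSET = "sentence_onset"
EVENT_TARGET_FIXATION = "target_fixation"

EVENT_COLUMNS = ["sample", "event_class", "subject", "trial", "condition", "quad_id"]


@dataclass(frozen=True)
class EffectTemplate:
    """One induced band-power effect, locked to an event class.

    ``gain_db`` is either a scalar (constant within the window) or a
    (start, end) pair interpolated linearly in dB across the window (a ramp).
    The gain is reached on a plateau; the envelope edges are half-Hann tapers
    of ``taper_ms`` so the modulation starts and ends smoothly. A gain of
    0 dB leaves the signal unchanged.
    """

    band: tuple[float, float]  # Hz, inclusive edges
    gain_db: float | tuple[float, float]
    window_ms: tuple[float, float]  # relative to the locking event
    clusters: dict[str, float]  # cluster name -> weight in (0, 1]
    event_class: str
    conditions: tuple[str, ...]
    taper_ms: float = 75.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo <= hi:
            raise ValueError("band edges must be positive and ordered")
        for w in self.clusters.values():
            if not 0 < w <= 1:
                raise ValueError("cluster weights must lie in (0, 1]")

    def is_ramp(self) -> bool:
        return isinstance(self.gain_db, tuple)


def default_templates() -> list[EffectTemplate]:
    return [
        EffectTemplate(
            band=(13.0, 18.0), gain_db=-1.0, window_ms=(0.0, 300.0),
            clusters={"parieto_occipital_left": 1.0},
            event_class=EVENT_TARGET_FIXATION, conditions=("ORD_SEM",),
        ),
        EffectTemplate(
            band=(4.0, 7.0), gain_db=+1.0, window_ms=(300.0, 900.0),
            clusters={"parieto_occipital_left": 1.0, "parieto_occipital_right": 1.0},
            event_class=EVENT_SENTENCE_ONSET, conditions=("ORD_COR", "ORD_SEM"),
        ),
        EffectTemplate(
            band=(31.0, 55.0), gain_db=(0.0, +1.0), window_ms=(0.0, 1800.0),
            clusters={"parieto_occipital_right": 1.0, "central_right": 1.0},
            event_class=EVENT_SENTENCE_ONSET, conditions=("ORD_COR", "ORD_SEM"),
        ),
    ]


@dataclass
class SyntheticRecording:
    """Continuous multichannel EEG (microvolts) with an event table."""

    data: np.ndarray  # (n_channels, n_samples) float32, microvolts
    fs: float
    ch_names: tuple[str, ...]
    events: pd.DataFrame  # EVENT_COLUMNS

    def __post_init__(self) -> None:
        s = self.events["sample"].to_numpy()
        if len(s) and ((s < 0).any() or (s >= self.data.shape[1]).any()):
            raise ValueError("event sample indices outside recording bounds")
        if len(s) and (np.diff(s) <= 0).any():
            raise ValueError("event sample indices must be strictly increasing")


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def generate_background(
    duration_s: float,
    n_channels: int = 64,
    noise_exponent: float = 1.0,
    fs: float = 500.0,
    rng: np.random.Generator | int = 0,
    ch_names: tuple[str, ...] | None = None,
    rms_uv: float = 10.0,
    alpha_rms_uv: float = 4.0,
) -> SyntheticRecording:
    """Zero-mean 1/f^chi noise per channel, 10 Hz idle rhythm at posterior sites.

    chi = 0 gives white noise. Channels carry independent noise streams drawn
    from one generator. Amplitudes are scaled to ``rms_uv`` microvolts RMS.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if noise_exponent < 0:
        raise ValueError("noise_exponent must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = int(round(duration_s * fs))
    if ch_names is None:
        ch_names = tuple(
            DEFAULT_MONTAGE.channels[i] if i < 64 else f"CH{i}" for i in range(n_channels)
        )

    white = rng.standard_normal((n_channels, n))
    spec = sfft.rfft(white, axis=-1)
    f = sfft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-noise_exponent / 2.0)
    x = sfft.irfft(spec * scale, n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    x *= rms_uv / x.std(axis=-1, keepdims=True)

    posterior = [i for i, name in enumerate(ch_names) if is_posterior(name)]
    if posterior and alpha_rms_uv > 0:
        # narrowband 9-11 Hz noise as an idle rhythm
        aw = rng.standard_normal((len(posterior), n))
        sos = ssig.butter(4, [9.0, 11.0], btype="bandpass", fs=fs, output="sos")
        alpha = ssig.sosfiltfilt(sos, aw, axis=-1)
        alpha *= alpha_rms_uv / alpha.std(axis=-1, keepdims=True)
        x[posterior] += alpha

    events = pd.DataFrame(columns=EVENT_COLUMNS)
    return SyntheticRecording(
        data=x.astype(np.float32), fs=fs, ch_names=tuple(ch_names), events=events
    )


# ---------------------------------------------------------------------------
# effect injection
# ---------------------------------------------------------------------------

def _bandpass_fir(lo: float, hi: float, fs: float, transition_hz: float = 2.0) -> np.ndarray:
    """Linear-phase band-pass FIR; applied centred, hence zero-phase."""
    numtaps = int(round(3.3 * fs / transition_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    return ssig.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def _gain_profile(template: EffectTemplate, n_samp: int, fs: float) -> np.ndarray:
    """dB-domain envelope over the injection window (plateau at gain_db)."""
    if template.is_ramp():
        g0, g1 = template.gain_db
        prof = np.linspace(g0, g1, n_samp)
    else:
        prof = np.full(n_samp, float(template.gain_db))
    n_taper = min(int(round(template.taper_ms * fs / 1000.0)), n_samp // 2)
    if n_taper > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_taper) / n_taper))
        prof[:n_taper] *= ramp
        prof[-n_taper:] *= ramp[::-1]
    return prof


def inject_band_power(
    rec: SyntheticRecording,
    template: EffectTemplate,
    event_samples: np.ndarray,
    montage: MontageSpec = DEFAULT_MONTAGE,
) -> SyntheticRecording:
    """Multiply the band-limited component by the template's gain envelope at
    each event, on the template's cluster channels; returns a new recording.

    Overlapping windows on one channel compose multiplicatively (their dB
    envelopes add). The band-stop remainder is untouched.
    """
    lo, hi = template.band
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError("band must lie within (0, fs/2)")
    n = rec.data.shape[1]
    t0 = int(round(template.window_ms[0] * rec.fs / 1000.0))
    t1 = int(round(template.window_ms[1] * rec.fs / 1000.0))
    profile = _gain_profile(template, t1 - t0, rec.fs)

    out = rec.data.copy()
    h = _bandpass_fir(lo, hi, rec.fs)
    for cluster, weight in template.clusters.items():
        idx = [rec.ch_names.index(ch) for ch in montage.clusters[cluster]
               if ch in rec.ch_names]
        if not idx:
            continue
        db_env = np.zeros(n)
        for ev in np.asarray(event_samples, dtype=int):
            a, b = ev + t0, ev + t1
            pa, pb = max(a, 0), min(b, n)
            if pb > pa:
                db_env[pa:pb] += weight * profile[pa - a : pb - a]
        amp_env = 10.0 ** (db_env / 20.0)
        xb = ssig.fftconvolve(out[idx], h[None, :], mode="same", axes=-1)
        out[idx] = (out[idx] - xb) + xb * amp_env[None, :]
    return SyntheticRecording(out.astype(np.float32), rec.fs, rec.ch_names, rec.events)


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def assemble_session(
    trials: list[TrialRecord],
    corpus: list[StimulusQuadruple],
    templates: list[EffectTemplate] | None = None,
    rng: np.random.Generator | int = 0,
    montage: MontageSpec = DEFAULT_MONTAGE,
    fs: float = 500.0,
    noise_exponent: float = 1.0,
    iti_range_ms: tuple[float, float] = (750.0, 1220.0),
    pre_roll_ms: float = 2000.0,
    post_roll_ms: float = 3500.0,
    trial_tail_ms: float = 200.0,
) -> SyntheticRecording:
    """One continuous recording for one subject's trial sequence.

    Trials are laid out in the given order, separated by intertrial intervals
    drawn uniformly from ``iti_range_ms``. Sentence-onset events mark the
    first fixation on word 0 of every trial; target-fixation events mark the
    first first-pass fixation on the target (absent if the target was
    skipped). Effects are injected per template at matching events.
    """
    if templates is None:
        templates = default_templates()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not trials:
        raise ValueError("no trials to assemble")
    if any(not t.scanpath for t in trials):
        raise ValueError("all trials must carry scanpaths")
    by_id = {q.quad_id: q for q in corpus}
    if iti_range_ms[0] < 750.0:
        raise ValueError("intertrial interval must be at least 750 ms")

    rows = []
    cursor_ms = pre_roll_ms
    last_end = -np.inf
    for trial_no, rec in enumerate(trials):
        if cursor_ms < last_end:
            raise ValueError("trial overlap in session layout")
        quad = by_id[rec.quad_id]
        onset0 = None
        target_onset = None
        for ev in rec.scanpath:
            if ev.word_index == 0 and onset0 is None:
                onset0 = ev.onset
            if (
                target_onset is None
                and ev.word_index == quad.target_index
                and ev.pass_label == "first_pass"
            ):
                target_onset = ev.onset
        if onset0 is None:
            raise ValueError("trial has no fixation on the first word")
        rows.append((cursor_ms + onset0, EVENT_SENTENCE_ONSET, rec, quad))
        if target_onset is not None:
            rows.append((cursor_ms + target_onset, EVENT_TARGET_FIXATION, rec, quad))
        trial_dur = rec.scanpath[-1].onset + rec.scanpath[-1].duration + trial_tail_ms
        last_end = cursor_ms + trial_dur
        cursor_ms = last_end + rng.uniform(*iti_range_ms)

    total_s = (cursor_ms + post_roll_ms) / 1000.0
    ch_names = montage.channels
    recording = generate_background(
        total_s, n_channels=len(ch_names), noise_exponent=noise_exponent,
        fs=fs, rng=rng, ch_names=ch_names,
    )

    events = pd.DataFrame(
        {
            "sample": [int(round(ms * fs / 1000.0)) for ms, *_ in rows],
            "event_class": [cls for _, cls, *_ in rows],
            "subject": [rec.subject_id for *_, rec, _ in rows],
            "trial": [i for i, (_, _, rec, _) in enumerate(rows)],
            "condition": [rec.condition for *_, rec, _ in rows],
            "quad_id": [rec.quad_id for *_, rec, _ in rows],
        }
    )
    # trial column should index trials, not event rows
    trial_ids: list[int] = []
    tid = -1
    for cls in events["event_class"]:
        if cls == EVENT_SENTENCE_ONSET:
            tid += 1
        trial_ids.append(tid)
    events["trial"] = trial_ids
    events = events.sort_values("sample", kind="stable").reset_index(drop=True)
    recording = SyntheticRecording(recording.data, fs, ch_names, events)

    for template in templates:
        sel = events[
            (events["event_class"] == template.event_class)
            & (events["condition"].isin(template.conditions))
        ]["sample"].to_numpy()
        if len(sel):
            recording = inject_band_power(recording, template, sel, montage)
    return recording
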