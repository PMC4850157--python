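# Methods

This note documents the models, parameters and numerical choices behind the
`frsp` package: what the synthetic generator emulates, how the
fixation-related spectral perturbation (FRSP) is computed, and how the
statistics are assembled. It also states the known limitations — in
particular, what passing tests on synthetic data do and do not show about
recorded data.

## 1. The measurement model

### Fixation-related spectral perturbation

For an event class (the first fixation on a critical word, or the first
fixation on a sentence), epochs of EEG are extracted around each event and
decomposed with a bank of complex, Hann-tapered, constant-3-cycle sinusoidal
wavelets on a linear 1 Hz grid from 3 to 70 Hz:

    h_f(t) = Hann(L_f) · exp(i 2π f t),     L_f = round(3 · fs / f) samples,

odd-adjusted so the kernel peak sits on a sample. Power is the squared
magnitude of the convolution. Each kernel is normalized so a unit-amplitude
sinusoid at its centre frequency yields unit power; any per-frequency gain
cancels in the FRSP, which is a power *ratio*:

    FRSP(c, f, t) = 10 · log10( P_post(c, f, t) / B(c, f) )   [dB],

with `B` the mean power in the 1000 ms before event onset. In the default
`trial_mean` scheme the trial average is taken before the ratio; a
`single_trial` scheme (divide each trial by its own baseline, then average
the dB values) is available, since published descriptions of the log-ratio
baseline are often ambiguous on this point. For stationary input the FRSP is
0 dB in expectation under either scheme.

Frequency bands (inclusive edges): theta 4–7, alpha 8–12, lower beta 13–18,
upper beta 19–30, gamma 31–55 Hz. dB values are averaged over six clusters
of five 10-10 electrodes (frontal / central / parieto-occipital × left /
right), in-band bins, and 300 ms time windows — two windows (0–300,
300–600 ms) for target-locked epochs (−1000..+1500 ms), six (0–1800 ms) for
sentence-locked epochs (−1000..+2500 ms).

### Edge handling and the baseline mask

A frequency-f kernel spans `L_f` samples, so power estimates within half a
kernel of an epoch edge mix in zero padding; those (frequency, time) cells
are marked invalid and excluded from every average. At 3 Hz the kernel is
~1000 ms long, so the −1000..0 ms baseline window is only partially valid;
the baseline mean uses the per-frequency intersection of the window with the
validity mask (at 3 Hz, effectively −500..0 ms). A continuous mode that
convolves the whole recording before epoching (no interior masking) is
provided for overlapping fixation epochs in natural reading, and agrees with
the epoched mode on the jointly valid region.

### Statistics

Cell tables (subject × condition × cluster × band × window mean dB) feed
fully within-subject repeated-measures ANOVAs: subject is the random factor
and every effect is tested against its effect-by-subject interaction; the
sums-of-squares come from `statsmodels`' `AnovaRM` and are verified in the
test suite against an independent Möbius/brute-force decomposition to 1e-10.
No sphericity correction is applied by default. Planned contrasts are paired
t-tests per cluster without multiple-comparison correction; α = 0.05
throughout. The hierarchical follow-up driver mirrors the standard gating:
overall interaction → per-hemisphere ANOVA → per-window ANOVA → per-cluster
t. At the target level the six clusters are modelled as Hemisphere(2) ×
Region(3); at the sentence level the cluster factor has six levels and the
two syntactically ordered conditions are pooled (ORD) against the two
randomized ones (RDM).

The linear-trend (gamma ramp) test fits an ordinary-least-squares line per
subject and condition through the six successive window means, using the
window index 1..6 as regressor — slopes are then in dB per 300 ms step and
comparable across subjects. Group inference is a one-sample one-sided t
(slope > 0) per condition plus a two-sided paired t between conditions. The
slope is invariant to adding a constant to all windows.

Degenerate inputs are mapped to their limiting values rather than NaN:
identical paired samples give t = 0, p = 1; a constant dependent variable
gives F = 0, p = 1; identically zero slopes give one-sided p = 0.5.

## 2. The synthetic generator

The generator produces a full co-registered experiment so that every
analysis stage can be exercised and calibrated without recorded data.

### Stimulus corpus

120 sentence quadruples; each quadruple has a syntactically ordered word
layout and a randomized permutation of it, each in a "correct" and a
"semantic-violation" version sharing one target word position. Sentence
lengths are round-half-even normal draws (mean 9.56, SD 1.61 words, clipped
at 4); the 1-based target position is a rounded normal draw (SD 1.37)
resampled until it lies in 2..length−1. Because that truncation is
asymmetric (sentences are short relative to the target position), the
location parameter of the position distribution is calibrated by a
deterministic bisection on the exact discrete truncated mean so that the
*generated* corpus mean equals the requested 7.1. Word identities are not
modelled — only word lengths (a fixed discrete distribution over 2..12
characters, mean ≈ 6.4), since no downstream computation consults
orthography. Each subject reads one ORD version and the *opposite* RDM
version of every quadruple, with the pairing counterbalanced across two
experiment lists (half the subjects each).

### Scanpaths

A trial's scanpath is a left-to-right first pass: each word is fixated
(skipping probability 0.10, target 0.05, first word never skipped) with a
Gamma-distributed duration (shape 25, giving CV = 0.2 and < 0.1 % of
fixations below the 80 ms exclusion cut); with probability `p_refix` an
immediate same-word refixation follows; after the first pass, with
probability `p_reg`, one second-pass regression fixation lands on the
target. Onsets accumulate durations plus a fixed 30 ms saccade gap (only
fixation onsets and durations enter any downstream computation). The
per-condition parameters are calibrated so that the closed-form expectations

    FFD = μ_first,   GD = FFD + p_refix · μ_refix,   TVT = GD + p_reg · μ_second

equal the target condition means:

| condition | μ_first | p_refix | μ_refix | p_reg | μ_second | FFD | GD | TVT |
|-----------|--------:|--------:|--------:|------:|---------:|----:|----:|----:|
| ORD_COR   | 198 | 0.20 | 145 | 0.08  | 150 | 198 | 227 | 239 |
| ORD_SEM   | 203 | 0.20 | 170 | 0.22  | 150 | 203 | 237 | 270 |
| RDM_COR   | 211 | 0.20 | 185 | 1/6   | 150 | 211 | 248 | 273 |
| RDM_SEM   | 217 | 0.20 | 215 | 0.20  | 150 | 217 | 260 | 290 |

Skipping and regression *rates* are the package's own choices (no published
rates exist to match); only the means above are calibration targets. A note
on precision: with 32 subjects × ~57 non-skipped target trials per
condition, the Monte-Carlo standard error of a GD/TVT condition mean is
2.3–2.7 ms (dominated by the Bernoulli refixation/regression mixture), so
single-run means scatter by a few ms around the table; the large-sample bias
is < 1.5 ms (asserted in the test suite at 256 subjects).

### EEG

Per subject, one continuous 64-channel, 500 Hz recording: independent
1/f^χ background noise per channel (χ = 1 by default, ~10 µV RMS,
zero-mean) plus a 10 Hz idle rhythm at posterior channels, with trials laid
out in the subject's randomized order, separated by 750–1220 ms intertrial
intervals. Experimental effects are *induced* power modulations: the
band-limited component of the ongoing signal (zero-phase FIR, 2 Hz
transition width) is multiplied by a gain envelope around matching events
and recombined with the band-stop remainder — no additive evoked transient,
so the FRSP sees a pure ongoing-power change, and channels outside the
target clusters receive nothing. The envelope reaches the nominal dB gain
on a plateau, with half-Hann tapers (75 ms by default) at the window edges;
a pure Hann envelope would attain the nominal gain only at a single sample
and could not satisfy a ±0.3 dB recovery check once wavelet smoothing is
applied. Overlapping windows compose multiplicatively (their dB envelopes
add). Ramp effects interpolate the gain linearly in dB across the window.

Default templates (gain sizes are package choices sized for detectability
at n = 32; no published effect sizes in dB exist to match):

* lower beta 13–18 Hz, −1 dB, 0–300 ms after ORD_SEM target fixations,
  left parieto-occipital cluster;
* theta 4–7 Hz, +1 dB, 300–900 ms after ORD sentence onsets, both
  parieto-occipital clusters;
* gamma 31–55 Hz, 0 → +1 dB linear ramp over 0–1800 ms after ORD sentence
  onsets, right parieto-occipital and right central clusters.

## 3. Problem sizes and defaults

The default experiment is 32 subjects × 120 quadruples (240 trials each)
for the eye-movement analyses — scanpath simulation needs no EEG and runs in
seconds. The EEG session uses a reduced recording length of 24 quadruples
(48 trials, ~3 minutes of signal) per subject; with ±1 dB injected effects
the band/cluster statistics recover all three effects decisively at that
size, and the full two-level FRSP analysis of all 32 subjects completes in
a few minutes on one CPU. Time-frequency power is computed at full temporal
resolution and decimated to 20 ms columns (`decim=10`) before aggregation.

## 4. Numerical choices

* FFT-based complex convolution per channel/frequency, chunked over trials,
  complex64/float32 precision (dB values are reproducible to ~1e-3; the
  scale invariance of the dB ratio holds to the same precision).
* Round-half-even for all normal-to-integer conversions; epoch slicing is
  half-open `[start, end)` with the event sample on the post-event side;
  time windows are half-open in ms.
* Exclusion rules: the 80 ms cut is applied before the per-subject
  mean + 3 SD cut (sample SD, pooled over all of a subject's surviving
  fixations, one pass, strict inequality). Equal durations are never
  trimmed (SD = 0).
* One root seed; corpus, list assignment, scanpath and per-subject EEG
  streams are independent deterministic children of it, so any pipeline
  output is a pure function of (config, seed).
* BrainVision output is multiplexed IEEE float32 by default (lossless for
  the float32 recordings); the int16-with-resolution dialect (0.1 µV steps)
  is provided for interoperability.

## 5. What the synthetic data do not show

The generator is a measurement-model testbed, not a brain model. It omits:
ocular and myogenic artifacts (hence no ICA stage); volume conduction and
reference topography (channels are independent noise streams, effects appear
only at their target clusters); between-subject variability in effect size
(every subject carries the same injected gain, so group t statistics on
synthetic data are larger than plausible for recorded EEG); parafoveal
preview, landing positions and saccade kinematics; and any lexical content.
Passing the effect-direction tests therefore shows that the *pipeline*
recovers known ongoing-power modulations of the stated size and location
from realistic 1/f background at the study's design size — it does not
constitute evidence about reading itself.

Two further caveats. First, band-limited gain recovery at ±0.3 dB requires
the measuring kernel's bandwidth to fit inside the injected band: a 3-cycle
wavelet at 15 Hz is ~6 Hz wide and dilutes a 13–18 Hz gain with unmodulated
neighbouring power, so the recovery tests measure with a 12-cycle bank (the
cycle count is configurable; the default analysis keeps the constant
3-cycle convention). Second, the per-frequency valid-time ranges derived
from the half-kernel arithmetic (e.g. ±500 ms trim at 3 Hz) are what this
package reports; toolboxes that round to an internal output grid may report
slightly different ranges for nominally identical settings, and we do not
chase such differences.
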