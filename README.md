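# frsp — fixation-related spectral perturbation analysis of sentence reading

`frsp` implements the analysis pipeline of a co-registered eye-tracking +
EEG reading experiment, together with a synthetic data generator that makes
every stage testable and calibratable without any recorded data.

In natural, self-paced reading there is no external stimulus trigger: the
onset of processing a word is marked by the eyes landing on it. The
**fixation-related spectral perturbation (FRSP)** is the fixation-locked
analogue of the event-related spectral perturbation — the change of
oscillatory EEG power after a fixation onset relative to a pre-fixation
baseline, expressed as a dB log ratio:

$$\mathrm{FRSP}(c, f, t) = 10 \log_{10} \frac{P_{\text{post}}(c,f,t)}{B(c,f)}$$

where power comes from a bank of Hann-tapered, 3-cycle complex sinusoidal
wavelets (3–70 Hz, 1 Hz steps) and $B$ is the mean power in the 1000 ms
before the fixation. Band (theta 4–7, alpha 8–12, lower beta 13–18, upper
beta 19–30, gamma 31–55 Hz) × electrode-cluster × 300 ms-window means feed
fully within-subject repeated-measures ANOVAs, planned paired contrasts,
and a per-subject linear-trend (slope) test for power ramps across a
sentence.

The package is aimed at researchers studying reading with fixation-related
EEG designs: it provides the eye-movement measures (first-fixation duration
FFD, gaze duration GD, total viewing time TVT, with the standard 80 ms /
3 SD exclusions), the wavelet/baseline machinery, the cluster statistics —
and a generator producing stimulus corpora, condition-dependent fixation
scanpaths and 64-channel, 500 Hz EEG whose band-limited power is modulated
at known times by known dB gains, so that the whole chain can be verified
by parameter recovery.

## Layout

```
src/frsp/        the library
  reading.py       stimulus corpus, experiment lists, scanpath simulation
  em.py            first-pass segmentation, exclusions, FFD/GD/TVT, stats
  eeg.py           1/f background, induced band-power injection, sessions
  tfr.py           wavelet bank, epoching, dB baseline (FRSP)
  stats.py         band x cluster x window cells, RM-ANOVA, contrasts, slopes
  montage.py       64-channel 10-10 montage, six analysis clusters
  io.py            BrainVision, scanpath TSV, HDF5, YAML config
  cli.py           `frsp` command-line pipeline
analysis/        numbered drivers reproducing the full study on synthetic data
scripts/         acceptance.py (see "Reproducing the calibration results")
tests/           pytest suite
docs/methods.md  models, parameters, numerical choices, limitations
```

## Worked example

The numbered scripts under `analysis/` run the three analyses on the
default synthetic experiment (32 subjects; 120 sentence quadruples in four
conditions — ordered/randomized word order × semantically correct/violated
target; seed 0):

```
$ python analysis/01_generate_dataset.py
corpus: 120 quadruples, mean length 9.39 words (SD 1.48), mean target position 7.03
trials: 7680 (32 subjects x 240), 80829 fixations

$ python analysis/02_eye_movement_stats.py
exclusions: 24 below 80 ms, 322 above 3 SD (0.43% of 80829 fixations)
raw target-word condition means (ms):
  FFD:  ORD_COR=196.7  ORD_SEM=202.5  RDM_COR=209.7  RDM_SEM=214.3
  GD:   ORD_COR=226.8  ORD_SEM=237.4  RDM_COR=249.3  RDM_SEM=258.6
  TVT:  ORD_COR=238.0  ORD_SEM=269.9  RDM_COR=276.9  RDM_SEM=287.5
  FFD ORD_SEM_vs_ORD_COR: t(31) = 3.97, p = 0.0003918
  ...
```

Reading the output: semantically violated targets cost ~5 ms in first
fixations and ~30 ms in total viewing time within ordered sentences — the
generator is calibrated so these means land on the classic self-paced
reading values (FFD ≈ 200 ms, GD ≈ 230 ms), and the paired t-tests recover
the violation effect in every measure.

```
$ python analysis/03_frsp_target_level.py
planned per-cluster t-tests, lower beta, 0-300 ms (ORD_SEM - ORD_COR):
  parieto_occipital_left   t(31) = -2.66, p = 0.012, mean diff = -0.192 dB *
  (all other clusters n.s.)

$ python analysis/04_frsp_sentence_level.py
theta ORD vs RDM, parieto-occipital clusters:
  300-600 ms  left  t(31) = +4.40, p = 0.0001 *   right t(31) = +6.71 *
  600-900 ms  left  t(31) = +4.69, p = 0.0001 *   right t(31) = +5.10 *
gamma slope test (dB per 300 ms window):
  parieto_occipital_right ORD: mean slope +0.112, one-sided p = 8.7e-21
  parieto_occipital_right RDM: mean slope -0.005, one-sided p = 0.83
  parieto_occipital_right ORD vs RDM: t(31) = 14.88, p = 1.2e-15
```

These are parameter recoveries: the generator injected a −1 dB lower-beta
gain after semantically violated target fixations at the left
parieto-occipital cluster, a +1 dB theta gain at 300–900 ms and a 0→+1 dB
gamma ramp over 0–1800 ms after ordered-sentence onsets — and the pipeline's
inference finds exactly those effects, at those clusters and windows, and
nothing at the uninjected ones.

The same stages are available as a CLI for arbitrary configurations
(`frsp generate`, `frsp em-stats`, `frsp frsp-target`, `frsp frsp-sentence`,
`frsp report`; see `frsp --help`), including BrainVision export of the
synthetic sessions and import of real recordings.

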