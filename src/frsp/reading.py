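"""Synthetic stimulus corpus and fixation scanpaths for sentence reading.

The generator emulates a reading experiment with 120 sentence quadruples in
four conditions — syntactically ordered vs. word-order-randomized sentences
(ORD / RDM), each either fully correct or containing a semantically unrelated
target word (COR / SEM) — and per-subject left-to-right scanpaths whose
aggregate first-fixation duration (FFD), gaze duration (GD) and total viewing
time (TVT) on the target word are calibrated to the condition means the
downstream analyses expect:

=========  =====  ====  ====
condition    FFD    GD   TVT
=========  =====  ====  ====
ORD_COR      198   227   239
ORD_SEM      203   237   270
RDM_COR      211   248   273
RDM_SEM      217   260   290
=========  =====  ====  ====

(ms; GD = FFD + P(refix)·E[refix], TVT = GD + P(regression)·E[second pass].)

Only word *lengths* are modelled — no orthography: every downstream
computation consumes fixation timing and word indices alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

CONDITIONS = ("ORD_COR", "ORD_SEM", "RDM_COR", "RDM_SEM")

#: word_index used for fixations that land on no word interest area.
OFF_WORD = -1

#: Fixed discrete word-length distribution (characters), mean ≈ 6.4.
WORD_LENGTHS = np.arange(2, 13)
WORD_LENGTH_P = np.array(
    [0.05, 0.10, 0.13, 0.13, 0.13, 0.12, 0.10, 0.09, 0.07, 0.05, 0.03]
)


@dataclass(frozen=True)
class StimulusQuadruple:
    """One sentence quadruple: an ordered word-length layout, its random
    permutation, and the shared target position (0-based, never first/last)."""

    quad_id: int
    words_ord: tuple[int, ...]
    words_rdm: tuple[int, ...]
    target_index: int

    @property
    def sentence_length(self) -> int:
        return len(self.words_ord)

    def __post_init__(self) -> None:
        n = len(self.words_ord)
        if n < 4:
            raise ValueError("sentence_length must be >= 4")
        if not 1 <= self.target_index <= n - 2:
            raise ValueError("target is never the initial or the final word")
        if sorted(self.words_rdm) != sorted(self.words_ord):
            raise ValueError("words_rdm must be a permutation of words_ord")


@dataclass(frozen=True)
class ConditionScanpath:
    """Per-condition scanpath timing parameters (ms / probabilities)."""

    first_fixation_mean: float
    refixation_prob: float
    refixation_mean: float
    regression_prob: float
    second_pass_mean: float

    def __post_init__(self) -> None:
        for p in (self.refixation_prob, self.regression_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for m in (self.first_fixation_mean, self.refixation_mean, self.second_pass_mean):
            if m <= 80.0:
                raise ValueError("mean fixation durations must exceed 80 ms")


#: Calibrated per-condition defaults (see module docstring).
DEFAULT_CONDITION_PARAMS: dict[str, ConditionScanpath] = {
    "ORD_COR": ConditionScanpath(198.0, 0.20, 145.0, 0.08, 150.0),
    "ORD_SEM": ConditionScanpath(203.0, 0.20, 170.0, 0.22, 150.0),
    "RDM_COR": ConditionScanpath(211.0, 0.20, 185.0, 1.0 / 6.0, 150.0),
    "RDM_SEM": ConditionScanpath(217.0, 0.20, 215.0, 0.20, 150.0),
}


@dataclass(frozen=True)
class ScanpathConfig:
    """Scanpath model parameters.

    Durations are Gamma-distributed with shape ``duration_shape`` (CV =
    1/sqrt(shape); the default shape 25 puts less than 0.1 % of first-pass
    fixations below the 80 ms exclusion cut). Fixation onsets accumulate
    durations plus a fixed saccade gap. The first word of a sentence is never
    skipped, so the sentence-onset event always exists.
    """

    conditions: dict[str, ConditionScanpath] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PARAMS)
    )
    duration_shape: float = 25.0
    skip_prob_target: float = 0.05
    skip_prob_other: float = 0.10
    saccade_gap_ms: float = 30.0
    fs: float = 500.0

    def __post_init__(self) -> None:
        for p in (self.skip_prob_target, self.skip_prob_other):
            if not 0.0 <= p <= 1.0:
                raise ValueError("skip probabilities must lie in [0, 1]")
        if self.duration_shape <= 0:
            raise ValueError("duration_shape must be positive")


DEFAULT_SCANPATH_CONFIG = ScanpathConfig()


@dataclass(frozen=True)
class FixationEvent:
    """One fixation: onset (ms from trial start), duration, resolved word."""

    onset: float
    duration: float
    word_index: int
    pass_label: str  # "first_pass" | "second_pass"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be positive")


@dataclass
class TrialRecord:
    """One sentence presentation by one subject."""

    subject_id: int
    quad_id: int
    condition: str
    scanpath: list[FixationEvent] = field(default_factory=list)

    def target_skipped(self, target_index: int) -> bool:
        """True if the target word received no first-pass fixation."""
        return not any(
            ev.word_index == target_index and ev.pass_label == "first_pass"
            for ev in self.scanpath
        )

    @property
    def sentence_onset(self) -> float:
        """Onset of the first fixation on word 0."""
        for ev in self.scanpath:
            if ev.word_index == 0:
                return ev.onset
        raise ValueError("no fixation on the first word")


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x).astype(int)


def _length_pmf(length_mean: float, length_sd: float, lo: int = 4, hi: int = 40):
    """Discrete pmf of round(Normal) clipped below at `lo`."""
    ks = np.arange(lo, hi + 1)
    if length_sd == 0:
        p = (ks == int(round(length_mean))).astype(float)
        if p.sum() == 0:
            p = (ks == lo).astype(float)
        return ks, p
    upper = sps.norm.cdf(ks + 0.5, length_mean, length_sd)
    lower = sps.norm.cdf(ks - 0.5, length_mean, length_sd)
    p = upper - lower
    p[0] += sps.norm.cdf(lo - 0.5, length_mean, length_sd)  # clip mass
    p[-1] += sps.norm.sf(hi + 0.5, length_mean, length_sd)
    return ks, p / p.sum()


def _truncated_pos_mean(loc: float, pos_sd: float, ks: np.ndarray, pk: np.ndarray) -> float:
    """Exact mean 1-based target position under resample-until-valid, averaged
    over the sentence-length pmf (positions constrained to 2..L-1)."""
    total = 0.0
    for L, pL in zip(ks, pk):
        if pL == 0:
            continue
        pos = np.arange(2, L)  # 1-based positions 2..L-1
        if pos_sd == 0:
            w = (pos == int(round(loc))).astype(float)
            if w.sum() == 0:  # degenerate: nearest valid position
                w = np.zeros_like(pos, float)
                w[np.argmin(np.abs(pos - loc))] = 1.0
        else:
            w = sps.norm.cdf(pos + 0.5, loc, pos_sd) - sps.norm.cdf(pos - 0.5, loc, pos_sd)
        if w.sum() == 0:
            raise ValueError("target-position distribution has no mass in range")
        total += pL * float((pos * w).sum() / w.sum())
    return total


def _calibrate_pos_loc(pos_mean: float, pos_sd: float, ks, pk) -> float:
    """Location parameter such that the *truncated* mean equals pos_mean.

    Resampling a rounded Normal into [2, L-1] truncates mostly from above
    (sentences are short relative to the target position), which biases the
    empirical mean low; a deterministic bisection on the exact discrete
    truncated mean removes the bias.
    """
    lo, hi = pos_mean - 1.0, pos_mean + 4.0
    f_lo = _truncated_pos_mean(lo, pos_sd, ks, pk) - pos_mean
    f_hi = _truncated_pos_mean(hi, pos_sd, ks, pk) - pos_mean
    if f_lo > 0 or f_hi < 0:  # cannot bracket: fall back to the nominal mean
        return pos_mean
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _truncated_pos_mean(mid, pos_sd, ks, pk) < pos_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_corpus(
    n_quads: int = 120,
    length_mean: float = 9.56,
    length_sd: float = 1.61,
    pos_mean: float = 7.1,
    pos_sd: float = 1.37,
    seed: int | np.random.Generator = 0,
) -> list[StimulusQuadruple]:
    """Generate ``n_quads`` stimulus quadruples.

    Sentence lengths are round-half-even draws from Normal(length_mean,
    length_sd) clipped to >= 4 words. The 1-based target position is a rounded
    Normal draw resampled until it lies in 2..length-1 (the target word is
    never sentence-initial or -final); the location of that Normal is
    calibrated so the post-truncation empirical mean equals ``pos_mean``.
    Word lengths come from a fixed discrete distribution over 2..12 characters;
    the randomized version permutes the non-target words, keeping the target
    at its position.
    """
    if n_quads < 1:
        raise ValueError("n_quads must be >= 1")
    if length_mean < 4:
        raise ValueError("length_mean must be >= 4")
    if length_sd < 0 or pos_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if pos_mean >= length_mean:
        warnings.warn(
            "pos_mean >= length_mean: target-position resampling may be slow",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    ks, pk = _length_pmf(length_mean, length_sd)
    pos_loc = _calibrate_pos_loc(pos_mean, pos_sd, ks, pk)

    quads: list[StimulusQuadruple] = []
    for q in range(n_quads):
        if length_sd == 0:
            length = max(4, int(round(length_mean)))
        else:
            length = max(4, int(_round_half_even(rng.normal(length_mean, length_sd))))
        while True:
            pos = (
                int(round(pos_loc))
                if pos_sd == 0
                else int(_round_half_even(rng.normal(pos_loc, pos_sd)))
            )
            if 2 <= pos <= length - 1:
                break
            if pos_sd == 0:  # degenerate and out of range: clamp
                pos = min(max(pos, 2), length - 1)
                break
        target_index = pos - 1  # 0-based

        words = tuple(rng.choice(WORD_LENGTHS, size=length, p=WORD_LENGTH_P))
        other = [i for i in range(length) if i != target_index]
        perm = rng.permutation(len(other))
        words_rdm = list(words)
        for dst, src in zip(other, perm):
            words_rdm[dst] = words[other[src]]
        quads.append(
            StimulusQuadruple(
                quad_id=q,
                words_ord=words,
                words_rdm=tuple(words_rdm),
                target_index=target_index,
            )
        )
    return quads


# ---------------------------------------------------------------------------
# scanpath generation
# ---------------------------------------------------------------------------

def _gamma_ms(rng: np.random.Generator, mean: float, shape: float) -> float:
    return float(rng.gamma(shape, mean / shape))


def generate_scanpath(
    quad: StimulusQuadruple,
    condition: str,
    cfg: ScanpathConfig,
    rng: np.random.Generator,
) -> list[FixationEvent]:
    """Simulate one trial's scanpath.

    A strictly left-to-right first pass fixates each word (skipping with the
    configured probabilities; word 0 is always fixated); each fixated word may
    receive one immediate refixation (contributing to GD); after the first
    pass the target may receive one second-pass regression fixation
    (contributing to TVT only). Onsets accumulate durations plus a fixed
    saccade gap.
    """
    if condition not in cfg.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    par = cfg.conditions[condition]
    shape = cfg.duration_shape
    gap = cfg.saccade_gap_ms

    events: list[FixationEvent] = []
    t = 0.0
    target_fixated = False
    for w in range(quad.sentence_length):
        skip_p = cfg.skip_prob_target if w == quad.target_index else cfg.skip_prob_other
        if w > 0 and rng.random() < skip_p:
            continue
        d = _gamma_ms(rng, par.first_fixation_mean, shape)
        events.append(FixationEvent(t, d, w, "first_pass"))
        t += d + gap
        if w == quad.target_index:
            target_fixated = True
        if rng.random() < par.refixation_prob:
            d2 = _gamma_ms(rng, par.refixation_mean, shape)
            events.append(FixationEvent(t, d2, w, "first_pass"))
            t += d2 + gap
    if target_fixated and rng.random() < par.regression_prob:
        d3 = _gamma_ms(rng, par.second_pass_mean, shape)
        events.append(FixationEvent(t, d3, quad.target_index, "second_pass"))
        t += d3 + gap
    return events


def assign_experiment_lists(
    subjects: int,
    corpus: list[StimulusQuadruple],
    seed: int | np.random.Generator = 0,
) -> list[TrialRecord]:
    """Counterbalanced trial skeletons: each subject sees one ORD version and
    the *opposite* RDM version of every quadruple (ORD_COR pairs with RDM_SEM),
    with the pairing alternating between the two experiment lists; half the
    subjects are assigned to each list. Trial order is randomized per subject.
    """
    if subjects % 2 != 0:
        raise ValueError("number of subjects must be even (two experiment lists)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    trials: list[TrialRecord] = []
    for s in range(subjects):
        lst = s % 2
        recs: list[TrialRecord] = []
        for quad in corpus:
            if (quad.quad_id + lst) % 2 == 0:
                pair = ("ORD_COR", "RDM_SEM")
            else:
                pair = ("ORD_SEM", "RDM_COR")
            for cond in pair:
                recs.append(TrialRecord(subject_id=s, quad_id=quad.quad_id, condition=cond))
        order = rng.permutation(len(recs))
        trials.extend(recs[i] for i in order)
    return trials


def simulate_scanpaths(
    trials: list[TrialRecord],
    corpus: list[StimulusQuadruple],
    cfg: ScanpathConfig,
    seed: int | np.random.Generator = 0,
) -> list[TrialRecord]:
    """Fill trial skeletons with simulated scanpaths (in place; returns input)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    by_id = {q.quad_id: q for q in corpus}
    for rec in trials:
        rec.scanpath = generate_scanpath(by_id[rec.quad_id], rec.condition, cfg, rng)
    return trials


def expected_measures(par: ConditionScanpath) -> dict[str, float]:
    """Closed-form target-word expectations for one condition's parameters."""
    ffd = par.first_fixation_mean
    gd = ffd + par.refixation_prob * par.refixation_mean
    tvt = gd + par.regression_prob * par.second_pass_mean
    return {"FFD": ffd, "GD": gd, "TVT": tvt}
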