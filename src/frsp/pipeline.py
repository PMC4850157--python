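"""End-to-end drivers: simulate a co-registered dataset and run the analyses.

A run is a pure function of (config, seed): one root seed is split into
deterministic child streams (corpus, list assignment, scanpaths, one per
subject's EEG session), so any stage can be recomputed in isolation.

Three analyses mirror the study structure:

* eye movements — FFD/GD/TVT on the target word, 80 ms / 3 SD exclusions,
  log-transformed one-way repeated-measures ANOVA plus paired t-tests;
* target-locked FRSP — ORD_COR vs ORD_SEM, epochs -1000..+1500 ms around the
  first fixation on the target, windows 0-300 / 300-600 ms;
* sentence-locked FRSP — pooled ORD vs pooled RDM, epochs -1000..+2500 ms
  around the first fixation on the sentence, six 300 ms windows, theta
  contrasts and the gamma linear-trend (slope) test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import em as em_mod
from . import reading, stats
from .eeg import (
    EVENT_SENTENCE_ONSET,
    EVENT_TARGET_FIXATION,
    SyntheticRecording,
    assemble_session,
    default_templates,
)
from .io import RunConfig
from .montage import DEFAULT_MONTAGE, MontageSpec
from .tfr import (
    FRSPResult,
    WaveletSpec,
    baseline_normalize,
    epoch_by_events,
    epoch_power,
    tf_transform,
)

ORD_CONDITIONS = ("ORD_COR", "ORD_SEM")
RDM_CONDITIONS = ("RDM_COR", "RDM_SEM")


def _child_seeds(seed: int, n: int = 4) -> list[np.random.SeedSequence]:
    """Deterministic child streams: corpus, lists, scanpaths, EEG sessions."""
    return np.random.SeedSequence(seed).spawn(n)


def scanpath_config(cfg: RunConfig) -> reading.ScanpathConfig:
    conditions = {
        name: reading.ConditionScanpath(*params)
        for name, params in cfg.condition_params.items()
    }
    return reading.ScanpathConfig(
        conditions=conditions,
        duration_shape=cfg.duration_shape,
        skip_prob_target=cfg.skip_prob_target,
        skip_prob_other=cfg.skip_prob_other,
        saccade_gap_ms=cfg.saccade_gap_ms,
        fs=cfg.fs,
    )


def wavelet_spec(cfg: RunConfig) -> WaveletSpec:
    return WaveletSpec(
        freqs=np.arange(cfg.f_min, cfg.f_max + 1.0), n_cycles=cfg.n_cycles, fs=cfg.fs
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    cfg: RunConfig, seed: int, n_quads: int | None = None
) -> tuple[list[reading.StimulusQuadruple], list[reading.TrialRecord]]:
    """Corpus plus per-subject trial sequences with simulated scanpaths."""
    ss_corpus, ss_lists, ss_paths, _ = _child_seeds(seed)
    rng_corpus = np.random.default_rng(ss_corpus)
    rng_lists = np.random.default_rng(ss_lists)
    rng_paths = np.random.default_rng(ss_paths)
    corpus = reading.generate_corpus(
        n_quads=n_quads or cfg.n_quads,
        length_mean=cfg.length_mean,
        length_sd=cfg.length_sd,
        pos_mean=cfg.pos_mean,
        pos_sd=cfg.pos_sd,
        seed=rng_corpus,
    )
    trials = reading.assign_experiment_lists(cfg.subjects, corpus, seed=rng_lists)
    reading.simulate_scanpaths(trials, corpus, scanpath_config(cfg), seed=rng_paths)
    return corpus, trials


def scanpaths_to_frames(
    corpus: list[reading.StimulusQuadruple], trials: list[reading.TrialRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten trial records into the scanpath TSV schema plus a trial table."""
    by_id = {q.quad_id: q for q in corpus}
    fix_rows, trial_rows = [], []
    trial_no: dict[int, int] = {}
    for rec in trials:
        t = trial_no.get(rec.subject_id, 0)
        trial_no[rec.subject_id] = t + 1
        quad = by_id[rec.quad_id]
        trial_rows.append(
            (
                rec.subject_id, t, rec.condition, rec.quad_id,
                quad.target_index, quad.sentence_length,
                rec.target_skipped(quad.target_index),
            )
        )
        for ev in rec.scanpath:
            fix_rows.append(
                (rec.subject_id, t, rec.condition, ev.word_index,
                 ev.onset, ev.duration, ev.pass_label)
            )
    fixations = pd.DataFrame(fix_rows, columns=em_mod.SCANPATH_COLUMNS)
    trial_table = pd.DataFrame(
        trial_rows,
        columns=["subject", "trial", "condition", "quad_id", "target_index",
                 "sentence_length", "target_skipped"],
    )
    return fixations, trial_table


# ---------------------------------------------------------------------------
# eye-movement analysis
# ---------------------------------------------------------------------------

def run_em_analysis(
    fixations: pd.DataFrame,
    trial_table: pd.DataFrame,
    return_tables: bool = False,
) -> dict:
    """Full EM pipeline on a scanpath table: pass labels, exclusions,
    word measures, target restriction, condition statistics.

    With ``return_tables`` the per-word and target measure DataFrames are
    included under non-JSON keys ("word_measures", "target_measures").
    """
    labelled = em_mod.first_pass_segment(fixations)
    kept, report = em_mod.apply_exclusions(labelled)
    measures = em_mod.compute_measures(kept)
    target = em_mod.target_measures(measures, trial_table)
    result = em_mod.em_condition_stats(target)
    out = {
        "exclusions": report.to_dict(),
        "n_target_trials": int(len(target)),
        "measures": result,
    }
    if return_tables:
        out["word_measures"] = measures
        out["target_measures"] = target
    return out


def em_condition_means(em_result: dict) -> dict[str, dict[str, float]]:
    """measure -> condition -> raw mean (ms), from a run_em_analysis result."""
    return {
        m: em_result["measures"][m]["raw_condition_means_ms"]
        for m in em_result["measures"]
    }


# ---------------------------------------------------------------------------
# FRSP analyses
# ---------------------------------------------------------------------------

def _subject_frsps(
    rec: SyntheticRecording,
    cfg: RunConfig,
    subject: int,
    level: str,
    montage: MontageSpec,
    mode: str = "epoched",
) -> list[FRSPResult]:
    """FRSP maps for one subject's recording, one per condition group."""
    picks = montage.analysis_channels()
    idx = [rec.ch_names.index(ch) for ch in picks]
    data = rec.data[idx]
    spec = wavelet_spec(cfg)

    if level == "target":
        window = cfg.target_epoch_ms
        groups = {c: (EVENT_TARGET_FIXATION, (c,)) for c in ORD_CONDITIONS}
    elif level == "sentence":
        window = cfg.sentence_epoch_ms
        groups = {
            "ORD": (EVENT_SENTENCE_ONSET, ORD_CONDITIONS),
            "RDM": (EVENT_SENTENCE_ONSET, RDM_CONDITIONS),
        }
    else:
        raise ValueError("level must be 'target' or 'sentence'")

    tf_cont = None
    if mode == "continuous":
        # convolve the whole recording once, then slice power epochs: no
        # interior edge masking, appropriate for overlapping fixation epochs
        tf_cont = tf_transform(
            data, spec, mode="continuous", decim=cfg.decim, ch_names=tuple(picks)
        )

    out = []
    for label, (event_class, conds) in groups.items():
        sel = rec.events[
            (rec.events["event_class"] == event_class)
            & (rec.events["condition"].isin(conds))
        ]["sample"].to_numpy()
        if mode == "continuous":
            tf = epoch_power(tf_cont, sel, window, decim=cfg.decim)
        else:
            epochs, times, _ = epoch_by_events(data, rec.fs, sel, window)
            tf = tf_transform(
                epochs, spec, mode="epoched", times_ms=times, decim=cfg.decim,
                ch_names=tuple(picks),
            )
        out.append(
            baseline_normalize(
                tf, cfg.baseline_ms, scheme=cfg.baseline_scheme,
                condition=label, subject=subject,
            )
        )
    return out


def compute_session_cells_multi(
    cfg: RunConfig,
    seed: int,
    levels: tuple[str, ...] = ("target", "sentence"),
    montage: MontageSpec = DEFAULT_MONTAGE,
    templates=None,
    mode: str = "epoched",
    progress: bool = False,
) -> dict[str, pd.DataFrame]:
    """Simulate every subject's EEG session and aggregate FRSP cell tables
    for one or both locking levels (each subject's recording is simulated
    once and analyzed at every requested level).

    The EEG session uses ``cfg.session_quads`` quadruples per subject (a
    reduced recording length; the scanpath statistics are unaffected).
    """
    if templates is None:
        templates = default_templates()
    corpus, trials = simulate_dataset(cfg, seed, n_quads=cfg.session_quads)
    *_, ss_sessions = _child_seeds(seed)
    subject_seeds = ss_sessions.spawn(cfg.subjects)

    windows = {"target": stats.TARGET_WINDOWS, "sentence": stats.SENTENCE_WINDOWS}
    by_subject: dict[int, list[reading.TrialRecord]] = {}
    for rec in trials:
        by_subject.setdefault(rec.subject_id, []).append(rec)

    tables: dict[str, list[pd.DataFrame]] = {lv: [] for lv in levels}
    for s in range(cfg.subjects):
        rng = np.random.default_rng(subject_seeds[s])
        session = assemble_session(
            by_subject[s], corpus, templates=templates, rng=rng,
            montage=montage, fs=cfg.fs, noise_exponent=cfg.noise_exponent,
        )
        for level in levels:
            frsps = _subject_frsps(session, cfg, s, level, montage, mode=mode)
            tables[level].append(
                stats.aggregate_cells(frsps, montage, windows=windows[level])
            )
        if progress:
            print(f"  subject {s + 1}/{cfg.subjects} done", flush=True)
    return {lv: pd.concat(tables[lv], ignore_index=True) for lv in levels}


def compute_session_cells(
    cfg: RunConfig, seed: int, level: str, montage: MontageSpec = DEFAULT_MONTAGE,
    **kw,
) -> pd.DataFrame:
    """Single-level convenience wrapper around compute_session_cells_multi."""
    return compute_session_cells_multi(cfg, seed, (level,), montage, **kw)[level]


def analyze_target_cells(cells: pd.DataFrame) -> dict:
    """Target-locked inference (ORD_COR vs ORD_SEM) on a cell table, all bands."""
    out = {"cells": cells}
    for band in stats.BANDS:
        out[band] = stats.target_level_analysis(cells, band=band)
    return out


def analyze_sentence_cells(cells: pd.DataFrame) -> dict:
    """Sentence-locked inference (pooled ORD vs RDM): theta windows, gamma slopes."""
    out = {"cells": cells}
    out["theta"] = stats.sentence_level_analysis(cells, band="theta")
    out["gamma"] = stats.sentence_level_analysis(cells, band="gamma")
    out["gamma_slopes"] = {
        cluster: stats.slope_test(cells, cluster=cluster, band="gamma")
        for cluster in ("parieto_occipital_right", "central_right")
    }
    return out


def run_target_analysis(
    cfg: RunConfig, seed: int, montage: MontageSpec = DEFAULT_MONTAGE, **kw
) -> dict:
    """Target-locked FRSP contrast (ORD_COR vs ORD_SEM), all five bands."""
    return analyze_target_cells(compute_session_cells(cfg, seed, "target", montage, **kw))


def run_sentence_analysis(
    cfg: RunConfig, seed: int, montage: MontageSpec = DEFAULT_MONTAGE, **kw
) -> dict:
    """Sentence-locked FRSP (pooled ORD vs RDM): theta windows, gamma slopes."""
    return analyze_sentence_cells(
        compute_session_cells(cfg, seed, "sentence", montage, **kw)
    )
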