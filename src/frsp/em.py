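"""Word-level eye-movement reading measures and their condition statistics.

Measures follow the standard definitions: first-fixation duration (FFD) is
the duration of the first fixation on a word during first-pass reading; gaze
duration (GD) sums all first-pass fixations on the word; total viewing time
(TVT) sums all fixations on the word, first and second pass. Fixations
shorter than 80 ms, or longer than 3 SD above the subject's mean fixation
duration, are excluded before measures are computed; trials in which the
target word was skipped are excluded from target analyses.

All functions operate on the tab-separated scanpath schema
(subject, trial, condition, word_index, onset_ms, duration_ms, pass_label).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reading import OFF_WORD

SCANPATH_COLUMNS = [
    "subject",
    "trial",
    "condition",
    "word_index",
    "onset_ms",
    "duration_ms",
    "pass_label",
]


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping for the 80 ms and 3 SD fixation-duration exclusions."""

    n_fixations_total: int
    n_below_80ms: int
    n_above_3sd: int

    @property
    def fraction_removed(self) -> float:
        if self.n_fixations_total == 0:
            return 0.0
        return (self.n_below_80ms + self.n_above_3sd) / self.n_fixations_total

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fraction_removed"] = self.fraction_removed
        return d


def first_pass_segment(fixations: pd.DataFrame) -> pd.DataFrame:
    """(Re-)assign pass labels from the fixation sequence.

    A word's first pass is the maximal run of consecutive fixations on it
    starting at its first fixation, before gaze leaves the word in either
    direction; every later fixation on the word is second pass. Off-word
    fixations keep no pass structure and are labelled second pass.
    """
    fixations = fixations.sort_values(["subject", "trial", "onset_ms"], kind="stable")
    labels = np.empty(len(fixations), dtype=object)
    pos = 0
    for _, trial in fixations.groupby(["subject", "trial"], sort=False):
        seen: set[int] = set()
        prev_word: int | None = None
        prev_first = False
        for w in trial["word_index"].to_numpy():
            if w == OFF_WORD:
                labels[pos] = "second_pass"
                prev_word, prev_first = None, False
            elif w not in seen:
                seen.add(w)
                labels[pos] = "first_pass"
                prev_word, prev_first = w, True
            elif w == prev_word and prev_first:
                labels[pos] = "first_pass"
            else:
                labels[pos] = "second_pass"
                prev_word, prev_first = w, False
            pos += 1
    out = fixations.copy()
    out["pass_label"] = labels
    return out


def apply_exclusions(
    fixations: pd.DataFrame, min_duration_ms: float = 80.0, n_sd: float = 3.0
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove too-short and outlying fixations.

    The 80 ms cut is applied first; the upper cut removes durations strictly
    greater than mean + 3 SD, with mean and (sample) SD computed per subject
    over that subject's remaining fixation durations, pooled over all words
    and conditions. Trimming is one-pass.
    """
    n_total = len(fixations)
    short = fixations["duration_ms"] < min_duration_ms
    kept = fixations.loc[~short]

    above = pd.Series(False, index=kept.index)
    for subject, grp in kept.groupby("subject"):
        d = grp["duration_ms"]
        if len(d) < 2:
            warnings.warn(
                f"subject {subject!r} has fewer than 2 fixations; "
                "no upper trim applied",
                stacklevel=2,
            )
            continue
        cut = d.mean() + n_sd * d.std(ddof=1)
        above.loc[grp.index] = d > cut

    report = ExclusionReport(
        n_fixations_total=n_total,
        n_below_80ms=int(short.sum()),
        n_above_3sd=int(above.sum()),
    )
    return kept.loc[~above].copy(), report


def compute_measures(fixations: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, trial, word) FFD / GD / TVT in ms.

    Pass labels must already be assigned and exclusions applied. Words with
    no surviving first-pass fixation are flagged skipped with NaN measures.
    """
    fixations = fixations[fixations["word_index"] != OFF_WORD]
    fixations = fixations.sort_values(["subject", "trial", "onset_ms"], kind="stable")
    first = fixations["pass_label"] == "first_pass"
    fp = fixations[first]

    keys = ["subject", "trial", "condition", "word_index"]
    tvt = fixations.groupby(keys, sort=False)["duration_ms"].sum().rename("TVT")
    gd = fp.groupby(keys, sort=False)["duration_ms"].sum().rename("GD")
    ffd = fp.groupby(keys, sort=False)["duration_ms"].first().rename("FFD")

    out = pd.concat([ffd, gd, tvt], axis=1).reset_index()
    out["skipped"] = out["FFD"].isna()
    return out


def target_measures(
    measures: pd.DataFrame, trials: pd.DataFrame
) -> pd.DataFrame:
    """Restrict a measures table to target words, dropping skipped-target trials.

    ``trials`` must carry (subject, trial, target_index).
    """
    merged = measures.merge(
        trials[["subject", "trial", "target_index"]], on=["subject", "trial"]
    )
    on_target = merged[merged["word_index"] == merged["target_index"]]
    return on_target[~on_target["skipped"]].drop(columns="target_index")


def em_condition_stats(
    target: pd.DataFrame,
    measures: tuple[str, ...] = ("FFD", "GD", "TVT"),
) -> dict:
    """Condition statistics for target-word measures.

    Per measure: natural-log transform, aggregate to subject x condition
    means, one-way repeated-measures ANOVA over the four conditions, then
    paired t-tests ORD_SEM vs ORD_COR and RDM_SEM vs RDM_COR on the subject
    means. Raw (untransformed) condition means of the subject means are
    reported alongside for comparability with ms-scale tables.
    """
    from .stats import rm_anova  # local import to avoid a cycle

    results: dict = {}
    for m in measures:
        df = target[["subject", "condition", m]].dropna().copy()
        df["log_value"] = np.log(df[m])
        cells = (
            df.groupby(["subject", "condition"], as_index=False)
            .agg(log_value=("log_value", "mean"), raw=(m, "mean"))
        )
        counts = cells.groupby("subject")["condition"].nunique()
        incomplete = counts[counts < cells["condition"].nunique()].index
        if len(incomplete):
            warnings.warn(
                f"dropping subjects with missing cells: {list(incomplete)}",
                stacklevel=2,
            )
            cells = cells[~cells["subject"].isin(incomplete)]

        anova = rm_anova(cells, dv="log_value", within=["condition"], subject="subject")
        wide = cells.pivot(index="subject", columns="condition", values="log_value")
        contrasts = {}
        for a, b in (("ORD_SEM", "ORD_COR"), ("RDM_SEM", "RDM_COR")):
            if a in wide.columns and b in wide.columns:
                if np.allclose(wide[a], wide[b]):  # identical: null, not NaN
                    t, p = 0.0, 1.0
                else:
                    t, p = sps.ttest_rel(wide[a], wide[b])
                contrasts[f"{a}_vs_{b}"] = {
                    "t": float(t),
                    "df": int(len(wide) - 1),
                    "p": float(p),
                }
        raw_means = (
            cells.groupby("condition")["raw"].mean().round(6).to_dict()
        )
        results[m] = {
            "anova": anova.to_dict(orient="records"),
            "paired_t": contrasts,
            "raw_condition_means_ms": raw_means,
        }
    return results
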