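"""Band x cluster x time-window aggregation and within-subject inference.

The dB maps from the time-frequency stage are reduced to a cell table
(subject x condition x cluster x band x window mean dB) and analyzed with

* fully within-subject repeated-measures ANOVA (each effect tested against
  its effect-by-subject interaction; uncorrected degrees of freedom by
  default),
* planned paired t-tests per cluster (no multiple-comparison correction),
* a linear-trend test: per-subject OLS slope of band power over successive
  300 ms windows (window index as regressor), a one-sided one-sample t per
  condition, and a paired t between conditions.

Frequency bands (inclusive edges, Hz): theta 4-7, alpha 8-12, lower beta
13-18, upper beta 19-30, gamma 31-55.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from .montage import MontageSpec, hemisphere_of, region_of
from .tfr import FRSPResult

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "lower_beta": (13.0, 18.0),
    "upper_beta": (19.0, 30.0),
    "gamma": (31.0, 55.0),
}

TARGET_WINDOWS: tuple[tuple[float, float], ...] = ((0.0, 300.0), (300.0, 600.0))
SENTENCE_WINDOWS: tuple[tuple[float, float], ...] = tuple(
    (300.0 * k, 300.0 * (k + 1)) for k in range(6)
)

ALPHA = 0.05


def window_label(window: tuple[float, float]) -> str:
    return f"{int(window[0])}-{int(window[1])}"


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_cells(
    frsps: list[FRSPResult],
    montage: MontageSpec,
    bands: dict[str, tuple[float, float]] = BANDS,
    windows: tuple[tuple[float, float], ...] = TARGET_WINDOWS,
) -> pd.DataFrame:
    """Unweighted mean dB over cluster channels, in-band frequency bins and
    in-window valid time points, for every FRSP map in ``frsps``.

    Each FRSPResult must carry subject, condition and channel names. Windows
    are half-open [t0, t1) ms. A cell whose window holds no valid time point
    at some in-band frequency raises, naming the cell.
    """
    rows = []
    for res in frsps:
        if res.subject is None or res.condition is None or res.ch_names is None:
            raise ValueError("FRSPResult must carry subject, condition, ch_names")
        ch_index = {ch: i for i, ch in enumerate(res.ch_names)}
        for band_name, (f_lo, f_hi) in bands.items():
            fsel = np.flatnonzero((res.freqs >= f_lo) & (res.freqs <= f_hi))
            if len(fsel) == 0:
                raise ValueError(f"no frequency bins in band {band_name}")
            for window in windows:
                tsel = (res.times >= window[0]) & (res.times < window[1])
                cols = [np.flatnonzero(tsel & res.mask[fi]) for fi in fsel]
                if any(len(c) == 0 for c in cols):
                    raise ValueError(
                        f"cell subject={res.subject} condition={res.condition} "
                        f"band={band_name} window={window_label(window)} has no "
                        "valid time points"
                    )
                for cluster in montage.clusters:
                    try:
                        chs = [ch_index[ch] for ch in montage.clusters[cluster]]
                    except KeyError as err:
                        raise ValueError(f"channel {err} missing from FRSP") from err
                    vals = [res.db[np.ix_(chs, [fi], c)] for fi, c in zip(fsel, cols)]
                    cell = float(np.mean(np.concatenate([v.ravel() for v in vals])))
                    rows.append(
                        (res.subject, res.condition, cluster, band_name,
                         window_label(window), cell)
                    )
    return pd.DataFrame(
        rows, columns=["subject", "condition", "cluster", "band", "window", "value"]
    )


def add_hemisphere_region(cells: pd.DataFrame) -> pd.DataFrame:
    """Split the 6-level cluster factor into Hemisphere(2) x Region(3)."""
    out = cells.copy()
    out["hemisphere"] = out["cluster"].map(hemisphere_of)
    out["region"] = out["cluster"].map(region_of)
    return out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova(
    cells: pd.DataFrame,
    dv: str = "value",
    within: list[str] | None = None,
    subject: str = "subject",
) -> pd.DataFrame:
    """Fully within-subject factorial ANOVA.

    Subject is the random factor; each within-subject effect is tested
    against its effect-by-subject interaction mean square, the standard
    decomposition for fully crossed repeated-measures designs. Degrees of
    freedom are uncorrected (no sphericity correction).
    """
    within = within or ["condition"]
    if cells.groupby([subject, *within]).size().nunique() != 1:
        raise ValueError("unbalanced cell table: aggregate to one value per cell first")
    n_subj = cells[subject].nunique()
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    fit = AnovaRM(data=cells, depvar=dv, subject=subject, within=within).fit()
    tab = fit.anova_table.reset_index().rename(
        columns={
            "index": "effect",
            "F Value": "F",
            "Num DF": "df_num",
            "Den DF": "df_den",
            "Pr > F": "p",
        }
    )
    tab["effect"] = tab["effect"].str.replace(":", " x ")
    # degenerate input (no variance anywhere) leaves 0/0 cancellation noise;
    # a true F is non-negative by construction, so NaN/negative means zero
    bad = tab["F"].isna() | (tab["F"] < 0)
    tab.loc[bad, "F"] = 0.0
    tab.loc[bad, "p"] = 1.0
    return tab[["effect", "F", "df_num", "df_den", "p"]]


def effect_p(anova_table: pd.DataFrame, effect: str) -> float:
    row = anova_table[anova_table["effect"] == effect]
    if row.empty:
        raise KeyError(f"effect {effect!r} not in table")
    return float(row["p"].iloc[0])


# ---------------------------------------------------------------------------
# planned contrasts
# ---------------------------------------------------------------------------

def paired_t(
    cells: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    subject: str = "subject",
    value: str = "value",
) -> dict:
    """Two-sided paired t of cond_a minus cond_b across subjects."""
    wide = (
        cells.groupby([subject, "condition"], as_index=False)[value].mean()
        .pivot(index=subject, columns="condition", values=value)
    )
    if cond_a not in wide.columns or cond_b not in wide.columns:
        raise ValueError(f"conditions {cond_a!r}/{cond_b!r} not both present")
    if len(wide) < 3:
        raise ValueError("need at least 3 subjects for a paired t-test")
    diff = wide[cond_a] - wide[cond_b]
    if np.allclose(diff, 0.0):  # identical conditions: no evidence, not NaN
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(wide[cond_a], wide[cond_b])
    return {
        "t": float(t),
        "df": int(len(wide) - 1),
        "p": float(p),
        "mean_diff": float(diff.mean()),
    }


def planned_contrasts(
    cells: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    by: tuple[str, ...] = ("cluster",),
) -> pd.DataFrame:
    """Paired t per combination of the grouping columns (no correction)."""
    rows = []
    for key, grp in cells.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        res = paired_t(grp, cond_a, cond_b)
        rows.append({**dict(zip(by, key)), **res})
    return pd.DataFrame(rows)


def target_level_analysis(
    cells: pd.DataFrame,
    band: str = "lower_beta",
    cond_a: str = "ORD_SEM",
    cond_b: str = "ORD_COR",
    alpha: float = ALPHA,
) -> dict:
    """Hierarchical follow-up for the target-locked analysis of one band.

    Overall ANOVA Time(2) x Hemisphere(2) x Region(3) x Condition(2); then a
    per-hemisphere Time x Region x Condition ANOVA; for hemispheres with a
    significant three-way interaction, per-window Region x Condition ANOVAs;
    for windows with a Region x Condition interaction, per-cluster paired
    t-tests. The full planned per-cluster t table for the first window is
    reported regardless, as the planned contrasts.
    """
    sub = add_hemisphere_region(
        cells[(cells["band"] == band) & (cells["condition"].isin([cond_a, cond_b]))]
    )
    out: dict = {"band": band}
    out["overall"] = rm_anova(
        sub, within=["window", "hemisphere", "region", "condition"]
    ).to_dict(orient="records")

    out["by_hemisphere"] = {}
    out["by_window"] = {}
    out["cluster_t"] = {}
    for hemi, hgrp in sub.groupby("hemisphere"):
        tab = rm_anova(hgrp, within=["window", "region", "condition"])
        out["by_hemisphere"][hemi] = tab.to_dict(orient="records")
        if effect_p(tab, "window x region x condition") >= alpha:
            continue
        for win, wgrp in hgrp.groupby("window"):
            wtab = rm_anova(wgrp, within=["region", "condition"])
            out["by_window"][f"{hemi}/{win}"] = wtab.to_dict(orient="records")
            if effect_p(wtab, "region x condition") < alpha:
                out["cluster_t"][f"{hemi}/{win}"] = planned_contrasts(
                    wgrp, cond_a, cond_b, by=("cluster",)
                ).to_dict(orient="records")

    first_win = sorted(sub["window"].unique(), key=lambda w: float(w.split("-")[0]))[0]
    out["planned_t_first_window"] = planned_contrasts(
        sub[sub["window"] == first_win], cond_a, cond_b, by=("cluster",)
    ).to_dict(orient="records")
    return out


def sentence_level_analysis(
    cells: pd.DataFrame,
    band: str,
    cond_a: str = "ORD",
    cond_b: str = "RDM",
    alpha: float = ALPHA,
) -> dict:
    """Sentence-locked analysis of one band: overall Time(6) x Cluster(6) x
    Condition(2) ANOVA, per-window Cluster x Condition ANOVAs, and per-cluster
    paired t-tests in every window (planned, uncorrected)."""
    sub = cells[(cells["band"] == band) & (cells["condition"].isin([cond_a, cond_b]))]
    out: dict = {"band": band}
    out["overall"] = rm_anova(
        sub, within=["window", "cluster", "condition"]
    ).to_dict(orient="records")
    out["by_window"] = {}
    out["cluster_t"] = {}
    for win, wgrp in sub.groupby("window"):
        tab = rm_anova(wgrp, within=["cluster", "condition"])
        out["by_window"][win] = tab.to_dict(orient="records")
        out["cluster_t"][win] = planned_contrasts(
            wgrp, cond_a, cond_b, by=("cluster",)
        ).to_dict(orient="records")
    return out


# ---------------------------------------------------------------------------
# linear-trend (slope) test
# ---------------------------------------------------------------------------

@dataclass
class SlopeResult:
    """Per-subject slopes (dB per window step) and their group-level tests."""

    cluster: str
    band: str
    slopes: pd.DataFrame  # columns: subject, condition, slope
    one_sample: dict  # condition -> {t, df, p_one_sided, mean_slope}
    paired: dict  # {t, df, p, mean_diff} for cond_a - cond_b


def slope_test(
    cells: pd.DataFrame,
    cluster: str,
    band: str,
    cond_a: str = "ORD",
    cond_b: str = "RDM",
) -> SlopeResult:
    """Fit an OLS line per subject and condition over the successive window
    means (window index 1..k as regressor) and test the slopes: one-sample
    one-sided t (> 0) per condition, and a two-sided paired t between the two
    conditions' slopes."""
    sub = cells[(cells["cluster"] == cluster) & (cells["band"] == band)]
    if sub.empty:
        raise ValueError(f"no cells for cluster={cluster} band={band}")
    windows = sorted(sub["window"].unique(), key=lambda w: float(w.split("-")[0]))
    if len(windows) < 2:
        raise ValueError("need at least 2 windows for a slope")
    word = {w: i + 1 for i, w in enumerate(windows)}

    rows = []
    for (subject, condition), grp in sub.groupby(["subject", "condition"]):
        g = grp.set_index("window")["value"].reindex(windows)
        if g.isna().any():
            raise ValueError(f"missing windows for subject {subject}, {condition}")
        xs = np.array([word[w] for w in windows], dtype=float)
        slope = float(np.polyfit(xs, g.to_numpy(dtype=float), 1)[0])
        rows.append((subject, condition, slope))
    slopes = pd.DataFrame(rows, columns=["subject", "condition", "slope"])

    one_sample = {}
    for condition, grp in slopes.groupby("condition"):
        if np.allclose(grp["slope"], grp["slope"].iloc[0]) and np.isclose(
            grp["slope"].iloc[0], 0.0
        ):  # identically zero slopes: null symmetry
            t, p = 0.0, 0.5
        else:
            t, p = sps.ttest_1samp(grp["slope"], 0.0, alternative="greater")
        one_sample[condition] = {
            "t": float(t), "df": int(len(grp) - 1),
            "p_one_sided": float(p), "mean_slope": float(grp["slope"].mean()),
        }

    wide = slopes.pivot(index="subject", columns="condition", values="slope")
    paired = {}
    if cond_a in wide.columns and cond_b in wide.columns:
        t, p = sps.ttest_rel(wide[cond_a], wide[cond_b])
        paired = {
            "t": float(t), "df": int(len(wide) - 1), "p": float(p),
            "mean_diff": float((wide[cond_a] - wide[cond_b]).mean()),
        }
    return SlopeResult(cluster=cluster, band=band, slopes=slopes,
                       one_sample=one_sample, paired=paired)
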