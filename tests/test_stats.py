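"""Cell aggregation and within-subject inference against independent oracles."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from frsp.montage import DEFAULT_MONTAGE
from frsp.stats import (
    BANDS,
    SENTENCE_WINDOWS,
    TARGET_WINDOWS,
    aggregate_cells,
    paired_t,
    planned_contrasts,
    rm_anova,
    slope_test,
)
from frsp.tfr import FRSPResult


# ---------------------------------------------------------------------------
# brute-force repeated-measures ANOVA oracle (Moebius decomposition of the
# balanced fully-crossed design, subject as random factor)
# ---------------------------------------------------------------------------

def brute_force_rm_anova(df, factors, subject="subject", dv="value"):
    all_factors = [subject, *factors]
    levels = {f: sorted(df[f].unique()) for f in all_factors}

    def cell_mean(assign):
        sel = np.ones(len(df), dtype=bool)
        for f, lv in assign.items():
            sel &= (df[f] == lv).to_numpy()
        return df.loc[sel, dv].mean()

    def effect_ss(effect):
        # sum over the effect's level combinations of the Moebius term^2,
        # times the number of observations sharing each combination
        combos = list(product(*(levels[f] for f in effect)))
        reps = len(df) / max(len(combos), 1)
        total = 0.0
        for combo in combos:
            term = 0.0
            for r in range(len(effect) + 1):
                for sub in combinations(range(len(effect)), r):
                    assign = {effect[i]: combo[i] for i in sub}
                    sign = (-1) ** (len(effect) - r)
                    term += sign * cell_mean(assign)
            total += reps * term**2
        return total

    def df_effect(effect):
        out = 1
        for f in effect:
            out *= len(levels[f]) - 1
        return out

    results = {}
    for r in range(1, len(factors) + 1):
        for effect in combinations(factors, r):
            ss_num = effect_ss(list(effect))
            ss_den = effect_ss([subject, *effect])
            dfn = df_effect(effect)
            dfd = df_effect([subject, *effect])
            results[" x ".join(effect)] = (
                (ss_num / dfn) / (ss_den / dfd), dfn, dfd
            )
    return results


def random_cells(factors, n_subj=4, seed=0, effect=None):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        for combo in product(*(lv for lv in factors.values())):
            val = rng.integers(-10, 10) + 0.1 * rng.standard_normal()
            rows.append((s, *combo, float(val)))
    return pd.DataFrame(rows, columns=["subject", *factors.keys(), "value"])


class TestRmAnova:
    @pytest.mark.parametrize(
        "factors",
        [
            {"condition": ["a", "b"]},
            {"f1": ["a", "b"], "f2": ["x", "y"]},
            {"window": ["w1", "w2"], "region": ["r1", "r2", "r3"],
             "condition": ["a", "b"]},
        ],
    )
    def test_matches_brute_force_oracle(self, factors):
        cells = random_cells(factors, n_subj=4, seed=len(factors))
        got = rm_anova(cells, within=list(factors))
        want = brute_force_rm_anova(cells, list(factors))
        for _, row in got.iterrows():
            f, dfn, dfd = want[row["effect"]]
            assert row["F"] == pytest.approx(f, rel=1e-10)
            assert row["df_num"] == dfn and row["df_den"] == dfd

    def test_ss_decomposition_sums_to_total(self):
        # for a saturated within design with one observation per cell, the
        # Moebius effect sums (incl. subject terms) recover the total SS
        factors = {"f1": ["a", "b"], "f2": ["x", "y", "z"]}
        cells = random_cells(factors, n_subj=5, seed=7)

        def ss(effect):
            return brute_force_rm_anova(cells, effect and list(effect))

        # recompute all Moebius sums directly
        names = ["subject", "f1", "f2"]
        levels = {f: sorted(cells[f].unique()) for f in names}
        grand = cells["value"].mean()
        total_ss = ((cells["value"] - grand) ** 2).sum()

        def effect_ss(effect):
            combos = list(product(*(levels[f] for f in effect)))
            reps = len(cells) / len(combos)
            tot = 0.0
            for combo in combos:
                term = 0.0
                for r in range(len(effect) + 1):
                    for sub in combinations(range(len(effect)), r):
                        sel = np.ones(len(cells), bool)
                        for i in sub:
                            sel &= (cells[effect[i]] == combo[i]).to_numpy()
                        term += (-1) ** (len(effect) - r) * cells.loc[sel, "value"].mean()
                tot += reps * term**2
            return tot

        parts = sum(
            effect_ss(list(e))
            for r in range(1, 4)
            for e in combinations(names, r)
        )
        assert parts == pytest.approx(total_ss, rel=1e-8)

    def test_constant_dv_gives_zero_f(self):
        cells = random_cells({"condition": ["a", "b"]}, n_subj=4, seed=1)
        cells["value"] = 3.14
        got = rm_anova(cells, within=["condition"])
        assert got["F"].iloc[0] == 0.0 and got["p"].iloc[0] == 1.0

    def test_two_level_f_equals_paired_t_squared(self):
        cells = random_cells({"condition": ["a", "b"]}, n_subj=8, seed=2)
        f = rm_anova(cells, within=["condition"])["F"].iloc[0]
        t = paired_t(cells, "a", "b")["t"]
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_unbalanced_table_rejected(self):
        cells = random_cells({"condition": ["a", "b"]}, n_subj=4, seed=3)
        with pytest.raises(ValueError):
            rm_anova(cells.iloc[:-1], within=["condition"])

    def test_label_permutation_type_i_error_at_nominal_alpha(self):
        # permuting condition labels uniformly at random (per subject)
        # destroys the condition effect: rejection rate ~ alpha
        rng = np.random.default_rng(42)
        n_subj, n_reps, alpha = 20, 500, 0.05
        base = random_cells({"condition": ["a", "b"]}, n_subj=n_subj, seed=4)
        wide = base.pivot(index="subject", columns="condition", values="value")
        wide["a"] += 1.5  # a genuine effect, destroyed by permutation
        rejections = 0
        for _ in range(n_reps):
            flip = rng.random(n_subj) < 0.5
            a = np.where(flip, wide["b"], wide["a"])
            b = np.where(flip, wide["a"], wide["b"])
            _, p = sps.ttest_rel(a, b)
            rejections += p < alpha
        assert rejections / n_reps == pytest.approx(alpha, abs=0.02)


class TestPlannedContrasts:
    def test_identical_conditions_null(self):
        cells = random_cells({"condition": ["a", "b"]}, n_subj=5, seed=5)
        wide = cells.pivot(index="subject", columns="condition", values="value")
        cells.loc[cells["condition"] == "b", "value"] = wide["a"].to_numpy()
        res = paired_t(cells, "a", "b")
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_six_subject_table_matches_textbook_formula(self):
        a = np.array([1.2, 0.8, 1.5, 0.9, 1.1, 1.3])
        b = np.array([0.9, 0.7, 1.1, 1.0, 0.8, 1.0])
        rows = [(s, "a", a[s]) for s in range(6)] + [(s, "b", b[s]) for s in range(6)]
        cells = pd.DataFrame(rows, columns=["subject", "condition", "value"])
        res = paired_t(cells, "a", "b")
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_hand = 2 * sps.t.sf(abs(t_hand), len(d) - 1)
        assert res["t"] == pytest.approx(t_hand, rel=1e-12)
        assert res["p"] == pytest.approx(p_hand, rel=1e-12)
        assert res["df"] == 5

    def test_too_few_subjects_rejected(self):
        cells = random_cells({"condition": ["a", "b"]}, n_subj=2, seed=6)
        with pytest.raises(ValueError):
            paired_t(cells, "a", "b")

    def test_per_cluster_grouping(self):
        cells = random_cells(
            {"condition": ["a", "b"], "cluster": ["c1", "c2"]}, n_subj=5, seed=7
        )
        tab = planned_contrasts(cells, "a", "b", by=("cluster",))
        assert set(tab["cluster"]) == {"c1", "c2"}
        assert len(tab) == 2


class TestSlopeTest:
    @staticmethod
    def window_cells(values_by_subject_condition):
        windows = [f"{300 * k}-{300 * (k + 1)}" for k in range(6)]
        rows = []
        for (s, c), vals in values_by_subject_condition.items():
            for w, v in zip(windows, vals):
                rows.append((s, c, "po", "gamma", w, float(v)))
        return pd.DataFrame(
            rows, columns=["subject", "condition", "cluster", "band", "window", "value"]
        )

    def test_unit_ramp_gives_unit_slope(self):
        cells = self.window_cells({(s, "ORD"): [1, 2, 3, 4, 5, 6] for s in range(4)})
        res = slope_test(cells, "po", "gamma")
        assert np.allclose(res.slopes["slope"], 1.0)

    def test_zero_slopes_give_half_p(self):
        cells = self.window_cells({(s, "ORD"): [2, 2, 2, 2, 2, 2] for s in range(4)})
        res = slope_test(cells, "po", "gamma")
        assert res.one_sample["ORD"]["p_one_sided"] == 0.5

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(8)
        base = {(s, "ORD"): rng.standard_normal(6) for s in range(5)}
        shifted = {k: v + 7.5 for k, v in base.items()}
        r1 = slope_test(self.window_cells(base), "po", "gamma")
        r2 = slope_test(self.window_cells(shifted), "po", "gamma")
        assert np.allclose(r1.slopes["slope"], r2.slopes["slope"])

    def test_paired_comparison_between_conditions(self):
        rng = np.random.default_rng(9)
        vals = {}
        for s in range(8):
            vals[(s, "ORD")] = np.arange(6) * 0.2 + 0.05 * rng.standard_normal(6)
            vals[(s, "RDM")] = 0.05 * rng.standard_normal(6)
        res = slope_test(self.window_cells(vals), "po", "gamma")
        assert res.one_sample["ORD"]["p_one_sided"] < 0.05
        assert res.one_sample["RDM"]["p_one_sided"] > 0.05
        assert res.paired["p"] < 0.05 and res.paired["mean_diff"] > 0

    def test_single_window_rejected(self):
        cells = self.window_cells({(0, "ORD"): [1, 2, 3, 4, 5, 6]})
        cells = cells[cells["window"] == "0-300"]
        with pytest.raises(ValueError):
            slope_test(cells, "po", "gamma")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def make_frsp(db, subject=0, condition="ORD_COR"):
    n_ch, n_f, n_t = db.shape
    freqs = np.arange(3.0, 3.0 + n_f)
    times = np.arange(n_t) * 20.0  # 0..n_t*20 ms
    return FRSPResult(
        db=db, freqs=freqs, times=times,
        mask=np.ones((n_f, n_t), bool), baseline_ms=(-1000.0, 0.0),
        scheme="trial_mean", ch_names=DEFAULT_MONTAGE.channels,
        condition=condition, subject=subject,
    )


class TestAggregateCells:
    def test_constant_field_gives_constant_cells(self):
        db = np.full((64, 60, 40), 0.7)
        cells = aggregate_cells([make_frsp(db)], DEFAULT_MONTAGE)
        assert np.allclose(cells["value"], 0.7)
        assert len(cells) == len(BANDS) * len(TARGET_WINDOWS) * 6

    def test_off_cluster_channel_has_no_influence(self):
        db = np.zeros((64, 60, 40))
        base = aggregate_cells([make_frsp(db.copy())], DEFAULT_MONTAGE)
        db[DEFAULT_MONTAGE.index("Cz")] = 99.0  # Cz is in no cluster
        spiked = aggregate_cells([make_frsp(db)], DEFAULT_MONTAGE)
        assert np.allclose(base["value"], spiked["value"])

    def test_hand_built_mean(self):
        db = np.zeros((64, 60, 40))
        i1 = DEFAULT_MONTAGE.index("P5")
        i2 = DEFAULT_MONTAGE.index("PO3")
        # theta band = freqs 4..7 -> bins 1..4; window 0-300 ms = cols 0..14
        db[i1, 1:5, :15] = 2.0
        db[i2, 1:5, :15] = 4.0
        cells = aggregate_cells([make_frsp(db)], DEFAULT_MONTAGE)
        cell = cells.query(
            "cluster == 'parieto_occipital_left' and band == 'theta' "
            "and window == '0-300'"
        )["value"].iloc[0]
        assert cell == pytest.approx((2.0 + 4.0 + 0.0 * 3) / 5)

    def test_missing_valid_times_raises_with_cell_name(self):
        db = np.zeros((64, 60, 40))
        res = make_frsp(db)
        res.mask[:, :15] = False  # kill the 0-300 ms window everywhere
        with pytest.raises(ValueError, match="0-300"):
            aggregate_cells([res], DEFAULT_MONTAGE)

    def test_sentence_windows_need_long_epoch(self):
        db = np.zeros((64, 60, 95))  # 0..1880 ms at 20 ms steps
        cells = aggregate_cells(
            [make_frsp(db)], DEFAULT_MONTAGE, windows=SENTENCE_WINDOWS
        )
        assert len(cells) == len(BANDS) * 6 * 6
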