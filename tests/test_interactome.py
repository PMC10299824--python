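import math

import numpy as np
import pandas as pd
import pytest

from mobint import (
    InteractomeConfig,
    call_significant,
    differential_interactome,
    impute_missing,
    log2_transform,
    qc_filter,
    score_differential,
    valid_values_filter,
)
from mobint.interactome import DesignError, ImputationError, IntensityMatrix
from mobint.interactome import test_enrichment as enrichment_table

from conftest import tiny_matrix

DESIGN_4x4 = {
    f"{g}_{r}": g for g in ("WT", "R35A", "TurboID", "noDox") for r in range(1, 5)
}


def matrix_4x4(log2_values, flags=None):
    """IntensityMatrix over the canonical 16-sample design from log2 values."""
    df = pd.DataFrame(log2_values, columns=list(DESIGN_4x4))
    return tiny_matrix(np.exp2(df), design=DESIGN_4x4, flags=flags)


def brute_force_bh(pvals):
    """Independent step-up FDR: adj_i = min over j>=rank(i) of m*p_j/j."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj[i] = running
    return adj


class TestQcFilter:
    def test_no_flags_identity(self):
        m = tiny_matrix(np.full((5, 2), 100.0))
        assert qc_filter(m).intensities.equals(m.intensities)

    def test_one_flag_of_each_kind_removed(self):
        flags = pd.DataFrame(
            {
                "contaminant": [True] + [False] * 9,
                "reverse": [False, True] + [False] * 8,
                "only_by_site": [False, False, True] + [False] * 7,
            },
            index=[f"P{i}" for i in range(10)],
        )
        m = tiny_matrix(np.full((10, 2), 10.0), flags=flags)
        out = qc_filter(m)
        assert len(out.intensities) == 7
        out2 = qc_filter(out)
        assert out2.intensities.equals(out.intensities)

    def test_all_flagged_gives_empty(self):
        flags = pd.DataFrame(
            {k: [True] * 3 for k in ("contaminant", "reverse", "only_by_site")},
            index=[f"P{i}" for i in range(3)],
        )
        m = tiny_matrix(np.full((3, 2), 10.0), flags=flags)
        assert len(qc_filter(m).intensities) == 0


class TestValidValuesFilter:
    def test_one_complete_group_keeps_protein(self):
        vals = np.full((1, 16), np.nan)
        vals[0, :4] = 100.0  # complete in WT only
        m = matrix_4x4(np.log2(vals))
        assert len(valid_values_filter(m).intensities) == 1

    def test_three_of_four_everywhere_drops_protein(self):
        vals = np.full((1, 16), 100.0)
        vals[0, ::4] = np.nan  # one hole per group
        m = tiny_matrix(pd.DataFrame(vals, columns=list(DESIGN_4x4)), DESIGN_4x4)
        assert len(valid_values_filter(m).intensities) == 0

    def test_complete_matrix_all_kept(self):
        m = matrix_4x4(np.full((6, 16), 20.0))
        assert len(valid_values_filter(m).intensities) == 6

    def test_wrong_replicate_count_is_design_error(self):
        design = {"WT_1": "WT", "WT_2": "WT", "WT_3": "WT"}
        m = tiny_matrix(
            pd.DataFrame(np.full((2, 3), 10.0), columns=list(design)), design
        )
        with pytest.raises(DesignError):
            valid_values_filter(m)


class TestLog2AndImpute:
    def test_log2_exact_values_and_missing_preserved(self):
        m = tiny_matrix(pd.DataFrame({"a": [8.0, 1.0], "b": [2.0, np.nan]}))
        out = log2_transform(m)
        assert out.loc["P0", "a"] == 3.0
        assert out.loc["P1", "a"] == 0.0
        assert math.isnan(out.loc["P1", "b"])

    def test_non_positive_intensity_rejected_at_construction(self):
        with pytest.raises(ValueError):
            tiny_matrix(pd.DataFrame({"a": [0.0, 2.0]}))

    def test_complete_matrix_identity(self):
        df = pd.DataFrame(np.arange(1.0, 13.0).reshape(4, 3))
        assert impute_missing(df, rng=0).equals(df)

    def test_only_missing_cells_change_and_seed_reproduces(self, rng):
        df = pd.DataFrame(rng.normal(20, 2, (50, 4)))
        df.iloc[::7, 2] = np.nan
        a = impute_missing(df, rng=np.random.default_rng(5))
        b = impute_missing(df, rng=np.random.default_rng(5))
        assert a.equals(b)
        observed_mask = df.notna()
        assert a[observed_mask].equals(df[observed_mask])
        assert not a.isna().any().any()

    def test_downshift_and_width_moments(self, rng):
        # the imputed cloud sits downshift sigmas below the observed mean
        # with width x the observed spread (Monte-Carlo over ~3e4 cells)
        df = pd.DataFrame(rng.normal(20, 2, (10_000, 4)))
        miss = rng.random(df.shape) < 0.4
        masked = df.mask(miss)
        out = impute_missing(masked, width=0.3, downshift=1.8, rng=7)
        shifts, widths = [], []
        for col in df.columns:
            obs = masked[col].dropna()
            imp = out.loc[masked[col].isna(), col]
            shifts.append((obs.mean() - imp.mean()) / obs.std(ddof=1))
            widths.append(imp.std(ddof=1) / obs.std(ddof=1))
        assert np.mean(shifts) == pytest.approx(1.8, abs=0.05)
        assert np.mean(widths) == pytest.approx(0.3, abs=0.02)

    def test_sparse_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan, np.nan], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ImputationError):
            impute_missing(df)


class TestEnrichment:
    def test_null_identity(self):
        log2 = pd.DataFrame(
            np.tile(np.linspace(18, 22, 5)[:, None], (1, 16)),
            columns=list(DESIGN_4x4),
        )
        res = enrichment_table(log2, pd.Series(DESIGN_4x4), "WT", "TurboID")
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["adj_p"], 1.0)

    def test_planted_shift_matches_hand_t_formula(self, rng):
        from scipy import stats as sps

        case = np.array([23.0, 23.1, 22.9, 23.05])
        ctrl = np.array([20.0, 20.1, 19.9, 20.05])
        log2 = pd.DataFrame(
            np.concatenate([case, case, ctrl, ctrl])[None, :],
            columns=list(DESIGN_4x4),
        )
        res = enrichment_table(log2, pd.Series(DESIGN_4x4), "WT", "TurboID")
        assert res["log2fc"].iloc[0] == pytest.approx(3.0, abs=1e-9)
        # independent Student-t computation
        sp = math.sqrt(((case.std(ddof=1) ** 2 + ctrl.std(ddof=1) ** 2) / 2))
        t = (case.mean() - ctrl.mean()) / (sp * math.sqrt(2 / 4))
        p_hand = 2 * sps.t.sf(abs(t), df=6)
        assert res["p"].iloc[0] == pytest.approx(p_hand, rel=1e-9)
        assert res["p"].iloc[0] < 1e-4

    def test_bh_adjustment_matches_brute_force(self, rng):
        log2 = pd.DataFrame(
            rng.normal(20, 1, (40, 16)), columns=list(DESIGN_4x4)
        )
        res = enrichment_table(log2, pd.Series(DESIGN_4x4), "WT", "noDox")
        brute = brute_force_bh(res["p"].to_numpy())
        assert np.allclose(res["adj_p"], brute)
        # the oracle itself on the textbook example
        assert np.allclose(brute_force_bh(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)

    def test_bh_monotone_and_at_least_raw(self, rng):
        log2 = pd.DataFrame(
            rng.normal(20, 1, (60, 16)), columns=list(DESIGN_4x4)
        )
        res = enrichment_table(log2, pd.Series(DESIGN_4x4), "R35A", "TurboID")
        srt = res.sort_values("p")
        assert (np.diff(srt["adj_p"]) >= -1e-12).all()
        assert (res["adj_p"] >= res["p"] - 1e-12).all()


class TestCalling:
    def _res(self, log2fc, adj_p):
        return pd.DataFrame(
            {"log2fc": log2fc, "adj_p": adj_p},
            index=[f"P{i}" for i in range(len(log2fc))],
        )

    def test_conjunction_rule(self):
        vs_turbo = self._res([1.5, 0.9, 2.0], [0.01, 0.001, 0.2])
        vs_nodox = self._res([2.0, 3.0, 2.5], [0.02, 0.001, 0.01])
        sig = call_significant(vs_turbo, vs_nodox)
        assert sig.tolist() == [True, False, False]

    def test_boundaries_are_strict(self):
        vs_a = self._res([1.0, 1.01], [0.05, 0.049])
        vs_b = self._res([2.0, 2.0], [0.01, 0.01])
        sig = call_significant(vs_a, vs_b)
        assert sig.tolist() == [False, True]


class TestDifferentialScoring:
    def test_zero_spread_labels_nothing(self):
        s = pd.Series([1.0] * 5)
        assert (score_differential(s) == "none").all()

    def test_single_extreme_outlier_labelled(self, rng):
        vals = pd.Series(rng.normal(0, 1, 200))
        vals.loc[200] = -10.0
        labels = score_differential(vals)
        assert labels.loc[200] == "R35A_preferential"
        assert (labels.drop(200) == "none").all()

    def test_positive_outlier_is_wt_preferential(self, rng):
        vals = pd.Series(rng.normal(0, 0.5, 100))
        vals.loc[100] = 8.0
        assert score_differential(vals).loc[100] == "WT_preferential"

    def test_cohort_too_small(self):
        with pytest.raises(ValueError):
            score_differential(pd.Series([1.0]))


class TestFullCaller:
    def test_planted_truth_recovery(self, planted_proteomics):
        matrix, truth = planted_proteomics
        res = differential_interactome(matrix, InteractomeConfig(seed=1))
        planted_ids = set(truth.loc[truth["is_planted"], "protein"])
        called = set(res.calls.loc[res.calls["significant_WT"], "protein"])
        # recall over planted proteins that survived the QC/flag filters
        surviving = planted_ids & set(res.calls["protein"])
        recall = len(called & surviving) / len(surviving)
        assert recall >= 0.9
        false_calls = called - planted_ids
        assert len(false_calls) <= 0.05 * len(called) + 2

    def test_call_soundness_on_outputs(self, planted_proteomics):
        matrix, _ = planted_proteomics
        res = differential_interactome(matrix, InteractomeConfig(seed=1))
        calls = res.calls
        for case in ("WT", "R35A"):
            sig = calls[calls[f"significant_{case}"]]
            for ctrl in ("TurboID", "noDox"):
                assert (sig[f"log2fc_{case}_vs_{ctrl}"] > 1.0).all()
                assert (sig[f"adj_p_{case}_vs_{ctrl}"] < 0.05).all()

    def test_pipeline_seed_determinism(self, planted_proteomics):
        matrix, _ = planted_proteomics
        a = differential_interactome(matrix, InteractomeConfig(seed=3))
        b = differential_interactome(matrix, InteractomeConfig(seed=3))
        assert a.calls.equals(b.calls)

    def test_differential_labels_respect_cutoff(self, planted_proteomics):
        matrix, _ = planted_proteomics
        res = differential_interactome(matrix)
        ratios = res.calls.set_index("protein")["wt_r35a_log2fc"]
        mu, sd = ratios.mean(), ratios.std(ddof=1)
        labelled = res.calls[res.calls["differential"] != "none"]
        for _, row in labelled.iterrows():
            assert abs(row["wt_r35a_log2fc"] - mu) > 3 * sd
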