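"""DM calling criteria, BH FDR, sex adjustment, gene aggregation, set algebra."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dsdm.arrays import BetaMatrix
from dsdm.dm import (
    adjust_for_sex,
    aggregate_to_genes,
    benjamini_hochberg,
    call_dm_cpgs,
    intersect_dm_sets,
)
from conftest import toy_beta, toy_sheet


def reference_bh(p):
    """Independent step-up reference: q_i = min_{j>=i} (m * p_(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate_vectors(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(benjamini_hochberg(p), reference_bh(p), atol=1e-12)

    def test_q_at_least_p_and_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestCallDmCpgs:
    def test_extreme_separation_passes(self):
        beta = toy_beta(
            {"cg1": [0.8, 0.8 + 1e-6, 0.8, 0.2, 0.2 + 1e-6, 0.2]},
            [f"s{i}" for i in range(6)],
        )
        sheet = toy_sheet(["case"] * 3 + ["control"] * 3)
        calls = call_dm_cpgs(beta, sheet)
        assert calls.loc["cg1", "passes"]
        assert calls.loc["cg1", "delta"] == pytest.approx(0.6, abs=1e-5)
        assert calls.loc["cg1", "direction"] == "hyper"

    def test_identical_groups_do_not_pass(self):
        beta = toy_beta({"cg1": [0.4, 0.5, 0.6, 0.4, 0.5, 0.6]}, [f"s{i}" for i in range(6)])
        sheet = toy_sheet(["case"] * 3 + ["control"] * 3)
        calls = call_dm_cpgs(beta, sheet)
        assert calls.loc["cg1", "delta"] == 0.0
        assert not calls.loc["cg1", "passes"]

    def test_small_n_toy_verified_against_closed_form(self):
        # case {0.7,0.8,0.9} vs control {0.4,0.5,0.6}: delta passes, p does not
        case, ctrl = [0.7, 0.8, 0.9], [0.4, 0.5, 0.6]
        beta = toy_beta({"cg1": case + ctrl}, [f"s{i}" for i in range(6)])
        sheet = toy_sheet(["case"] * 3 + ["control"] * 3)
        calls = call_dm_cpgs(beta, sheet)
        t_ref, p_ref = stats.ttest_ind(case, ctrl, equal_var=True)
        # closed form: t = (0.3) / (0.1 * sqrt(2/3)) = 3.674...
        assert t_ref == pytest.approx(0.3 / (0.1 * np.sqrt(2 / 3)), rel=1e-10)
        assert calls.loc["cg1", "t_statistic"] == pytest.approx(t_ref, rel=1e-10)
        assert calls.loc["cg1", "p_value"] == pytest.approx(p_ref, rel=1e-10)
        assert abs(calls.loc["cg1", "delta"]) >= 0.15
        assert p_ref > 0.001 and not calls.loc["cg1", "passes"]

    def test_zero_variance_recorded_not_crashed(self):
        beta = toy_beta({"cg1": [0.5] * 6, "cg2": [0.9] * 3 + [0.1] * 3},
                        [f"s{i}" for i in range(6)])
        sheet = toy_sheet(["case"] * 3 + ["control"] * 3)
        calls = call_dm_cpgs(beta, sheet)
        assert not calls.loc["cg1", "passes"]
        assert calls.loc["cg1", "reason"] == "zero_variance"

    def test_label_swap_negates_delta_and_preserves_p(self, small_cohort):
        calls = call_dm_cpgs(small_cohort.beta, small_cohort.sheet)
        swapped_sheet = small_cohort.sheet.copy()
        swapped_sheet["status"] = np.where(
            swapped_sheet["status"] == "case", "control", "case"
        )
        swapped = call_dm_cpgs(small_cohort.beta, swapped_sheet)
        np.testing.assert_allclose(calls["delta"], -swapped["delta"], atol=1e-12)
        np.testing.assert_allclose(
            calls["p_value"].dropna(), swapped["p_value"].dropna(), atol=1e-12
        )

    def test_planted_truth_recovery(self, small_cohort):
        calls = call_dm_cpgs(small_cohort.beta, small_cohort.sheet)
        truth = set(small_cohort.truth.dm_cpg_ids)
        hits = set(calls.index[calls["passes"]])
        sensitivity = len(hits & truth) / len(truth)
        fdr = len(hits - truth) / max(len(hits), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.05


class TestAdjustForSex:
    def test_balanced_design_close_to_unadjusted(self):
        rng = np.random.default_rng(2)
        n = 20
        sheet = toy_sheet(
            ["case"] * 10 + ["control"] * 10,
            sex=["M", "F"] * 10,
            sample_ids=[f"s{i}" for i in range(n)],
        )
        status = (sheet["status"] == "case").to_numpy(float)
        vals = np.clip(0.4 + 0.25 * status + rng.normal(0, 0.05, size=(40, n)), 0, 1)
        beta = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(40)],
                                       columns=sheet.index))
        calls = adjust_for_sex(beta, sheet, call_dm_cpgs(beta, sheet))
        passing = calls[calls["passes"]]
        ratio = passing["sex_adjusted_p"] / passing["p_value"]
        assert np.median(np.abs(np.log10(ratio))) < 0.5

    def test_confounded_sex_effect_deconfounded(self):
        # sex effect 0.3, status effect 0.1, sex 80/20 confounded with status
        rng = np.random.default_rng(3)
        n = 20
        status = np.r_[np.ones(10), np.zeros(10)]
        sex = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)]  # M=1
        sheet = toy_sheet(
            ["case" if s else "control" for s in status],
            sex=["M" if s else "F" for s in sex],
            sample_ids=[f"s{i}" for i in range(n)],
        )
        vals = np.clip(
            0.2 + 0.1 * status + 0.3 * sex + rng.normal(0, 0.03, size=(30, n)), 0, 1
        )
        beta = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(30)],
                                       columns=sheet.index))
        calls = call_dm_cpgs(beta, sheet, delta_min=0.0, p_max=1.0)
        raw_delta = calls["delta"].mean()  # inflated by the sex effect
        X = np.column_stack([np.ones(n), status, sex])
        coefs = np.linalg.lstsq(X, beta.values.to_numpy().T, rcond=None)[0][1]
        assert abs(coefs.mean() - 0.1) < abs(raw_delta - 0.1)

    def test_constant_sex_copies_p_with_warning(self):
        beta = toy_beta({"cg1": [0.9, 0.85, 0.9, 0.1, 0.15, 0.1]},
                        [f"s{i}" for i in range(6)])
        sheet = toy_sheet(["case"] * 3 + ["control"] * 3, sex=["M"] * 6)
        calls = call_dm_cpgs(beta, sheet)
        with pytest.warns(UserWarning, match="constant"):
            adjusted = adjust_for_sex(beta, sheet, calls)
        assert adjusted.loc["cg1", "sex_adjusted_p"] == adjusted.loc["cg1", "p_value"]


class TestGeneAggregation:
    def _annot(self, genes):
        return pd.DataFrame(
            {"gene_ids": genes}, index=pd.Index([f"cg{i}" for i in range(len(genes))],
                                                name="probe_id")
        )

    def _calls(self, passes, directions=None):
        n = len(passes)
        return pd.DataFrame(
            {
                "passes": passes,
                "direction": directions or ["hyper"] * n,
            },
            index=[f"cg{i}" for i in range(n)],
        )

    def test_two_cpgs_one_gene(self):
        out = aggregate_to_genes(self._calls([True, True]), self._annot(["GENE1", "GENE1"]))
        assert len(out) == 1 and out.loc["GENE1", "n_dm_cpgs"] == 2

    def test_multi_gene_probe_counts_toward_each(self):
        out = aggregate_to_genes(self._calls([True]), self._annot(["GENE1;GENE2"]))
        assert set(out.index) == {"GENE1", "GENE2"}

    def test_intergenic_cpg_in_cpg_total_only(self):
        out = aggregate_to_genes(
            self._calls([True, True, True]), self._annot(["A", "A;B", ""])
        )
        assert out.loc["A", "n_dm_cpgs"] == 2
        assert out.loc["B", "n_dm_cpgs"] == 1
        assert out.attrs["n_passing_cpgs"] == 3

    def test_empty_input_empty_output(self):
        out = aggregate_to_genes(self._calls([False]), self._annot(["GENE1"]))
        assert out.empty


class TestIntersectDmSets:
    def test_basic_partition(self):
        parts = intersect_dm_sets({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
        assert parts[("A", "B")] == {"g2"}
        assert parts[("A",)] == {"g1"}
        assert parts[("B",)] == {"g3"}

    def test_direction_aware_mismatch_not_shared(self):
        parts = intersect_dm_sets(
            {"A": {"g2": "hyper"}, "B": {"g2": "hypo"}}, direction_aware=True
        )
        assert ("A", "B") not in parts
        assert parts[("A",)] == {"g2"} and parts[("B",)] == {"g2"}

    def test_overlap_fraction_arithmetic(self):
        big = {f"g{i}" for i in range(65)}
        fetal = {f"g{i}" for i in range(18)} | {f"x{i}" for i in range(30)}
        parts = intersect_dm_sets({"adult": big, "fetal": fetal})
        frac = len(parts[("adult", "fetal")]) / len(big)
        assert frac == pytest.approx(18 / 65, abs=1e-12)

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            intersect_dm_sets({"A": {"g1"}})
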