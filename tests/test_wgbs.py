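"""Coverage filter, trisomy coverage ratio, window DM caller, composite score."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from dsdm.synthetic import CONTIG, WgbsSimConfig, simulate_wgbs_pair
from dsdm.wgbs import (
    call_window_dm,
    composite_confidence,
    coverage_ratio,
    filter_coverage,
    fisher_exact_two_sided,
    gain_loss_summary,
    global_methylation_delta,
    windows_from_positions,
)


def table(pos, m, total, chrom="chr1"):
    m = np.asarray(m)
    total = np.asarray(total)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "count_methylated": m,
            "count_total": total,
            "fraction": m / total,
        }
    )


def enumerate_fisher_two_sided(a, b, c, d):
    """Exhaustive two-sided Fisher p from binomial coefficients."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    probs = {}
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        probs[x] = comb(row1, x) * comb(n - row1, col1 - x) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisherOracle:
    def test_matches_enumeration_margins_up_to_eight(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b == 0 or c + d == 0:
                continue
            p = fisher_exact_two_sided(a, b, c, d)
            assert p == pytest.approx(
                enumerate_fisher_two_sided(a, b, c, d), rel=1e-9, abs=1e-12
            ), (a, b, c, d)


class TestFilterCoverage:
    def test_boundary_depth_kept(self):
        t = table([100, 200, 300], [5, 10, 20], [19, 20, 35])
        out = filter_coverage(t, min_depth=20)
        assert list(out["pos"]) == [200, 300]

    def test_identity_cases(self):
        t = table([1, 2], [10, 20], [30, 30])
        assert len(filter_coverage(t, 20)) == 2
        assert len(filter_coverage(t, 0)) == 2

    def test_empty_result_is_error(self):
        with pytest.raises(ValueError, match="coverage"):
            filter_coverage(table([1], [1], [5]), min_depth=20)

    def test_inconsistent_counts_rejected(self):
        bad = table([1], [10], [30])
        bad.loc[0, "count_methylated"] = 40
        with pytest.raises(ValueError):
            filter_coverage(bad)


class TestCoverageRatio:
    def test_identical_tables_ratio_one(self):
        t = table(np.arange(10) * 100, np.full(10, 10), np.full(10, 30))
        res = coverage_ratio(t, t, ("chr1", 0, 500))
        assert res["region_mean"] == pytest.approx(1.0)
        assert res["flank_mean"] == pytest.approx(1.0)
        assert np.allclose(res["track"]["ratio"], 1.0)

    def test_global_scaling_normalized_away(self):
        t = table(np.arange(10) * 100, np.full(10, 10), np.full(10, 30))
        doubled = t.assign(count_total=t["count_total"] * 2,
                           count_methylated=t["count_methylated"] * 2)
        res = coverage_ratio(doubled, t, ("chr1", 0, 500))
        assert res["region_mean"] == pytest.approx(1.0)

    def test_synthetic_duplication_recovered(self):
        pair = simulate_wgbs_pair(
            WgbsSimConfig(n_cpgs=50_000, mean_depth=30, n_dm_windows=0, dm_delta=0.0, seed=12)
        )
        case = filter_coverage(pair.case)
        wt = filter_coverage(pair.wt)
        res = coverage_ratio(case, wt, (CONTIG, *pair.dup_region))
        assert 1.45 <= res["region_mean"] <= 1.55
        assert 0.97 <= res["flank_mean"] <= 1.03

    def test_empty_region_is_error(self):
        t = table([100], [10], [30])
        with pytest.raises(ValueError, match="region"):
            coverage_ratio(t, t, ("chr1", 5000, 6000))


class TestCallWindowDm:
    def _window(self):
        return pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})

    def test_three_concordant_dm_cpgs_called(self):
        # deltas {+0.3, +0.3, +0.3} at depth 30: e.g. 21/30 vs 12/30 methylated
        case = table([100, 400, 700], [21, 21, 21], [30, 30, 30])
        wt = table([100, 400, 700], [12, 12, 12], [30, 30, 30])
        calls = call_window_dm(case, wt, self._window(), fisher_alpha=0.05)
        row = calls.iloc[0]
        assert row["called"] and row["direction"] == "gain"
        # per-CpG Fisher p verified against the enumeration oracle
        p = enumerate_fisher_two_sided(21, 9, 12, 18)
        assert row["min_fisher_p"] == pytest.approx(p, rel=1e-9)
        assert p <= 0.05

    def test_mixed_direction_not_called(self):
        case = table([100, 400, 700], [21, 21, 3], [30, 30, 30])
        wt = table([100, 400, 700], [12, 12, 12], [30, 30, 30])
        calls = call_window_dm(case, wt, self._window())
        assert not calls.iloc[0]["called"]

    def test_two_dm_cpgs_not_enough(self):
        case = table([100, 400], [21, 21], [30, 30])
        wt = table([100, 400], [12, 12], [30, 30])
        calls = call_window_dm(case, wt, self._window())
        assert not calls.iloc[0]["called"]

    def test_windows_without_coverage_skipped(self):
        case = table([100], [21], [30])
        wt = table([100], [12], [30])
        windows = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 5000], "end": [1000, 6000]}
        )
        calls = call_window_dm(case, wt, windows)
        assert len(calls) == 1

    def test_swapping_genomes_flips_directions(self, wgbs_pair):
        case = filter_coverage(wgbs_pair.case)
        wt = filter_coverage(wgbs_pair.wt)
        windows = windows_from_positions(wgbs_pair.wt[["chrom", "pos"]])
        fwd = call_window_dm(case, wt, windows)
        rev = call_window_dm(wt, case, windows)
        called = fwd[fwd["called"]].set_index(["chrom", "start"])
        rcalled = rev[rev["called"]].set_index(["chrom", "start"])
        assert set(called.index) == set(rcalled.index)
        for idx in called.index:
            assert {called.loc[idx, "direction"], rcalled.loc[idx, "direction"]} == {
                "gain", "loss",
            }

    def test_fisher_ladder_monotone(self, wgbs_pair):
        case = filter_coverage(wgbs_pair.case)
        wt = filter_coverage(wgbs_pair.wt)
        windows = windows_from_positions(wgbs_pair.wt[["chrom", "pos"]])
        counts = [
            int(call_window_dm(case, wt, windows, fisher_alpha=a)["called"].sum())
            for a in (0.05, 0.01, 0.005, 0.001)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_planted_windows_recovered(self, wgbs_pair):
        case = filter_coverage(wgbs_pair.case)
        wt = filter_coverage(wgbs_pair.wt)
        windows = windows_from_positions(wgbs_pair.wt[["chrom", "pos"]])
        calls = call_window_dm(case, wt, windows, fisher_alpha=0.05)
        truth = {(c, s) for c, s, _ in wgbs_pair.truth.dm_window_ids}
        keys = list(zip(calls["chrom"], calls["start"]))
        is_truth = pd.Series([k in truth for k in keys])
        assert calls.loc[is_truth.to_numpy(), "called"].mean() >= 0.9
        # planted directions match
        called_truth = calls[is_truth.to_numpy() & calls["called"].to_numpy()]
        for row in called_truth.itertuples():
            planted = wgbs_pair.truth.dm_window_directions[(row.chrom, row.start, row.end)]
            assert row.direction == ("gain" if planted > 0 else "loss")

    def test_wilcoxon_gate(self):
        case = table(np.arange(10) * 100, np.full(10, 21), np.full(10, 30))
        wt = table(np.arange(10) * 100, np.full(10, 12), np.full(10, 30))
        calls = call_window_dm(case, wt, self._window(), require_wilcoxon=True)
        assert calls.iloc[0]["wilcoxon_p"] < 0.05 and calls.iloc[0]["called"]


class TestCompositeScore:
    @pytest.mark.parametrize("median,n,expected", [(0.2, 5, 1.0), (0.16, 4, 0.8)])
    def test_hand_computed_values(self, median, n, expected):
        score = composite_confidence(
            {"called": True, "median_abs_delta": median, "n_dm_cpgs": n}
        )
        assert score == pytest.approx(expected, abs=1e-12)

    def test_uncalled_window_is_error(self):
        with pytest.raises(ValueError):
            composite_confidence({"called": False, "median_abs_delta": 0.2, "n_dm_cpgs": 5})

    def test_ranking_invariant_to_window_order(self, wgbs_pair):
        case = filter_coverage(wgbs_pair.case)
        wt = filter_coverage(wgbs_pair.wt)
        windows = windows_from_positions(wgbs_pair.wt[["chrom", "pos"]])
        fwd = call_window_dm(case, wt, windows)
        shuffled = call_window_dm(case, wt, windows.sample(frac=1, random_state=0))
        a = fwd[fwd["called"]].sort_values(["chrom", "start"])["composite_score"]
        b = shuffled[shuffled["called"]].sort_values(["chrom", "start"])["composite_score"]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


class TestGlobalDelta:
    def test_identical_tables_zero(self):
        t = table(np.arange(5) * 100, np.full(5, 15), np.full(5, 30))
        assert global_methylation_delta(t, t)["delta_overall"] == 0.0

    def test_exact_shift(self):
        wt = table(np.arange(5) * 100, np.full(5, 15), np.full(5, 30))
        case = wt.assign(fraction=wt["fraction"] + 0.01)
        assert global_methylation_delta(case, wt)["delta_overall"] == pytest.approx(0.01)

    def test_null_simulation_small(self):
        pair = simulate_wgbs_pair(
            WgbsSimConfig(n_cpgs=10_000, mean_depth=30, n_dm_windows=0, dm_delta=0.0, seed=4)
        )
        res = global_methylation_delta(pair.case, pair.wt)
        assert abs(res["delta_overall"]) < 0.005

    def test_region_stratification(self):
        wt = table(np.arange(10) * 100, np.full(10, 15), np.full(10, 30))
        case = wt.copy()
        case.loc[:4, "fraction"] += 0.1
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
        res = global_methylation_delta(case, wt, regions)
        assert res["delta_inside"] == pytest.approx(0.1)
        assert res["delta_outside"] == pytest.approx(0.0)


class TestGainLossSummary:
    def test_fractions(self):
        calls = pd.DataFrame(
            {"called": [True] * 10, "direction": ["gain"] * 6 + ["loss"] * 4}
        )
        out = gain_loss_summary(calls).set_index("direction")
        assert out.loc["gain", "fraction"] == pytest.approx(0.6)
        assert out.loc["loss", "n_windows"] == 4

    def test_zero_calls_no_crash(self):
        out = gain_loss_summary(pd.DataFrame({"called": [False], "direction": ["mixed"]}))
        assert out.empty

    def test_planted_gain_fraction_recovered(self):
        pair = simulate_wgbs_pair(
            WgbsSimConfig(n_cpgs=20_000, mean_depth=30, n_dm_windows=60, dm_delta=0.3, seed=8)
        )
        case = filter_coverage(pair.case)
        wt = filter_coverage(pair.wt)
        windows = windows_from_positions(pair.wt[["chrom", "pos"]])
        calls = call_window_dm(case, wt, windows, fisher_alpha=0.05)
        planted_gain = np.mean(
            [d > 0 for d in pair.truth.dm_window_directions.values()]
        )
        out = gain_loss_summary(calls).set_index("direction")
        se = np.sqrt(planted_gain * (1 - planted_gain) / 60)
        assert abs(out.loc["gain", "fraction"] - planted_gain) < 4 * se + 0.05
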