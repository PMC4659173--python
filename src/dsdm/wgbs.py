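"""Windowed differential-methylation calling on WGBS read counts.

Inputs are per-CpG count tables (``chrom``, ``pos``, ``count_methylated``,
``count_total``, ``fraction``) for one case genome and one wild-type
genome — single animals, as in engineered-duplication designs, so evidence
comes from read depth rather than biological replication.

The caller operates on 1-kb windows: a member CpG is DM when its
case-minus-wt fraction difference exceeds ``delta_min`` (default 0.15) in
absolute value; a window is called when at least ``min_dm_cpgs`` (default 3)
DM CpGs agree in direction and no DM CpG disagrees.  A stringency ladder is
obtained by additionally requiring at least one DM CpG to reach a two-sided
Fisher exact p <= alpha on its methylated/unmethylated 2x2 table, for
decreasing alpha; an optional paired Wilcoxon signed-rank test across the
window's member-CpG fractions adds a cluster-level criterion.  Called
windows carry a composite confidence score
``sqrt(median(|delta| over DM CpGs) * n_dm_cpgs)``.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "filter_coverage",
    "coverage_ratio",
    "call_window_dm",
    "composite_confidence",
    "global_methylation_delta",
    "gain_loss_summary",
    "windows_from_positions",
]


def _validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "pos", "count_methylated", "count_total"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if (table["count_methylated"] > table["count_total"]).any():
        raise ValueError("methylated counts exceed totals")
    if (table["count_total"] < 0).any() or (table["count_methylated"] < 0).any():
        raise ValueError("negative read counts")
    if "fraction" not in table.columns:
        table = table.copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            table["fraction"] = table["count_methylated"] / table["count_total"]
    return table


def filter_coverage(table: pd.DataFrame, min_depth: int = 20) -> pd.DataFrame:
    """Drop CpGs with coverage below ``min_depth``; the 20x boundary is kept."""
    table = _validate_counts(table)
    kept = table[table["count_total"] >= min_depth].reset_index(drop=True)
    if kept.empty:
        raise ValueError(f"no CpGs survive the {min_depth}x coverage filter")
    log.info("filter_coverage: retained %d/%d CpGs (%.1f%%)",
             len(kept), len(table), 100.0 * len(kept) / len(table))
    return kept


def _merge_shared(case: pd.DataFrame, wt: pd.DataFrame) -> pd.DataFrame:
    case = _validate_counts(case)
    wt = _validate_counts(wt)
    merged = case.merge(wt, on=["chrom", "pos"], suffixes=("_case", "_wt"))
    if merged.empty:
        raise ValueError("no shared covered positions between case and wt")
    return merged


def coverage_ratio(
    case: pd.DataFrame,
    wt: pd.DataFrame,
    region: tuple[str, int, int],
    normalize: bool = True,
) -> dict:
    """Case/wt depth ratio track with region and flank summaries.

    Depths are normalized by each library's total read count (sum of
    ``count_total``), then the per-position ratio is reported along with the
    ratio of mean normalized depths inside ``region`` (chrom, start, end;
    0-based half-open) and over the flanking (outside-region) positions of
    the same chromosome.
    """
    merged = _merge_shared(case, wt)
    chrom, start, end = region
    lib_case = case["count_total"].sum() if normalize else 1.0
    lib_wt = wt["count_total"].sum() if normalize else 1.0
    norm_case = merged["count_total_case"] / lib_case
    norm_wt = merged["count_total_wt"] / lib_wt
    with np.errstate(divide="ignore", invalid="ignore"):
        track = norm_case / norm_wt
    in_region = (
        (merged["chrom"].astype(str) == str(chrom))
        & (merged["pos"] >= start)
        & (merged["pos"] < end)
    )
    on_chrom = merged["chrom"].astype(str) == str(chrom)
    if not in_region.any():
        raise ValueError("region contains no covered CpGs")
    region_mean = float(norm_case[in_region].mean() / norm_wt[in_region].mean())
    flank = on_chrom & ~in_region
    flank_mean = (
        float(norm_case[flank].mean() / norm_wt[flank].mean()) if flank.any() else np.nan
    )
    return {
        "track": pd.DataFrame(
            {"chrom": merged["chrom"], "pos": merged["pos"], "ratio": track}
        ),
        "region_mean": region_mean,
        "flank_mean": flank_mean,
    }


def windows_from_positions(
    positions: pd.DataFrame, window_size: int = 1000, half_open: bool = True
) -> pd.DataFrame:
    """Tile non-overlapping windows of ``window_size`` covering the given CpGs."""
    rows = []
    for chrom, sub in positions.groupby("chrom"):
        starts = np.unique((sub["pos"].to_numpy() // window_size) * window_size)
        for s in starts:
            rows.append((chrom, int(s), int(s) + window_size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


_fisher_cache: dict[tuple[int, int, int, int], float] = {}


def fisher_exact_two_sided(m_case: int, u_case: int, m_wt: int, u_wt: int) -> float:
    """Two-sided Fisher exact p for the (methylated, unmethylated) x (case, wt) table.

    Conditional on the margins, sums the hypergeometric probabilities of all
    tables no more likely than the observed one (the standard two-sided
    definition).  Results are memoized; read depths recur constantly across
    CpGs, so the cache hit rate is high.
    """
    key = (m_case, u_case, m_wt, u_wt)
    hit = _fisher_cache.get(key)
    if hit is not None:
        return hit
    n1 = m_case + u_case  # case depth
    m = m_case + m_wt  # methylated-read margin
    n = n1 + m_wt + u_wt
    lo, hi = max(0, m - (n - n1)), min(m, n1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, m, n1)
    p_obs = pmf[m_case - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)
    _fisher_cache[key] = p
    return p


_fisher_p = fisher_exact_two_sided


def _wilcoxon_p(frac_case: np.ndarray, frac_wt: np.ndarray) -> float:
    diffs = frac_case - frac_wt
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return 1.0
    method = "exact" if len(nz) <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            _, p = stats.wilcoxon(frac_case, frac_wt, zero_method="wilcox", method=method)
        except ValueError:
            return 1.0
    return float(p)


def call_window_dm(
    case: pd.DataFrame,
    wt: pd.DataFrame,
    windows: pd.DataFrame,
    delta_min: float = 0.15,
    min_dm_cpgs: int = 3,
    fisher_alpha: float | None = None,
    require_wilcoxon: bool = False,
) -> pd.DataFrame:
    """Evaluate every window for concordant differential methylation.

    Both tables should already be coverage-filtered.  ``windows`` has
    ``chrom``, ``start``, ``end`` (and optionally ``anchor``/``gene``
    columns, which are carried through).  Windows without covered CpGs are
    skipped with a log entry.  ``min_fisher_p`` (minimum two-sided Fisher
    exact p over the window's DM CpGs) is always computed when
    ``fisher_alpha`` is not None, so one pass supports a whole ladder of
    thresholds.
    """
    merged = _merge_shared(case, wt)
    merged["delta"] = merged["fraction_case"] - merged["fraction_wt"]
    by_chrom = {c: sub.sort_values("pos") for c, sub in merged.groupby("chrom")}

    carry = [c for c in ("anchor", "gene") if c in windows.columns]
    rows = []
    n_skipped = 0
    for win in windows.itertuples(index=False):
        chrom, start, end = str(win.chrom), int(win.start), int(win.end)
        sub = by_chrom.get(chrom)
        if sub is not None:
            pos = sub["pos"].to_numpy()
            lo, hi = np.searchsorted(pos, [start, end])
            members = sub.iloc[lo:hi]
        else:
            members = None
        if members is None or members.empty:
            n_skipped += 1
            continue
        deltas = members["delta"].to_numpy()
        dm_mask = np.abs(deltas) > delta_min
        n_dm = int(dm_mask.sum())
        dm_deltas = deltas[dm_mask]
        pos_n = int((dm_deltas > 0).sum())
        neg_n = int((dm_deltas < 0).sum())
        concordant = n_dm >= min_dm_cpgs and (pos_n == 0 or neg_n == 0)
        direction = "gain" if pos_n and not neg_n else "loss" if neg_n and not pos_n else "mixed"

        min_fisher = np.nan
        if fisher_alpha is not None and n_dm:
            dm_rows = members[dm_mask]
            ps = [
                _fisher_p(
                    int(r.count_methylated_case),
                    int(r.count_total_case - r.count_methylated_case),
                    int(r.count_methylated_wt),
                    int(r.count_total_wt - r.count_methylated_wt),
                )
                for r in dm_rows.itertuples(index=False)
            ]
            min_fisher = float(min(ps))
        wilcoxon_p = (
            _wilcoxon_p(members["fraction_case"].to_numpy(), members["fraction_wt"].to_numpy())
            if require_wilcoxon
            else np.nan
        )

        called = concordant
        if fisher_alpha is not None:
            called = called and (not np.isnan(min_fisher)) and min_fisher <= fisher_alpha
        if require_wilcoxon:
            called = called and wilcoxon_p < 0.05

        score = (
            math.sqrt(float(np.median(np.abs(dm_deltas))) * n_dm) if called else np.nan
        )
        row = {
            "chrom": chrom,
            "start": start,
            "end": end,
            "n_covered_cpgs": int(len(members)),
            "n_dm_cpgs": n_dm,
            "direction": direction if called else (direction if concordant else "mixed"),
            "called": bool(called),
            "min_fisher_p": min_fisher,
            "wilcoxon_p": wilcoxon_p,
            "composite_score": score,
            "median_abs_delta": float(np.median(np.abs(dm_deltas))) if n_dm else np.nan,
        }
        for c in carry:
            row[c] = getattr(win, c)
        rows.append(row)
    if n_skipped:
        log.info("call_window_dm: skipped %d windows with no covered CpGs", n_skipped)
    return pd.DataFrame(rows)


def composite_confidence(call: pd.Series | dict) -> float:
    """sqrt(median |delta| over DM CpGs x number of DM CpGs) for a called window."""
    called = bool(call["called"]) if "called" in call else True
    if not called:
        raise ValueError("composite confidence is defined only for called windows")
    return math.sqrt(float(call["median_abs_delta"]) * int(call["n_dm_cpgs"]))


def global_methylation_delta(
    case: pd.DataFrame, wt: pd.DataFrame, regions: pd.DataFrame | None = None
) -> dict:
    """Mean fraction difference (case - wt) over shared covered CpGs.

    With ``regions`` (BED-like), the delta is additionally stratified into
    inside-region and outside-region CpG sets.
    """
    merged = _merge_shared(case, wt)
    delta = merged["fraction_case"] - merged["fraction_wt"]
    out = {"delta_overall": float(delta.mean()), "n_cpgs": int(len(merged))}
    if regions is not None and len(regions):
        inside = np.zeros(len(merged), dtype=bool)
        for reg in regions.itertuples(index=False):
            inside |= (
                (merged["chrom"].astype(str) == str(reg.chrom))
                & (merged["pos"] >= int(reg.start))
                & (merged["pos"] < int(reg.end))
            ).to_numpy()
        out["delta_inside"] = float(delta[inside].mean()) if inside.any() else np.nan
        out["delta_outside"] = float(delta[~inside].mean()) if (~inside).any() else np.nan
    return out


def gain_loss_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of gain versus loss windows among called windows."""
    if calls.empty or not calls["called"].any():
        return pd.DataFrame(columns=["direction", "n_windows", "fraction"])
    called = calls[calls["called"]]
    counts = called["direction"].value_counts()
    out = pd.DataFrame(
        {
            "direction": counts.index,
            "n_windows": counts.to_numpy(),
            "fraction": (counts / counts.sum()).to_numpy(),
        }
    )
    return out.reset_index(drop=True)
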