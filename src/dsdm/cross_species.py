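"""Human-array to mouse-window mapping and concordance enrichment.

A mapping table (one row per human array probe with a lifted-over mouse
coordinate and a shared orthologous gene symbol) is materialized into 1-kb
mouse windows centered on each mapped position.  Mouse windows called DM by
the WGBS caller roll up to genes (direction from the highest-composite-score
window when windows disagree), and the overlap of mouse DM genes with human
DM genes — counting only genes whose methylation moves in the same
direction in both species — is tested for enrichment with the shared
hypergeometric implementation, at each level of the Fisher stringency
ladder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import hypergeom_enrichment
from .wgbs import call_window_dm

log = logging.getLogger(__name__)

__all__ = [
    "build_windows",
    "gene_directions_from_calls",
    "concordant_overlap",
    "stringency_ladder",
    "ConcordanceResult",
    "DEFAULT_ALPHA_LADDER",
]

DEFAULT_ALPHA_LADDER = (0.05, 0.01, 0.005, 0.001)
WINDOW_HALFWIDTH = 500


@dataclass
class ConcordanceResult:
    stringency_level: float | None
    n_mouse_dm_genes: int
    n_human_dm_genes: int
    n_overlap_concordant: int
    universe_size: int
    fold: float
    p_hypergeom: float

    def as_dict(self) -> dict:
        return vars(self).copy()


def build_windows(map_table: pd.DataFrame) -> pd.DataFrame:
    """Materialize 1-kb mouse windows around each mapped probe position.

    Expects columns ``human_probe``, ``mouse_chrom``, ``mouse_pos`` and
    optionally ``gene``.  Malformed rows (non-numeric or negative
    positions) are rejected with a log entry; duplicate windows (same
    coordinates) are collapsed to one row.
    """
    table = map_table.copy()
    pos = pd.to_numeric(table["mouse_pos"], errors="coerce")
    bad = pos.isna() | (pos < 0)
    if bad.any():
        log.warning("build_windows: rejected %d malformed mapping rows", int(bad.sum()))
        table = table[~bad]
        pos = pos[~bad]
    table = table.assign(
        start=(pos.astype(int) - WINDOW_HALFWIDTH).clip(lower=0),
        end=pos.astype(int) + WINDOW_HALFWIDTH,
    )
    table = table.rename(columns={"mouse_chrom": "chrom"})
    cols = ["chrom", "start", "end", "human_probe"] + (
        ["gene"] if "gene" in table.columns else []
    )
    out = table[cols].drop_duplicates(subset=["chrom", "start", "end"]).reset_index(drop=True)
    return out.rename(columns={"human_probe": "anchor"})


def gene_directions_from_calls(calls: pd.DataFrame) -> dict[str, int]:
    """Per-gene direction (+1 gain / -1 loss) from called windows.

    When a gene has both gain and loss windows, the direction of its
    highest-composite-score window wins.
    """
    if calls.empty or "gene" not in calls.columns:
        return {}
    called = calls[calls["called"]].copy()
    if called.empty:
        return {}
    called["dir_sign"] = np.where(called["direction"] == "gain", 1, -1)
    called = called.sort_values("composite_score", ascending=False)
    best = called.drop_duplicates(subset=["gene"], keep="first")
    return dict(zip(best["gene"], best["dir_sign"].astype(int)))


def concordant_overlap(
    human_dm_genes: dict[str, int],
    mouse_dm_genes: dict[str, int],
    universe,
    stringency_level: float | None = None,
    require_direction: bool = True,
) -> ConcordanceResult:
    """Direction-matched gene overlap with upper-tail hypergeometric enrichment.

    Both inputs map gene -> direction sign (+1 hyper/gain, -1 hypo/loss).
    The universe is the set of genes evaluable on both sides (mappable,
    coverage-surviving); genes outside it are ignored.  With
    ``require_direction=False`` the overlap counts shared membership
    regardless of direction — the mode in which the hypergeometric
    expectation is exactly calibrated (fold ~ 1 for independent sets);
    direction matching halves the null overlap when directions are
    symmetric, so the default mode is conservative under the null.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    human = {g: d for g, d in human_dm_genes.items() if g in universe}
    mouse = {g: d for g, d in mouse_dm_genes.items() if g in universe}
    shared = human.keys() & mouse.keys()
    if require_direction:
        overlap = {g for g in shared if np.sign(human[g]) == np.sign(mouse[g])}
    else:
        overlap = set(shared)
    k, n, K, N = len(overlap), len(mouse), len(human), len(universe)
    if n == 0 or K == 0:
        return ConcordanceResult(stringency_level, n, K, k, N, np.nan, 1.0)
    enr = hypergeom_enrichment(k, n, K, N, feature="human_dm_orthologs")
    return ConcordanceResult(
        stringency_level=stringency_level,
        n_mouse_dm_genes=n,
        n_human_dm_genes=K,
        n_overlap_concordant=k,
        universe_size=N,
        fold=enr.fold,
        p_hypergeom=enr.p_value,
    )


def stringency_ladder(
    human_dm_genes: dict[str, int],
    case: pd.DataFrame,
    wt: pd.DataFrame,
    windows: pd.DataFrame,
    universe,
    alphas=DEFAULT_ALPHA_LADDER,
    delta_min: float = 0.15,
    min_dm_cpgs: int = 3,
) -> list[ConcordanceResult]:
    """Concordance enrichment at each Fisher stringency level.

    The window caller runs once with Fisher p-values recorded; each ladder
    level then re-thresholds ``min_fisher_p``, so mouse call sets (and the
    derived gene sets) are nested and counts are monotone non-increasing
    with stringency.
    """
    base = call_window_dm(
        case, wt, windows, delta_min=delta_min, min_dm_cpgs=min_dm_cpgs, fisher_alpha=1.0
    )
    results = []
    for alpha in alphas:
        level = base.copy()
        level["called"] = level["called"] & (level["min_fisher_p"] <= alpha)
        mouse_genes = gene_directions_from_calls(level)
        results.append(
            concordant_overlap(human_dm_genes, mouse_genes, universe, stringency_level=alpha)
        )
    return results
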