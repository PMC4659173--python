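"""Enrichment statistics: hypergeometric tests, genomic-context annotation,
chromatin-state classification, known-motif window enrichment by logistic
regression, and expression-pattern classes.

All interval inputs are BED-style DataFrames with ``chrom``, ``start``,
``end`` columns, 0-based half-open.  The hypergeometric test is upper-tail
(P[X >= k]) and is the single shared implementation used by every module
that reports a set-overlap p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
import statsmodels.api as sm

from .dm import benjamini_hochberg

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrichment",
    "annotate_genomic_context",
    "classify_chromatin_state",
    "motif_window_enrichment",
    "classify_expression_pattern",
    "stage_expression_enrichment",
]


@dataclass
class EnrichmentResult:
    """2x2 set-overlap enrichment: k of n in the target set, K of N in background."""

    feature: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    odds_ratio: float
    p_value: float

    def as_dict(self) -> dict:
        return vars(self).copy()


def hypergeom_enrichment(k: int, n: int, K: int, N: int, feature: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of k/n versus K/N.

    ``k`` successes in a draw of ``n`` from a population of ``N`` containing
    ``K`` successes.  p = P[X >= k]; fold = (k/n)/(K/N); the odds ratio is
    from the 2x2 table (k, n-k; K-k, N-K-n+k).
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N and N - K - n + k >= 0):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if n and K else np.nan
    a, b, c, d = k, n - k, K - k, N - K - n + k
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return EnrichmentResult(feature=feature, k=k, n=n, K=K, N=N, fold=fold,
                            odds_ratio=float(odds), p_value=p)


def _trees(bed: pd.DataFrame | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if bed is None or len(bed) == 0:
        return trees
    for chrom, sub in bed.groupby("chrom"):
        tree = IntervalTree()
        for s, e in zip(sub["start"], sub["end"]):
            if e > s:
                tree.addi(int(s), int(e))
        trees[str(chrom)] = tree
    return trees


def annotate_genomic_context(
    positions: pd.DataFrame,
    cgi_bed: pd.DataFrame,
    gene_bed: pd.DataFrame,
    tss_bed: pd.DataFrame,
    promoter_halfwidth: int = 1000,
    shore_width: int = 2000,
) -> pd.DataFrame:
    """Label CpGs island/shore/open_sea and flag gene-body/promoter membership.

    ``positions`` needs ``chrom`` and ``pos`` columns.  A CpG is a shore CpG
    when it is within ``shore_width`` bp of a CGI edge but not inside one;
    promoters span TSS +/- ``promoter_halfwidth``.  CpGs on chromosomes
    absent from every annotation are labeled ``unmapped`` with a warning.
    """
    cgi_trees = _trees(cgi_bed)
    shore_bed = None
    if cgi_bed is not None and len(cgi_bed):
        shore_bed = cgi_bed.assign(
            start=(cgi_bed["start"] - shore_width).clip(lower=0),
            end=cgi_bed["end"] + shore_width,
        )
    shore_trees = _trees(shore_bed)
    gene_trees = _trees(gene_bed)
    tss = tss_bed
    if tss is not None and len(tss):
        centers = (tss["start"] + tss["end"]) // 2
        tss = tss.assign(
            start=(centers - promoter_halfwidth).clip(lower=0),
            end=centers + promoter_halfwidth,
        )
    promoter_trees = _trees(tss)

    known_chroms = set(cgi_trees) | set(gene_trees) | set(promoter_trees)
    labels, in_gene, in_prom = [], [], []
    n_unmapped = 0
    for chrom, pos in zip(positions["chrom"].astype(str), positions["pos"].astype(int)):
        if chrom not in known_chroms:
            labels.append("unmapped")
            in_gene.append(False)
            in_prom.append(False)
            n_unmapped += 1
            continue
        if chrom in cgi_trees and cgi_trees[chrom].overlaps_point(pos):
            labels.append("island")
        elif chrom in shore_trees and shore_trees[chrom].overlaps_point(pos):
            labels.append("shore")
        else:
            labels.append("open_sea")
        in_gene.append(chrom in gene_trees and gene_trees[chrom].overlaps_point(pos))
        in_prom.append(chrom in promoter_trees and promoter_trees[chrom].overlaps_point(pos))
    if n_unmapped:
        warnings.warn(f"{n_unmapped} CpGs on chromosomes absent from the annotation (unmapped)")
    return pd.DataFrame(
        {
            "chrom": positions["chrom"].to_numpy(),
            "pos": positions["pos"].to_numpy(),
            "cgi_relation": labels,
            "in_gene_body": in_gene,
            "in_promoter": in_prom,
        },
        index=positions.index,
    )


def classify_chromatin_state(
    k4me3: bool, k4me1: bool, k27me3: bool, k27ac: bool
) -> str:
    """Map histone-mark peak overlaps to a regulatory state.

    Precedence: H3K4me3 with H3K27me3 -> poised (bivalent) promoter;
    H3K4me3 -> active promoter; H3K4me1 with H3K27ac -> active enhancer;
    H3K4me1 with H3K27me3 -> poised enhancer; H3K4me1 alone -> intermediate
    enhancer; otherwise none.  Total on all 16 flag combinations.
    """
    if k4me3 and k27me3:
        return "poised_promoter"
    if k4me3:
        return "active_promoter"
    if k4me1 and k27ac:
        return "active_enhancer"
    if k4me1 and k27me3:
        return "poised_enhancer"
    if k4me1:
        return "intermediate_enhancer"
    return "none"


def _window_presence(
    positions: pd.DataFrame, motif_bed: pd.DataFrame, window: int
) -> np.ndarray:
    trees = _trees(motif_bed)
    half = window // 2
    out = np.zeros(len(positions), dtype=bool)
    for i, (chrom, pos) in enumerate(
        zip(positions["chrom"].astype(str), positions["pos"].astype(int))
    ):
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(pos - half, pos + half):
            out[i] = True
    return out


def motif_window_enrichment(
    dm_positions: pd.DataFrame,
    background_positions: pd.DataFrame,
    motif_beds: dict[str, pd.DataFrame],
    window: int = 200,
) -> pd.DataFrame:
    """Logistic-regression enrichment of motif presence near DM CpGs.

    For each motif, presence is >= 1 bp overlap of a motif interval with the
    half-open window [pos - window/2, pos + window/2) around each CpG.  The
    model is DM-membership ~ presence; the odds ratio is exp(coefficient).
    Motifs present in none or all windows are inestimable and flagged.
    BH q-values are computed over all estimable motifs.
    """
    pos_all = pd.concat([dm_positions, background_positions], ignore_index=True)
    y = np.r_[np.ones(len(dm_positions)), np.zeros(len(background_positions))]
    rows = []
    for name, bed in motif_beds.items():
        x = _window_presence(pos_all, bed, window).astype(float)
        if x.sum() == 0 or x.sum() == len(x):
            rows.append(
                {"feature": name, "odds_ratio": np.nan, "coef": np.nan,
                 "p_value": np.nan, "estimable": False,
                 "n_dm_with_motif": int(x[y == 1].sum()),
                 "n_bg_with_motif": int(x[y == 0].sum())}
            )
            continue
        X = sm.add_constant(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0)
            coef = float(fit.params[1])
            pval = float(fit.pvalues[1])
            estimable = np.isfinite(coef)
        except Exception:  # perfect separation and friends
            coef, pval, estimable = np.nan, np.nan, False
        rows.append(
            {"feature": name, "odds_ratio": float(np.exp(coef)) if estimable else np.nan,
             "coef": coef, "p_value": pval, "estimable": estimable,
             "n_dm_with_motif": int(x[y == 1].sum()),
             "n_bg_with_motif": int(x[y == 0].sum())}
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


EXPRESSION_CLASSES = (
    "brain_specific_expression",
    "brain_specific_repression",
    "other_tissue_specific",
    "multi_tissue",
)


def classify_expression_pattern(
    z_scores: pd.DataFrame, brain_tissue_label: str, z_cutoff: float = 0.5
) -> pd.Series:
    """Classify genes by tissue expression pattern from per-tissue Z-scores.

    Rules, first match wins per gene:

    i.   brain-specific expression — Z_brain >= 0.5 and fewer than two
         additional tissues with Z >= 0.5;
    ii.  brain-specific repression — Z_brain <= -0.5 and fewer than two
         additional tissues with Z <= -0.5;
    iii. other-tissue-specific — |Z| >= 0.5 somewhere but not in brain, in
         fewer than three tissues;
    iv.  multi-tissue/pan — everything else (|Z| >= 0.5 in three or more
         tissues, or no tissue-restricted signal).
    """
    if brain_tissue_label not in z_scores.columns:
        raise ValueError(f"brain tissue column {brain_tissue_label!r} missing")
    if z_scores.shape[1] < 3:
        raise ValueError("need at least three tissues")
    zb = z_scores[brain_tissue_label]
    others = z_scores.drop(columns=[brain_tissue_label])
    n_hi_other = (others >= z_cutoff).sum(axis=1)
    n_lo_other = (others <= -z_cutoff).sum(axis=1)
    n_any = ((z_scores >= z_cutoff) | (z_scores <= -z_cutoff)).sum(axis=1)

    out = pd.Series("multi_tissue", index=z_scores.index, dtype=object)
    rule3 = (n_any > 0) & (n_any < 3) & (zb.abs() < z_cutoff)
    out[rule3] = "other_tissue_specific"
    rule2 = (zb <= -z_cutoff) & (n_lo_other < 2)
    out[rule2] = "brain_specific_repression"
    rule1 = (zb >= z_cutoff) & (n_hi_other < 2)
    out[rule1] = "brain_specific_expression"
    return out


def stage_expression_enrichment(
    dm_genes, fetal_higher, adult_higher, similar, universe=None
) -> EnrichmentResult:
    """Hypergeometric enrichment of DM genes in the fetal-higher expression class.

    The universe defaults to the union of the three expression classes
    (genes with expression data); DM genes outside the universe are dropped,
    mirroring the requirement that tested genes have both expression and
    methylation data.
    """
    fetal_higher, adult_higher, similar = set(fetal_higher), set(adult_higher), set(similar)
    universe = set(universe) if universe is not None else fetal_higher | adult_higher | similar
    if not universe:
        raise ValueError("empty gene universe")
    dm = set(dm_genes) & universe
    k = len(dm & fetal_higher)
    return hypergeom_enrichment(
        k, len(dm), len(fetal_higher & universe), len(universe), feature="fetal_higher"
    )
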