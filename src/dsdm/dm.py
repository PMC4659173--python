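"""Supervised differential-methylation (DM) calling on array beta matrices.

A CpG is called DM between case and control groups when it passes both a
magnitude criterion (|mean-beta difference| >= ``delta_min``, default 0.15)
and an unadjusted two-sided Student's t-test criterion (p <= ``p_max``,
default 0.001).  Benjamini-Hochberg q-values are reported over all tested
CpGs so the effective FDR of the fixed p cutoff can be read off per
analysis.  A multivariate model beta ~ status + sex provides sex-adjusted
status p-values for the passing CpGs, and passing CpGs aggregate to genes
through the probe annotation (a probe annotated to several genes counts
toward each).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .arrays import BetaMatrix, normalize_annotation, validate_sample_sheet

log = logging.getLogger(__name__)

__all__ = [
    "call_dm_cpgs",
    "adjust_for_sex",
    "benjamini_hochberg",
    "aggregate_to_genes",
    "intersect_dm_sets",
    "DmGeneSet",
]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate to NaN q."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def call_dm_cpgs(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    delta_min: float = 0.15,
    p_max: float = 0.001,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-CpG two-group test; returns one row per probe with a ``passes`` flag.

    Columns: mean_case, mean_control, delta (case - control), t_statistic,
    p_value, q_value (BH over tested probes), direction (hyper/hypo),
    passes, reason.  CpGs with zero variance in both groups are untestable
    and recorded as non-passing with reason ``zero_variance``.
    """
    sheet = validate_sample_sheet(beta, sheet)
    is_case = (sheet["status"] == "case").to_numpy()
    is_ctrl = (sheet["status"] == "control").to_numpy()
    if is_case.sum() < 2 or is_ctrl.sum() < 2:
        raise ValueError("need at least two samples per group")
    vals = beta.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("beta matrix contains missing values; filter or impute first")
    case = vals[:, is_case]
    ctrl = vals[:, is_ctrl]

    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    delta = mean_case - mean_ctrl
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    untestable = np.isnan(p)
    q = benjamini_hochberg(p)
    passes = (~untestable) & (np.abs(delta) >= delta_min) & (p <= p_max)
    reason = np.where(untestable, "zero_variance", "")

    calls = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "delta": delta,
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "direction": np.where(delta > 0, "hyper", "hypo"),
            "passes": passes,
            "reason": reason,
        },
        index=beta.probe_ids,
    )
    log.info("call_dm_cpgs: %d/%d probes pass (delta>=%.3g, p<=%.3g)",
             int(passes.sum()), len(calls), delta_min, p_max)
    return calls


def adjust_for_sex(beta: BetaMatrix, sheet: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Fill ``sex_adjusted_p`` for passing CpGs from the model beta ~ status + sex.

    The reported value is the p-value of the status coefficient.  If sex is
    constant across samples the unadjusted p is copied with a warning.
    """
    sheet = validate_sample_sheet(beta, sheet)
    calls = calls.copy()
    calls["sex_adjusted_p"] = np.nan
    passing = calls.index[calls["passes"]]
    if len(passing) == 0:
        return calls

    if sheet["sex"].nunique() < 2:
        warnings.warn("sex is constant across samples; sex-adjusted p equals unadjusted p")
        calls.loc[passing, "sex_adjusted_p"] = calls.loc[passing, "p_value"]
        return calls

    status = (sheet["status"] == "case").to_numpy(float)
    sex = (sheet["sex"].astype(str) == "M").to_numpy(float)
    X = np.column_stack([np.ones_like(status), status, sex])
    n, k = X.shape
    Y = beta.values.loc[passing].to_numpy(dtype=float).T  # samples x probes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_status = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_status = coef[1] / se_status
    p_status = 2 * stats.t.sf(np.abs(t_status), dof)
    calls.loc[passing, "sex_adjusted_p"] = p_status
    return calls


@dataclass
class DmGeneSet:
    gene_id: str
    n_dm_cpgs: int
    directions: frozenset


def aggregate_to_genes(calls: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Aggregate passing CpGs to genes via the (possibly multi-gene) annotation.

    Returns one row per gene with ``n_dm_cpgs`` and the set of directions
    observed; the ``attrs`` dict carries the total passing-CpG count,
    including intergenic CpGs that map to no gene.
    """
    annot = normalize_annotation(annot)
    passing = calls[calls["passes"]]
    rows: list[tuple[str, str, str]] = []
    for probe, row in passing.iterrows():
        genes = annot["gene_ids"].get(probe, "")
        genes = "" if pd.isna(genes) else str(genes)
        for gene in filter(None, genes.split(";")):
            rows.append((gene, probe, row["direction"]))
    if not rows:
        out = pd.DataFrame(columns=["gene_id", "n_dm_cpgs", "directions"]).set_index("gene_id")
        out.attrs["n_passing_cpgs"] = int(len(passing))
        return out
    df = pd.DataFrame(rows, columns=["gene_id", "probe_id", "direction"])
    out = df.groupby("gene_id").agg(
        n_dm_cpgs=("probe_id", "nunique"),
        directions=("direction", lambda s: frozenset(s)),
    )
    out.attrs["n_passing_cpgs"] = int(len(passing))
    return out


def intersect_dm_sets(named_sets: dict, direction_aware: bool = False) -> dict:
    """Full Venn partition of >= 2 named DM sets.

    ``named_sets`` maps a set name either to an iterable of ids or, when
    ``direction_aware`` is true, to a mapping id -> direction; with
    direction awareness an id shared between two sets with opposite
    directions is *not* shared.  Returns a dict keyed by a tuple of the
    member set names (sorted) with the ids falling exactly in that region.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two sets to intersect")
    elements: dict = {}
    for name, s in named_sets.items():
        if direction_aware:
            if not hasattr(s, "items"):
                raise ValueError("direction-aware intersection needs id -> direction mappings")
            keys = {(k, v) for k, v in s.items()}
        else:
            keys = set(s)
        elements[name] = keys
    universe = set().union(*elements.values())
    partition: dict = {}
    for item in universe:
        members = tuple(sorted(n for n, s in elements.items() if item in s))
        partition.setdefault(members, set()).add(item[0] if direction_aware else item)
    return partition
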