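"""5mC/5hmC decomposition from paired bisulfite / oxidative-bisulfite data.

Standard bisulfite conversion (BS) reads 5mC + 5hmC jointly; oxidative
bisulfite (OXBS) reads 5mC alone.  The hydroxymethyl component is therefore
estimated by subtraction, 5hmC = BS - OXBS, clamped at zero (small negative
raw values arise from assay noise and are retained for QC).  Differential
methylation can then be classified by which mark carries the case/control
difference: 5mC only, 5hmC only, or both additively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import warnings

from .arrays import BetaMatrix, validate_sample_sheet

__all__ = ["OxDecomposition", "decompose", "classify_modality", "direction_concordance"]


@dataclass
class OxDecomposition:
    """Per-CpG 5mC and 5hmC matrices; ``hmc_raw`` keeps pre-clamp negatives."""

    mc: pd.DataFrame
    hmc: pd.DataFrame
    hmc_raw: pd.DataFrame


def decompose(beta_bs: BetaMatrix, beta_oxbs: BetaMatrix) -> OxDecomposition:
    """5mC = OXBS beta; 5hmC = clamp(BS - OXBS, 0, 1), raw difference retained."""
    if not beta_bs.probe_ids.equals(beta_oxbs.probe_ids) or not beta_bs.sample_ids.equals(
        beta_oxbs.sample_ids
    ):
        raise ValueError("BS and OXBS matrices must share probes and samples, aligned")
    raw = beta_bs.values - beta_oxbs.values
    return OxDecomposition(mc=beta_oxbs.values.copy(), hmc=raw.clip(0.0, 1.0), hmc_raw=raw)


def _component_test(values: pd.DataFrame, is_case: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    case = values.to_numpy(float)[:, is_case]
    ctrl = values.to_numpy(float)[:, ~is_case]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
    delta = case.mean(axis=1) - ctrl.mean(axis=1)
    return delta, np.asarray(p, float)


def classify_modality(
    decomp: OxDecomposition,
    sheet: pd.DataFrame,
    p_max: float = 0.05,
    delta_min: float = 0.15,
) -> pd.DataFrame:
    """Classify each CpG's DM modality from separate t-tests on 5mC and 5hmC.

    A component "passes" when its uncorrected p < ``p_max`` and its
    |case - control| difference > ``delta_min``.  Classes: ``mc_only``,
    ``hmc_only``, ``additive`` (both pass), ``none``.  Zero-variance
    components are untestable and flagged.
    """
    bm = BetaMatrix(decomp.mc.clip(0, 1))
    sheet = validate_sample_sheet(bm, sheet)
    is_case = (sheet["status"] == "case").to_numpy()
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need at least two samples per group")

    d_mc, p_mc = _component_test(decomp.mc, is_case)
    d_hmc, p_hmc = _component_test(decomp.hmc, is_case)

    pass_mc = (p_mc < p_max) & (np.abs(d_mc) > delta_min)
    pass_hmc = (p_hmc < p_max) & (np.abs(d_hmc) > delta_min)
    pass_mc &= ~np.isnan(p_mc)
    pass_hmc &= ~np.isnan(p_hmc)

    cls = np.where(
        pass_mc & pass_hmc,
        "additive",
        np.where(pass_mc, "mc_only", np.where(pass_hmc, "hmc_only", "none")),
    )
    return pd.DataFrame(
        {
            "delta_5mc": d_mc,
            "delta_5hmc": d_hmc,
            "delta_net": d_mc + d_hmc,
            "p_5mc": p_mc,
            "p_5hmc": p_hmc,
            "class": cls,
            "untestable_5mc": np.isnan(p_mc),
            "untestable_5hmc": np.isnan(p_hmc),
        },
        index=decomp.mc.index,
    )


def direction_concordance(modality: pd.DataFrame, screen_delta: float = 0.05) -> dict:
    """Fraction of CpGs where the 5mC and 5hmC differences share a sign.

    Eligibility uses a loose screen: both component |deltas| must exceed
    ``screen_delta``.  Raises on an empty eligible set.
    """
    eligible = modality[
        (modality["delta_5mc"].abs() > screen_delta)
        & (modality["delta_5hmc"].abs() > screen_delta)
    ]
    if eligible.empty:
        raise ValueError("no CpGs pass the concordance screen")
    concordant = np.sign(eligible["delta_5mc"]) == np.sign(eligible["delta_5hmc"])
    return {
        "fraction_concordant": float(concordant.mean()),
        "n_concordant": int(concordant.sum()),
        "n_eligible": int(len(eligible)),
    }
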