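"""Age-dependence and disease x age interaction models for methylation.

Two screening profiles are supported, matching the different sensitivity of
fetal versus adult tissue:

* ``fetal`` — a CpG is age-dependent when |slope| > 0.1 beta units per 10
  age units (gestational weeks), R^2 >= 0.8 and the age p-value < 0.05;
  the differential-maturation flag additionally requires an interaction
  p < 0.05 and |interaction slope| > 0.1 per 10 units.
* ``adult`` — methylation drift is subtler, so the magnitude criterion is
  dropped: age p < 0.05 and adjusted R^2 > 0.8 (and interaction p < 0.05
  for differential aging).

All slopes are reported per 10 age units.  "R squared" is read as the
adjusted R^2 by default (``use_adjusted_r2``) in both profiles; the plain
R^2 is available by flag.  Thresholds are strict inequalities except the
fetal R^2 bound, which is >=.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arrays import BetaMatrix, validate_sample_sheet
from .enrichment import hypergeom_enrichment

__all__ = [
    "AgeFit",
    "InteractionFit",
    "fit_age_univariate",
    "scan_age_dependence",
    "fit_interaction",
    "summarize_trajectory",
    "overlap_dm_with_age",
]

PROFILES = ("fetal", "adult")


def _check_profile(profile: str) -> None:
    if profile not in PROFILES:
        raise ValueError(f"profile must be one of {PROFILES}")


@dataclass
class AgeFit:
    slope_per10: float
    intercept: float
    p_age: float
    r2: float
    adj_r2: float
    flagged_age_dependent: bool


@dataclass
class InteractionFit:
    baseline_status_effect: float
    age_effect_control: float  # per 10 units
    age_effect_case: float  # per 10 units; equals control + interaction by algebra
    interaction: float  # per 10 units
    p_interaction: float
    p_age_adj: float
    p_status: float
    adj_r2: float
    flagged_differential_aging: bool


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Coefficients, their p-values, R^2 and adjusted R^2 for one response."""
    n, k = X.shape
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    dof = n - k
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    sigma2 = rss / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
    return coef, pvals, r2, adj_r2


def fit_age_univariate(
    y,
    ages,
    profile: str = "fetal",
    slope_min_per10: float = 0.1,
    r2_min: float = 0.8,
    p_max: float = 0.05,
    use_adjusted_r2: bool = True,
) -> AgeFit:
    """OLS of one CpG's beta on age, with the profile's age-dependence flag."""
    _check_profile(profile)
    y = np.asarray(y, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(np.unique(ages)) < 2:
        raise ValueError("ages are constant; age effect inestimable")
    if len(y) < 4:
        raise ValueError("need at least four samples for the age fit")
    X = np.column_stack([np.ones_like(ages), ages])
    coef, pvals, r2, adj_r2 = _ols(X, y)
    slope10 = coef[1] * 10.0
    r2_used = adj_r2 if use_adjusted_r2 else r2
    if profile == "fetal":
        flag = (abs(slope10) > slope_min_per10) and (r2_used >= r2_min) and (pvals[1] < p_max)
    else:
        flag = (pvals[1] < p_max) and (r2_used > r2_min)
    return AgeFit(
        slope_per10=float(slope10),
        intercept=float(coef[0]),
        p_age=float(pvals[1]),
        r2=float(r2),
        adj_r2=float(adj_r2),
        flagged_age_dependent=bool(flag),
    )


def scan_age_dependence(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    profile: str = "fetal",
    status: str = "control",
    **kwargs,
) -> pd.DataFrame:
    """Apply :func:`fit_age_univariate` to every probe (within one status group)."""
    sheet = validate_sample_sheet(beta, sheet)
    mask = (sheet["status"] == status).to_numpy()
    ages = sheet.loc[mask, "age"].to_numpy(float)
    vals = beta.values.to_numpy(float)[:, mask]
    rows = [fit_age_univariate(v, ages, profile=profile, **kwargs) for v in vals]
    return pd.DataFrame([vars(r) for r in rows], index=beta.probe_ids)


def fit_interaction(
    y,
    ages,
    status,
    profile: str = "fetal",
    slope_min_per10: float = 0.1,
    r2_min: float = 0.8,
    p_max: float = 0.05,
    use_adjusted_r2: bool = True,
) -> InteractionFit:
    """OLS of beta ~ status + age + status:age with the differential-aging flag.

    The status coefficient is the baseline (age-centered) case/control
    difference; the interaction coefficient is exactly the case-minus-control
    slope difference.
    """
    _check_profile(profile)
    y = np.asarray(y, dtype=float)
    ages = np.asarray(ages, dtype=float)
    status = np.asarray(status)
    is_case = (
        status.astype(bool)
        if status.dtype != object and status.dtype.kind != "U"
        else (status == "case")
    ).astype(float)
    X = np.column_stack([np.ones_like(ages), is_case, ages, is_case * ages])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("status perfectly collinear with age; interaction inestimable")
    coef, pvals, r2, adj_r2 = _ols(X, y)
    slope_ctrl = coef[2] * 10.0
    inter = coef[3] * 10.0
    r2_used = adj_r2 if use_adjusted_r2 else r2
    flag = (r2_used > r2_min) and (pvals[2] < p_max) and (pvals[3] < p_max)
    if profile == "fetal":
        flag = flag and (abs(inter) > slope_min_per10)
    return InteractionFit(
        baseline_status_effect=float(coef[1]),
        age_effect_control=float(slope_ctrl),
        age_effect_case=float(slope_ctrl + inter),
        interaction=float(inter),
        p_interaction=float(pvals[3]),
        p_age_adj=float(pvals[2]),
        p_status=float(pvals[1]),
        adj_r2=float(adj_r2),
        flagged_differential_aging=bool(flag),
    )


def summarize_trajectory(beta: BetaMatrix, sheet: pd.DataFrame, panel=None) -> pd.DataFrame:
    """Per-group OLS line of the panel-mean methylation versus age.

    The panel mean is computed per sample first (averaging fractional
    methylation across the panel CpGs), then a straight line is fitted per
    status group.  Returns one row per group with intercept, slope and
    slope per 10 age units.
    """
    sheet = validate_sample_sheet(beta, sheet)
    values = beta.values if panel is None else beta.values.loc[panel]
    if values.empty:
        raise ValueError("empty CpG panel")
    panel_mean = values.mean(axis=0)
    rows = {}
    for group, sub in sheet.groupby("status"):
        ages = sub["age"].to_numpy(float)
        y = panel_mean[sub.index].to_numpy(float)
        X = np.column_stack([np.ones_like(ages), ages])
        coef, pvals, r2, adj_r2 = _ols(X, y)
        rows[group] = {
            "intercept": float(coef[0]),
            "slope": float(coef[1]),
            "slope_per10": float(coef[1] * 10.0),
            "p_age": float(pvals[1]),
            "adj_r2": float(adj_r2),
            "n": int(len(y)),
        }
    return pd.DataFrame(rows).T


def overlap_dm_with_age(dm_cpg_set, age_dependent_set, universe_size: int) -> dict:
    """Overlap count/fraction of DM CpGs with age-dependent CpGs, plus hypergeometric p."""
    dm = set(dm_cpg_set)
    age = set(age_dependent_set)
    k = len(dm & age)
    result = {
        "n_overlap": k,
        "fraction_of_dm": (k / len(dm)) if dm else 0.0,
        "expected": (len(dm) * len(age) / universe_size) if universe_size else np.nan,
    }
    if dm and age and universe_size:
        enr = hypergeom_enrichment(k, len(dm), len(age), universe_size)
        result["p_hypergeom"] = enr.p_value
        result["fold"] = enr.fold
    return result
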