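"""Array-style beta-matrix containers, probe QC filtering, and batch adjustment.

The central object is :class:`BetaMatrix`: a probes x samples table of
fractional methylation (beta) values in [0, 1], optionally paired with a
detection p-value matrix of identical shape.  Probe metadata travels in a
plain :class:`pandas.DataFrame` indexed by probe id (see
:func:`normalize_annotation`), and per-sample covariates in a sample sheet
DataFrame indexed by sample id with columns ``status`` (case/control),
``sex``, ``age``, ``batch`` and optionally ``tissue``.

Three operations live here:

* :func:`filter_probes` — the standard probe-level QC ladder for methylation
  arrays: drop sex-chromosome probes, probes overlapping common SNPs, and
  probes whose detection p-value fails in more than a tolerated number of
  samples of any status subgroup.
* :func:`adjust_batch` — parametric empirical-Bayes (ComBat-style)
  location/scale batch adjustment with disease status protected as a model
  covariate.
* :func:`summarize_global_methylation` — per-group mean beta and a two-group
  t-test on the per-sample means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})

__all__ = [
    "BetaMatrix",
    "SEX_CHROMOSOMES",
    "normalize_annotation",
    "validate_sample_sheet",
    "filter_probes",
    "adjust_batch",
    "summarize_global_methylation",
    "GlobalMethylationSummary",
]


@dataclass
class BetaMatrix:
    """Probes x samples fractional-methylation matrix with optional detection p-values."""

    values: pd.DataFrame
    detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("beta values must lie in [0, 1]")
        if self.detection is not None:
            if self.detection.shape != self.values.shape:
                raise ValueError("detection p-value matrix must match beta matrix shape")
            if not self.detection.index.equals(self.values.index) or not (
                self.detection.columns.equals(self.values.columns)
            ):
                raise ValueError("detection matrix must be aligned (same probes and samples)")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes) -> "BetaMatrix":
        det = self.detection.loc[probes] if self.detection is not None else None
        return BetaMatrix(self.values.loc[probes], det)

    def copy(self) -> "BetaMatrix":
        det = self.detection.copy() if self.detection is not None else None
        return BetaMatrix(self.values.copy(), det)


def normalize_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Return the probe annotation indexed by probe id.

    Accepts either a frame already indexed by probe id or one carrying a
    ``probe_id`` column.
    """
    if "probe_id" in annot.columns:
        annot = annot.set_index("probe_id")
    return annot


def validate_sample_sheet(beta: BetaMatrix, sheet: pd.DataFrame) -> pd.DataFrame:
    """Check that every beta-matrix sample appears exactly once in the sheet."""
    if "sample_id" in sheet.columns:
        sheet = sheet.set_index("sample_id")
    if sheet.index.has_duplicates:
        raise ValueError("sample sheet contains duplicated sample ids")
    missing = beta.sample_ids.difference(sheet.index)
    if len(missing):
        raise ValueError(f"samples missing from sample sheet: {list(missing)[:5]}")
    return sheet.loc[beta.sample_ids]


def _subgroup_labels(sheet: pd.DataFrame) -> pd.Series:
    """Status-within-tissue subgroup label per sample (tissue optional)."""
    if "tissue" in sheet.columns:
        return sheet["status"].astype(str) + "/" + sheet["tissue"].astype(str)
    return sheet["status"].astype(str)


def filter_probes(
    beta: BetaMatrix,
    annot: pd.DataFrame,
    sheet: pd.DataFrame,
    detection_alpha: float = 0.05,
    max_failures_per_subgroup: int = 1,
    snp_maf_cutoff: float = 0.01,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Apply the probe-level QC ladder and return (filtered matrix, report).

    Removal rules, applied jointly:

    1. probes on the X or Y chromosome;
    2. probes with dbSNP minor allele frequency >= ``snp_maf_cutoff``
       (missing MAF is treated as non-polymorphic);
    3. probes with detection p > ``detection_alpha`` in more than
       ``max_failures_per_subgroup`` samples of any status subgroup
       (subgroup = status within tissue).

    The report lists probes removed per rule (a probe hit by several rules
    counts under each).
    """
    annot = normalize_annotation(annot)
    sheet = validate_sample_sheet(beta, sheet)
    annot = annot.reindex(beta.probe_ids)

    sex_rule = annot["chromosome"].astype(str).isin(SEX_CHROMOSOMES)

    if "snp_maf" in annot.columns:
        maf = pd.to_numeric(annot["snp_maf"], errors="coerce")
        snp_rule = maf.notna() & (maf >= snp_maf_cutoff)
    else:
        snp_rule = pd.Series(False, index=beta.probe_ids)

    if beta.detection is not None:
        fails = beta.detection > detection_alpha
        groups = _subgroup_labels(sheet)
        per_group = fails.T.groupby(groups.to_numpy()).sum().T  # probes x subgroups
        det_rule = (per_group > max_failures_per_subgroup).any(axis=1)
    else:
        det_rule = pd.Series(False, index=beta.probe_ids)

    removed = sex_rule | snp_rule | det_rule
    report = pd.DataFrame(
        {
            "rule": ["sex_chromosome", "snp_overlap", "detection_failure", "retained"],
            "probes_removed": [
                int(sex_rule.sum()),
                int(snp_rule.sum()),
                int(det_rule.sum()),
                int((~removed).sum()),
            ],
        }
    )
    if removed.all():
        dominant = report.iloc[:3].sort_values("probes_removed").iloc[-1]["rule"]
        raise ValueError(f"all probes removed by QC filtering (dominating rule: {dominant})")
    for _, row in report.iterrows():
        log.info("filter_probes: %s -> %d probes", row["rule"], row["probes_removed"])
    return beta.subset_probes(beta.probe_ids[~removed]), report


def _batch_design(sheet: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list]:
    batches = sheet["batch"].astype(str)
    levels = sorted(batches.unique())
    onehot = np.column_stack([(batches == b).to_numpy(float) for b in levels])
    status = (sheet["status"].astype(str) == "case").to_numpy(float)
    return onehot, status, levels


def adjust_batch(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    shrink: bool = True,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> BetaMatrix:
    """Remove batch effects by empirical-Bayes location/scale adjustment.

    Per probe the model ``beta ~ batch + status`` is fitted; data are
    standardized against the batch-free fit, per-batch means and variances
    are shrunk toward their parametric priors across probes (``shrink=True``,
    the default) or used as-is (``shrink=False``, plain location/scale
    adjustment), batch terms are removed and the scale restored.  Disease
    status is protected as a covariate throughout.  Output values are
    re-clipped to [0, 1].

    Raises if any batch has fewer than two samples or if batch is perfectly
    confounded with status (inestimable).
    """
    sheet = validate_sample_sheet(beta, sheet)
    onehot, status, levels = _batch_design(sheet)
    if len(levels) == 1:
        return beta.copy()
    n_per_batch = onehot.sum(axis=0)
    if (n_per_batch < 2).any():
        raise ValueError("each batch must contain at least two samples")

    design = np.column_stack([onehot, status])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("batch is confounded with status; batch effect inestimable")

    Y = beta.values.to_numpy(dtype=float)  # probes x samples
    n_probes, n_samples = Y.shape
    n_batch = len(levels)

    # OLS fit of beta ~ batch + status, all probes at once
    B_hat, *_ = np.linalg.lstsq(design, Y.T, rcond=None)  # (n_batch+1) x probes
    grand_mean = (n_per_batch / n_samples) @ B_hat[:n_batch]  # probes
    resid = Y.T - design @ B_hat
    var_pooled = (resid**2).mean(axis=0)  # probes
    var_pooled = np.maximum(var_pooled, 1e-12)

    # standardized data: remove grand mean + covariate effects, unit scale
    stand_mean = grand_mean[None, :] + np.outer(status, B_hat[n_batch])  # samples x probes
    s_data = (Y.T - stand_mean) / np.sqrt(var_pooled)[None, :]

    adjusted = np.empty_like(s_data)
    # per-batch estimates
    gamma_hat = np.vstack(
        [s_data[onehot[:, i] == 1].mean(axis=0) for i in range(n_batch)]
    )  # batches x probes
    delta_hat = np.vstack(
        [s_data[onehot[:, i] == 1].var(axis=0, ddof=1) for i in range(n_batch)]
    )
    delta_hat = np.maximum(delta_hat, 1e-12)

    for i in range(n_batch):
        in_batch = onehot[:, i] == 1
        n_i = int(n_per_batch[i])
        g_hat, d_hat = gamma_hat[i], delta_hat[i]
        if shrink:
            g_bar = g_hat.mean()
            t2 = g_hat.var(ddof=1)
            d_mean, d_var = d_hat.mean(), d_hat.var(ddof=1)
            d_var = max(d_var, 1e-12)
            a_prior = (2 * d_var + d_mean**2) / d_var
            b_prior = (d_mean * d_var + d_mean**3) / d_var
            g_star, d_star = g_hat.copy(), d_hat.copy()
            batch_data = s_data[in_batch]
            for _ in range(max_iter):
                g_new = (n_i * t2 * g_hat + d_star * g_bar) / (n_i * t2 + d_star)
                sum2 = ((batch_data - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (0.5 * sum2 + b_prior) / (n_i / 2.0 + a_prior - 1)
                change = max(
                    np.abs(g_new - g_star).max() / max(np.abs(g_star).max(), 1e-12),
                    np.abs(d_new - d_star).max() / max(np.abs(d_star).max(), 1e-12),
                )
                g_star, d_star = g_new, d_new
                if change < tol:
                    break
        else:
            g_star, d_star = g_hat, d_hat
        adjusted[in_batch] = (s_data[in_batch] - g_star[None, :]) / np.sqrt(d_star)[None, :]

    out = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean
    out = np.clip(out.T, 0.0, 1.0)
    values = pd.DataFrame(out, index=beta.probe_ids, columns=beta.sample_ids)
    return BetaMatrix(values, beta.detection.copy() if beta.detection is not None else None)


@dataclass
class GlobalMethylationSummary:
    mean_case: float
    mean_control: float
    delta: float
    t_statistic: float
    p_value: float
    per_sample_means: pd.Series = field(repr=False)


def summarize_global_methylation(beta: BetaMatrix, sheet: pd.DataFrame) -> GlobalMethylationSummary:
    """Group-mean beta over all probes and a two-sided t-test on sample means."""
    sheet = validate_sample_sheet(beta, sheet)
    per_sample = beta.values.mean(axis=0)
    case = per_sample[(sheet["status"] == "case").to_numpy()]
    control = per_sample[(sheet["status"] == "control").to_numpy()]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least two samples per group for the global summary")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(case, control, equal_var=True)
    return GlobalMethylationSummary(
        mean_case=float(case.mean()),
        mean_control=float(control.mean()),
        delta=float(case.mean() - control.mean()),
        t_statistic=float(t),
        p_value=float(p),
        per_sample_means=per_sample,
    )
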