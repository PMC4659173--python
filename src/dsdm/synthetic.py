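"""Synthetic methylation cohorts with planted ground truth.

Every input consumed by the analysis stages can be generated here, so the
whole pipeline is testable without any external download:

* :func:`simulate_array_cohort` — a two-group array-style beta matrix with
  planted differentially methylated (DM) CpGs, age-dependent CpGs,
  status x age interaction CpGs, batch shifts, and a detection p-value
  matrix with sporadic failures.
* :func:`simulate_oxbs_pair` — paired standard-bisulfite (BS = 5mC + 5hmC)
  and oxidative-bisulfite (OXBS = 5mC) matrices with planted
  hydroxymethylation and DM assigned to one of three modality classes.
* :func:`simulate_wgbs_pair` — per-CpG read-count tables for a case and a
  wild-type genome with planted 1-kb DM windows and an engineered
  coverage duplication, plus an ortholog map and annotation intervals.

Noise is truncated-normal on the beta scale (values clipped to [0, 1]);
baseline methylation is drawn from a Beta(2,10)/Beta(10,2) mixture to mimic
the bimodal shape of real methylomes.  CpGs carrying planted effects get
mid-range baselines so the planted deltas survive clipping intact.  All
generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .arrays import BetaMatrix

__all__ = [
    "ArraySimConfig",
    "WgbsSimConfig",
    "TruthLabels",
    "ArrayCohort",
    "OxbsPair",
    "WgbsPair",
    "simulate_array_cohort",
    "simulate_oxbs_pair",
    "simulate_wgbs_pair",
    "make_probe_annotation",
]

CONTIG = "chr1"
CPG_SPACING = 100  # bp between simulated CpGs; coordinates 0-based half-open


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value}")


@dataclass
class ArraySimConfig:
    """Study conditions for the array-style cohort generator.

    Defaults mirror the scale of the fetal-brain arm of the study design:
    10+10 samples, DM effect size 0.25 beta units at 2% of CpGs,
    inter-individual noise sd 0.05, gestational ages 13-18 weeks, age slope
    0.2 per 10 weeks for age-dependent CpGs and an interaction (case minus
    control slope difference) of -0.13 per 10 weeks.
    """

    n_cpgs: int = 10_000
    n_case: int = 10
    n_control: int = 10
    frac_dm: float = 0.02
    delta_dm: float = 0.25
    noise_sd: float = 0.05
    frac_age_dependent: float = 0.01
    age_slope: float = 0.2  # delta-beta per 10 age units
    frac_interaction: float = 0.01
    interaction_slope: float = -0.13  # case minus control slope, per 10 age units
    batch_shift: float = 0.05
    n_batches: int = 1
    age_range: tuple[float, float] = (13.0, 18.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_dm", "frac_age_dependent", "frac_interaction"):
            _check_fraction(name, getattr(self, name))
        _check_fraction("delta_dm", self.delta_dm)
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least two samples per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass
class WgbsSimConfig:
    """Study conditions for the two-genome read-count generator.

    ``mean_depth`` defaults to 28 (the sequencing depth scale of the mouse
    arm of the design); ``dup_region`` emulates an engineered duplication as
    a 1.5x coverage gain in the case genome over a small slice (~2%) of the
    contig, so that library-size normalization is only mildly perturbed,
    as for a sub-chromosomal duplication.
    """

    n_cpgs: int = 10_000
    mean_depth: float = 28.0
    window_size: int = 1000
    n_dm_windows: int = 50
    dm_delta: float = 0.30
    dup_region: tuple[int, int] | None = None  # 0-based half-open, on the contig
    dup_ratio: float = 1.5
    meth_noise_sd: float = 0.0  # extra beta-scale jitter on true methylation
    seed: int = 0

    def validate(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dup_ratio <= 1:
            raise ValueError("dup_ratio must exceed 1")
        if self.window_size < CPG_SPACING:
            raise ValueError("window_size smaller than CpG spacing")
        if not 0.0 <= self.dm_delta <= 1.0:
            raise ValueError("dm_delta must be in [0, 1]")
        contig_len = self.n_cpgs * CPG_SPACING
        region = self.resolved_dup_region()
        if region[0] < 0 or region[1] > contig_len or region[0] >= region[1]:
            raise ValueError(f"dup_region {region} outside simulated contig [0, {contig_len})")

    def resolved_dup_region(self) -> tuple[int, int]:
        if self.dup_region is not None:
            return self.dup_region
        contig_len = self.n_cpgs * CPG_SPACING
        start = int(contig_len * 0.49)
        return (start, start + max(int(contig_len * 0.02), self.window_size))


@dataclass
class TruthLabels:
    """Planted ground truth: ids and directions of every simulated effect."""

    dm_cpg_ids: list[str] = field(default_factory=list)
    dm_directions: dict[str, int] = field(default_factory=dict)  # +1 hyper / -1 hypo
    age_cpg_ids: list[str] = field(default_factory=list)
    interaction_cpg_ids: list[str] = field(default_factory=list)
    hmc_component: dict[str, str] = field(default_factory=dict)  # modality class per CpG
    dm_window_ids: list[tuple[str, int, int]] = field(default_factory=list)
    dm_window_directions: dict[tuple[str, int, int], int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dm_window_ids"] = [list(w) for w in self.dm_window_ids]
        d["dm_window_directions"] = {
            f"{c}:{s}-{e}": v for (c, s, e), v in self.dm_window_directions.items()
        }
        return d


@dataclass
class ArrayCohort:
    beta: BetaMatrix  # carries the detection p-value matrix
    sheet: pd.DataFrame
    truth: TruthLabels


@dataclass
class OxbsPair:
    beta_bs: BetaMatrix
    beta_oxbs: BetaMatrix
    sheet: pd.DataFrame
    truth: TruthLabels
    true_mc: pd.DataFrame | None = None  # planted per-CpG/per-sample 5mC, pre-noise
    true_hmc: pd.DataFrame | None = None


@dataclass
class WgbsPair:
    case: pd.DataFrame  # CpG count table: chrom, pos, count_methylated, count_total, fraction
    wt: pd.DataFrame
    truth: TruthLabels
    ortholog_map: pd.DataFrame
    annotations: dict[str, pd.DataFrame]  # name -> BED-like intervals
    dup_region: tuple[int, int]


def _probe_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")


def _sample_sheet(config: ArraySimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_case + config.n_control
    sample_ids = [f"case{i + 1:02d}" for i in range(config.n_case)] + [
        f"ctrl{i + 1:02d}" for i in range(config.n_control)
    ]
    status = ["case"] * config.n_case + ["control"] * config.n_control
    sex = [("M" if i % 2 == 0 else "F") for i in range(config.n_case)] + [
        ("M" if i % 2 == 0 else "F") for i in range(config.n_control)
    ]
    lo, hi = config.age_range
    ages = np.concatenate(
        [
            np.linspace(lo, hi, config.n_case),
            np.linspace(lo, hi, config.n_control),
        ]
    )
    # round-robin within each status group keeps batch and status balanced
    batch = [f"B{i % config.n_batches + 1}" for i in range(config.n_case)] + [
        f"B{i % config.n_batches + 1}" for i in range(config.n_control)
    ]
    return pd.DataFrame(
        {
            "status": status,
            "sex": sex,
            "age": ages,
            "batch": batch,
            "tissue": ["brain"] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def _bimodal_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    low = rng.beta(2, 10, size=n)
    high = rng.beta(10, 2, size=n)
    pick_high = rng.random(n) < 0.5
    return np.where(pick_high, high, low)


def simulate_array_cohort(config: ArraySimConfig) -> ArrayCohort:
    """Generate a two-group beta matrix with planted DM/age/interaction CpGs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    probes = _probe_ids(config.n_cpgs)
    sheet = _sample_sheet(config, rng)
    n_samples = len(sheet)
    is_case = (sheet["status"] == "case").to_numpy()
    ages = sheet["age"].to_numpy()
    age_centered = ages - ages.mean()

    baseline = _bimodal_baseline(rng, config.n_cpgs)

    # disjoint planted sets
    n_dm = int(round(config.frac_dm * config.n_cpgs))
    n_age = int(round(config.frac_age_dependent * config.n_cpgs))
    n_int = int(round(config.frac_interaction * config.n_cpgs))
    planted = rng.choice(config.n_cpgs, size=n_dm + n_age + n_int, replace=False)
    dm_idx = planted[:n_dm]
    age_idx = planted[n_dm : n_dm + n_age]
    int_idx = planted[n_dm + n_age :]

    # mid-range baselines so planted deltas are not clipped
    for idx in (age_idx, int_idx):
        baseline[idx] = rng.uniform(0.3, 0.7, size=len(idx))
    lo = min(0.05 + config.delta_dm, 0.5)
    hi = max(0.95 - config.delta_dm, 0.5)
    baseline[dm_idx] = rng.uniform(lo, hi, size=n_dm)

    directions = rng.choice([-1, 1], size=n_dm)

    mu = np.tile(baseline[:, None], (1, n_samples))
    if n_dm:
        mu[dm_idx[:, None], np.where(is_case)[0][None, :]] += (
            directions[:, None] * config.delta_dm
        )
    if n_age:
        mu[age_idx] += (config.age_slope / 10.0) * age_centered[None, :]
    if n_int:
        mu[int_idx] += (config.age_slope / 10.0) * age_centered[None, :]
        mu[int_idx[:, None], np.where(is_case)[0][None, :]] += (
            config.interaction_slope / 10.0
        ) * age_centered[None, is_case]
    if config.batch_shift != 0 and config.n_batches > 1:
        batch_level = sheet["batch"].str.removeprefix("B").astype(int).to_numpy() - 1
        mu += config.batch_shift * batch_level[None, :]

    values = mu + rng.normal(0.0, config.noise_sd, size=mu.shape)
    values = np.clip(values, 0.0, 1.0)

    detection = rng.uniform(0.0, 0.01, size=mu.shape)
    n_fail = int(round(0.005 * detection.size))
    if n_fail:
        flat = rng.choice(detection.size, size=n_fail, replace=False)
        detection.flat[flat] = rng.uniform(0.05, 1.0, size=n_fail)

    beta = BetaMatrix(
        pd.DataFrame(values, index=probes, columns=sheet.index),
        pd.DataFrame(detection, index=probes, columns=sheet.index),
    )
    truth = TruthLabels(
        dm_cpg_ids=[probes[i] for i in np.sort(dm_idx)],
        dm_directions={probes[i]: int(d) for i, d in zip(dm_idx, directions)},
        age_cpg_ids=[probes[i] for i in np.sort(age_idx)],
        interaction_cpg_ids=[probes[i] for i in np.sort(int_idx)],
    )
    return ArrayCohort(beta=beta, sheet=sheet, truth=truth)


MODALITY_CLASSES = ("mc_only", "hmc_only", "additive")


def simulate_oxbs_pair(config: ArraySimConfig, hmc_level: float = 0.2) -> OxbsPair:
    """Generate paired BS/OXBS matrices with planted 5mC/5hmC differential methylation.

    ``hmc_level`` scales the baseline hydroxymethylation content.  Planted DM
    CpGs rotate through three modality classes: difference carried by 5mC
    only, by 5hmC only, or additively by both (same direction, half the
    delta on each mark).
    """
    config.validate()
    _check_fraction("hmc_level", hmc_level)
    rng = np.random.default_rng(config.seed)
    probes = _probe_ids(config.n_cpgs)
    sheet = _sample_sheet(config, rng)
    n_samples = len(sheet)
    is_case = (sheet["status"] == "case").to_numpy()

    mc = _bimodal_baseline(rng, config.n_cpgs)
    hmc = hmc_level * rng.beta(2, 5, size=config.n_cpgs)

    n_dm = int(round(config.frac_dm * config.n_cpgs))
    dm_idx = rng.choice(config.n_cpgs, size=n_dm, replace=False)
    directions = rng.choice([-1, 1], size=n_dm)
    classes = [MODALITY_CLASSES[i % 3] for i in range(n_dm)]

    # planted baselines leave headroom so the full delta fits on each affected
    # mark in either direction without clipping (losses need room below,
    # gains room above, and 5mC + 5hmC must stay <= 1 post-effect)
    delta = config.delta_dm
    mc_hi = max(0.12, 0.88 - 0.12 - 2 * delta)
    d_mc = np.zeros(config.n_cpgs)
    d_hmc = np.zeros(config.n_cpgs)
    for i, direc, cls in zip(dm_idx, directions, classes):
        down = direc < 0
        affects_mc = cls in ("mc_only", "additive")
        affects_hmc = cls in ("hmc_only", "additive")
        mc_base = rng.uniform(0.10, mc_hi) + (delta if down and affects_mc else 0.0)
        hmc_base = rng.uniform(0.02, 0.10) + (delta if down and affects_hmc else 0.0)
        mc[i], hmc[i] = mc_base, hmc_base
        if affects_mc:
            d_mc[i] = direc * delta
        if affects_hmc:
            d_hmc[i] = direc * delta

    mc_mat = np.tile(mc[:, None], (1, n_samples))
    hmc_mat = np.tile(hmc[:, None], (1, n_samples))
    mc_mat[:, is_case] += d_mc[:, None]
    hmc_mat[:, is_case] += d_hmc[:, None]
    mc_mat = np.clip(mc_mat, 0.0, 1.0)
    hmc_mat = np.clip(hmc_mat, 0.0, 1.0 - mc_mat)  # keep 5mC + 5hmC <= 1

    bs = np.clip(mc_mat + hmc_mat + rng.normal(0, config.noise_sd, mc_mat.shape), 0, 1)
    oxbs = np.clip(mc_mat + rng.normal(0, config.noise_sd, mc_mat.shape), 0, 1)

    truth = TruthLabels(
        dm_cpg_ids=[probes[i] for i in np.sort(dm_idx)],
        dm_directions={probes[i]: int(d) for i, d in zip(dm_idx, directions)},
        hmc_component={probes[i]: cls for i, cls in zip(dm_idx, classes)},
    )
    return OxbsPair(
        beta_bs=BetaMatrix(pd.DataFrame(bs, index=probes, columns=sheet.index)),
        beta_oxbs=BetaMatrix(pd.DataFrame(oxbs, index=probes, columns=sheet.index)),
        sheet=sheet,
        truth=truth,
        true_mc=pd.DataFrame(mc_mat, index=probes, columns=sheet.index),
        true_hmc=pd.DataFrame(hmc_mat, index=probes, columns=sheet.index),
    )


def _count_table(
    positions: np.ndarray, depth: np.ndarray, meth: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    m = rng.binomial(depth, meth)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, m / np.maximum(depth, 1), np.nan)
    return pd.DataFrame(
        {
            "chrom": CONTIG,
            "pos": positions,
            "count_methylated": m,
            "count_total": depth,
            "fraction": frac,
        }
    )


def simulate_wgbs_pair(config: WgbsSimConfig) -> WgbsPair:
    """Generate case/wild-type read-count tables with planted DM windows and a duplication."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    positions = np.arange(config.n_cpgs) * CPG_SPACING
    dup_region = config.resolved_dup_region()

    meth = _bimodal_baseline(rng, config.n_cpgs)
    cpgs_per_window = config.window_size // CPG_SPACING
    n_windows_total = config.n_cpgs // cpgs_per_window
    if config.n_dm_windows > n_windows_total:
        raise ValueError("more DM windows requested than available windows")

    dm_windows: list[tuple[str, int, int]] = []
    window_dirs: dict[tuple[str, int, int], int] = {}
    delta = np.zeros(config.n_cpgs)
    if config.dm_delta > 0 and config.n_dm_windows > 0:
        chosen = rng.choice(n_windows_total, size=config.n_dm_windows, replace=False)
        for w in np.sort(chosen):
            start = int(w * config.window_size)
            end = start + config.window_size
            direc = int(rng.choice([-1, 1]))
            # regional DM: the delta spans the window's CpGs (>= 3 of them)
            planted = np.arange(w * cpgs_per_window, (w + 1) * cpgs_per_window)
            lo, hi = 0.05 + config.dm_delta, 0.95 - config.dm_delta
            meth[planted] = rng.uniform(min(lo, hi), max(lo, hi), size=len(planted))
            delta[planted] = direc * config.dm_delta
            dm_windows.append((CONTIG, start, end))
            window_dirs[(CONTIG, start, end)] = direc

    meth_case = np.clip(meth + delta, 0.0, 1.0)
    if config.meth_noise_sd > 0:
        meth_case = np.clip(meth_case + rng.normal(0, config.meth_noise_sd, meth.shape), 0, 1)

    in_dup = (positions >= dup_region[0]) & (positions < dup_region[1])
    depth_wt = rng.poisson(config.mean_depth, size=config.n_cpgs)
    lam_case = np.where(in_dup, config.mean_depth * config.dup_ratio, config.mean_depth)
    depth_case = rng.poisson(lam_case)

    case = _count_table(positions, depth_case, meth_case, rng)
    wt = _count_table(positions, depth_wt, meth, rng)

    # ortholog map: each simulated CpG corresponds to a human array probe;
    # genes tile the contig one per window
    gene_ids = [f"GENE{(p // config.window_size):05d}" for p in positions]
    ortholog_map = pd.DataFrame(
        {
            "human_probe": [f"cg{i:08d}" for i in range(config.n_cpgs)],
            "human_chrom": "chr21",
            "human_pos": positions + 5_000_000,
            "mouse_chrom": CONTIG,
            "mouse_pos": positions,
            "gene": gene_ids,
        }
    )

    contig_len = config.n_cpgs * CPG_SPACING
    step = max(contig_len // 20, config.window_size)
    cgis = pd.DataFrame(
        {
            "chrom": CONTIG,
            "start": np.arange(0, contig_len, step),
            "end": np.minimum(np.arange(0, contig_len, step) + step // 4, contig_len),
        }
    )
    gene_names = sorted(set(gene_ids))
    gene_starts = np.array([int(g[4:]) * config.window_size for g in gene_names])
    genes_bed = pd.DataFrame(
        {
            "chrom": CONTIG,
            "start": gene_starts,
            "end": gene_starts + config.window_size,
            "name": gene_names,
        }
    )
    tss = genes_bed.assign(end=genes_bed["start"] + 1)[["chrom", "start", "end", "name"]]
    n_motifs = max(config.n_cpgs // 50, 1)
    motif_starts = np.sort(rng.choice(contig_len - 20, size=n_motifs, replace=False))
    motifs = pd.DataFrame(
        {"chrom": CONTIG, "start": motif_starts, "end": motif_starts + 12, "name": "MOTIF1"}
    )
    dup_bed = pd.DataFrame(
        {"chrom": [CONTIG], "start": [dup_region[0]], "end": [dup_region[1]], "name": ["dup"]}
    )

    truth = TruthLabels(dm_window_ids=dm_windows, dm_window_directions=window_dirs)
    return WgbsPair(
        case=case,
        wt=wt,
        truth=truth,
        ortholog_map=ortholog_map,
        annotations={"cgi": cgis, "genes": genes_bed, "tss": tss, "motifs": motifs, "dup": dup_bed},
        dup_region=dup_region,
    )


def make_probe_annotation(
    probe_ids, seed: int = 0, frac_sex: float = 0.02, frac_snp: float = 0.01
) -> pd.DataFrame:
    """Fixture probe annotation for an array cohort (positions, context, genes).

    Probes sit on a single autosomal contig at fixed 100-bp spacing except
    for a planted fraction relocated to chrX/chrY and a fraction flagged as
    SNP-overlapping; ten consecutive probes share a gene, alternating
    island/shore/open-sea context.
    """
    rng = np.random.default_rng(seed)
    probe_ids = pd.Index(probe_ids, name="probe_id")
    n = len(probe_ids)
    chrom = np.array([CONTIG] * n, dtype=object)
    n_sex = int(round(frac_sex * n))
    sex_idx = rng.choice(n, size=n_sex, replace=False)
    chrom[sex_idx[: n_sex // 2]] = "chrX"
    chrom[sex_idx[n_sex // 2 :]] = "chrY"
    snp_maf = np.full(n, np.nan)
    snp_idx = rng.choice(n, size=int(round(frac_snp * n)), replace=False)
    snp_maf[snp_idx] = rng.uniform(0.01, 0.5, size=len(snp_idx))
    cgi_cycle = np.array(["island", "shore", "open_sea"], dtype=object)
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "position": np.arange(n) * CPG_SPACING,
            "snp_maf": snp_maf,
            "cgi_relation": cgi_cycle[np.arange(n) % 3],
            "gene_ids": [f"GENE{(i // 10):05d}" for i in range(n)],
            "in_gene_body": (np.arange(n) % 2 == 0),
            "in_promoter": (np.arange(n) % 10 < 2),
        },
        index=probe_ids,
    )
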