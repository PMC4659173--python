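"""Readers and writers for the delimited formats shared by all stages.

Conventions: beta and detection matrices are TSV with probe ids as the row
index and sample ids as the header; sample sheets are CSV with a
``sample_id`` column; interval sets are BED (0-based half-open, written
natively); WGBS counts are Bismark-coverage-style TSV
(chrom, start, end, %meth, count_methylated, count_unmethylated) or the
plain (chrom, pos, count_methylated, count_total) dialect; truth labels and
manifests are JSON; pipeline configuration is YAML and round-trips
load -> save -> load identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arrays import BetaMatrix

__all__ = [
    "PipelineConfig",
    "read_beta_tsv",
    "write_beta_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "write_truth",
    "read_truth",
    "load_config",
    "save_config",
]


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and paths driving a full pipeline run."""

    delta_min: float = 0.15
    p_max: float = 0.001
    detection_alpha: float = 0.05
    snp_maf_cutoff: float = 0.01
    min_depth: int = 20
    window_size: int = 1000
    fisher_ladder: list = dataclasses.field(default_factory=lambda: [0.05, 0.01, 0.005, 0.001])
    maturation_profile: str = "fetal"
    seed: int = 0
    output_dir: str = "dsdm_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_beta_tsv(values_path, detection_path=None) -> BetaMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index.name = "probe_id"
    values.columns.name = "sample_id"
    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, sep="\t", index_col=0)
        detection.index.name = "probe_id"
        detection.columns.name = "sample_id"
    return BetaMatrix(values, detection)


def write_beta_tsv(beta: BetaMatrix, values_path, detection_path=None) -> None:
    beta.values.to_csv(values_path, sep="\t")
    if detection_path is not None and beta.detection is not None:
        beta.detection.to_csv(detection_path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("sample_id")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index_label="sample_id")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in intervals]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_counts(path, dialect: str = "bismark") -> pd.DataFrame:
    """Read a CpG count table.

    ``bismark``: chrom, start, end, %methylation, count_methylated,
    count_unmethylated (positions taken from ``start``).  ``plain``: chrom,
    pos, count_methylated, count_total.
    """
    if dialect == "bismark":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "pct", "count_methylated", "count_unmethylated"],
        )
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["start"],
                "count_methylated": df["count_methylated"],
                "count_total": df["count_methylated"] + df["count_unmethylated"],
            }
        )
    elif dialect == "plain":
        out = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "pos", "count_methylated", "count_total"],
        )
    else:
        raise ValueError(f"unknown count-table dialect: {dialect!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fraction"] = out["count_methylated"] / out["count_total"]
    return out


def write_counts(table: pd.DataFrame, path, dialect: str = "bismark") -> None:
    if dialect == "bismark":
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * table["count_methylated"] / table["count_total"]
        out = pd.DataFrame(
            {
                "chrom": table["chrom"],
                "start": table["pos"],
                "end": table["pos"] + 1,
                "pct": pct,
                "count_methylated": table["count_methylated"],
                "count_unmethylated": table["count_total"] - table["count_methylated"],
            }
        )
    elif dialect == "plain":
        out = table[["chrom", "pos", "count_methylated", "count_total"]]
    else:
        raise ValueError(f"unknown count-table dialect: {dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict() if hasattr(truth, "to_dict") else truth, fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_manifest(path, inputs: dict, config: dict) -> None:
    import hashlib

    payload = {"inputs": {k: str(v) for k, v in inputs.items()}, "config": config}
    payload["config_hash"] = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    try:
        from importlib.metadata import version

        payload["dsdm_version"] = version("dsdm")
    except Exception:
        payload["dsdm_version"] = "unknown"
    Path(path).write_text(json.dumps(payload, indent=1))
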