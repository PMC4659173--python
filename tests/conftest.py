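import numpy as np
import pandas as pd
import pytest

from dsdm.arrays import BetaMatrix
from dsdm.synthetic import (
    ArraySimConfig,
    WgbsSimConfig,
    make_probe_annotation,
    simulate_array_cohort,
    simulate_oxbs_pair,
    simulate_wgbs_pair,
)


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-CpG two-group cohort with planted DM, age and interaction CpGs."""
    return simulate_array_cohort(ArraySimConfig(n_cpgs=2000, seed=11))


@pytest.fixture(scope="session")
def small_annotation(small_cohort):
    return make_probe_annotation(small_cohort.beta.probe_ids, seed=11)


@pytest.fixture(scope="session")
def oxbs_pair():
    return simulate_oxbs_pair(
        ArraySimConfig(n_cpgs=1500, n_case=6, n_control=6, frac_dm=0.06, seed=21),
        hmc_level=0.2,
    )


@pytest.fixture(scope="session")
def wgbs_pair():
    return simulate_wgbs_pair(
        WgbsSimConfig(n_cpgs=8000, mean_depth=30, n_dm_windows=40, dm_delta=0.30, seed=31)
    )


def toy_beta(values: dict[str, list[float]], sample_ids: list[str]) -> BetaMatrix:
    """Tiny beta matrix from a probe -> row-of-values mapping."""
    return BetaMatrix(
        pd.DataFrame.from_dict(values, orient="index", columns=sample_ids).astype(float)
    )


def toy_sheet(status: list[str], **extra) -> pd.DataFrame:
    n = len(status)
    data = {
        "status": status,
        "sex": extra.get("sex", ["M", "F"] * (n // 2 + 1))[:n],
        "age": extra.get("age", list(np.linspace(10, 20, n))),
        "batch": extra.get("batch", ["B1"] * n),
    }
    ids = extra.get("sample_ids", [f"s{i}" for i in range(n)])
    return pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))
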