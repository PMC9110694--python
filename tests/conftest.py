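import numpy as np
import pandas as pd
import pytest

from uromet import preprocess as pp
from uromet.simulate import SimConfig, generate_cohort


def make_table(values: dict[str, list[float]], injection_ids: list[str]) -> pd.DataFrame:
    """Feature table (features x injections) from {feature_id: row}."""
    return pd.DataFrame.from_dict(values, orient="index", columns=injection_ids).rename_axis(
        "feature_id"
    )


def make_meta(rows: list[dict]) -> pd.DataFrame:
    """Injection metadata with sensible defaults for unspecified columns."""
    defaults = {
        "sample_id": None,
        "subject_id": None,
        "site": "site_A",
        "batch": 1,
        "injection_order": None,
        "replicate_group": None,
        "dilution_level": np.nan,
        "ga_weeks": np.nan,
        "ga_delivery_weeks": np.nan,
        "delivery_group": None,
    }
    out = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        r.setdefault("injection_id", f"inj{i + 1:03d}")
        if r["injection_order"] is None:
            r["injection_order"] = i + 1
        if r["sample_id"] is None:
            r["sample_id"] = r["injection_id"]
        if r["subject_id"] is None:
            r["subject_id"] = r["sample_id"]
        if r["replicate_group"] is None:
            r["replicate_group"] = r["sample_id"]
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Reduced cohort used across unit tests: quick but structurally complete."""
    return SimConfig(
        n_subjects=30,
        n_validation=8,
        n_features=200,
        n_informative=10,
        n_batches=2,
        qc_every=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cfg, small_cohort):
    """Preprocessed features x samples matrix of the small cohort, with GA
    and delivery-group labels."""
    table, meta, truth = small_cohort
    matrix, _ = pp.run_preprocessing(table, meta, seed=small_cfg.seed)
    study = meta[meta["type"] == "study"].drop_duplicates("sample_id").set_index("sample_id")
    X = matrix.T
    y = study.loc[X.index, "ga_weeks"].astype(float)
    groups = study.loc[X.index, "delivery_group"]
    return X, y, groups, truth
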