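"""Reading, writing and validating feature tables and injection metadata."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_META_COLUMNS = [
    "injection_id",
    "sample_id",
    "subject_id",
    "type",
    "batch",
    "injection_order",
    "replicate_group",
    "dilution_level",
]

VALID_TYPES = {"study", "qc_pool", "blank", "qc_dilution"}


def read_table(path: str | Path) -> pd.DataFrame:
    """Feature table TSV, rows = features, columns = injections."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "feature_id"
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def validate_inputs(table_path: str | Path, meta_path: str | Path) -> list[str]:
    """Schema report for a table/metadata pair; empty list means clean."""
    violations: list[str] = []
    table = read_table(table_path)
    meta = read_metadata(meta_path)

    for col in REQUIRED_META_COLUMNS:
        if col not in meta.columns:
            violations.append(f"metadata missing required column '{col}'")
    if violations:
        return violations

    if meta["injection_id"].duplicated().any():
        dupes = meta.loc[meta["injection_id"].duplicated(), "injection_id"].tolist()
        violations.append(f"duplicate injection ids in metadata: {dupes[:5]}")
    if table.index.duplicated().any():
        violations.append("duplicate feature ids in table")

    meta_ids = set(meta["injection_id"])
    for inj in table.columns:
        if inj not in meta_ids:
            violations.append(f"injection '{inj}' in table absent from metadata")
    for inj in meta_ids - set(table.columns):
        violations.append(f"injection '{inj}' in metadata absent from table")

    bad_types = sorted(set(meta["type"]) - VALID_TYPES)
    if bad_types:
        violations.append(f"unknown injection types: {bad_types}")

    vals = table.to_numpy(float)
    neg = np.argwhere(vals < 0)
    for i, j in neg[:10]:
        violations.append(
            f"negative abundance at feature '{table.index[i]}', injection '{table.columns[j]}'"
        )

    if "ga_weeks" in meta.columns:
        ga = pd.to_numeric(meta["ga_weeks"], errors="coerce").dropna()
        out_of_range = ga[(ga <= 0) | (ga >= 45)]
        for idx in out_of_range.index[:10]:
            violations.append(
                f"implausible ga_weeks={meta.loc[idx, 'ga_weeks']} for injection "
                f"'{meta.loc[idx, 'injection_id']}'"
            )
    return violations
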