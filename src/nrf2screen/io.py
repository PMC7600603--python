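"""File schemas shared by all stages.

Conventions: comma-separated CSV (expression matrices are tab-separated),
UTF-8, "." decimal, mandatory header row; concentrations in nM, times in
months, responses in percent.  All writes are atomic (write-then-rename).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ._util import atomic_write_text, sha256_file, write_dataframe
from .signature import ExpressionCohort


def write_expression_tsv(cohort: ExpressionCohort, expr_path, labels_path) -> None:
    """Expression matrix as gene-rows x sample-columns TSV plus a label
    sidecar CSV (sample, class)."""
    atomic_write_text(expr_path, cohort.values.to_csv(sep="\t"))
    labels = cohort.labels.rename_axis("sample").rename("class").reset_index()
    write_dataframe(labels, labels_path)


def read_expression_tsv(expr_path, labels_path, name: str | None = None) -> ExpressionCohort:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    labels_df = pd.read_csv(labels_path)
    for col in ("sample", "class"):
        if col not in labels_df.columns:
            raise ValueError(f"labels file {labels_path} missing column {col!r}")
    labels = labels_df.set_index("sample")["class"]
    return ExpressionCohort(values=values, labels=labels,
                            name=name or Path(expr_path).stem)


def read_plates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"plate", "well", "compound", "dose_nM", "cell_line", "readout", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate file {path} missing columns: {sorted(missing)}")
    return df


def read_tma_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient", "observer", "pct_unstained", "pct_weak",
                "pct_moderate", "pct_strong", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TMA file {path} missing columns: {sorted(missing)}")
    return df


def read_qpcr_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample", "condition", "gene", "ct", "housekeeping_ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct file {path} missing columns: {sorted(missing)}")
    return df


def write_json(obj, path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def file_checksums(paths) -> dict[str, str]:
    return {Path(p).name: sha256_file(p) for p in paths if Path(p).exists()}
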