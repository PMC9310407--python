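"""Validated TSV/CSV readers and writers for every table the pipelines touch.

All matrices are written genes-as-rows with a header of sample ids; sample
metadata lives in a separate sample sheet (tidy separation).  Readers
validate schema and cell contents and raise :class:`SchemaError` naming the
offending column or cell; writers round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_counts", "write_counts",
    "read_annotation", "write_annotation",
    "read_sample_sheet", "write_sample_sheet",
    "read_truth", "write_truth",
    "read_matrix", "write_matrix",
    "read_contrast_table", "write_contrast_table",
    "read_survival", "write_survival",
    "read_gene_list", "write_gene_list",
    "write_json", "read_json",
]

SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "age_months", "genotype", "treatment", "tissue"]
SURVIVAL_COLUMNS = ["animal_id", "arm", "time_months", "event"]
CONTRAST_COLUMNS = ["gene_id", "log2_fc", "p_raw", "q_bh"]
TRUTH_COLUMNS = ["gene_id", "aging_direction", "reverted", "dependence", "trt_direction"]


class SchemaError(ValueError):
    """A file does not match its expected schema; message names the problem."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _require_numeric(df: pd.DataFrame, path, nonnegative=False, integer=False) -> None:
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() | ~np.isfinite(series)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise SchemaError(f"{path}: non-numeric cell at row '{row}', column '{col}'")
        if nonnegative and (series < 0).any():
            row = df.index[(series < 0).to_numpy().nonzero()[0][0]]
            raise SchemaError(f"{path}: negative value at row '{row}', column '{col}'")
        if integer and (series != series.round()).any():
            row = df.index[(series != series.round()).to_numpy().nonzero()[0][0]]
            raise SchemaError(f"{path}: non-integer count at row '{row}', column '{col}'")


# -- matrices ---------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "gene_id":
        raise SchemaError(f"{path}: first column must be 'gene_id', got '{df.columns[0]}'")
    df = df.set_index("gene_id")
    if df.index.has_duplicates:
        raise SchemaError(f"{path}: duplicated gene_ids")
    _require_numeric(df, path, nonnegative=True, integer=True)
    return df.astype(float).astype(np.int64)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("gene_id")
    _require_numeric(df, path)
    return df.astype(float)


# -- metadata tables --------------------------------------------------------

def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "length_bp"], path)
    if df["gene_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicated gene_ids")
    _require_numeric(df[["length_bp"]], path, nonnegative=True, integer=True)
    if (df["length_bp"] < 1).any():
        raise SchemaError(f"{path}: length_bp must be >= 1")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SAMPLE_SHEET_COLUMNS, path)
    if df["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicated sample_ids")
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, TRUTH_COLUMNS, path)
    return df.set_index("gene_id")


# -- contrast tables --------------------------------------------------------

def write_contrast_table(table: pd.DataFrame, path, name: str | None = None) -> None:
    """ContrastTable TSV with a `# contrast: <name>` header comment.

    The log2_fc column is the difference of mean log2-transformed expression
    (comparison minus reference), noted in the header for downstream readers.
    """
    name = name or table.attrs.get("contrast", "unnamed")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# contrast: {name}\n")
        fh.write("# log2_fc = mean log2(expr+pseudocount) comparison - reference\n")
        table.to_csv(fh, sep="\t", index=False)


def read_contrast_table(path) -> pd.DataFrame:
    name = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# contrast:"):
                name = line.split(":", 1)[1].strip()
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, CONTRAST_COLUMNS, path)
    _require_numeric(df[["log2_fc", "p_raw", "q_bh"]], path)
    if ((df["p_raw"] < 0) | (df["p_raw"] > 1) | (df["q_bh"] < 0) | (df["q_bh"] > 1)).any():
        raise SchemaError(f"{path}: p_raw/q_bh outside [0, 1]")
    if name:
        df.attrs["contrast"] = name
    return df


# -- survival ---------------------------------------------------------------

def write_survival(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SURVIVAL_COLUMNS, path)
    _require_numeric(df[["time_months", "event"]], path, nonnegative=True)
    if (df["time_months"] <= 0).any():
        raise SchemaError(f"{path}: time_months must be > 0")
    if ~df["event"].isin([0, 1]).all():
        raise SchemaError(f"{path}: event must be 0 or 1")
    return df


# -- misc -------------------------------------------------------------------

def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
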