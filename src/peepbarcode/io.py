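"""Tabular I/O with schema validation.

All stage files are tab-separated with a header row.  Readers validate
the expected columns and coerce numeric fields, reporting the offending
row on failure so malformed inputs fail fast and loudly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


def read_table(
    path: str | Path,
    required: Sequence[str],
    numeric: Sequence[str] = (),
    unique_key: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a TSV, checking columns, numeric parses, and key uniqueness."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} (found {list(df.columns)})")
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0])
            raise ValueError(
                f"{path}: non-numeric value {df.at[row, col]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        if parsed.isna().any():
            row = int(parsed.index[parsed.isna()][0])
            raise ValueError(f"{path}: missing value in column {col!r} at data row {row + 1}")
        df[col] = parsed
    if unique_key and df.duplicated(list(unique_key)).any():
        row = int(df.index[df.duplicated(list(unique_key))][0])
        raise ValueError(
            f"{path}: duplicate key {tuple(df.loc[row, list(unique_key)])} at data row {row + 1}"
        )
    return df


def read_histamine(path: str | Path) -> pd.DataFrame:
    """histamine.tsv: donor_id, release_pct."""
    return read_table(
        path, required=["donor_id", "release_pct"], numeric=["release_pct"],
        unique_key=["donor_id"],
    )


def read_labels(path: str | Path) -> dict[str, str]:
    """labels.tsv: donor_id, (release_pct,) label -> mapping donor -> label."""
    df = read_table(path, required=["donor_id", "label"], unique_key=["donor_id"])
    return dict(zip(df["donor_id"], df["label"]))


def read_plates(path: str | Path) -> pd.DataFrame:
    """plates.tsv: plate_id, donor_id, gene, Qs, Gs, Qc, Gc."""
    return read_table(
        path,
        required=["plate_id", "donor_id", "gene", "Qs", "Gs", "Qc", "Gc"],
        numeric=["Qs", "Gs", "Qc", "Gc"],
        unique_key=["donor_id", "gene"],
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Donor x gene Log2 matrix: donors as rows, gene-name header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: expression matrix has missing entries")
    return df.astype(float)


def read_peep_calls(path: str | Path) -> pd.DataFrame:
    """peep_calls.tsv (donor_id, gene, status) -> donor x gene status matrix."""
    df = read_table(
        path, required=["donor_id", "gene", "status"], unique_key=["donor_id", "gene"]
    )
    mat = df.pivot(index="donor_id", columns="gene", values="status")
    return mat.loc[
        df["donor_id"].drop_duplicates().tolist(), df["gene"].drop_duplicates().tolist()
    ]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    expr.to_csv(path, sep="\t", index=True, index_label="donor_id")
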