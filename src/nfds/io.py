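"""Flat-file schemas for the pipeline.

All tables are plain CSV with header rows.  Generations are 0-based
integers and every frequency refers to haplotype HI (f_II = 1 - f_I).

counts.csv    sample_id,line_id,generation,snp_id,count_HI,count_HII
design.csv    line_id,start_freq,environment,replicate
freqs.csv     line_id,generation,f_HI
truth.csv     line_id,generation,true_p,census
estimates.csv line_id,interval,delta_f,s_I,valid
anova.csv     response,term,stratum,df,SS,MS,F,p,p_perm
summary.csv   quantity,group,value
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SchemaError", "read_counts", "read_design", "read_freqs", "write_csv"]

COUNTS_COLUMNS = ["sample_id", "line_id", "generation", "snp_id", "count_HI", "count_HII"]
DESIGN_COLUMNS = ["line_id", "start_freq", "environment", "replicate"]
FREQS_COLUMNS = ["line_id", "generation", "f_HI"]


class SchemaError(ValueError):
    """An input table violates its schema; the message names the offender."""


def _read(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df[columns]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read and validate a diagnostic-SNP read-count table."""
    df = _read(path, COUNTS_COLUMNS)
    for col in ("count_HI", "count_HII"):
        if (df[col] < 0).any():
            row = int(df.index[df[col] < 0][0])
            raise SchemaError(f"{path}: negative {col} at row {row}")
    zero = df["count_HI"] + df["count_HII"] == 0
    if zero.any():
        bad = df.loc[zero, "sample_id"].tolist()
        raise SchemaError(f"{path}: zero total depth for samples {bad}")
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    """Read and validate an experimental-design table."""
    df = _read(path, DESIGN_COLUMNS)
    if df["line_id"].duplicated().any():
        dup = df.loc[df["line_id"].duplicated(), "line_id"].tolist()
        raise SchemaError(f"{path}: duplicated line_id {dup}")
    bad = ~df["start_freq"].between(0.0, 1.0)
    if bad.any():
        raise SchemaError(
            f"{path}: start_freq outside [0,1] for lines "
            f"{df.loc[bad, 'line_id'].tolist()}"
        )
    return df


def read_freqs(path: str | Path) -> pd.DataFrame:
    """Read and validate a haplotype-frequency table."""
    df = _read(path, FREQS_COLUMNS)
    bad = ~df["f_HI"].between(0.0, 1.0)
    if bad.any():
        raise SchemaError(
            f"{path}: f_HI outside [0,1] for lines {df.loc[bad, 'line_id'].tolist()}"
        )
    return df


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as headered CSV at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path
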