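"""Readers and preprocessing for the standard omics input tables.

Covers the preprocessing protocol applied before any modelling: missing-value
filtering (genes with >= 5% missing dropped), median imputation of the rest,
averaging of repeated sample ids, FPKM -> TPM conversion, unit conversion of
survival times to years, CNV binarization (non-zero call = out of normal
range), and survival dichotomization at a horizon t.

On-disk conventions: expression/CNV are TSV with genes in rows and a header
row of sample ids; mutations are a MAF-like TSV with at least Hugo_Symbol
and Tumor_Sample_Barcode columns; clinical is a TSV with sample id, time and
event columns (names configurable). All matrices are oriented samples x
genes in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalTable",
    "LabeledDataset",
    "MISSING_TOKENS",
    "read_expression",
    "read_clinical",
    "read_mutations_to_matrix",
    "fpkm_to_tpm",
    "filter_and_impute",
    "collapse_duplicates",
    "binarize_cnv",
    "dichotomize",
]

#: Missing-value token dialect accepted in input tables.
MISSING_TOKENS = ("NA", "NaN", "nan", "")


@dataclass
class ClinicalTable:
    """Per-sample overall survival: time in years and 0/1 event indicator."""

    table: pd.DataFrame  # columns: sample_id, os_time_years, os_event

    def __post_init__(self) -> None:
        required = {"sample_id", "os_time_years", "os_event"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if (self.table["os_time_years"] < 0).any():
            raise ValueError("negative survival times")


@dataclass
class LabeledDataset:
    """One omics matrix with binary survival labels at horizon t (years).

    Label 1 = event within t years; label 0 = survival beyond t. Samples
    censored before t have an indeterminate t-year status and are excluded
    (listed in ``excluded_samples``).
    """

    matrix: pd.DataFrame
    labels: pd.Series
    horizon_years: float
    excluded_samples: list[str] = field(default_factory=list)


def read_expression(
    path: str | Path,
    missing_tokens: tuple[str, ...] = MISSING_TOKENS,
) -> pd.DataFrame:
    """Read a genes-in-rows TSV into a samples x genes matrix.

    First column holds gene ids (whitespace-trimmed symbols), header holds
    sample ids. Missing cells (any of ``missing_tokens``) become NaN;
    duplicate sample columns are preserved for the collapse step. Any other
    non-numeric cell raises with its row/column location.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    values = raw.replace(dict.fromkeys(missing_tokens, np.nan))
    try:
        numeric = values.astype(float)
    except ValueError:
        numeric = values.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & values.notna()
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {values.iat[r, c]!r} at gene "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        ) from None
    out = numeric.T  # samples x genes
    out.index.name = None
    out.columns.name = None
    return out


def read_clinical(
    path: str | Path,
    sample_col: str = "sample_id",
    time_col: str = "os_time_years",
    event_col: str = "os_event",
    time_divisor: float = 1.0,
) -> ClinicalTable:
    """Read a clinical TSV and convert survival time to years.

    ``time_divisor`` converts the stored unit: 1 for years, 12 for months
    (OS_MONTHS / 12), 365.25 for day-based fields.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not found; columns present: {list(df.columns)}"
            )
    out = pd.DataFrame(
        {
            "sample_id": df[sample_col].astype(str).str.strip(),
            "os_time_years": df[time_col].astype(float) / time_divisor,
            "os_event": df[event_col].astype(int),
        }
    )
    out = out.groupby("sample_id", as_index=False).agg(
        {"os_time_years": "mean", "os_event": "max"}
    )
    return ClinicalTable(out)


def fpkm_to_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale per-sample FPKM to TPM: every sample then sums to 10^6."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative FPKM values")
    totals = np.nansum(values, axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            f"all-zero expression for sample(s): {list(matrix.index[zero])}"
        )
    return matrix.div(totals, axis=0) * 1e6


def filter_and_impute(
    matrix: pd.DataFrame, max_missing_fraction: float = 0.05
) -> tuple[pd.DataFrame, int]:
    """Drop genes with >= 5% missing values; median-impute the remainder.

    Returns the cleaned matrix and the number of genes removed. A gene with
    all values missing is removed by the same rule.
    """
    frac = matrix.isna().mean(axis=0)
    keep = frac[frac < max_missing_fraction].index
    removed = matrix.shape[1] - len(keep)
    out = matrix[keep].copy()
    medians = out.median(axis=0, skipna=True)
    out = out.fillna(medians)
    return out, removed


def collapse_duplicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average rows with repeated sample ids; output ids are unique."""
    if not matrix.index.duplicated().any():
        return matrix
    return matrix.groupby(level=0, sort=False).mean()


def read_mutations_to_matrix(
    path: str | Path,
    gene_ids: list[str],
    sample_ids: list[str],
    gene_col: str = "Hugo_Symbol",
    sample_col: str = "Tumor_Sample_Barcode",
) -> pd.DataFrame:
    """Turn a MAF-like table into a samples x genes 0/1 mutation matrix.

    Entry (s, g) is 1 iff the table holds at least one somatic-mutation row
    for that pair; pairs absent from the table are 0.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (gene_col, sample_col):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not found; columns present: {list(df.columns)}"
            )
    out = pd.DataFrame(0, index=list(sample_ids), columns=list(gene_ids), dtype=int)
    genes = df[gene_col].astype(str).str.strip()
    samples = df[sample_col].astype(str).str.strip()
    mask = genes.isin(out.columns) & samples.isin(out.index)
    for s, g in zip(samples[mask], genes[mask]):
        out.at[s, g] = 1
    return out


def binarize_cnv(matrix: pd.DataFrame) -> pd.DataFrame:
    """Encode non-zero copy-number calls as 1 (copy number out of normal range)."""
    if matrix.isna().any().any():
        raise ValueError("CNV matrix has missing values; run filter_and_impute first")
    return (matrix != 0).astype(int)


def dichotomize(
    clinical: ClinicalTable,
    t: float,
    horizons: tuple[float, ...] = (1.0, 3.0, 5.0, 10.0),
) -> tuple[pd.Series, list[str]]:
    """Binary survival status at horizon ``t`` (years).

    Label 1: event observed at or before t (short survival). Label 0:
    survival time beyond t, event or censored. Samples censored at or before
    t are excluded: their t-year status is unknown, and forcing either label
    would inject label noise.
    """
    if t <= 0:
        raise ValueError("horizon t must be > 0")
    if t not in horizons:
        warnings.warn(f"horizon {t} not among configured horizons {horizons}", stacklevel=2)
    df = clinical.table
    time = df["os_time_years"].to_numpy()
    event = df["os_event"].to_numpy()
    ids = df["sample_id"].to_numpy()
    label1 = (time <= t) & (event == 1)
    label0 = time > t
    excluded = (time <= t) & (event == 0)
    labels = pd.Series(
        np.where(label1, 1, 0)[label1 | label0],
        index=ids[label1 | label0],
        name=f"label_{t:g}yr",
    )
    return labels, list(ids[excluded])
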