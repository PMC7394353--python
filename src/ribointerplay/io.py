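"""Readers and writers for the pipeline's tab-separated tables.

Dialect: UTF-8, tab-separated, header row, first column is the identifier,
``NA`` is the missing-value literal, ``.`` is disallowed as an identifier.
Integer tables round-trip bit-identically; real tables round-trip within
1e-12 relative (values are written with repr-level precision).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceMatrix,
    CoremMembershipMatrix,
    CountMatrix,
    EdgeList,
    GeneAnnotation,
    ProteinIntensityMatrix,
    SampleDesign,
    TableValidationError,
)

log = logging.getLogger("ribointerplay")

SCHEMAS = (
    "counts", "abundance", "design", "annotation", "protein",
    "membership", "compendium", "categories", "edges", "differential",
)

_NA = "NA"


def _read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[_NA],
                       keep_default_na=False)


def read_table(path: str | Path, schema: str, *, design: SampleDesign | None = None,
               tpm_normalized: bool = True):
    """Read and validate one typed table.

    ``schema`` selects the container; see :data:`SCHEMAS`.  ``design`` is
    required for ``protein`` tables and optionally cross-checked for count
    and abundance tables.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    if schema in ("design", "edges", "annotation", "categories", "differential"):
        df = _read_tsv(path, index_col=None)
    else:
        df = _read_tsv(path, index_col=0)
        df.index = df.index.astype(str)

    if schema == "counts":
        obj = CountMatrix(df)
        if design is not None:
            obj.check_design(design)
    elif schema == "abundance":
        obj = AbundanceMatrix(df, tpm_normalized=tpm_normalized)
    elif schema == "design":
        obj = SampleDesign(df)
    elif schema == "annotation":
        obj = GeneAnnotation(df.set_index(df.columns[0]))
    elif schema == "protein":
        if design is None:
            raise ValueError("protein tables require a design")
        obj = ProteinIntensityMatrix(df, design.subset("protein"))
    elif schema == "membership":
        obj = CoremMembershipMatrix(df)
    elif schema == "compendium":
        obj = df.astype(float)
    elif schema == "categories":
        for col in ("condition", "category"):
            if col not in df.columns:
                raise TableValidationError(f"category table missing column {col!r}")
        obj = df
    elif schema == "edges":
        obj = EdgeList(df)
    elif schema == "differential":
        for col in ("gene_id", "log2fc", "pvalue", "padj"):
            if col not in df.columns:
                raise TableValidationError(f"differential table missing column {col!r}")
        obj = df.set_index("gene_id")
    log.info("read %s table from %s", schema, path)
    return obj


def write_table(obj, path: str | Path) -> None:
    """Write a typed table (or plain DataFrame) as TSV with the NA convention."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, (CountMatrix, AbundanceMatrix, CoremMembershipMatrix)):
        df, index = obj.data, True
    elif isinstance(obj, ProteinIntensityMatrix):
        df, index = obj.data, True
    elif isinstance(obj, (SampleDesign, EdgeList, GeneAnnotation)):
        df = obj.table
        index = isinstance(obj, GeneAnnotation)
    elif isinstance(obj, pd.DataFrame):
        df, index = obj, True
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    df.to_csv(path, sep="\t", na_rep=_NA, index=index,
              index_label=df.index.name or ("gene_id" if index else None))
    log.info("wrote table %s (%d rows)", path, len(df))


def tpm_from_counts(counts: CountMatrix, lengths: pd.Series | dict,
                    *, zero_policy: str = "error") -> AbundanceMatrix:
    """Length-normalize counts to transcripts per million.

    Per sample: ``rate_g = count_g / length_g``; ``TPM_g = 1e6 * rate_g /
    sum(rate)``.  ``zero_policy`` controls all-zero columns: ``"error"``
    raises, ``"zero"`` leaves the column all zero.
    """
    lengths = pd.Series(lengths, dtype=float).reindex(counts.gene_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    rates = counts.data.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        if zero_policy == "error":
            raise ValueError(f"all-zero column {totals.index[zero_cols][0]!r}")
        totals = totals.replace(0, np.nan)
    tpm = rates.div(totals, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    return AbundanceMatrix(tpm, tpm_normalized=True)
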