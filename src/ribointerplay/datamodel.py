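"""Shared typed containers for the pipeline.

All tabular data is held in pandas objects wrapped by light dataclasses that
carry schema-level validation.  Gene identifiers are opaque strings (VNG-style
locus tags in fixtures); no genome coordinates are used anywhere.  Fold
changes are log2 throughout; abundances are TPM unless a table is explicitly
declared normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TIME_POINTS = ("TP1", "TP2", "TP3", "TP4")

REGULATORY_CLASSES = (
    "TC+", "TC-", "COMP+", "COMP-", "TL+", "TL-",
    "NR", "DISCORDANT", "NOT_ASSESSED",
)


class TableValidationError(ValueError):
    """A table violated a schema invariant; the message names the offending cell."""


@dataclass
class SampleDesign:
    """Sample sheet: one row per sample with time point, replicate and assay.

    ``assay`` is ``rna`` (RNA-seq), ``ribo`` (ribosome footprints) or
    ``protein`` (ribosome-enriched fraction intensities).
    """

    table: pd.DataFrame
    time_point_order: tuple[str, ...] = DEFAULT_TIME_POINTS
    reference_time_point: str = "TP1"

    REQUIRED = ("sample_id", "time_point", "replicate", "assay")

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise TableValidationError(f"design table missing columns {missing}")
        sid = self.table["sample_id"]
        if sid.duplicated().any():
            dup = sid[sid.duplicated()].iloc[0]
            raise TableValidationError(f"duplicate sample_id {dup!r}")
        bad_tp = set(self.table["time_point"]) - set(self.time_point_order)
        if bad_tp:
            raise TableValidationError(f"unknown time points {sorted(bad_tp)}")
        if (self.table["replicate"].astype(int) < 1).any():
            raise TableValidationError("replicate numbers must be positive")
        if self.reference_time_point not in set(self.table["time_point"]):
            raise TableValidationError(
                f"reference time point {self.reference_time_point} absent from design"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def time_points(self, assay: str | None = None) -> list[str]:
        tab = self.table if assay is None else self.table[self.table["assay"] == assay]
        present = set(tab["time_point"])
        return [tp for tp in self.time_point_order if tp in present]

    def samples_for(self, time_point: str, assay: str) -> list[str]:
        mask = (self.table["time_point"] == time_point) & (self.table["assay"] == assay)
        return list(self.table.loc[mask, "sample_id"])

    def subset(self, assay: str) -> "SampleDesign":
        return SampleDesign(
            self.table[self.table["assay"] == assay].copy(),
            self.time_point_order,
            self.reference_time_point,
        )


def _check_matrix(data: pd.DataFrame, what: str) -> pd.DataFrame:
    if data.index.duplicated().any():
        dup = data.index[data.index.duplicated()][0]
        raise TableValidationError(f"{what}: duplicate row identifier {dup!r}")
    if data.columns.duplicated().any():
        dup = data.columns[data.columns.duplicated()][0]
        raise TableValidationError(f"{what}: duplicate column identifier {dup!r}")
    if "." in data.index:
        raise TableValidationError(f"{what}: '.' is not a valid identifier")
    return data


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts for one assay."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_matrix(self.data, "CountMatrix")
        if self.data.size == 0:
            self.data = self.data.astype(np.int64)
            return
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableValidationError("CountMatrix: non-numeric entries")
        if np.isnan(arr.astype(float)).any():
            r, c = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise TableValidationError(
                f"CountMatrix: missing value at ({self.data.index[r]}, {self.data.columns[c]})"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise TableValidationError(
                f"CountMatrix: negative count at ({self.data.index[r]}, {self.data.columns[c]})"
            )
        if not np.allclose(arr, np.round(arr)):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise TableValidationError(
                f"CountMatrix: non-integer count at ({self.data.index[r]}, {self.data.columns[c]})"
            )
        self.data = self.data.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def check_design(self, design: SampleDesign) -> None:
        unknown = set(self.samples) - set(design.sample_ids)
        if unknown:
            raise TableValidationError(f"CountMatrix: samples not in design {sorted(unknown)}")


TPM_TOTAL = 1_000_000.0


@dataclass
class AbundanceMatrix:
    """Genes x samples non-negative real abundances (TPM by convention)."""

    data: pd.DataFrame
    tpm_normalized: bool = True

    def __post_init__(self) -> None:
        _check_matrix(self.data, "AbundanceMatrix")
        arr = self.data.to_numpy(dtype=float)
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise TableValidationError(
                f"AbundanceMatrix: negative value at ({self.data.index[r]}, {self.data.columns[c]})"
            )
        if self.tpm_normalized:
            sums = arr.sum(axis=0)
            ok = np.isclose(sums, TPM_TOTAL, rtol=1e-6) | (sums == 0)
            if not ok.all():
                j = int(np.argwhere(~ok)[0][0])
                raise TableValidationError(
                    f"AbundanceMatrix: column {self.data.columns[j]} sums to {sums[j]:.6g}, "
                    f"expected {TPM_TOTAL:g} for a TPM-normalized table"
                )
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GeneAnnotation:
    """Per-gene annotation: ribosomal-protein status/name and operon membership."""

    table: pd.DataFrame  # index gene_id; columns is_rp, rp_name, operon_id

    def __post_init__(self) -> None:
        _check_matrix(self.table, "GeneAnnotation")
        for col in ("is_rp",):
            if col not in self.table.columns:
                raise TableValidationError(f"GeneAnnotation missing column {col!r}")
        if "rp_name" not in self.table.columns:
            self.table["rp_name"] = pd.NA
        is_rp = self.table["is_rp"].astype(bool)
        has_name = self.table["rp_name"].notna()
        bad = is_rp != has_name
        if bad.any():
            g = self.table.index[bad][0]
            raise TableValidationError(
                f"GeneAnnotation: rp_name must be present iff is_rp (gene {g!r})"
            )

    @property
    def rp_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_rp"].astype(bool)])


@dataclass
class ProteinIntensityMatrix:
    """Proteins x samples intensities from the ribosome-enriched fraction."""

    data: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        _check_matrix(self.data, "ProteinIntensityMatrix")
        arr = self.data.to_numpy(dtype=float)
        if not np.isfinite(arr[~np.isnan(arr)]).all():
            raise TableValidationError("ProteinIntensityMatrix: non-finite intensity")
        if np.nanmin(arr) < 0:
            raise TableValidationError("ProteinIntensityMatrix: negative intensity")
        unknown = set(self.data.columns) - set(self.design.sample_ids)
        if unknown:
            raise TableValidationError(
                f"ProteinIntensityMatrix: samples not in design {sorted(unknown)}"
            )
        for tp in self.design.time_points():
            if not self.design.samples_for(tp, "protein"):
                raise TableValidationError(
                    f"ProteinIntensityMatrix: no replicate at time point {tp}"
                )


BAIT_ROLES = ("TBP", "TFB", "Bat", "other")


@dataclass
class EdgeList:
    """Directed bait -> prey interaction records with bait role annotation."""

    table: pd.DataFrame  # columns bait, prey, bait_role

    def __post_init__(self) -> None:
        for col in ("bait", "prey"):
            if col not in self.table.columns:
                raise TableValidationError(f"EdgeList missing column {col!r}")
        if "bait_role" not in self.table.columns:
            self.table = self.table.assign(bait_role="other")
        bad = set(self.table["bait_role"]) - set(BAIT_ROLES)
        if bad:
            raise TableValidationError(f"EdgeList: unknown bait roles {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    def deduplicated(self) -> "EdgeList":
        """Remove repeated (bait, prey) pairs, keeping the first record."""
        return EdgeList(self.table.drop_duplicates(subset=["bait", "prey"]).reset_index(drop=True))

    @property
    def n_edges(self) -> int:
        return len(self.table)


@dataclass
class CoremMembershipMatrix:
    """Binary genes x corems membership matrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_matrix(self.data, "CoremMembershipMatrix")
        arr = self.data.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            r, c = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise TableValidationError(
                f"CoremMembershipMatrix: non-binary entry at "
                f"({self.data.index[r]}, {self.data.columns[c]})"
            )
        self.data = self.data.astype(np.int8)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def corem_ids(self) -> list[str]:
        return list(self.data.columns)

    def drop_unassigned_genes(self) -> "CoremMembershipMatrix":
        """Genes present in no corem carry no clustering information; drop them."""
        keep = self.data.sum(axis=1) > 0
        return CoremMembershipMatrix(self.data.loc[keep].copy())
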