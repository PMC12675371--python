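"""Cohort data structures and file I/O.

The package works on two co-ordered tables:

* an expression matrix (genes x samples, TPM or normalized values), stored on
  disk as a tab-separated file whose first row is the sample header and whose
  first column holds gene symbols;
* a clinical table with one row per sample: sample ID, patient ID, overall
  survival time in months, an event indicator (1 = death observed, 0 =
  right-censored) and a timepoint label (``primary`` or ``recurrent``).

A :class:`Cohort` couples the two with identical sample order.  Patients may
own several samples (e.g. two recurrent resections), which matters for
patient-grouped cross-validation and for pooling patients along network paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CohortAssemblyError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: default clinical column names (consortium-export style); remappable.
DEFAULT_CLINICAL_COLUMNS = {
    "sample_id": "sample_barcode",
    "patient_id": "case_barcode",
    "time": "survival_months",
    "event": "event",
    "timepoint": "timepoint",
}

TIMEPOINTS = ("primary", "recurrent")


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of expression values.

    ``values`` holds TPM (non-negative) before normalization; after
    :func:`netsurv.preprocess.log_z_normalize` it holds real-valued z-scores
    and ``normalized`` is set.
    """

    gene_ids: pd.Index
    sample_ids: pd.Index
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        self.sample_ids = pd.Index(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.gene_ids.has_duplicates:
            dup = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dup[:5]}")
        if self.sample_ids.has_duplicates:
            dup = self.sample_ids[self.sample_ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dup[:5]}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if not self.normalized and (self.values < 0).any():
            raise ValidationError("TPM-stage expression matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = self.sample_ids.get_indexer(sample_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(list(sample_ids), idx) if i < 0]
            raise KeyError(f"unknown sample IDs: {missing[:5]}")
        return replace(self, sample_ids=pd.Index(sample_ids), values=self.values[:, idx])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.gene_ids.get_indexer(gene_ids)
        if (idx < 0).any():
            missing = [g for g, i in zip(list(gene_ids), idx) if i < 0]
            raise KeyError(f"unknown gene IDs: {missing[:5]}")
        return replace(self, gene_ids=pd.Index(gene_ids), values=self.values[idx, :])


@dataclass
class Cohort:
    """Expression matrix and clinical table with identical sample order."""

    expression: ExpressionMatrix
    clinical: pd.DataFrame  # columns: sample_id, patient_id, time, event, timepoint

    def __post_init__(self) -> None:
        if list(self.expression.sample_ids) != list(self.clinical["sample_id"]):
            raise CohortAssemblyError(
                "expression and clinical sample orders differ; use assemble_cohort()"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.sample_ids

    @property
    def patient_ids(self) -> pd.Index:
        return pd.Index(self.clinical["patient_id"].unique())

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    @property
    def n_patients(self) -> int:
        return self.clinical["patient_id"].nunique()

    def patient_table(self) -> pd.DataFrame:
        """One row per patient (first sample's outcome; outcomes are per patient)."""
        return (
            self.clinical.groupby("patient_id", sort=True)
            .first()
            .reset_index()[["patient_id", "time", "event"]]
        )

    def subset_samples(self, sample_ids) -> "Cohort":
        expr = self.expression.subset_samples(sample_ids)
        clin = (
            self.clinical.set_index("sample_id")
            .loc[list(sample_ids)]
            .reset_index()
        )
        return Cohort(expression=expr, clinical=clin)


def read_expression_matrix(path, sep: str = "\t") -> ExpressionMatrix:
    """Read a gene x sample expression table.

    The first row must be the sample header, the first column the gene symbol.
    Non-numeric cells raise :class:`FormatError` naming the offending line;
    negative values and duplicate gene/sample IDs raise
    :class:`ValidationError`.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any() or values.isna().to_numpy().any():
        isbad = (values.isna()).to_numpy()
        row = int(np.argwhere(isbad.any(axis=1))[0][0])
        col = int(np.argwhere(isbad[row])[0][0])
        # +2: one for the header line, one for 1-based line numbers
        raise FormatError(
            f"{path}: non-numeric cell {raw.iloc[row, col]!r} for gene "
            f"{raw.index[row]!r}, sample {raw.columns[col]!r} (line {row + 2})"
        )
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene IDs: {dup[:5]}")
    if (values.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative expression values")
    return ExpressionMatrix(
        gene_ids=raw.index, sample_ids=raw.columns, values=values.to_numpy()
    )


def write_expression_matrix(matrix: ExpressionMatrix, path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene")


def read_clinical_table(
    path, sep: str = "\t", columns: dict | None = None
) -> pd.DataFrame:
    """Read the per-sample clinical table.

    ``columns`` maps the canonical field names (sample_id, patient_id, time,
    event, timepoint) to the column names used in the file; defaults are the
    consortium-style names in :data:`DEFAULT_CLINICAL_COLUMNS`.  Rows with a
    missing required field are dropped (count logged).  ``time <= 0`` or an
    event indicator outside {0, 1} raise :class:`ValidationError`.
    """
    colmap = dict(DEFAULT_CLINICAL_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = [c for c in colmap.values() if c not in raw.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing clinical columns {missing_cols}")
    table = pd.DataFrame(
        {field: raw[src] for field, src in colmap.items()}
    )
    table = table.replace({"": np.nan})
    n_before = len(table)
    table = table.dropna(subset=list(colmap))
    n_dropped = n_before - len(table)
    if n_dropped:
        logger.info("read_clinical_table: dropped %d rows with missing fields", n_dropped)
    table["time"] = pd.to_numeric(table["time"], errors="raise")
    table["event"] = pd.to_numeric(table["event"], errors="raise")
    return validate_clinical(table.reset_index(drop=True))


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory clinical table (same contract as the reader)."""
    if (table["time"] <= 0).any():
        raise ValidationError("survival time must be > 0")
    if not table["event"].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0 or 1")
    table["event"] = table["event"].astype(int)
    table["timepoint"] = table["timepoint"].astype(str).str.lower()
    unknown = set(table["timepoint"]) - set(TIMEPOINTS)
    if unknown:
        raise ValidationError(f"unknown timepoint labels: {sorted(unknown)}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample IDs in clinical table: {dup[:5]}")
    return table


def write_clinical_table(
    table: pd.DataFrame, path, sep: str = "\t", columns: dict | None = None
) -> None:
    colmap = dict(DEFAULT_CLINICAL_COLUMNS)
    if columns:
        colmap.update(columns)
    out = table.rename(columns={k: v for k, v in colmap.items()})
    out.to_csv(path, sep=sep, index=False)


def assemble_cohort(expression: ExpressionMatrix, clinical: pd.DataFrame) -> Cohort:
    """Join expression and clinical data on their shared samples.

    Samples present on only one side are dropped (counts logged); the shared
    samples are ordered lexicographically so assembly is deterministic and
    idempotent.  An empty intersection raises :class:`CohortAssemblyError`.
    """
    clinical = validate_clinical(clinical.copy())
    expr_samples = set(expression.sample_ids)
    clin_samples = set(clinical["sample_id"])
    shared = sorted(expr_samples & clin_samples)
    if not shared:
        raise CohortAssemblyError("expression and clinical tables share no samples")
    n_expr_drop = len(expr_samples) - len(shared)
    n_clin_drop = len(clin_samples) - len(shared)
    if n_expr_drop or n_clin_drop:
        logger.info(
            "assemble_cohort: dropped %d expression-only and %d clinical-only samples",
            n_expr_drop,
            n_clin_drop,
        )
    expr = expression.subset_samples(shared)
    clin = clinical.set_index("sample_id").loc[shared].reset_index()
    return Cohort(expression=expr, clinical=clin)
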