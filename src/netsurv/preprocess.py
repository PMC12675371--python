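"""Gene filtering, normalization, cross-validation folds and the log-rank screen.

The preprocessing chain mirrors common practice for TPM expression cohorts
with right-censored outcomes: drop genes that are zero in more than a
configurable fraction of samples, log2(x+1)-transform, z-score per gene,
split patients (not samples) into cross-validation folds, and reduce
dimensionality with a univariate log-rank screen at the per-gene median cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._stats import logrank_two_group_batch
from .cohort import Cohort, ExpressionMatrix
from .errors import ConfigurationError, EmptyResultError

logger = logging.getLogger(__name__)


def filter_low_expression_genes(
    expr: ExpressionMatrix, zero_fraction_max: float = 0.8
) -> ExpressionMatrix:
    """Remove genes whose fraction of exactly-zero values exceeds the threshold.

    A gene is *retained* when ``fraction_zero <= zero_fraction_max`` (the
    boundary is kept: removal requires strictly more zeros than the
    threshold).  Gene order is preserved.
    """
    frac_zero = (expr.values == 0).mean(axis=1)
    keep = frac_zero <= zero_fraction_max
    if not keep.any():
        raise EmptyResultError("low-expression filter removed every gene")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_low_expression_genes: removed %d genes", n_removed)
    return replace(expr, gene_ids=expr.gene_ids[keep], values=expr.values[keep])


def log_z_normalize(expr: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """log2(x+1) transform followed by per-gene z-scoring.

    The SD uses ``ddof`` delta degrees of freedom (default 1, the sample SD;
    with three log2 values (0, 1, 2) this yields z-scores (-1, 0, 1)).
    Zero-variance genes become all-zero rows with a logged warning rather
    than NaNs, so constant genes stay representable downstream.
    """
    logged = np.log2(expr.values + 1.0)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if flat.any():
        logger.warning(
            "log_z_normalize: %d zero-variance genes set to all-zero rows",
            int(flat.sum()),
        )
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (logged - mean) / safe_sd
    z[flat, :] = 0.0
    return replace(expr, values=z, normalized=True)


@dataclass
class FoldSplit:
    """Patient-grouped cross-validation assignment.

    ``assignments`` maps patient_id -> fold index in 1..k; every sample of a
    patient inherits the patient's fold, so no patient straddles the
    train/test boundary.
    """

    k: int
    assignments: dict[str, int]

    def patient_fold(self, patient_id: str) -> int:
        return self.assignments[patient_id]

    def sample_folds(self, clinical: pd.DataFrame) -> np.ndarray:
        return clinical["patient_id"].map(self.assignments).to_numpy()

    def train_test_samples(self, clinical: pd.DataFrame, fold: int):
        """Sample-ID lists (train, test) for one fold."""
        folds = self.sample_folds(clinical)
        samples = clinical["sample_id"].to_numpy()
        return list(samples[folds != fold]), list(samples[folds == fold])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignments.items()), columns=["patient_id", "fold"]
        )


def make_patient_folds(cohort: Cohort, k: int = 5, seed: int = 0) -> FoldSplit:
    """Randomly partition patients into k folds of near-equal size.

    Patients are sorted before shuffling, so the split depends only on the
    seed and the patient set, not on sample order.  Fold sizes differ by at
    most one patient.
    """
    patients = sorted(cohort.clinical["patient_id"].unique())
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > len(patients):
        raise ConfigurationError(
            f"k={k} folds requested but only {len(patients)} patients available"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    assignments: dict[str, int] = {}
    for fold_idx, chunk in enumerate(np.array_split(order, k), start=1):
        for j in chunk:
            assignments[patients[j]] = fold_idx
    return FoldSplit(k=k, assignments=assignments)


def median_dichotomize(values: np.ndarray) -> np.ndarray:
    """Binary high/low split at the median (values equal to the median -> low)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("median_dichotomize needs at least 2 values")
    return values > np.median(values)


def logrank_screen(train: Cohort, top_n: int = 1000) -> pd.DataFrame:
    """Univariate log-rank screen over all genes of a (normalized) cohort.

    Each gene is dichotomized at its median across the training samples and
    tested with a two-group log-rank test.  Genes whose dichotomization
    leaves a group empty (constant genes) get p = 1 by convention.  Genes are
    ranked ascending by p, ties broken by descending statistic then gene ID;
    the ``selected`` flag marks the ``top_n`` best ranks.

    Returns a DataFrame with columns gene, statistic, p, rank, selected.
    """
    if top_n < 1:
        raise ConfigurationError("top_n must be >= 1")
    expr = train.expression
    medians = np.median(expr.values, axis=1, keepdims=True)
    high = (expr.values > medians).T  # samples x genes
    time = train.clinical["time"].to_numpy(float)
    event = train.clinical["event"].to_numpy(int)
    chi2, p = logrank_two_group_batch(high, time, event)
    # empty high or low group -> untestable -> p = 1 (already 0-variance, but
    # make the convention explicit)
    group_sizes = high.sum(axis=0)
    degenerate = (group_sizes == 0) | (group_sizes == high.shape[0])
    chi2[degenerate] = 0.0
    p[degenerate] = 1.0

    table = pd.DataFrame({"gene": expr.gene_ids, "statistic": chi2, "p": p})
    table = table.sort_values(
        ["p", "statistic", "gene"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["selected"] = table["rank"] <= min(top_n, len(table))
    return table
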