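"""Synthetic expression/survival cohort generator with planted ground truth.

The generator emulates the structure of a longitudinal glioma expression
cohort: ~158 patients contributing ~180 recurrent tumor samples (a few
patients have two resections), >= hundreds to thousands of genes with
log-normal TPM background, ~11% right-censoring, a minority of genes with
true survival effects, and optional paired primary/recurrent samples with
planted differential expression.

Survival times follow the log-normal accelerated failure time model

    log T = b0 + sum_g beta*_g x_g + sigma* W,

where x_g is the z-scored (patient-level) log2 expression of a planted
prognostic gene.  Prognostic genes are over-expressed in a shared *patient
block*, which (a) gives those patients systematically shorter or longer
survival and (b) makes the planted genes' extreme-expression clusters share
patients, so the network stage has edges to discover by construction.
Censoring is independent Uniform(0, c) with c calibrated numerically to the
requested censoring fraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Cohort, ExpressionMatrix
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated cohort: 158 patients / 180 recurrent
    samples, 11.1% censoring, log-normal AFT survival with scale 0.567 and
    a median survival of exp(3.25) ~ 25.8 months at baseline.
    ``n_genes`` defaults to 2,000 (stress-scale runs can raise it to
    20,000); planted prognostic genes share one patient block of
    ``block_size`` patients over-expressed by ``block_shift`` log2 units.
    """

    n_patients: int = 158
    n_samples: int = 180
    n_genes: int = 2000
    n_prognostic: int = 3
    prognostic_beta: float = -0.25     # AFT effect per planted gene (z-scale)
    intercept: float = 3.25            # baseline mean log survival time (months)
    scale: float = 0.567               # AFT sigma*
    censoring_fraction: float = 0.111
    block_size: int = 25               # patients sharing extreme expression
    block_shift: float = 2.5           # log2 over-expression of block patients
    baseline_log2_range: tuple[float, float] = (1.0, 6.0)
    noise_sd: float = 1.0              # per-sample log2 noise
    replicate_sd: float = 0.3          # extra noise between samples of a patient
    low_expression_fraction: float = 0.05  # genes that are mostly zeros
    low_expression_zero_prob: float = 0.9
    # paired-cohort settings
    recurrent_fraction: float = 0.6    # patients with a paired recurrent sample
    n_recurrence_shift: int = 0
    recurrence_shift: float = 1.0      # log2 offset planted in recurrent samples

    def validate(self) -> "SimConfig":
        if self.n_samples < self.n_patients:
            raise ConfigurationError("n_samples must be >= n_patients")
        if self.n_prognostic > self.n_genes or self.n_recurrence_shift > self.n_genes:
            raise ConfigurationError("planted gene counts exceed n_genes")
        if not 0 <= self.censoring_fraction < 1:
            raise ConfigurationError("censoring_fraction must be in [0, 1)")
        if self.block_size > self.n_patients:
            raise ConfigurationError("block_size exceeds n_patients")
        return self


@dataclass
class SimTruth:
    """Planted ground truth of a generated cohort."""

    prognostic: dict[str, float]          # gene -> beta*
    block_patients: list[str]
    shifted: dict[str, float] = field(default_factory=dict)  # gene -> log2 shift
    censoring_upper: float = np.inf
    achieved_censoring: float = 0.0


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _calibrate_censoring(t_true: np.ndarray, fraction: float):
    """Upper bound c of Uniform(0, c) censoring hitting the target fraction.

    For C ~ U(0, c) the expected censored fraction over the realized event
    times is mean(min(T_i / c, 1)), monotone decreasing in c; solved with
    brentq.  Returns (c, expected_fraction_at_c).
    """
    if fraction <= 0:
        return np.inf, 0.0

    def expected(c):
        return float(np.minimum(t_true / c, 1.0).mean())

    lo, hi = t_true.min() * 1e-3, t_true.max() * 1e4
    if expected(hi) > fraction:  # cannot censor this little
        warnings.warn(
            f"censoring calibration infeasible; achieved {expected(hi):.3f}"
        )
        return hi, expected(hi)
    c = brentq(lambda x: expected(x) - fraction, lo, hi)
    return float(c), float(expected(c))


def _patient_log2_matrix(config: SimConfig, rng: np.random.Generator):
    """Per-patient log2 expression (genes x patients) with planted structure."""
    genes = _gene_ids(config.n_genes)
    baseline = rng.uniform(*config.baseline_log2_range, size=config.n_genes)
    values = baseline[:, None] + config.noise_sd * rng.normal(
        size=(config.n_genes, config.n_patients)
    )
    block = rng.choice(config.n_patients, size=config.block_size, replace=False)
    prognostic_idx = np.arange(config.n_prognostic)
    values[np.ix_(prognostic_idx, block)] += config.block_shift
    return genes, values, block, prognostic_idx


def _survival_from_expression(
    values: np.ndarray, prognostic_idx: np.ndarray, config: SimConfig,
    rng: np.random.Generator,
):
    """Log-normal AFT event times driven by the planted genes' z-scores."""
    eta = np.full(values.shape[1], config.intercept)
    for gi in prognostic_idx:
        row = values[gi]
        z = (row - row.mean()) / row.std(ddof=1)
        eta += config.prognostic_beta * z
    t_true = np.exp(eta + config.scale * rng.normal(size=values.shape[1]))
    c_upper, expected = _calibrate_censoring(t_true, config.censoring_fraction)
    if np.isfinite(c_upper):
        censor = rng.uniform(0.0, c_upper, size=t_true.size)
        time = np.minimum(t_true, censor)
        event = (t_true <= censor).astype(int)
    else:
        time, event = t_true, np.ones(t_true.size, dtype=int)
    return time, event, c_upper


def _to_tpm(log2_values: np.ndarray) -> np.ndarray:
    return np.clip(np.exp2(log2_values) - 1.0, 0.0, None)


def _zero_inflate(tpm: np.ndarray, config: SimConfig, rng: np.random.Generator):
    """Make the last genes mostly zero so the low-expression filter has work."""
    n_low = int(config.low_expression_fraction * tpm.shape[0])
    if n_low == 0:
        return
    low_idx = np.arange(tpm.shape[0] - n_low, tpm.shape[0])
    mask = rng.random(size=(n_low, tpm.shape[1])) < config.low_expression_zero_prob
    tpm[low_idx] = np.where(mask, 0.0, tpm[low_idx])


def generate_cohort(config: SimConfig | None = None, seed: int = 0):
    """Generate a recurrent-sample cohort with planted survival truth.

    Returns ``(cohort, truth)``.  Patients beyond ``n_patients`` sample
    slots are reused: the first ``n_samples - n_patients`` patients
    contribute a second recurrent sample whose expression is the patient
    value plus replicate noise.  Identical seeds give bit-identical output.
    """
    config = (config or SimConfig()).validate()
    rng = np.random.default_rng(seed)
    genes, values, block, prognostic_idx = _patient_log2_matrix(config, rng)
    time, event, c_upper = _survival_from_expression(
        values, prognostic_idx, config, rng
    )
    patients = [f"PT{i:04d}" for i in range(config.n_patients)]

    n_extra = config.n_samples - config.n_patients
    sample_patient_idx = list(range(config.n_patients)) + list(range(n_extra))
    sample_ids, sample_cols = [], []
    counters: dict[int, int] = {}
    for pidx in sample_patient_idx:
        k = counters.get(pidx, 0)
        counters[pidx] = k + 1
        sample_ids.append(f"{patients[pidx]}-R{k + 1}")
        col = values[:, pidx]
        if k > 0:
            col = col + config.replicate_sd * rng.normal(size=config.n_genes)
        sample_cols.append(col)
    log2_samples = np.column_stack(sample_cols)
    tpm = _to_tpm(log2_samples)
    _zero_inflate(tpm, config, rng)

    order = np.argsort(sample_ids)
    expr = ExpressionMatrix(
        gene_ids=pd.Index(genes),
        sample_ids=pd.Index(np.array(sample_ids)[order]),
        values=tpm[:, order],
    )
    clinical = pd.DataFrame(
        {
            "sample_id": np.array(sample_ids)[order],
            "patient_id": [patients[sample_patient_idx[i]] for i in order],
            "time": time[[sample_patient_idx[i] for i in order]],
            "event": event[[sample_patient_idx[i] for i in order]],
            "timepoint": "recurrent",
        }
    )
    cohort = Cohort(expression=expr, clinical=clinical)
    achieved = 1.0 - clinical.groupby("patient_id")["event"].first().mean()
    truth = SimTruth(
        prognostic={genes[i]: config.prognostic_beta for i in prognostic_idx},
        block_patients=[patients[i] for i in sorted(block)],
        censoring_upper=c_upper,
        achieved_censoring=float(achieved),
    )
    return cohort, truth


def generate_paired_samples(config: SimConfig | None = None, seed: int = 0):
    """Generate a cohort with primary samples and paired recurrent samples.

    Every patient contributes a primary sample; a ``recurrent_fraction``
    subset additionally contributes a recurrent sample in which the first
    ``n_recurrence_shift`` genes are offset by ``recurrence_shift`` log2
    units.  Returns ``(cohort, truth)``.
    """
    config = (config or SimConfig()).validate()
    rng = np.random.default_rng(seed)
    genes, values, block, prognostic_idx = _patient_log2_matrix(config, rng)
    time, event, c_upper = _survival_from_expression(
        values, prognostic_idx, config, rng
    )
    patients = [f"PT{i:04d}" for i in range(config.n_patients)]
    n_recurrent = int(round(config.recurrent_fraction * config.n_patients))
    recurrent_patients = rng.choice(config.n_patients, n_recurrent, replace=False)

    shift_idx = np.arange(config.n_recurrence_shift)
    sample_ids, cols, rows = [], [], []
    for pidx in range(config.n_patients):
        sample_ids.append(f"{patients[pidx]}-P1")
        cols.append(values[:, pidx])
        rows.append((pidx, "primary"))
    for pidx in sorted(recurrent_patients):
        col = values[:, pidx] + config.replicate_sd * rng.normal(size=config.n_genes)
        col = col.copy()
        col[shift_idx] += config.recurrence_shift
        sample_ids.append(f"{patients[pidx]}-R1")
        cols.append(col)
        rows.append((pidx, "recurrent"))

    tpm = _to_tpm(np.column_stack(cols))
    _zero_inflate(tpm, config, rng)
    order = np.argsort(sample_ids)
    expr = ExpressionMatrix(
        gene_ids=pd.Index(genes),
        sample_ids=pd.Index(np.array(sample_ids)[order]),
        values=tpm[:, order],
    )
    clinical = pd.DataFrame(
        {
            "sample_id": np.array(sample_ids)[order],
            "patient_id": [patients[rows[i][0]] for i in order],
            "time": time[[rows[i][0] for i in order]],
            "event": event[[rows[i][0] for i in order]],
            "timepoint": [rows[i][1] for i in order],
        }
    )
    cohort = Cohort(expression=expr, clinical=clinical)
    truth = SimTruth(
        prognostic={genes[i]: config.prognostic_beta for i in prognostic_idx},
        block_patients=[patients[i] for i in sorted(block)],
        shifted={genes[i]: config.recurrence_shift for i in shift_idx},
        censoring_upper=c_upper,
        achieved_censoring=float(
            1.0 - clinical.groupby("patient_id")["event"].first().mean()
        ),
    )
    return cohort, truth


def simulate_aft_data(
    n: int,
    beta,
    sigma: float,
    censoring_fraction: float = 0.111,
    intercept: float = 3.25,
    seed: int = 0,
):
    """Plain log-normal AFT data with standard-normal covariates.

    Returns ``(X, time, event)`` with log T = intercept + X beta + sigma W
    and Uniform(0, c) censoring calibrated to the requested fraction; used
    for parameter-recovery and family-selection experiments.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, float)
    X = rng.normal(size=(n, beta.size))
    t_true = np.exp(intercept + X @ beta + sigma * rng.normal(size=n))
    c_upper, _ = _calibrate_censoring(t_true, censoring_fraction)
    if np.isfinite(c_upper):
        censor = rng.uniform(0.0, c_upper, size=n)
        time = np.minimum(t_true, censor)
        event = (t_true <= censor).astype(int)
    else:
        time, event = t_true, np.ones(n, dtype=int)
    return X, time, event
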