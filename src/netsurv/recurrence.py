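"""Primary-vs-recurrent expression comparison with Wilcoxon rank tests.

For each candidate gene the screen runs an unpaired Wilcoxon rank-sum
(Mann-Whitney) test over all primary vs all recurrent samples and a paired
Wilcoxon signed-rank test over matched primary/recurrent samples of the
same patient, both two-sided on log2(TPM + 1) values (a common scale across
samples; per-set z-scores would erase group shifts).  P-values are
BH-corrected per test across genes, and a gene is flagged when both
q-values fall below the threshold.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import benjamini_hochberg
from .cohort import Cohort
from .errors import ValidationError

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 25


def _has_ties(values) -> bool:
    values = np.asarray(values, float)
    return np.unique(values).size < values.size


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U of x, p).

    Exact null distribution when the smaller sample has at most 25
    observations and there are no ties across the pooled sample; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both samples must be non-empty")
    exact = min(x.size, y.size) <= _EXACT_MAX_N and not _has_ties(np.r_[x, y])
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(differences) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired differences; returns (W+, p).

    Zero differences are dropped; if all differences are zero the degenerate
    contract output (statistic 0, p = 1) is returned with a warning.  The
    null is exact for at most 25 informative pairs without tied |difference|,
    otherwise normal approximation with continuity correction.
    """
    d = np.asarray(differences, float)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; returning (0, 1)")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    exact = d.size <= _EXACT_MAX_N and not _has_ties(np.abs(d))
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        alternative="two-sided",
        method="exact" if exact else "approx",
        correction=not exact,
    )
    return w_plus, float(res.pvalue)


def paired_samples(clinical: pd.DataFrame) -> pd.DataFrame:
    """Matched (primary, recurrent) sample pairs, one per patient.

    Patients with several samples at a timepoint contribute their earliest
    sample (lowest sample ID, a proxy for resection order; logged).
    """
    rows = []
    n_multi = 0
    for patient, sub in clinical.groupby("patient_id", sort=True):
        by_tp = {}
        for tp in ("primary", "recurrent"):
            ids = sorted(sub.loc[sub["timepoint"] == tp, "sample_id"])
            if len(ids) > 1:
                n_multi += 1
            if ids:
                by_tp[tp] = ids[0]
        if len(by_tp) == 2:
            rows.append(
                {
                    "patient_id": patient,
                    "primary_sample": by_tp["primary"],
                    "recurrent_sample": by_tp["recurrent"],
                }
            )
    if n_multi:
        logger.info(
            "paired_samples: %d patient/timepoint groups had multiple samples; "
            "kept the earliest by sample ID",
            n_multi,
        )
    return pd.DataFrame(rows, columns=["patient_id", "primary_sample", "recurrent_sample"])


def recurrence_screen(
    cohort: Cohort, genes=None, q_max: float = 0.05, use_raw_p: bool = False
) -> pd.DataFrame:
    """Unpaired and paired Wilcoxon screen of primary vs recurrent expression.

    Returns a table with columns gene, unpaired_stat, unpaired_p,
    unpaired_q, paired_stat, paired_p, paired_q, significant_both.  With
    ``use_raw_p`` the significance flags use raw p-values instead of BH q.
    """
    genes = list(genes) if genes is not None else list(cohort.expression.gene_ids)
    clin = cohort.clinical
    tp = clin["timepoint"].to_numpy()
    if not {"primary", "recurrent"} <= set(tp):
        raise ValidationError("cohort must contain both primary and recurrent samples")
    expr = np.log2(cohort.expression.subset_genes(genes).values + 1.0)
    sample_pos = {s: i for i, s in enumerate(cohort.sample_ids)}
    primary_idx = np.flatnonzero(tp == "primary")
    recurrent_idx = np.flatnonzero(tp == "recurrent")

    pairs = paired_samples(clin)
    if pairs.empty:
        warnings.warn("no patients with both timepoints; paired columns empty")
    p_idx = [sample_pos[s] for s in pairs["primary_sample"]]
    r_idx = [sample_pos[s] for s in pairs["recurrent_sample"]]

    rows = []
    for gi, gene in enumerate(genes):
        u_stat, u_p = wilcoxon_rank_sum(expr[gi, primary_idx], expr[gi, recurrent_idx])
        if pairs.empty:
            w_stat, w_p = np.nan, np.nan
        else:
            diffs = expr[gi, r_idx] - expr[gi, p_idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w_stat, w_p = wilcoxon_signed_rank(diffs)
        rows.append(
            {"gene": gene, "unpaired_stat": u_stat, "unpaired_p": u_p,
             "paired_stat": w_stat, "paired_p": w_p}
        )
    table = pd.DataFrame(rows)
    table["unpaired_q"] = benjamini_hochberg(table["unpaired_p"].to_numpy())
    if table["paired_p"].notna().all():
        table["paired_q"] = benjamini_hochberg(table["paired_p"].to_numpy())
    else:
        table["paired_q"] = np.nan
    u_col, p_col = ("unpaired_p", "paired_p") if use_raw_p else ("unpaired_q", "paired_q")
    table["significant_both"] = (table[u_col] < q_max) & (table[p_col] < q_max)
    return table[
        ["gene", "unpaired_stat", "unpaired_p", "unpaired_q",
         "paired_stat", "paired_p", "paired_q", "significant_both"]
    ]
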