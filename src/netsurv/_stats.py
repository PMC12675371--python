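"""Internal vectorized survival statistics.

The gene screen tests every gene and the network stage tests tens of
thousands of walk paths; both reduce to two-group log-rank tests that differ
only in the group-membership vector.  ``logrank_two_group_batch`` computes
all of them in one pass over the risk sets (O(n * m) with numpy), and is
asserted equal to the lifelines log-rank test in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def logrank_two_group_batch(
    membership: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-group log-rank chi-square and p for many membership vectors.

    Parameters
    ----------
    membership:
        Boolean array of shape ``(n_subjects, n_tests)``; column ``k`` marks
        the subjects in group 1 of test ``k`` (group 0 is the complement).
    time, event:
        Observed times and event indicators, length ``n_subjects``.

    Returns
    -------
    (chi2, p):
        Arrays of length ``n_tests``.  A test whose log-rank variance is zero
        (e.g. one group empty, or no events) gets ``chi2 = 0``, ``p = 1``.
    """
    membership = np.asarray(membership, dtype=bool)
    if membership.ndim == 1:
        membership = membership[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = time.shape[0]
    if membership.shape[0] != n:
        raise ValueError("membership rows must match number of subjects")

    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    m_sorted = membership[order].astype(np.float64)

    # block starts of distinct times (risk set at t_j = rows starts[j]..n-1)
    starts = np.flatnonzero(np.r_[True, t_sorted[1:] != t_sorted[:-1]])
    n_at_risk = (n - starts).astype(np.float64)

    # events per distinct time (total and within group 1, per test)
    d_total = np.add.reduceat(e_sorted.astype(np.float64), starts)
    d1 = np.add.reduceat(m_sorted * e_sorted[:, None], starts, axis=0)

    # group-1 at-risk counts: suffix sums of membership at each block start
    suffix = np.cumsum(m_sorted[::-1], axis=0)[::-1]
    n1_at_risk = suffix[starts]

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n1_at_risk / n_at_risk[:, None]
        observed_minus_expected = (d1 - d_total[:, None] * frac).sum(axis=0)
        var_term = (
            d_total[:, None]
            * frac
            * (1.0 - frac)
            * ((n_at_risk - d_total) / np.maximum(n_at_risk - 1.0, 1.0))[:, None]
        )
        # a block with a single subject at risk contributes no variance
        var_term[n_at_risk <= 1, :] = 0.0
        variance = var_term.sum(axis=0)

    chi2 = np.zeros(membership.shape[1])
    ok = variance > 0
    chi2[ok] = observed_minus_expected[ok] ** 2 / variance[ok]
    p = np.ones_like(chi2)
    p[ok] = stats.chi2.sf(chi2[ok], df=1)
    return chi2, p


def logrank_two_group(
    membership: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, float]:
    """Scalar convenience wrapper around :func:`logrank_two_group_batch`."""
    chi2, p = logrank_two_group_batch(np.asarray(membership)[:, None], time, event)
    return float(chi2[0]), float(p[0])


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (delegates to statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
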