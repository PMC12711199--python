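"""Vectorized two-group Mantel-Haenszel log-rank test.

The permutation screen evaluates on the order of 10^5-10^7 log-rank tests
per run (genes x gradients x permutations), all sharing one (time, event)
vector per drawn subset.  The statistic is therefore computed for a whole
block of group-label vectors at once: at each distinct death time t with d
deaths and n subjects at risk, the group-1 contribution is

    O1 - E1 = d1 - d * n1 / n
    V       = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)

summed over death times; (O1 - E1)^2 / V is chi-square on 1 df.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def logrank_pvalues(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log-rank p-values for many binary groupings of one cohort.

    Parameters
    ----------
    time, event
        Follow-up times (> 0) and event indicators (1 = event), length n.
    groups
        Boolean array (G, n); ``True`` marks membership of group 1.  Each row
        is an independent two-group comparison on the same subjects.

    Returns
    -------
    pvalues : (G,) float array; ``nan`` where the test is undefined.
    valid : (G,) bool array; ``False`` when a group is empty or the variance
        of the statistic is zero (e.g. no events), in which case the caller
        should treat the test as non-significant.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=np.int64)
    groups = np.atleast_2d(np.asarray(groups, dtype=bool))
    n = time.size
    if groups.shape[1] != n:
        raise ValueError("groups must have one column per subject")

    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    z = groups[:, order].astype(np.int64)

    # distinct-time block boundaries in the sorted order
    starts = np.flatnonzero(np.r_[True, t_sorted[1:] != t_sorted[:-1]])
    n_at_risk = (n - starts).astype(float)
    deaths = np.add.reduceat(e_sorted, starts).astype(float)

    # group-1 at-risk counts at each distinct time: suffix sums of z
    csum = np.cumsum(z, axis=1)
    total1 = csum[:, -1][:, None].astype(float)
    before = np.zeros((z.shape[0], starts.size))
    nz = starts > 0
    before[:, nz] = csum[:, starts[nz] - 1]
    n1_at_risk = total1 - before

    d1 = np.add.reduceat(e_sorted[None, :] * z, starts, axis=1).astype(float)

    death_times = deaths > 0
    d = deaths[death_times]
    n_r = n_at_risk[death_times]
    n1 = n1_at_risk[:, death_times]
    d1 = d1[:, death_times]

    frac = n1 / n_r
    observed_minus_expected = (d1 - d * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = d * frac * (1.0 - frac) * (n_r - d) / (n_r - 1.0)
    var_terms = np.where(n_r > 1.0, var_terms, 0.0)
    variance = var_terms.sum(axis=1)

    group1_size = total1[:, 0]
    valid = (group1_size > 0) & (group1_size < n) & (variance > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        statistic = observed_minus_expected**2 / variance
    pvalues = np.full(groups.shape[0], np.nan)
    pvalues[valid] = stats.chi2.sf(statistic[valid], df=1)
    return pvalues, valid


def logrank_pvalue(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """Scalar log-rank p-value for one binary grouping.

    Raises ``ValueError`` when the test is undefined (a group is empty or no
    events occur), mirroring the vectorized routine's ``valid`` mask.
    """
    p, valid = logrank_pvalues(time, event, np.asarray(group, dtype=bool)[None, :])
    if not valid[0]:
        raise ValueError("log-rank test undefined: empty group or zero variance")
    return float(p[0])
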