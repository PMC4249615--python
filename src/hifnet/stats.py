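"""Small statistical helpers shared across modules.

Welch's unequal-variance t-test (vectorized over probe rows) and the standard
multiple-testing corrections.  These wrap scipy/statsmodels; the only local
logic is the handling of degenerate rows (zero variance in both groups), which
are reported as t=0, p=1 rather than NaN so they are cleanly non-significant.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["welch_rows", "bh_adjust", "bonferroni_adjust"]


def welch_rows(case: np.ndarray, rest: np.ndarray):
    """Row-wise Welch two-sample t-test.

    Parameters
    ----------
    case, rest : 2-D arrays with matching row counts (rows x samples).

    Returns
    -------
    t, p, delta : 1-D arrays; ``delta`` is ``mean(case) - mean(rest)`` per row.
    """
    case = np.atleast_2d(np.asarray(case, dtype=float))
    rest = np.atleast_2d(np.asarray(rest, dtype=float))
    if case.shape[1] < 2 or rest.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    res = sps.ttest_ind(case, rest, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    p[bad] = 1.0
    delta = case.mean(axis=1) - rest.mean(axis=1)
    return t, p, delta


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.minimum(p * p.size, 1.0)
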