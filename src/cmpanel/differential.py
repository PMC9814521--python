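"""Per-protein case-control differential abundance screening.

Each protein is tested with a two-sample Welch t-test on log2 intensities
(one quantified value per subject per trimester, trimesters analyzed
separately, so a per-protein two-group comparison is the full model).  A
protein is called significant when the linear-scale fold change is at least
2 (|log2FC| >= 1, threshold inclusive) AND the Benjamini-Hochberg adjusted
p-value is below 0.05.  Missing cells are handled pairwise-complete; proteins
with fewer than two non-missing values in either arm are flagged untestable
and excluded from the multiplicity correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AbundanceMatrix
from .errors import AlignmentError

__all__ = ["benjamini_hochberg", "differential_test", "FOLD_CHANGE_LOG2", "ALPHA"]

FOLD_CHANGE_LOG2 = 1.0  # linear fold change of 2
ALPHA = 0.05
_MIN_PER_ARM = 2


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorts the m raw p-values, multiplies the i-th smallest by m/i, enforces
    monotonicity by a cumulative minimum from the largest rank down, clips at
    1, and returns values in the original input order.

    Raises
    ------
    ValueError
        If any input lies outside [0, 1] or is not finite.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def differential_test(matrix: AbundanceMatrix, cohort: pd.DataFrame) -> pd.DataFrame:
    """Welch-t differential screen of every testable protein.

    Parameters
    ----------
    matrix : AbundanceMatrix
        log2 intensities for one trimester.
    cohort : pandas.DataFrame
        Clinical table supplying case/control status per sample_id.

    Returns
    -------
    pandas.DataFrame
        One row per protein: ``protein_id, log2fc, p, adj_p, significant,
        testable``.  ``log2fc`` is the case-minus-control mean difference on
        the log2 scale; untestable proteins carry NaN statistics and never
        enter the BH correction.
    """
    status = cohort.drop_duplicates("sample_id").set_index("sample_id")["status"]
    common = [s for s in matrix.sample_ids if s in status.index]
    if not common:
        raise AlignmentError(
            "no overlap between abundance sample_ids and clinical sample_ids"
        )
    idx = [matrix.sample_ids.index(s) for s in common]
    values = matrix.values[idx, :]
    is_case = (status.loc[common] == "case").to_numpy()

    case_vals = values[is_case, :]
    ctrl_vals = values[~is_case, :]
    n_case = (~np.isnan(case_vals)).sum(axis=0)
    n_ctrl = (~np.isnan(ctrl_vals)).sum(axis=0)
    testable = (n_case >= _MIN_PER_ARM) & (n_ctrl >= _MIN_PER_ARM)

    log2fc = np.full(len(matrix.protein_ids), np.nan)
    pvals = np.full(len(matrix.protein_ids), np.nan)
    if testable.any():
        with np.errstate(invalid="ignore"):
            mc = np.nanmean(case_vals[:, testable], axis=0)
            mx = np.nanmean(ctrl_vals[:, testable], axis=0)
            res = stats.ttest_ind(
                case_vals[:, testable],
                ctrl_vals[:, testable],
                equal_var=False,
                nan_policy="omit",
                axis=0,
            )
        log2fc[testable] = mc - mx
        pvals[testable] = res.pvalue

    adj = np.full_like(pvals, np.nan)
    adj[testable] = benjamini_hochberg(pvals[testable])
    significant = testable & (np.abs(log2fc) >= FOLD_CHANGE_LOG2) & (adj < ALPHA)
    return pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "log2fc": log2fc,
            "p": pvals,
            "adj_p": adj,
            "significant": significant,
            "testable": testable,
        }
    )
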