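"""Descriptive cohort statistics and univariate case-control comparisons.

Continuous covariates are summarized as median (IQR) per arm and compared
with a two-sided Wilcoxon rank-sum test; categorical covariates as n (%) per
arm with a Pearson chi-square test (no continuity correction by default,
matching the plain Pearson statistic).  Among cases the report also derives
the per-grade antenatal ultrasound detection rate, the fraction with neither
prior cesarean nor previa, and the fraction whose grade was determined by
clinical criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError

__all__ = ["SummaryReport", "summarize_cohort", "chi_square_2x2", "wilcoxon_rank_sum"]

_EXACT_WILCOXON_MAX_N = 25


def chi_square_2x2(a: int, b: int, c: int, d: int, correction: bool = False):
    """Pearson chi-square test on the 2x2 table [[a, b], [c, d]].

    Returns ``(statistic, p_value)`` with df = 1 and a two-sided p.  Yates
    continuity correction is off by default.

    Raises
    ------
    DegenerateTableError
        If any row or column margin is zero.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() <= 0:
        raise ValueError("grand total must be positive")
    _check_margins(table)
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def _check_margins(table: np.ndarray) -> None:
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise DegenerateTableError(
            f"contingency table has a zero margin: {table.astype(int).tolist()}"
        )


def _chi_square_table(table: np.ndarray, correction: bool = False):
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError(
            "contingency table needs at least two levels on each axis"
        )
    _check_margins(table)
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both arms have <= 25 untied observations, otherwise
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    pooled = np.concatenate([x, y])
    if len(pooled) and np.all(pooled == pooled[0]):
        # every value tied: the statistic equals its null expectation
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(x), len(y)) <= _EXACT_WILCOXON_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def _median_iqr(v: pd.Series) -> str:
    v = v.dropna().astype(float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _pct(n: int, total: int) -> float:
    return round(100.0 * n / total, 1) if total else float("nan")


@dataclass
class SummaryReport:
    """Per-variable comparison rows plus case-only derived proportions.

    ``rows`` columns: variable, case, control, test, statistic, p_value,
    degenerate (True when a zero-margin table made the test undefined; the
    test is then skipped, not raised).
    """

    rows: pd.DataFrame
    derived: dict

    def to_dict(self) -> dict:
        return {
            "rows": self.rows.to_dict(orient="records"),
            "derived": self.derived,
        }


def _cesarean_bin(n: int) -> str:
    return "0" if n == 0 else ("1" if n == 1 else ">=2")


def summarize_cohort(cohort: pd.DataFrame) -> SummaryReport:
    """Build the case-vs-control summary from a clinical table.

    The clinical table has one row per sample (two draws per subject);
    subject-level covariates are deduplicated to one row per subject before
    testing.  Requires at least one case and one control.
    """
    subjects = cohort.drop_duplicates("subject_id")
    cases = subjects[subjects["status"] == "case"]
    controls = subjects[subjects["status"] == "control"]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("cohort must contain at least one case and one control")

    rows = []

    def add_continuous(name: str, case_v, ctrl_v):
        stat, p = wilcoxon_rank_sum(case_v, ctrl_v)
        rows.append(
            {
                "variable": name,
                "case": _median_iqr(case_v),
                "control": _median_iqr(ctrl_v),
                "test": "wilcoxon-rank-sum",
                "statistic": stat,
                "p_value": p,
                "degenerate": False,
            }
        )

    def add_categorical(name: str, case_counts: dict, ctrl_counts: dict):
        levels = sorted(set(case_counts) | set(ctrl_counts))
        table = np.array(
            [
                [case_counts.get(l, 0) for l in levels],
                [ctrl_counts.get(l, 0) for l in levels],
            ],
            dtype=float,
        )
        # drop all-zero levels; a remaining zero margin flags the row instead
        table = table[:, table.sum(axis=0) > 0]
        fmt = lambda counts, total: "; ".join(
            f"{l}: {counts.get(l, 0)} ({_pct(counts.get(l, 0), total)})" for l in levels
        )
        try:
            stat, p = _chi_square_table(table)
            degenerate = False
        except DegenerateTableError:
            stat, p, degenerate = float("nan"), float("nan"), True
        rows.append(
            {
                "variable": name,
                "case": fmt(case_counts, len(cases)),
                "control": fmt(ctrl_counts, len(controls)),
                "test": "chi-square",
                "statistic": stat,
                "p_value": p,
                "degenerate": degenerate,
            }
        )

    add_continuous("maternal_age", cases["maternal_age"], controls["maternal_age"])
    for t in sorted(cohort["trimester"].unique()):
        sub = cohort[cohort["trimester"] == t]
        add_continuous(
            f"gestational_age_{t}",
            sub.loc[sub["status"] == "case", "gestational_age_at_draw"],
            sub.loc[sub["status"] == "control", "gestational_age_at_draw"],
        )
    ces_case = cases["n_prior_cesareans"].map(_cesarean_bin).value_counts().to_dict()
    ces_ctrl = controls["n_prior_cesareans"].map(_cesarean_bin).value_counts().to_dict()
    add_categorical("n_prior_cesareans", ces_case, ces_ctrl)
    add_categorical(
        "previa_at_delivery",
        cases["previa_at_delivery"].map({True: "yes", False: "no"}).value_counts().to_dict(),
        controls["previa_at_delivery"].map({True: "yes", False: "no"}).value_counts().to_dict(),
    )
    add_categorical(
        "n_fetuses",
        cases["n_fetuses"].value_counts().to_dict(),
        controls["n_fetuses"].value_counts().to_dict(),
    )

    # --- case-only derived proportions -------------------------------------
    n_cases = len(cases)
    no_ces_no_previa = int(
        ((cases["n_prior_cesareans"] == 0) & (~cases["previa_at_delivery"])).sum()
    )
    clinical_det = int((cases["diagnosis_mode"] == "clinical").sum())
    ultrasound_by_grade = {}
    for grade, grp in cases.groupby("pas_grade"):
        detected = int(grp["ultrasound_detected"].sum())
        ultrasound_by_grade[int(grade)] = {
            "n": int(len(grp)),
            "detected": detected,
            "pct": _pct(detected, len(grp)),
        }
    grade_counts = {
        int(g): {"n": int(n), "pct": _pct(int(n), n_cases)}
        for g, n in cases["pas_grade"].value_counts().items()
    }
    derived = {
        "n_cases": n_cases,
        "n_controls": len(controls),
        "no_cesarean_no_previa": {
            "n": no_ces_no_previa,
            "pct": _pct(no_ces_no_previa, n_cases),
        },
        "clinical_determination": {
            "n": clinical_det,
            "pct": _pct(clinical_det, n_cases),
        },
        "ultrasound_detection_by_grade": ultrasound_by_grade,
        "grade_distribution": grade_counts,
    }
    return SummaryReport(rows=pd.DataFrame(rows), derived=derived)
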