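"""Permuted-label null workflow and observed-vs-null AUC comparison.

Chance-level performance of the discovery workflow is estimated by rerunning
the complete protocol with randomly permuted case/control labels (a fresh
permutation per workflow run, preserving class counts) and pooling the
external-validation AUCs.  Observed and permuted AUC collections are compared
with a two-sided Mann-Whitney rank-sum test (AUCs are bounded and non-normal;
a Welch t-test is available behind a flag), and exported as kernel-density
curves for the classic observed-vs-permuted density plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import WorkflowConfig, run_workflow

__all__ = [
    "NullComparison",
    "run_permuted",
    "compare_distributions",
    "compare_trimesters",
]

_KDE_GRID_SIZE = 512
_DEGENERATE_BW = 1e-3


@dataclass
class NullComparison:
    """Observed vs permuted external-AUC distributions and their test."""

    observed_aucs: np.ndarray
    permuted_aucs: np.ndarray
    observed_mean: float
    permuted_mean: float
    test: str
    statistic: float
    p_value: float
    density: pd.DataFrame  # columns: grid, observed_density, permuted_density

    def to_dict(self) -> dict:
        return {
            "observed_mean": self.observed_mean,
            "permuted_mean": self.permuted_mean,
            "n_observed": int(len(self.observed_aucs)),
            "n_permuted": int(len(self.permuted_aucs)),
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }


def run_permuted(
    X,
    y,
    config: WorkflowConfig,
    n_runs: int = 1,
    feature_names=None,
    seed: int | None = None,
) -> np.ndarray:
    """Pool external AUCs from ``n_runs`` permuted-label workflow runs.

    Each run shuffles the label vector once (class counts preserved) and
    executes the full protocol with ``config.n_iterations`` iterations, so the
    pooled null has up to ``n_runs * n_iterations`` AUCs.  Runs in which every
    iteration was skipped contribute nothing.
    """
    y = np.asarray(y)
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(n_runs)
    pooled = []
    for r in range(n_runs):
        rng = np.random.default_rng(children[r])
        y_perm = rng.permutation(y)
        run_cfg = WorkflowConfig(
            **{
                **config.__dict__,
                "seed": int(rng.integers(2**31 - 1)),
            }
        )
        try:
            result = run_workflow(X, y_perm, run_cfg, feature_names=feature_names)
        except Exception as exc:  # a fully-skipped run is a valid null outcome
            from .errors import WorkflowError

            if isinstance(exc, WorkflowError):
                continue
            raise
        pooled.append(result.external_aucs)
    if not pooled:
        from .errors import WorkflowError

        raise WorkflowError("no permuted run produced a usable iteration")
    return np.concatenate(pooled)


def _kde_curve(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if np.std(values) == 0 or len(values) < 2:
        # degenerate sample: a narrow Gaussian bump at the common value
        return stats.norm.pdf(grid, loc=float(values[0]), scale=_DEGENERATE_BW)
    kde = stats.gaussian_kde(values, bw_method="silverman")
    return kde(grid)


def _density_table(observed: np.ndarray, permuted: np.ndarray) -> pd.DataFrame:
    spread = max(np.std(observed), np.std(permuted), _DEGENERATE_BW)
    lo = min(observed.min(), permuted.min()) - 4 * spread
    hi = max(observed.max(), permuted.max()) + 4 * spread
    grid = np.linspace(lo, hi, _KDE_GRID_SIZE)
    return pd.DataFrame(
        {
            "grid": grid,
            "observed_density": _kde_curve(observed, grid),
            "permuted_density": _kde_curve(permuted, grid),
        }
    )


def compare_distributions(
    observed,
    permuted,
    test: str = "ranksum",
    alternative: str = "two-sided",
) -> NullComparison:
    """Distribution-level comparison of two iteration-level AUC collections.

    ``test`` is ``"ranksum"`` (Mann-Whitney with tie correction, default) or
    ``"welch"``.  Identical inputs give p = 1; both vectors must have length
    >= 2.
    """
    observed = np.asarray(observed, dtype=float)
    permuted = np.asarray(permuted, dtype=float)
    if len(observed) < 2 or len(permuted) < 2:
        raise ValueError("both AUC vectors must have length >= 2")
    pooled = np.concatenate([observed, permuted])
    fully_tied = np.all(pooled == pooled[0])
    if test == "ranksum":
        if fully_tied:
            # every pooled value identical: the statistic sits exactly at its
            # null expectation and the normal approximation degenerates (0/0)
            from types import SimpleNamespace

            res = SimpleNamespace(
                statistic=len(observed) * len(permuted) / 2.0,
                pvalue=1.0 if alternative == "two-sided" else 0.5,
            )
        else:
            res = stats.mannwhitneyu(
                observed, permuted, alternative=alternative, method="asymptotic",
                use_continuity=False,
            )
        name = "mann-whitney-rank-sum"
    elif test == "welch":
        res = stats.ttest_ind(observed, permuted, equal_var=False,
                              alternative=alternative)
        name = "welch-t"
    else:
        raise ValueError("test must be 'ranksum' or 'welch'")
    return NullComparison(
        observed_aucs=observed,
        permuted_aucs=permuted,
        observed_mean=float(observed.mean()),
        permuted_mean=float(permuted.mean()),
        test=name,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        density=_density_table(observed, permuted),
    )


def compare_trimesters(
    aucs_a, aucs_b, test: str = "ranksum", alternative: str = "two-sided"
) -> NullComparison:
    """Compare external-AUC collections from two trimesters (or any two runs).

    ``alternative="greater"`` tests whether the first collection is
    stochastically larger than the second.
    """
    return compare_distributions(aucs_a, aucs_b, test=test, alternative=alternative)
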