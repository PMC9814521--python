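"""The two-step iterative panel-discovery workflow.

Each iteration draws a fresh stratified 80/20 train/validation split and, on
the training 80% only: (1) screens the protein superset with L1-penalized
logistic regression (penalty chosen on an inner cross-validated path), (2)
ranks the surviving candidates by bootstrap-averaged single-predictor AIC
(ensemble feature selection), (3) exhaustively enumerates every panel of at
most ``max_panel_size`` proteins from the top ``top_k`` and scores each by
stratified k-fold cross-validated AUC, selecting the panel with the greatest
mean AUC (lowest AUC SD, then smallest panel, then lexicographic id order as
tie-breaks).  The selected panel is refit on the full training set and its
AUC recorded once on the untouched 20% validation samples.  Panels are then
aggregated across iterations by their protein-id set and ranked by mean
external AUC, mean external AUC SD, and selection count.

Imputation (training-set medians) and standardization (training-set mean/SD)
are learned on the 80% and applied to the 20%, so the validation samples never
inform any selection step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import l1_min_c

from .cohort import AbundanceMatrix
from .errors import AlignmentError, ConfigurationError, WorkflowError
from .glm import LogisticFit, _batched_newton, auc_hanley_se, compute_auc, logistic_fit

__all__ = [
    "WorkflowConfig",
    "PanelModel",
    "IterationRecord",
    "WorkflowResult",
    "l1_screen",
    "ensemble_rank",
    "exhaustive_cv_search",
    "run_workflow",
    "run_workflow_on_cohort",
    "count_panels",
    "enumerate_panels",
]

_AUC_TIE_TOL = 1e-9


@dataclass(frozen=True)
class WorkflowConfig:
    """Knobs of the iterative workflow.

    Defaults follow the published protocol: 80/20 split, fivefold CV, top 10
    candidates, panels of at most 5 proteins, 1000 iterations.  The L1 penalty
    rule, bootstrap count of the ensemble ranking, and penalty-path geometry
    are implementation choices exposed for sensitivity analysis.
    """

    train_fraction: float = 0.8
    n_folds: int = 5
    top_k: int = 10
    max_panel_size: int = 5
    n_iterations: int = 1000
    l1_strength_rule: str | float = "1se"  # "1se", "min", or a fixed penalty
    n_bootstrap: int = 50
    n_lambdas: int = 20
    lambda_min_ratio: float = 0.01
    standardize: bool = True
    stratify_splits: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if not 1 <= self.max_panel_size <= self.top_k:
            raise ConfigurationError("max_panel_size must be in [1, top_k]")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be >= 1")
        if isinstance(self.l1_strength_rule, str):
            if self.l1_strength_rule not in ("1se", "min"):
                raise ConfigurationError("l1_strength_rule must be '1se', 'min' or a penalty value")
        elif float(self.l1_strength_rule) < 0:
            raise ConfigurationError("a fixed l1 penalty must be >= 0")


@dataclass
class PanelModel:
    """A selected protein panel with its refit logistic model and CV summary."""

    protein_ids: tuple[str, ...]
    fit: LogisticFit
    cv_auc_mean: float
    cv_auc_sd: float
    feature_indices: tuple[int, ...] = ()

    @property
    def size(self) -> int:
        return len(self.protein_ids)


@dataclass
class IterationRecord:
    """Everything one workflow iteration produced (or why it was skipped)."""

    index: int
    candidates: tuple[str, ...] = ()
    top_ranked: tuple[tuple[str, float], ...] = ()  # (protein_id, mean AIC)
    panel: PanelModel | None = None
    external_auc: float = float("nan")
    external_auc_sd: float = float("nan")
    train_indices: tuple[int, ...] = ()
    val_indices: tuple[int, ...] = ()
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


@dataclass
class WorkflowResult:
    """All iteration records plus the aggregated panel ranking."""

    iterations: list[IterationRecord]
    ranking: pd.DataFrame
    config: WorkflowConfig
    feature_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def retained(self) -> list[IterationRecord]:
        return [r for r in self.iterations if not r.skipped]

    @property
    def external_aucs(self) -> np.ndarray:
        return np.array([r.external_auc for r in self.retained])

    @property
    def mean_external_auc(self) -> float:
        """Pooled mean external AUC over every retained iteration."""
        return float(self.external_aucs.mean())

    @property
    def top_panel(self) -> dict:
        """The first row of the ranking, with a representative fitted model."""
        row = self.ranking.iloc[0]
        proteins = tuple(row["proteins"].split(";"))
        best = max(
            (r for r in self.retained if frozenset(r.panel.protein_ids) == frozenset(proteins)),
            key=lambda r: r.external_auc,
        )
        return {
            "proteins": sorted(proteins),
            "n_selected": int(row["n_selected"]),
            "mean_external_auc": float(row["mean_external_auc"]),
            "mean_external_auc_sd": float(row["mean_external_auc_sd"]),
            "coefficients": {
                "intercept": float(best.panel.fit.coef[0]),
                **{
                    p: float(c)
                    for p, c in zip(best.panel.protein_ids, best.panel.fit.coef[1:])
                },
            },
        }

    def protein_selection_frequency(self) -> pd.Series:
        """Fraction of retained iterations in which each protein was selected.

        Distinct panels rarely repeat exactly across iterations, so this
        per-protein frequency is the stable aggregate readout of which
        proteins carry the signal.
        """
        from collections import Counter

        counts = Counter(p for r in self.retained for p in r.panel.protein_ids)
        freq = pd.Series(counts, dtype=float) / len(self.retained)
        return freq.sort_values(ascending=False, kind="mergesort")

    def iterations_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.iterations:
            rows.append(
                {
                    "iteration": r.index,
                    "skipped_reason": r.skipped_reason or "",
                    "n_candidates": len(r.candidates),
                    "top_ranked": ";".join(p for p, _ in r.top_ranked),
                    "panel": ";".join(sorted(r.panel.protein_ids)) if r.panel else "",
                    "cv_auc_mean": r.panel.cv_auc_mean if r.panel else np.nan,
                    "cv_auc_sd": r.panel.cv_auc_sd if r.panel else np.nan,
                    "external_auc": r.external_auc,
                    "external_auc_sd": r.external_auc_sd,
                }
            )
        return pd.DataFrame(rows)


def enumerate_panels(n: int, max_panel_size: int) -> list[tuple[int, ...]]:
    """Every non-empty subset of ``range(n)`` with size <= max_panel_size.

    Ordered by size, then lexicographically; this is the exact candidate-panel
    space of the exhaustive search (637 panels for n=10, max size 5).
    """
    return [
        c
        for k in range(1, min(max_panel_size, n) + 1)
        for c in combinations(range(n), k)
    ]


def count_panels(top_k: int, max_panel_size: int) -> int:
    """Number of non-empty panels of size <= max_panel_size from top_k proteins."""
    from math import comb

    return sum(comb(top_k, k) for k in range(1, min(max_panel_size, top_k) + 1))


# ---------------------------------------------------------------------------
# step 1: L1 screening
# ---------------------------------------------------------------------------

def _drop_constant(X: np.ndarray):
    sd = X.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    if keep.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - keep.size} constant column(s) before L1 fit",
            stacklevel=3,
        )
    return X[:, keep], keep


def _l1_fit(X, y, C):
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-5, max_iter=500,
        random_state=0,
    )
    model.fit(X, y)
    return model


def l1_screen(
    X,
    y,
    rule: str | float = "1se",
    n_folds: int = 5,
    n_lambdas: int = 20,
    lambda_min_ratio: float = 0.01,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Restrict the protein superset to L1-selected candidate columns.

    The penalty path runs from the smallest penalty that zeroes every
    coefficient down to ``lambda_min_ratio`` times it (glmnet-style geometry).
    ``rule`` picks the penalty: ``"min"`` minimizes k-fold cross-validated
    binomial deviance, ``"1se"`` takes the strongest penalty within one
    standard error of that minimum (the parsimonious default), and a float is
    used directly as a fixed penalty strength lambda in the
    (1/n) * deviance + lambda * ||w||_1 parameterization (0 = unpenalized,
    numpy.inf = full shrinkage).

    Returns the sorted indices of columns with nonzero coefficients; the set
    may be empty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    Xn, keep = _drop_constant(X)
    if Xn.shape[1] == 0:
        return np.array([], dtype=int)
    n = Xn.shape[0]

    if not isinstance(rule, str):
        lam = float(rule)
        if np.isinf(lam):
            return np.array([], dtype=int)
        C = 1e8 if lam == 0 else 1.0 / (n * lam)
        coef = _l1_fit(Xn, y, C).coef_.ravel()
        return np.sort(keep[np.flatnonzero(coef != 0)])

    rng = rng or np.random.default_rng()
    c0 = l1_min_c(Xn, y, loss="log")
    # C is inverse to the penalty: path from full shrinkage (C ~ c0) outward.
    c_grid = c0 * np.logspace(0.0, -np.log10(lambda_min_ratio), n_lambdas)
    splitter = StratifiedKFold(
        n_splits=n_folds, shuffle=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    deviance = np.empty((n_folds, n_lambdas))
    for f, (tr, te) in enumerate(splitter.split(Xn, y)):
        for j, C in enumerate(c_grid):
            model = _l1_fit(Xn[tr], y[tr], C)
            prob = np.clip(model.predict_proba(Xn[te])[:, 1], 1e-12, 1 - 1e-12)
            yt = (y[te] == model.classes_[1]).astype(float)
            deviance[f, j] = -2.0 * np.mean(
                yt * np.log(prob) + (1 - yt) * np.log(1 - prob)
            )
    mean_dev = deviance.mean(axis=0)
    se_dev = deviance.std(axis=0, ddof=1) / np.sqrt(n_folds)
    j_min = int(np.argmin(mean_dev))
    if rule == "min":
        j_sel = j_min
    else:  # 1se: strongest penalty (smallest C, earliest index) within 1 SE
        within = np.flatnonzero(mean_dev <= mean_dev[j_min] + se_dev[j_min])
        j_sel = int(within[0])
    coef = _l1_fit(Xn, y, c_grid[j_sel]).coef_.ravel()
    return np.sort(keep[np.flatnonzero(coef != 0)])


# ---------------------------------------------------------------------------
# step 2: bootstrap-ensemble AIC ranking
# ---------------------------------------------------------------------------

def ensemble_rank(
    X,
    y,
    candidates,
    n_bootstrap: int = 50,
    rng: np.random.Generator | None = None,
    feature_names=None,
) -> list[tuple[int, float]]:
    """Rank candidate columns by bootstrap-averaged single-predictor AIC.

    Each of ``n_bootstrap`` resamples of the training rows (drawn to contain
    both classes) fits one univariate logistic model per candidate; candidates
    are ordered by ascending mean AIC.  Ties, and candidates that are constant
    on the training set (sentinel score +inf, ranked last), are broken
    lexicographically by feature name.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        raise ValueError("candidate set must be non-empty")
    rng = rng or np.random.default_rng()
    names = (
        [str(feature_names[i]) for i in candidates]
        if feature_names is not None
        else [str(i) for i in candidates]
    )
    n = X.shape[0]
    usable = X[:, candidates].std(axis=0) > 0
    aic_sum = np.zeros(candidates.size)
    cols = X[:, candidates[usable]]
    for _ in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
        yb = y[idx]
        Xb = np.stack(
            [np.column_stack([np.ones(n), cols[idx, j]]) for j in range(cols.shape[1])]
        )
        _, loglik, _ = _batched_newton(Xb, yb, max_iter=40, tol=1e-8)
        aic_sum[usable] += 4.0 - 2.0 * loglik
    mean_aic = np.where(usable, aic_sum / n_bootstrap, np.inf)
    order = sorted(range(candidates.size), key=lambda i: (mean_aic[i], names[i]))
    return [(int(candidates[i]), float(mean_aic[i])) for i in order]


# ---------------------------------------------------------------------------
# step 3: exhaustive cross-validated subset search
# ---------------------------------------------------------------------------

def _batched_auc(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rank-formula AUC of each row of ``scores`` against one label vector."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores, axis=1)
    u = ranks[:, labels == 1].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def exhaustive_cv_search(
    X,
    y,
    top_indices,
    max_panel_size: int = 5,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
    feature_names=None,
) -> PanelModel:
    """Enumerate every panel of <= max_panel_size proteins from ``top_indices``
    and select the one with the best stratified CV AUC.

    Selection is lexicographic: greatest mean fold AUC, then lowest fold-AUC
    standard deviation (ties within 1e-9), then smallest panel, then protein
    ids.  The winning panel is refit on all of ``(X, y)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    top_indices = list(map(int, top_indices))
    rng = rng or np.random.default_rng()
    subsets = enumerate_panels(len(top_indices), max_panel_size)
    splitter = StratifiedKFold(
        n_splits=n_folds, shuffle=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    fold_aucs = np.empty((len(subsets), n_folds))
    cols = X[:, top_indices]
    for f, (tr, te) in enumerate(splitter.split(cols, y)):
        if len(np.unique(y[te])) < 2:
            raise WorkflowError(
                "a CV fold lost a class; too few cases for stratified folds"
            )
        ones_tr = np.ones(len(tr))
        by_size: dict[int, list[int]] = {}
        for s_i, s in enumerate(subsets):
            by_size.setdefault(len(s), []).append(s_i)
        for k, subset_rows in by_size.items():
            Xb = np.stack(
                [
                    np.column_stack([ones_tr, cols[np.ix_(tr, list(subsets[s_i]))]])
                    for s_i in subset_rows
                ]
            )
            beta, _, _ = _batched_newton(Xb, y[tr], max_iter=40, tol=1e-8)
            Xte = np.stack(
                [
                    np.column_stack(
                        [np.ones(len(te)), cols[np.ix_(te, list(subsets[s_i]))]]
                    )
                    for s_i in subset_rows
                ]
            )
            scores = np.einsum("bnp,bp->bn", Xte, beta)
            fold_aucs[subset_rows, f] = _batched_auc(scores, y[te])

    cv_mean = fold_aucs.mean(axis=1)
    cv_sd = fold_aucs.std(axis=1, ddof=1)
    names = feature_names if feature_names is not None else [str(i) for i in range(X.shape[1])]

    best_mean = cv_mean.max()
    tied = np.flatnonzero(cv_mean >= best_mean - _AUC_TIE_TOL)
    key = lambda s_i: (
        round(cv_sd[s_i] / _AUC_TIE_TOL) * _AUC_TIE_TOL,
        len(subsets[s_i]),
        tuple(sorted(str(names[top_indices[p]]) for p in subsets[s_i])),
    )
    winner = min(tied, key=key)
    chosen = tuple(top_indices[p] for p in subsets[winner])
    fit = logistic_fit(X[:, list(chosen)], y)
    return PanelModel(
        protein_ids=tuple(str(names[i]) for i in chosen),
        fit=fit,
        cv_auc_mean=float(cv_mean[winner]),
        cv_auc_sd=float(cv_sd[winner]),
        feature_indices=chosen,
    )


# ---------------------------------------------------------------------------
# full iterative workflow
# ---------------------------------------------------------------------------

def _impute_and_standardize(X_tr, X_val, standardize: bool):
    med = np.nanmedian(X_tr, axis=0)
    med = np.where(np.isnan(med), 0.0, med)

    def fill(A):
        A = A.copy()
        nan_r, nan_c = np.where(np.isnan(A))
        A[nan_r, nan_c] = med[nan_c]
        return A

    X_tr, X_val = fill(X_tr), fill(X_val)
    if standardize:
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        X_tr = (X_tr - mu) / sd
        X_val = (X_val - mu) / sd
    return X_tr, X_val


def run_workflow(X, y, config: WorkflowConfig, feature_names=None) -> WorkflowResult:
    """Run the full iterative discovery protocol on one samples x proteins matrix.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_proteins)
        log-scale intensities; NaN marks missing cells.
    y : array-like
        Binary labels (1 = case).
    config : WorkflowConfig
    feature_names : sequence of str, optional
        Protein identifiers (defaults to column indices as strings).

    Raises
    ------
    WorkflowError
        If every iteration was skipped (e.g. the L1 screen always came back
        empty), with the per-iteration reasons in the message.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise AlignmentError("X and y have different numbers of samples")
    y = y.astype(float)
    names = (
        tuple(str(n) for n in feature_names)
        if feature_names is not None
        else tuple(str(i) for i in range(X.shape[1]))
    )
    if len(names) != X.shape[1]:
        raise AlignmentError("feature_names length does not match X columns")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if min(n_pos, n_neg) < 10:
        warnings.warn(
            f"fewer than 10 samples in a class ({n_pos} cases / {n_neg} controls); "
            "stratified splits may be unstable",
            stacklevel=2,
        )

    children = np.random.SeedSequence(config.seed).spawn(config.n_iterations)
    records: list[IterationRecord] = []
    all_idx = np.arange(X.shape[0])
    for i in range(config.n_iterations):
        rng = np.random.default_rng(children[i])
        split_seed = int(rng.integers(2**31 - 1))
        tr_idx, val_idx = train_test_split(
            all_idx,
            train_size=config.train_fraction,
            random_state=split_seed,
            stratify=y if config.stratify_splits else None,
        )
        X_tr, X_val = _impute_and_standardize(
            X[tr_idx], X[val_idx], config.standardize
        )
        y_tr, y_val = y[tr_idx], y[val_idx]
        rec = IterationRecord(
            index=i, train_indices=tuple(map(int, tr_idx)),
            val_indices=tuple(map(int, val_idx)),
        )
        candidates = l1_screen(
            X_tr,
            y_tr,
            rule=config.l1_strength_rule,
            n_folds=config.n_folds,
            n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio,
            rng=rng,
        )
        if candidates.size == 0:
            rec.skipped_reason = "empty L1 candidate set"
            records.append(rec)
            continue
        rec.candidates = tuple(names[j] for j in candidates)
        ranked = ensemble_rank(
            X_tr, y_tr, candidates,
            n_bootstrap=config.n_bootstrap, rng=rng, feature_names=names,
        )
        top = ranked[: config.top_k]
        rec.top_ranked = tuple((names[j], aic) for j, aic in top)
        panel = exhaustive_cv_search(
            X_tr,
            y_tr,
            [j for j, _ in top],
            max_panel_size=config.max_panel_size,
            n_folds=config.n_folds,
            rng=rng,
            feature_names=names,
        )
        rec.panel = panel
        scores = panel.fit.predict_score(X_val[:, list(panel.feature_indices)])
        rec.external_auc = compute_auc(scores, y_val.astype(int))
        rec.external_auc_sd = auc_hanley_se(
            rec.external_auc, int(y_val.sum()), int(len(y_val) - y_val.sum())
        )
        records.append(rec)

    retained = [r for r in records if not r.skipped]
    if not retained:
        reasons = {r.skipped_reason for r in records}
        raise WorkflowError(f"all {len(records)} iterations skipped; reasons: {reasons}")
    ranking = _aggregate_ranking(retained, len(records))
    return WorkflowResult(
        iterations=records, ranking=ranking, config=config, feature_names=names
    )


def _aggregate_ranking(retained: list[IterationRecord], n_total: int) -> pd.DataFrame:
    groups: dict[frozenset, list[IterationRecord]] = {}
    for r in retained:
        groups.setdefault(frozenset(r.panel.protein_ids), []).append(r)
    rows = []
    for key, recs in groups.items():
        aucs = np.array([r.external_auc for r in recs])
        sds = np.array([r.external_auc_sd for r in recs])
        rows.append(
            {
                "proteins": ";".join(sorted(key)),
                "panel_size": len(key),
                "n_selected": len(recs),
                "mean_external_auc": float(aucs.mean()),
                "mean_external_auc_sd": float(sds.mean()),
                "mean_cv_auc": float(np.mean([r.panel.cv_auc_mean for r in recs])),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        by=["mean_external_auc", "mean_external_auc_sd", "n_selected", "proteins"],
        ascending=[False, True, False, True],
        kind="mergesort",
    )
    return df.reset_index(drop=True)


def run_workflow_on_cohort(
    matrix: AbundanceMatrix, cohort: pd.DataFrame, config: WorkflowConfig
) -> WorkflowResult:
    """Align an abundance matrix with a clinical table and run the workflow."""
    status = cohort.drop_duplicates("sample_id").set_index("sample_id")["status"]
    common = [s for s in matrix.sample_ids if s in status.index]
    if not common:
        raise AlignmentError("no overlap between abundance and clinical sample ids")
    idx = [matrix.sample_ids.index(s) for s in common]
    y = (status.loc[common] == "case").astype(int).to_numpy()
    return run_workflow(
        matrix.values[idx, :], y, config, feature_names=matrix.protein_ids
    )
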