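"""Rank-based AUC and maximum-likelihood logistic regression.

These are the two numerical primitives of the panel-search workflow.  The
logistic solver is a batched Newton/IRLS routine: the exhaustive subset search
evaluates hundreds of tiny candidate models (n <= ~100 samples, <= 6
parameters) per fold, and solving them as one stacked linear-algebra problem
is what keeps the 1000-iteration protocol tractable on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .errors import UndefinedAUCError

__all__ = ["compute_auc", "auc_hanley_se", "logistic_fit", "LogisticFit"]

# |eta| beyond this the likelihood is flat to double precision; clipping keeps
# Newton steps finite under (quasi-)complete separation.
_ETA_CAP = 30.0
_COEF_SEPARATION_BOUND = 25.0


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formula.

    Equals (concordant pairs + 0.5 * tied pairs) / (positives * negatives),
    so it is invariant under strictly increasing transforms of ``scores``.

    Parameters
    ----------
    scores : array-like
        Real-valued classifier scores, higher meaning "more case-like".
    labels : array-like
        Binary labels (1 = case/positive, 0 = control/negative).

    Raises
    ------
    UndefinedAUCError
        If only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"AUC undefined: {n_pos} positive and {n_neg} negative labels"
        )
    ranks = rankdata(scores)  # midranks handle ties -> half credit
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def auc_hanley_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate.

    Closed-form SE used to report the spread of a single validation-set AUC,
    where no resampling-based spread is available.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic model for one predictor subset.

    Attributes
    ----------
    coef : ndarray
        Coefficients, intercept first, then one per predictor column.
    loglik : float
        Maximized log-likelihood.
    aic : float
        2*(p+1) - 2*loglik for p predictors.
    converged : bool
        Newton iterations met the gradient tolerance.
    separated : bool
        The data are (quasi-)completely separated; the fit was capped at the
        iteration limit and should be interpreted as a boundary solution.
        Predicted scores from such a fit still rank samples, so the AUC
        remains well defined.
    """

    coef: np.ndarray
    loglik: float
    aic: float
    converged: bool
    separated: bool

    def predict_score(self, X) -> np.ndarray:
        """Linear predictor eta = intercept + X @ coef for new samples."""
        X = np.asarray(X, dtype=float)
        return self.coef[0] + X @ self.coef[1:]


def _batched_newton(Xb: np.ndarray, y: np.ndarray, max_iter: int, tol: float):
    """Newton/IRLS over a stack of design matrices sharing one response.

    Xb : (B, n, p) design matrices including the intercept column.
    y  : (n,) binary response.
    Returns (beta (B, p), loglik (B,), converged (B,) bool).
    """
    B, n, p = Xb.shape
    beta = np.zeros((B, p))
    converged = np.zeros(B, dtype=bool)
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(np.einsum("bnp,bp->bn", Xb, beta), -_ETA_CAP, _ETA_CAP)
        mu = expit(eta)
        grad = np.einsum("bnp,bn->bp", Xb, y[None, :] - mu)
        w = mu * (1.0 - mu)
        hess = np.einsum("bnp,bn,bnq->bpq", Xb, w, Xb) + ridge
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        # Damp absurd steps (separation): keeps the iteration stable.
        norms = np.max(np.abs(step), axis=1, keepdims=True)
        scale = np.where(norms > 10.0, 10.0 / np.maximum(norms, 1e-300), 1.0)
        step = step * scale
        beta = beta + step
        newly = np.max(np.abs(grad), axis=1) < tol
        converged |= newly
        if converged.all():
            break
    eta = np.clip(np.einsum("bnp,bp->bn", Xb, beta), -_ETA_CAP, _ETA_CAP)
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    loglik = np.einsum("n,bn->b", y, np.log(mu)) + np.einsum(
        "n,bn->b", 1.0 - y, np.log(1.0 - mu)
    )
    return beta, loglik, converged


def logistic_fit(X, y, max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression with an intercept.

    Parameters
    ----------
    X : array-like, shape (n, p) or (n,)
        Predictor columns for the protein subset; p = 0 (shape (n, 0)) gives
        the intercept-only model.
    y : array-like, shape (n,)
        Binary labels.

    Notes
    -----
    Perfect separation is not an error: the fit is capped, flagged via
    ``separated``, and its (boundary) log-likelihood and AIC are reported, so
    subset search can keep such models rather than biasing selection by
    dropping them.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.shape[0]
    if X.shape[0] != n:
        raise ValueError("X and y have different numbers of samples")
    if X.shape[1] > 0:
        col_sd = X.std(axis=0)
        if np.any(col_sd == 0):
            raise ValueError("constant (zero-variance) predictor column")
    Xb = np.concatenate([np.ones((n, 1)), X], axis=1)[None, :, :]
    beta, loglik, conv = _batched_newton(Xb, y, max_iter=max_iter, tol=tol)
    coef = beta[0]
    ll = float(loglik[0])
    p = X.shape[1]
    # A perfect fit (loglik ~ 0) or a coefficient at an absurd magnitude is a
    # boundary solution: (quasi-)complete separation.  Note the eta clip makes
    # the gradient vanish there, so "converged" alone cannot distinguish it.
    separated = bool(ll > -1e-6 * n or np.max(np.abs(coef)) > _COEF_SEPARATION_BOUND)
    return LogisticFit(
        coef=coef,
        loglik=ll,
        aic=2.0 * (p + 1) - 2.0 * ll,
        converged=bool(conv[0]),
        separated=separated,
    )
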