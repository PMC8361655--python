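"""ROC evaluation of candidate miRNAs as single and combined classifiers.

AUC is computed with the Mann-Whitney convention (ties count 1/2), which
equals the area under the empirical ROC curve; the combined signature is
the in-sample predicted probability of a logistic regression on the panel
miRNAs' expression, mirroring a standard biomarker-panel workflow (no
cross-validation by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

__all__ = ["ROCResult", "CombinedSignature", "auc", "fit_logistic", "evaluate_panel"]


@dataclass
class ROCResult:
    name: str
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class CombinedSignature:
    members: list[str]
    intercept: float
    coefficients: np.ndarray
    scores: np.ndarray = field(repr=False)
    converged: bool = True
    penalized: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(X, dtype=float) @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    return (y == classes[1]).astype(int) if not np.array_equal(classes, [0, 1]) else y.astype(int)


def auc(scores, labels, name: str = "predictor") -> ROCResult:
    """Empirical ROC curve and AUC for one score vector.

    The AUC reported is for the stated orientation (positive class scores
    high); it is not flipped to exceed 0.5.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape[0] != y.shape[0]:
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, s)
    return ROCResult(
        name=name,
        auc=float(roc_auc_score(y, s)),
        fpr=fpr,
        tpr=tpr,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
          tol: float = 1e-8, max_iter: int = 100) -> tuple[np.ndarray, bool]:
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    penalty = np.eye(p + 1) * ridge
    penalty[0, 0] = 0.0  # intercept unpenalised
    converged = False
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = Xd.T * w
        beta_new = np.linalg.solve(XtW @ Xd + penalty, XtW @ z)
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if step < tol:
            converged = True
            break
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e6:
            break  # diverging: perfect separation
    return beta, converged


def fit_logistic(expr: pd.DataFrame, labels) -> CombinedSignature:
    """Maximum-likelihood logistic fit of labels on expression columns.

    Fitted by iteratively reweighted least squares (convergence when the
    largest coefficient change drops below 1e-8, at most 100 iterations).
    Under perfect separation the MLE diverges; the fit falls back to a
    ridge penalty (lambda = 1e-4) with a logged warning — the in-sample
    score ranking, hence the combined AUC, is unaffected.  Constant
    predictor columns are dropped with a warning.
    """
    X = expr.to_numpy(dtype=float)
    y = _check_labels(labels)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need at least one predictor")
    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
    dropped = [c for i, c in enumerate(expr.columns) if i not in keep]
    if dropped:
        logger.warning("dropping constant predictor columns: %s", dropped)
    if not keep:
        raise ValueError("all predictor columns are constant")
    X = X[:, keep]
    members = [str(expr.columns[i]) for i in keep]
    if y.size < X.shape[1] + 1:
        raise ValueError(f"too few samples ({y.size}) for {X.shape[1]} predictors")

    beta, converged = _irls(X, y)
    penalized = False
    if not converged:
        logger.warning("logistic fit did not converge (likely perfect separation); "
                       "refitting with ridge penalty 1e-4")
        beta, converged = _irls(X, y, ridge=1e-4)
        penalized = True
    sig = CombinedSignature(
        members=members,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        scores=np.empty(0),
        converged=converged,
        penalized=penalized,
    )
    sig.scores = sig.predict(X)
    return sig


def evaluate_panel(expr: pd.DataFrame, labels, panel: list[str]) -> tuple[list[ROCResult], CombinedSignature]:
    """Per-miRNA and combined-signature ROC results.

    ``expr`` is samples x miRNAs; ``panel`` names the columns to evaluate.
    Returns one ROCResult per panel member plus one named "combined" for
    the logistic signature's in-sample scores.
    """
    missing = [m for m in panel if m not in expr.columns]
    if missing:
        raise KeyError(f"panel miRNAs absent from expression table: {missing}")
    y = _check_labels(labels)
    results = [auc(expr[m].to_numpy(), y, name=m) for m in panel]
    sig = fit_logistic(expr[panel], y)
    results.append(auc(sig.scores, y, name="combined"))
    return results, sig


def results_to_frame(results: list[ROCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.name, r.auc, r.n_pos, r.n_neg) for r in results],
        columns=["predictor", "AUC", "n_pos", "n_neg"],
    )
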