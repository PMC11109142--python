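"""Evaluation metrics for polygenic scores.

Binary traits are scored by ROC AUC (rank / Mann–Whitney formulation, ties
counted one half) and Nagelkerke's pseudo-R².  Following the usual
PRS-evaluation convention, Nagelkerke R² is computed by re-fitting a
univariate logistic regression of the phenotype on the score: with model
log-likelihood L1 and intercept-only log-likelihood L0,

    Cox–Snell R² = 1 − exp((2/n)(L0 − L1)),   Nagelkerke R² = CS / (1 − exp((2/n) L0)).

Quantitative traits are scored by the squared Pearson correlation between
phenotype and score, so affine miscalibration of the score is not penalised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata

__all__ = [
    "EvalReport",
    "roc_auc",
    "nagelkerke_r2",
    "nagelkerke_from_loglik",
    "r_squared",
    "evaluate",
]


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary phenotype must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def roc_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Probability that a random case outscores a random control (ties = 1/2)."""
    y = _check_binary(y)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and phenotype must have the same length")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    n_case = int(y.sum())
    n_ctrl = len(y) - n_case
    u = ranks[y == 1.0].sum() - n_case * (n_case + 1) / 2.0
    return float(u / (n_case * n_ctrl))


def nagelkerke_from_loglik(l1: float, l0: float, n: int) -> float:
    """Nagelkerke R² from fitted and null log-likelihoods."""
    cox_snell = 1.0 - np.exp((2.0 / n) * (l0 - l1))
    max_cs = 1.0 - np.exp((2.0 / n) * l0)
    if max_cs <= 0.0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def _logit_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """Maximised log-likelihood of a logistic regression (statsmodels fit)."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError("newton failed")
        except Exception:
            res = model.fit(disp=0, method="bfgs", maxiter=1000)
    return float(res.llf)


def null_loglik(y: np.ndarray) -> float:
    """Intercept-only binomial log-likelihood."""
    y = np.asarray(y, dtype=float)
    p = y.mean()
    n = len(y)
    return float(n * (p * np.log(p) + (1.0 - p) * np.log(1.0 - p)))


def nagelkerke_r2(y: np.ndarray, scores: np.ndarray) -> float:
    """Nagelkerke pseudo-R² of a score, via a univariate logistic re-fit."""
    y = _check_binary(y)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and phenotype must have the same length")
    l0 = null_loglik(y)
    if np.std(s) == 0.0:
        return 0.0  # no information: slope 0, L1 = L0
    s_std = (s - s.mean()) / s.std()  # invariant to positive affine maps anyway
    X = np.column_stack([np.ones_like(s_std), s_std])
    l1 = _logit_loglik(y, X)
    l1 = max(l1, l0)  # guard float noise: the null is nested
    return nagelkerke_from_loglik(l1, l0, len(y))


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Squared Pearson correlation between phenotype and prediction."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("inputs must have the same length")
    if np.std(y) == 0.0 or np.std(yhat) == 0.0:
        raise ValueError("zero variance input to r_squared")
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class EvalReport:
    trait_type: str
    partition: str
    model_id: str
    roc_auc: float | None = None
    nagelkerke_r2: float | None = None
    r2: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def to_row(self) -> str:
        def fmt(x):
            return "." if x is None else repr(float(x)) if isinstance(x, float) else str(x)

        return "\t".join(
            fmt(v)
            for v in (
                self.model_id, self.partition, self.trait_type,
                self.roc_auc, self.nagelkerke_r2, self.r2,
                self.n_cases, self.n_controls,
            )
        )


def evaluate(
    model_scores: np.ndarray,
    phenotype: np.ndarray,
    trait_type: str,
    partition: str = "test",
    model_id: str = "model",
) -> EvalReport:
    """Trait-appropriate metrics on one partition's scores."""
    if trait_type == "binary":
        y = _check_binary(phenotype)
        return EvalReport(
            trait_type=trait_type,
            partition=partition,
            model_id=model_id,
            roc_auc=roc_auc(y, model_scores),
            nagelkerke_r2=nagelkerke_r2(y, model_scores),
            n_cases=int(y.sum()),
            n_controls=int(len(y) - y.sum()),
        )
    if trait_type == "quantitative":
        return EvalReport(
            trait_type=trait_type,
            partition=partition,
            model_id=model_id,
            r2=r_squared(phenotype, model_scores),
        )
    raise ValueError(f"unknown trait_type {trait_type!r}")
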