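"""Exhaustive search over small logistic models with leave-one-out CV.

Candidate features from the selection ensemble are combined into every
logistic regression model with one to three main effects (three is the cap,
to limit overfitting at cohort scale).  Each model is scored by
leave-one-out cross-validation — one held-out *subject* per fold, so in
rolling matrices every visit-row of the held-out subject leaves with it —
and the winners are refitted on the whole data set.

The logistic fits use a small Newton-Raphson (IRLS) core with step halving.
Perfect separation is detected and flagged; the fit is then retained under a
tiny ridge penalty (1e-6) for numerical stability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .evaluate import DEFAULT_SPECIFICITIES, auc_delong, sensitivity_at_specificity
from .indices import complete_cases, feature_columns

MAX_FEATURES = 3
SEPARATION_RIDGE = 1e-6


# ---------------------------------------------------------------------------
# logistic core

def _loglik(X, y, beta, ridge=0.0):
    eta = np.clip(X @ beta, -30, 30)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    if ridge:
        ll -= 0.5 * ridge * float(beta @ beta)
    return ll


def irls_logit(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
               max_iter: int = 25, tol: float = 1e-8,
               beta0: np.ndarray | None = None):
    """Newton-Raphson maximum-likelihood logistic fit.

    ``X`` includes the intercept column.  Returns (beta, converged, loglik).
    ``ridge`` adds a quadratic penalty used as the separation fallback; the
    reported loglik is the penalised one in that case.  Iteration stops when
    the step or the log-likelihood stops moving — on separable data the
    likelihood plateaus near zero while the coefficients diverge, so the
    plateau stop keeps the cost bounded.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    ll = _loglik(X, y, beta, ridge)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving keeps Newton from overshooting on near-separation
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(X, y, cand, ridge)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        if not np.all(np.isfinite(cand)):
            break
        moved = np.max(np.abs(cand - beta))
        gained = ll_new - ll
        beta, ll = cand, ll_new
        if moved < tol:
            converged = True
            break
        if 0 <= gained < 1e-7:
            break
    return beta, converged, ll


def _detect_separation(X, y, beta) -> bool:
    mu = expit(np.clip(X @ beta, -30, 30))
    fits_perfectly = bool(np.all(mu[y == 1] > 1 - 1e-3)
                          and np.all(mu[y == 0] < 1e-3))
    # scale-aware blow-up check: effect of one feature SD on the log-odds
    if X.shape[1] > 1:
        sd = X[:, 1:].std(axis=0)
        blown = bool(np.max(np.abs(beta[1:]) * sd) > 30)
    else:
        blown = False
    return fits_perfectly or blown


# ---------------------------------------------------------------------------
# model specs and fits

@dataclass(frozen=True)
class ModelSpec:
    """A named logistic model over 1-3 trend-index features."""

    features: tuple[str, ...]

    def __post_init__(self):
        if not 1 <= len(self.features) <= MAX_FEATURES:
            raise ValueError("a model uses between 1 and 3 features")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in model spec")

    @property
    def name(self) -> str:
        return "".join(self.features)


@dataclass
class FittedModel:
    spec: ModelSpec
    intercept: float
    coefficients: dict[str, float]
    n: int
    converged: bool
    separation: bool
    loglik: float
    stderr: dict[str, float] | None = None  # Wald SEs incl. "(intercept)"

    @property
    def aic(self) -> float:
        return 2.0 * (len(self.coefficients) + 1) - 2.0 * self.loglik

    def wald_ci(self, feature: str, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats as _st
        if self.stderr is None:
            raise ValueError("no standard errors available for this fit")
        z = _st.norm.ppf(0.5 + level / 2.0)
        b = self.coefficients[feature]
        se = self.stderr[feature]
        return b - z * se, b + z * se

    def predict(self, fm: pd.DataFrame) -> pd.Series:
        """Predicted probabilities for the complete-case rows of ``fm``."""
        feats = list(self.spec.features)
        sub = fm.dropna(subset=feats)
        eta = self.intercept + sub[feats].values @ np.array(
            [self.coefficients[f] for f in feats])
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        return pd.Series(p, index=sub.index)

    def to_dict(self) -> dict:
        return {
            "name": self.spec.name,
            "features": list(self.spec.features),
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "n": self.n,
            "converged": self.converged,
            "separation": self.separation,
        }


def enumerate_models(pool) -> list[ModelSpec]:
    """All 1-, 2- and 3-feature subsets of the pool, lexicographic order."""
    pool = sorted(set(pool))
    if not pool:
        raise ValueError("empty candidate pool")
    specs = []
    for size in (1, 2, 3):
        for combo in itertools.combinations(pool, size):
            specs.append(ModelSpec(features=combo))
    return specs


def fit_logistic(spec: ModelSpec, fm: pd.DataFrame) -> FittedModel:
    """Maximum-likelihood whole-data fit of one model."""
    data = complete_cases(fm, list(spec.features))
    y = data["label"].to_numpy(dtype=float)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least 2 rows per class")
    X = np.column_stack([np.ones(len(data)), data[list(spec.features)].to_numpy()])
    beta, converged, ll = irls_logit(X, y)
    separation = _detect_separation(X, y, beta)
    if separation:
        beta, converged, ll = irls_logit(X, y, ridge=SEPARATION_RIDGE)
    mu = expit(np.clip(X @ beta, -30, 30))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = {"(intercept)": float(se[0]),
                  **{f: float(s) for f, s in zip(spec.features, se[1:])}}
    except np.linalg.LinAlgError:
        stderr = None
    return FittedModel(
        spec=spec,
        intercept=float(beta[0]),
        coefficients={f: float(b) for f, b in zip(spec.features, beta[1:])},
        n=len(data),
        converged=converged,
        separation=separation,
        loglik=ll,
        stderr=stderr,
    )


@dataclass
class LoocvResult:
    spec: ModelSpec
    predictions: pd.Series  # out-of-fold probability per unit
    labels: pd.Series
    cv_auc: float
    cv_sens: dict[float, float] = field(default_factory=dict)
    n_degenerate_folds: int = 0

    def score(self, criterion: str, target: float = 0.903) -> float:
        if criterion == "cv_auc":
            return self.cv_auc
        if criterion == "cv_sens_at_spec":
            return self.cv_sens[target]
        raise ValueError(f"unknown ranking criterion {criterion!r}")


def loocv_predict(spec: ModelSpec, fm: pd.DataFrame,
                  targets=DEFAULT_SPECIFICITIES) -> LoocvResult:
    """Leave-one-subject-out cross-validated predictions for one model."""
    data = complete_cases(fm, list(spec.features))
    subjects = data["subject_id"].unique()
    if len(subjects) < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    feats = list(spec.features)
    X = np.column_stack([np.ones(len(data)), data[feats].to_numpy()])
    y = data["label"].to_numpy(dtype=float)
    sid = data["subject_id"].to_numpy()

    beta_full, _, _ = irls_logit(X, y)
    preds = np.empty(len(data))
    n_degenerate = 0
    for s in subjects:
        mask = sid == s
        Xtr, ytr = X[~mask], y[~mask]
        if len(np.unique(ytr)) < 2:
            preds[mask] = float(np.mean(ytr))  # intercept-only fallback
            n_degenerate += 1
            continue
        # a separated fold gives saturated (clipped) predictions; no refit
        beta, _, _ = irls_logit(Xtr, ytr, beta0=beta_full)
        preds[mask] = expit(np.clip(X[mask] @ beta, -30, 30))

    preds = np.clip(preds, 1e-12, 1 - 1e-12)
    pred_s = pd.Series(preds, index=data.index)
    labels = data["label"]
    cv_auc, _ = auc_delong(preds, labels.to_numpy())
    cv_sens = {}
    for t in targets:
        sens, _, _ = sensitivity_at_specificity(
            preds[y == 1], preds[y == 0], t)
        cv_sens[t] = sens
    return LoocvResult(spec=spec, predictions=pred_s, labels=labels,
                       cv_auc=cv_auc, cv_sens=cv_sens,
                       n_degenerate_folds=n_degenerate)


def rank_models(results: list[LoocvResult], criterion: str = "cv_sens_at_spec",
                target: float = 0.903) -> list[LoocvResult]:
    """Stable descending sort by the criterion; ties go to the smaller model,
    then to the lexicographically earlier name."""
    if not results:
        raise ValueError("no results to rank")
    return sorted(
        results,
        key=lambda r: (-r.score(criterion, target), len(r.spec.features),
                       r.spec.name),
    )


def search_models(fm: pd.DataFrame, pool, criterion: str = "cv_sens_at_spec",
                  target: float = 0.903,
                  targets=DEFAULT_SPECIFICITIES) -> list[LoocvResult]:
    """Enumerate, cross-validate and rank every <=3-feature model."""
    results = [loocv_predict(spec, fm, targets=targets)
               for spec in enumerate_models(pool)]
    return rank_models(results, criterion, target)


def ranking_table(results: list[LoocvResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "name": r.spec.name,
            "n_features": len(r.spec.features),
            "features": ",".join(r.spec.features),
            "cv_auc": r.cv_auc,
            "degenerate_folds": r.n_degenerate_folds,
        }
        for t, v in r.cv_sens.items():
            row[f"cv_sens@{t:g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
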