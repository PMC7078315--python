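"""Variable selection ensemble for trend-index features.

Five criteria nominate candidate predictors from the feature matrix:

1. bidirectional stepwise logistic selection by AIC,
2. L1-penalised (lasso) logistic regression, with the penalty chosen as the
   first value on a 0.01-step grid from zero that leaves at most three
   variables in the model,
3. a 200-resample stratified bootstrap of that lasso rule, reporting each
   feature's frequency of inclusion in the per-resample top-three active set,
4. random-forest mean accuracy decrease (out-of-bag permutation importance),
5. random-forest Gini impurity importance.

The consensus pool passed on to model search is the union of the AIC set,
the lasso set, and the top-m features by bootstrap frequency, accuracy
decrease and impurity.  Features are standardised to zero mean and unit
variance before penalisation, since the index scales are heterogeneous.
All operations sort units by id internally, so results are invariant to row
order and fully determined by the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .indices import feature_columns
from .models import _detect_separation, irls_logit

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    lambda_step: float = 0.01
    lasso_target_vars: int = 3
    bootstrap_B: int = 200
    rf_trees: int = 500
    top_m: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.lambda_step <= 0:
            raise ValueError("lambda_step must be > 0")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")


def _complete(fm: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Complete-case rows over every feature column, sorted by unit id."""
    feats = feature_columns(fm)
    data = fm.dropna(subset=feats).sort_index()
    dropped = len(fm) - len(data)
    if dropped:
        logger.info("selection: dropped %d incomplete units", dropped)
    return data, feats


# ---------------------------------------------------------------------------
# criterion 1: stepwise AIC

def _aic(X, y, cols) -> float:
    Xs = X[:, [0] + [c + 1 for c in cols]]
    beta, _, ll = irls_logit(Xs, y)
    if _detect_separation(Xs, y, beta):
        logger.debug("aic_stepwise: perfect separation for feature set %s; "
                     "selection recorded but coefficients unreliable", cols)
        beta, _, ll = irls_logit(Xs, y, ridge=1e-6)
    return 2.0 * (len(cols) + 1) - 2.0 * ll


def aic_stepwise(fm: pd.DataFrame) -> list[str]:
    """Bidirectional stepwise logistic selection minimising AIC, starting
    from the intercept-only model.  Deterministic given the matrix."""
    data, feats = _complete(fm)
    y = data["label"].to_numpy(dtype=float)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least 2 rows per class")
    X = np.column_stack([np.ones(len(data)), data[feats].to_numpy()])

    current: list[int] = []
    best_aic = _aic(X, y, current)
    improved = True
    while improved:
        improved = False
        best_move = None
        for j in range(len(feats)):  # additions then removals, name order
            if j in current:
                cand = [c for c in current if c != j]
            else:
                cand = sorted(current + [j])
            a = _aic(X, y, cand)
            if a < best_aic - 1e-9:
                best_aic, best_move = a, cand
                improved = True
        if best_move is not None:
            current = best_move
    return [feats[j] for j in sorted(current)]


# ---------------------------------------------------------------------------
# criteria 2-3: lasso with the first-lambda rule, and its bootstrap

def _standardise(Z: np.ndarray) -> np.ndarray:
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (Z - mu) / sd


def _lasso_active(Z, y, lam, n) -> np.ndarray:
    """Nonzero-coefficient mask of an L1 logistic fit at penalty ``lam``
    (on the glmnet scale: mean log-loss + lam * ||beta||_1)."""
    C = 1e12 if lam == 0 else 1.0 / (n * lam)
    clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                             max_iter=2000, tol=1e-8)
    clf.fit(Z, y)
    return np.abs(clf.coef_[0]) > 1e-8


def lasso_first_lambda(fm: pd.DataFrame, cfg: SelectionConfig | None = None
                       ) -> tuple[float, list[str]]:
    """Scan lambda = 0, step, 2*step, ... and return the first penalty whose
    active set has at most ``lasso_target_vars`` features, with that set.

    If the active-set size jumps from above the target to below it without
    ever equalling it, the first lambda at or below target is returned.
    """
    cfg = cfg or SelectionConfig()
    data, feats = _complete(fm)
    y = data["label"].to_numpy(dtype=int)
    Z = _standardise(data[feats].to_numpy())
    n = len(data)
    # beyond lam_max the KKT conditions force an all-zero solution
    p_bar = y.mean()
    lam_max = float(np.max(np.abs(Z.T @ (y - p_bar))) / n)

    lam = 0.0
    while True:
        active = _lasso_active(Z, y, lam, n)
        if active.sum() <= cfg.lasso_target_vars:
            if active.sum() == 0 and lam > 0:
                logger.warning("lasso_first_lambda: active set empty at "
                               "lambda=%.3g", lam)
            return lam, [f for f, a in zip(feats, active) if a]
        lam = round(lam + cfg.lambda_step, 10)
        if lam > lam_max + cfg.lambda_step:
            logger.warning("lasso_first_lambda: grid exhausted at lambda=%.3g",
                           lam)
            return lam, []


def bootstrap_lasso(fm: pd.DataFrame, cfg: SelectionConfig | None = None
                    ) -> pd.Series:
    """Frequency with which each feature enters the lasso top-three active
    set over ``bootstrap_B`` stratified resamples (cases and controls drawn
    with replacement within class)."""
    cfg = cfg or SelectionConfig()
    data, feats = _complete(fm)
    rng = np.random.default_rng(cfg.seed)
    case_idx = np.flatnonzero(data["label"].to_numpy() == 1)
    ctrl_idx = np.flatnonzero(data["label"].to_numpy() == 0)
    if case_idx.size == 0 or ctrl_idx.size == 0:
        raise ValueError("both classes required for bootstrap lasso")
    counts = pd.Series(0.0, index=feats)
    for _ in range(cfg.bootstrap_B):
        take = np.concatenate([
            rng.choice(case_idx, size=case_idx.size, replace=True),
            rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True),
        ])
        _, selected = lasso_first_lambda(data.iloc[take], cfg)
        counts[selected] += 1.0
    return counts / cfg.bootstrap_B


# ---------------------------------------------------------------------------
# criteria 4-5: random-forest importances

def rf_importance(fm: pd.DataFrame, cfg: SelectionConfig | None = None
                  ) -> tuple[pd.Series, pd.Series]:
    """(mean accuracy decrease, Gini impurity importance) per feature from a
    seeded random forest.

    The forest is grown as an explicit bagging loop over CART trees
    (``max_features=sqrt(p)``), so the accuracy decrease can be measured
    out-of-bag: for each tree, each feature is permuted among that tree's
    out-of-bag rows and the drop in OOB accuracy is averaged over trees.
    OOB evaluation is what makes a label-independent feature's importance
    centre on zero; Gini importance is the mean per-tree impurity decrease.
    """
    cfg = cfg or SelectionConfig()
    data, feats = _complete(fm)
    y = data["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class label")
    X = data[feats].to_numpy()
    n, p = X.shape
    rng = np.random.default_rng(cfg.seed)
    mda_sum = np.zeros(p)
    gini_sum = np.zeros(p)
    n_oob_trees = 0
    for _ in range(cfg.rf_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2 ** 31)))
        tree.fit(X[idx], y[idx])
        gini_sum += tree.feature_importances_
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0 or len(np.unique(y[idx])) < 2:
            continue
        Xo, yo = X[oob], y[oob]
        base = float(np.mean(tree.predict(Xo) == yo))
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[rng.permutation(oob.size), j]
            mda_sum[j] += base - float(np.mean(tree.predict(Xp) == yo))
        n_oob_trees += 1
    mda = pd.Series(mda_sum / max(n_oob_trees, 1), index=feats)
    gini = pd.Series(gini_sum / cfg.rf_trees, index=feats)
    return mda, gini


# ---------------------------------------------------------------------------
# ensemble report and consensus pool

@dataclass
class SelectionReport:
    table: pd.DataFrame  # feature, aic, lasso, freq, mda, gini
    lasso_lambda: float
    config: SelectionConfig

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def select_features(fm: pd.DataFrame, cfg: SelectionConfig | None = None
                    ) -> SelectionReport:
    """Run all five criteria and assemble the per-feature report."""
    cfg = cfg or SelectionConfig()
    _, feats = _complete(fm)
    aic_set = set(aic_stepwise(fm))
    lam, lasso_set = lasso_first_lambda(fm, cfg)
    freq = bootstrap_lasso(fm, cfg)
    mda, gini = rf_importance(fm, cfg)
    table = pd.DataFrame({
        "feature": feats,
        "aic_selected": [f in aic_set for f in feats],
        "lasso_selected": [f in set(lasso_set) for f in feats],
        "bootstrap_frequency": freq.reindex(feats).to_numpy(),
        "rf_mda": mda.reindex(feats).to_numpy(),
        "rf_gini": gini.reindex(feats).to_numpy(),
    })
    return SelectionReport(table=table, lasso_lambda=lam, config=cfg)


def _top_m(table: pd.DataFrame, column: str, m: int) -> list[str]:
    ordered = table.sort_values([column, "feature"],
                                ascending=[False, True], kind="mergesort")
    return ordered["feature"].head(m).tolist()


def consensus_pool(report: SelectionReport,
                   cfg: SelectionConfig | None = None) -> list[str]:
    """Union of the AIC set, the lasso set, and the top-m features by
    bootstrap frequency, accuracy decrease and Gini importance; returned in
    feature-name order."""
    cfg = cfg or report.config
    t = report.table
    pool: set[str] = set()
    pool.update(t.loc[t["aic_selected"], "feature"])
    pool.update(t.loc[t["lasso_selected"], "feature"])
    for col in ("bootstrap_frequency", "rf_mda", "rf_gini"):
        pool.update(_top_m(t, col, cfg.top_m))
    return sorted(pool)
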