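"""Performance evaluation: fixed-specificity operating points, DeLong AUC,
paired McNemar comparison, calibration, and the univariate screen.

The reporting axis throughout is sensitivity at a fixed specificity: the
decision threshold is set on the control scores so that a stated fraction of
controls test negative, and the fraction of cases called positive at that
threshold is reported with a stratified-bootstrap confidence interval.
Paired superiority over the single-marker cut-off reference is tested with
the exact one-tailed McNemar test on discordant case calls, and calibration
with the Hosmer-Lemeshow goodness-of-fit statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_SPECIFICITIES = (0.903, 0.954)


# ---------------------------------------------------------------------------
# fixed-specificity operating points

def threshold_at_specificity(control_scores, target: float) -> float:
    """Smallest threshold at which the fraction of control scores strictly
    below it is at least ``target``.  Scores >= threshold are called
    positive; ties are called positive (conservative for specificity)."""
    c = np.asarray(control_scores, dtype=float)
    if c.size == 0:
        raise ValueError("no control scores")
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target specificity {target} outside [0, 1]")
    m = int(np.ceil(target * c.size))  # controls that must fall below
    if m == 0:
        return -np.inf
    u = np.unique(c)  # ascending distinct score values
    below = np.searchsorted(c[np.argsort(c)], u, side="left")
    # below[i] = #scores strictly less than u[i]
    for val, nb in zip(u, below):
        if nb >= m:
            return float(val)
    # even the maximum leaves too few below: threshold just above the max
    return float(np.nextafter(u[-1], np.inf))


def sensitivity_at_specificity(case_scores, control_scores,
                               target: float) -> tuple[float, float, float]:
    """Returns (sensitivity, achieved specificity, threshold)."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both case and control scores are required")
    thr = threshold_at_specificity(controls, target)
    sens = float(np.mean(cases >= thr))
    ach = float(np.mean(controls < thr))
    return sens, ach, thr


class BootstrapCI(NamedTuple):
    lo: float
    hi: float
    median: float


def bootstrap_sensitivity_ci(case_scores, control_scores, target: float,
                             B: int = 2000, seed: int = 0) -> BootstrapCI:
    """Percentile 95% CI for sensitivity at fixed specificity.

    Cases and controls are resampled independently with replacement
    (stratified bootstrap); the threshold and the sensitivity are recomputed
    in every replicate.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    rng = np.random.default_rng(seed)
    sens = np.empty(B)
    for b in range(B):
        cs = rng.choice(cases, size=cases.size, replace=True)
        ct = rng.choice(controls, size=controls.size, replace=True)
        sens[b], _, _ = sensitivity_at_specificity(cs, ct, target)
    lo, med, hi = np.percentile(sens, [2.5, 50.0, 97.5])
    return BootstrapCI(float(lo), float(hi), float(med))


# ---------------------------------------------------------------------------
# AUC with DeLong variance

def auc_delong(scores, labels) -> tuple[float, tuple[float, float]]:
    """AUC (Mann-Whitney with ties counted half) and its DeLong 95% CI.

    The variance uses DeLong's structural components: for each case the
    placement value against all controls and vice versa; the Wald interval
    is truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    x = scores[labels == 1]  # cases
    y = scores[labels == 0]  # controls
    if x.size == 0 or y.size == 0:
        raise ValueError("both classes must be present")
    # placement values via pairwise comparison (cohort sizes are small)
    gt = (x[:, None] > y[None, :]).astype(float)
    eq = (x[:, None] == y[None, :]).astype(float)
    psi = gt + 0.5 * eq
    v10 = psi.mean(axis=1)  # per-case component
    v01 = psi.mean(axis=0)  # per-control component
    auc = float(psi.mean())
    var = 0.0
    if x.size > 1:
        var += np.var(v10, ddof=1) / x.size
    if y.size > 1:
        var += np.var(v01, ddof=1) / y.size
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, (lo, hi)


# ---------------------------------------------------------------------------
# paired comparison and calibration

def mcnemar_exact_one_tailed(model_calls, ref_calls, labels) -> float:
    """Exact one-tailed McNemar p for the model being more sensitive than the
    reference, computed on case units only.

    With b = cases caught by the model but not the reference and c = the
    reverse, p = P(X >= b) for X ~ Binomial(b + c, 1/2); p = 1 when there is
    no discordance.
    """
    model_calls = np.asarray(model_calls, dtype=bool)
    ref_calls = np.asarray(ref_calls, dtype=bool)
    labels = np.asarray(labels, dtype=int)
    if model_calls.shape != ref_calls.shape or model_calls.shape != labels.shape:
        raise ValueError("calls and labels must be aligned")
    case = labels == 1
    b = int(np.sum(model_calls[case] & ~ref_calls[case]))
    c = int(np.sum(~model_calls[case] & ref_calls[case]))
    if b + c == 0:
        return 1.0
    return float(stats.binom.sf(b - 1, b + c, 0.5))


def hosmer_lemeshow(probs, labels, groups: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-fit statistic and p-value.

    Units are grouped into deciles of predicted risk (ties kept together);
    the statistic is sum over groups of (O - E)^2 / (E (1 - E/n_g)) with
    df = groups - 2.  Groups whose expected count is degenerate are merged
    into the neighbouring lower-risk group.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.size != labels.size:
        raise ValueError("probs and labels must be aligned")
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if probs.size < 2 * groups:
        raise ValueError(f"need at least {2 * groups} units for {groups} groups")
    if np.unique(probs).size < 3:
        raise ValueError("cannot form groups: fewer than 3 distinct probabilities")

    order = np.argsort(probs, kind="mergesort")
    p, y = probs[order], labels[order]
    # decile boundaries on ranks, ties kept together
    qs = np.quantile(p, np.linspace(0, 1, groups + 1)[1:-1], method="higher")
    edges = np.unique(qs)
    idx = np.searchsorted(edges, p, side="left")

    obs, exp, ns = [], [], []
    for g in np.unique(idx):
        sel = idx == g
        obs.append(y[sel].sum())
        exp.append(p[sel].sum())
        ns.append(sel.sum())
    # merge degenerate groups (E == 0 or E == n) downward
    i = 1
    while i < len(ns):
        if exp[i] <= 0 or exp[i] >= ns[i]:
            obs[i - 1] += obs[i]
            exp[i - 1] += exp[i]
            ns[i - 1] += ns[i]
            del obs[i], exp[i], ns[i]
        else:
            i += 1
    if exp and (exp[0] <= 0 or exp[0] >= ns[0]) and len(ns) > 1:
        obs[1] += obs[0]
        exp[1] += exp[0]
        ns[1] += ns[0]
        del obs[0], exp[0], ns[0]

    stat = 0.0
    for o, e, n in zip(obs, exp, ns):
        denom = e * (1.0 - e / n)
        if denom > 0:
            stat += (o - e) ** 2 / denom
    df = max(1, len(ns) - 2)
    pval = float(stats.chi2.sf(stat, df))
    return float(stat), pval


# ---------------------------------------------------------------------------
# univariate screen

def univariate_compare(group_a, group_b) -> tuple[str, float]:
    """Two-group comparison with a normality gate.

    If both groups pass the D'Agostino-Pearson omnibus normality test at
    alpha = 0.05, a two-sided Welch t test is used; otherwise the two-sided
    Mann-Whitney test.  Groups smaller than 8 (below the normality test's
    validity floor) default to Mann-Whitney with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if min(a.size, b.size) < 8:
        logger.warning("univariate_compare: group below n=8, using Mann-Whitney")
        return "mann-whitney", float(stats.mannwhitneyu(
            a, b, alternative="two-sided").pvalue)
    normal_a = stats.normaltest(a).pvalue > 0.05
    normal_b = stats.normaltest(b).pvalue > 0.05
    if normal_a and normal_b:
        return "t-test", float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return "mann-whitney", float(stats.mannwhitneyu(
        a, b, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# orchestration against a reference model

@dataclass
class SpecificityPoint:
    target: float
    threshold: float
    sensitivity: float
    achieved_specificity: float
    ci: BootstrapCI | None = None
    mcnemar_p: float | None = None


@dataclass
class PerformanceSummary:
    model_name: str
    n_cases: int
    n_control_units: int
    auc: float
    auc_ci: tuple[float, float]
    points: dict[float, SpecificityPoint] = field(default_factory=dict)
    hl_stat: float | None = None
    hl_p: float | None = None
    spec_unit: str = "visit"

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "n_cases": self.n_cases,
            "n_control_units": self.n_control_units,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "spec_unit": self.spec_unit,
            "hl_stat": self.hl_stat,
            "hl_p": self.hl_p,
            "points": {
                f"{t:g}": {
                    "threshold": pt.threshold,
                    "sensitivity": pt.sensitivity,
                    "achieved_specificity": pt.achieved_specificity,
                    "ci": list(pt.ci[:2]) if pt.ci else None,
                    "bootstrap_median": pt.ci.median if pt.ci else None,
                    "mcnemar_p": pt.mcnemar_p,
                }
                for t, pt in self.points.items()
            },
        }


def _case_unit_scores(fitted, fm_eval) -> "pd.Series":
    """Predicted probability of each case subject at its final eligible unit.

    The final eligible unit is the subject's last row in the evaluation
    matrix; subjects whose final row lacks the model's features are dropped
    with a logged count."""
    import pandas as pd  # local to keep module import light

    cases = fm_eval[fm_eval["label"] == 1]
    finals = cases.groupby("subject_id", sort=True).tail(1)
    probs = fitted.predict(finals)
    dropped = len(finals) - len(probs)
    if dropped:
        logger.info("evaluate: %d case subjects lack features at their final "
                    "unit and were dropped", dropped)
    return pd.Series(probs.values, index=finals.loc[probs.index, "subject_id"].values)


def evaluate_model(fitted, fm_eval, reference=None, spec_unit: str = "visit",
                   targets=DEFAULT_SPECIFICITIES, bootstrap_B: int = 2000,
                   seed: int = 0) -> PerformanceSummary:
    """Full fixed-specificity evaluation of a fitted model.

    Control scores are taken per ``spec_unit``: every control row of the
    evaluation matrix in visit mode (rolling matrix), or one score per
    control subject in subject mode (terminal matrix).  Case positivity is
    judged at each case subject's final eligible unit.  If ``reference`` is
    given it is scored on the identical case units and compared by the exact
    one-tailed McNemar test at each target specificity.
    """
    if spec_unit not in ("visit", "subject"):
        raise ValueError(f"unknown spec_unit {spec_unit!r}")

    controls = fm_eval[fm_eval["label"] == 0]
    if spec_unit == "subject":
        controls = controls.groupby("subject_id", sort=True).tail(1)
    control_scores = fitted.predict(controls)
    case_scores = _case_unit_scores(fitted, fm_eval)
    if control_scores.empty or case_scores.empty:
        raise ValueError("evaluation requires scored units in both classes")

    ref_case_scores = ref_control_scores = None
    if reference is not None:
        ref_controls = fm_eval[fm_eval["label"] == 0]
        if spec_unit == "subject":
            ref_controls = ref_controls.groupby("subject_id", sort=True).tail(1)
        ref_control_scores = reference.predict(ref_controls)
        ref_case_scores = _case_unit_scores(reference, fm_eval)

    scores = np.concatenate([case_scores.values, control_scores.values])
    labels = np.concatenate([np.ones(case_scores.size, dtype=int),
                             np.zeros(control_scores.size, dtype=int)])
    auc, auc_ci = auc_delong(scores, labels)

    hl_stat = hl_p = None
    try:
        hl_stat, hl_p = hosmer_lemeshow(scores, labels)
    except ValueError as exc:
        logger.info("evaluate: Hosmer-Lemeshow unavailable (%s)", exc)

    summary = PerformanceSummary(
        model_name=getattr(getattr(fitted, "spec", None), "name", "model"),
        n_cases=int(case_scores.size),
        n_control_units=int(control_scores.size),
        auc=auc, auc_ci=auc_ci, hl_stat=hl_stat, hl_p=hl_p,
        spec_unit=spec_unit,
    )
    for i, target in enumerate(targets):
        sens, ach, thr = sensitivity_at_specificity(
            case_scores.values, control_scores.values, target)
        ci = bootstrap_sensitivity_ci(
            case_scores.values, control_scores.values, target,
            B=bootstrap_B, seed=seed + i)
        mcp = None
        if reference is not None:
            common = case_scores.index.intersection(ref_case_scores.index)
            ref_thr = threshold_at_specificity(ref_control_scores.values, target)
            model_calls = case_scores.loc[common].values >= thr
            ref_calls = ref_case_scores.loc[common].values >= ref_thr
            mcp = mcnemar_exact_one_tailed(
                model_calls, ref_calls, np.ones(common.size, dtype=int))
        summary.points[target] = SpecificityPoint(
            target=target, threshold=thr, sensitivity=sens,
            achieved_specificity=ach, ci=ci, mcnemar_p=mcp)
    return summary
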