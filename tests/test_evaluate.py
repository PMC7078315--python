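import itertools

import numpy as np
import pytest
from scipy import stats

from seratrend.evaluate import (
    auc_delong,
    bootstrap_sensitivity_ci,
    evaluate_model,
    hosmer_lemeshow,
    mcnemar_exact_one_tailed,
    sensitivity_at_specificity,
    threshold_at_specificity,
    univariate_compare,
)


class TestThresholdAtSpecificity:
    def test_31_controls_at_0903_leaves_at_most_3_positive(self, rng):
        controls = rng.normal(size=31)
        thr = threshold_at_specificity(controls, 0.903)
        assert np.sum(controls >= thr) <= 3
        assert np.mean(controls < thr) >= 0.903

    def test_hand_enumerated_example(self):
        thr = threshold_at_specificity([0.1, 0.2, 0.9], 0.66)
        assert thr == 0.9
        sens, ach, _ = sensitivity_at_specificity([1.0], [0.1, 0.2, 0.9], 0.66)
        assert ach == pytest.approx(2 / 3)

    def test_target_zero_gives_all_positive_sentinel(self):
        thr = threshold_at_specificity([0.5, 0.7], 0.0)
        assert thr == -np.inf
        assert np.all(np.array([0.1, 0.5]) >= thr)

    def test_minimality_exhaustive_small_instances(self):
        """On every multiset of <= 6 scores from a small alphabet and a grid
        of targets, the returned threshold achieves the specificity and no
        smaller candidate threshold does."""
        values = [0.1, 0.2, 0.2, 0.5, 0.9]
        for n in (1, 2, 3, 6):
            for scores in itertools.combinations_with_replacement(values, n):
                scores = np.array(scores)
                for target in (0.2, 0.5, 0.66, 0.9, 1.0):
                    thr = threshold_at_specificity(scores, target)
                    assert np.mean(scores < thr) >= target
                    smaller = np.unique(scores[scores < thr])
                    for cand in smaller:
                        assert np.mean(scores < cand) < target

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError, match="control"):
            threshold_at_specificity([], 0.9)


class TestSensitivity:
    def test_perfect_separation_gives_full_sensitivity(self):
        sens, _, _ = sensitivity_at_specificity([10, 11, 12], [1, 2, 3], 0.9)
        assert sens == 1.0

    def test_exchangeable_scores_sensitivity_complements_target(self, rng):
        scores = rng.normal(size=200)
        sens, ach, _ = sensitivity_at_specificity(scores, scores, 0.9)
        # identical multisets: sensitivity ~ 1 - achieved specificity
        assert sens == pytest.approx(1 - ach, abs=0.01)

    def test_visit_level_order_statistic_arithmetic(self, rng):
        controls = rng.normal(size=175)
        case = [controls.max() + 1.0]
        sens, _, thr = sensitivity_at_specificity(case, controls, 0.954)
        assert sens == 1.0
        # ceil(0.954 * 175) = 167 controls below the threshold
        assert np.sum(controls < thr) == 167
        assert np.sum(controls >= thr) == 8

    def test_sensitivity_monotone_in_target(self, rng):
        cases = rng.normal(1.0, 1.0, size=50)
        controls = rng.normal(size=80)
        sens = [sensitivity_at_specificity(cases, controls, t)[0]
                for t in (0.5, 0.7, 0.9, 0.954, 0.99)]
        assert all(a >= b for a, b in zip(sens, sens[1:]))


class TestBootstrapCI:
    def test_perfectly_separated_ci_is_degenerate(self):
        ci = bootstrap_sensitivity_ci([5, 6, 7], [1, 2, 3], 0.9, B=200, seed=0)
        assert ci.lo == ci.hi == 1.0

    def test_point_estimate_within_ci(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            cases = r.normal(0.8, 1, size=30)
            controls = r.normal(size=40)
            sens, _, _ = sensitivity_at_specificity(cases, controls, 0.903)
            ci = bootstrap_sensitivity_ci(cases, controls, 0.903,
                                          B=2000, seed=seed)
            assert ci.lo - 1e-9 <= sens <= ci.hi + 1e-9

    def test_ci_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (20, 200):
            ws = []
            for seed in range(5):
                r = np.random.default_rng(seed)
                cases = r.normal(1.0, 1, size=n)
                controls = r.normal(size=n)
                ci = bootstrap_sensitivity_ci(cases, controls, 0.903,
                                              B=500, seed=seed)
                ws.append(ci.hi - ci.lo)
            widths[n] = np.mean(ws)
        assert widths[200] < widths[20]

    def test_small_B_rejected(self):
        with pytest.raises(ValueError, match="B"):
            bootstrap_sensitivity_ci([1], [0], 0.9, B=50)


class TestDelongAuc:
    def test_separated_and_tied_trivia(self):
        auc, _ = auc_delong([2, 3, 0, 1], [1, 1, 0, 0])
        assert auc == 1.0
        auc, _ = auc_delong([1.0, 1.0], [1, 0])
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            n1, n0 = rng.integers(2, 26, size=2)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # force ties
            labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            auc, _ = auc_delong(scores, labels)
            x, y = scores[:n1], scores[n1:]
            pairs = sum(1.0 if a > b else 0.5 if a == b else 0.0
                        for a in x for b in y)
            assert auc == pytest.approx(pairs / (n1 * n0), abs=1e-12)

    def test_ci_matches_r_proc_oracle_values(self):
        """Frozen from pROC::ci.auc(delong) in R for this exact instance."""
        cases = [2.1, 1.3, 3.5, 0.9, 2.8, 1.7]
        controls = [0.2, 1.1, 0.4, 1.9, 0.7, 0.3, 1.2]
        scores = np.array(cases + controls)
        labels = np.r_[np.ones(6, int), np.zeros(7, int)]
        auc, (lo, hi) = auc_delong(scores, labels)
        assert auc == pytest.approx(0.880952381, abs=1e-9)
        assert lo == pytest.approx(0.6893003474, abs=1e-6)
        assert hi == pytest.approx(1.0, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            auc_delong([1, 2], [1, 1])


class TestMcNemar:
    @pytest.mark.parametrize("b,c,expected", [
        (6, 0, 0.015625),            # (1/2)^6
        (3, 3, 0.65625),             # binomial tail P(X>=3), n=6
        (0, 5, 1.0),                 # wrong-direction discordance
        (0, 0, 1.0),                 # no discordance
    ])
    def test_closed_form_binomial_tail(self, b, c, expected):
        n = b + c + 4
        model = np.r_[np.ones(b), np.zeros(c), np.ones(2), np.zeros(2),
                      ].astype(bool)
        ref = np.r_[np.zeros(b), np.ones(c), np.ones(2), np.zeros(2),
                    ].astype(bool)
        labels = np.ones(n, int)
        p = mcnemar_exact_one_tailed(model, ref, labels)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_p_is_one_when_model_calls_subset_of_reference(self, rng):
        ref = rng.random(30) < 0.7
        model = ref & (rng.random(30) < 0.8)  # strict subset direction
        p = mcnemar_exact_one_tailed(model, ref, np.ones(30, int))
        assert p == 1.0

    def test_only_cases_enter_the_comparison(self):
        model = np.array([True, False, True, False])
        ref = np.array([False, False, False, True])
        labels = np.array([1, 1, 0, 0])  # discordance among controls ignored
        p = mcnemar_exact_one_tailed(model, ref, labels)
        assert p == pytest.approx(0.5)  # b=1, c=0 among cases


class TestHosmerLemeshow:
    def test_group_calibrated_probs_give_zero_statistic(self):
        # ten distinct risk levels, observed rate equal to the risk in each
        probs, labels = [], []
        for i, p in enumerate(np.linspace(0.05, 0.5, 10)):
            probs += [p] * 20
            k = round(20 * p)
            labels += [1] * k + [0] * (20 - k)
        probs = np.array(probs)
        labels = np.array(labels)
        # make observed rates exactly equal to expected in each group
        for i in range(10):
            sel = slice(20 * i, 20 * (i + 1))
            probs[sel] = labels[sel].mean() if 0 < labels[sel].mean() < 1 \
                else probs[sel]
        stat, p = hosmer_lemeshow(probs, labels)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_gross_miscalibration_detected(self):
        probs = np.full(200, 0.9)
        probs[:3] = [0.88, 0.89, 0.91]  # 3 distinct values to allow grouping
        labels = np.r_[np.ones(20, int), np.zeros(180, int)]
        stat, p = hosmer_lemeshow(probs, labels)
        assert p < 0.001

    def test_well_calibrated_null_rate(self):
        ok = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            probs = r.uniform(0.05, 0.95, size=500)
            labels = r.binomial(1, probs)
            _, p = hosmer_lemeshow(probs, labels)
            ok += p > 0.05
        assert ok >= 45

    def test_input_contracts(self):
        with pytest.raises(ValueError, match="groups"):
            hosmer_lemeshow(np.linspace(0.1, 0.9, 10), np.zeros(10, int))
        with pytest.raises(ValueError, match="distinct"):
            hosmer_lemeshow(np.full(40, 0.5), np.zeros(40, int))
        with pytest.raises(ValueError, match="strictly"):
            hosmer_lemeshow(np.r_[0.0, np.linspace(0.2, 0.8, 39)],
                            np.zeros(40, int))


class TestUnivariateCompare:
    def test_normal_samples_use_t_test(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        test, p = univariate_compare(a, b)
        assert test == "t-test"

    def test_lognormal_samples_use_mann_whitney(self, rng):
        a = np.exp(rng.normal(size=60) * 2)
        b = np.exp(rng.normal(size=60) * 2)
        test, _ = univariate_compare(a, b)
        assert test == "mann-whitney"

    def test_identical_distinct_groups_give_p_one(self):
        g = list(range(10))
        test, p = univariate_compare(g, g)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_null_p_values_approximately_uniform(self):
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            _, p = univariate_compare(r.normal(size=50), r.normal(size=50))
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_small_groups_error_or_fallback(self, rng):
        with pytest.raises(ValueError):
            univariate_compare([1.0, 2.0], [1.0, 2.0, 3.0])
        test, _ = univariate_compare(rng.normal(size=5), rng.normal(size=50))
        assert test == "mann-whitney"


class TestEvaluateModel:
    @staticmethod
    def _eval_matrix(seed=0, n_cases=25, n_controls=30, visits=3):
        import pandas as pd
        r = np.random.default_rng(seed)
        rows, idx = [], []
        for i in range(n_cases + n_controls):
            label = int(i < n_cases)
            base = r.normal(label * 1.5, 1.0)
            for v in range(visits):
                rows.append({"subject_id": f"s{i:03d}", "visit_age": 60.0 + v,
                             "label": label, "X{5}": base + 0.1 * v
                             + r.normal(0, 0.2)})
                idx.append(f"s{i:03d}@{v}")
        return pd.DataFrame(rows, index=idx)

    def test_reference_compared_to_itself(self):
        from seratrend.models import ModelSpec, fit_logistic
        fm = self._eval_matrix()
        fitted = fit_logistic(ModelSpec(("X{5}",)), fm)
        summary = evaluate_model(fitted, fm, reference=fitted,
                                 spec_unit="visit", bootstrap_B=200, seed=1)
        for pt in summary.points.values():
            assert pt.mcnemar_p == 1.0

    def test_visit_specificity_unit_counts_control_visits(self):
        from seratrend.models import ModelSpec, fit_logistic
        fm = self._eval_matrix(n_controls=40, visits=5)  # 200 control visits
        fitted = fit_logistic(ModelSpec(("X{5}",)), fm)
        summary = evaluate_model(fitted, fm, spec_unit="visit",
                                 bootstrap_B=200, seed=2)
        assert summary.n_control_units == 200
        pt = summary.points[0.954]
        assert pt.achieved_specificity >= 0.954

    def test_subject_specificity_unit_counts_subjects(self):
        from seratrend.models import ModelSpec, fit_logistic
        fm = self._eval_matrix()
        fitted = fit_logistic(ModelSpec(("X{5}",)), fm)
        summary = evaluate_model(fitted, fm, spec_unit="subject",
                                 bootstrap_B=200, seed=3)
        assert summary.n_control_units == 30

    def test_unit_kind_validated(self):
        from seratrend.models import ModelSpec, fit_logistic
        fm = self._eval_matrix()
        fitted = fit_logistic(ModelSpec(("X{5}",)), fm)
        with pytest.raises(ValueError, match="spec_unit"):
            evaluate_model(fitted, fm, spec_unit="sample")
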