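"""Stratified splitting, AUC, confusion metrics and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trigrs.cohort import ResponseLabel
from trigrs.evaluation import (
    auc_roc,
    confusion_metrics,
    cross_validate,
    run_prediction_protocol,
    stratified_split,
)


def study_labels(n_resp=80, n_nonresp=60):
    ids = [f"s{i}" for i in range(n_resp + n_nonresp)]
    return pd.Series([True] * n_resp + [False] * n_nonresp, index=ids)


def auc_pairwise_oracle(scores, labels):
    """Brute-force Mann-Whitney count over all label-discordant pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestStratifiedSplit:
    def test_study_sized_split(self):
        plan = stratified_split(study_labels(), fraction=0.5, seed=1)
        labels = study_labels()
        train = labels[plan.train_ids]
        test = labels[plan.test_ids]
        assert len(plan.train_ids) == 70 and len(plan.test_ids) == 70
        assert train.sum() == 40 and (~train).sum() == 30
        assert test.sum() == 40 and (~test).sum() == 30
        assert set(plan.train_ids).isdisjoint(plan.test_ids)

    def test_folds_partition_and_stratify(self):
        plan = stratified_split(study_labels(), fraction=0.5, seed=2, folds=10)
        labels = study_labels()
        all_fold_ids = [i for f in range(1, 11) for i in plan.fold_ids(f)]
        assert sorted(all_fold_ids) == sorted(plan.train_ids)
        for f in range(1, 11):
            fold = labels[plan.fold_ids(f)]
            assert fold.sum() == 4 and (~fold).sum() == 3

    def test_deterministic_given_seed(self):
        a = stratified_split(study_labels(), seed=7)
        b = stratified_split(study_labels(), seed=7)
        assert a == b
        c = stratified_split(study_labels(), seed=8)
        assert a != c

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(study_labels(), fraction=1.0)

    def test_tiny_class_rejected(self):
        labels = pd.Series([True] * 10 + [False], index=[f"s{i}" for i in range(11)])
        with pytest.raises(ValueError, match="at least 2"):
            stratified_split(labels)


class TestAucRoc:
    def test_perfect_separation(self):
        auc, _ = auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.binomial(1, 0.5, size=2000)
        auc, (lo, hi) = auc_roc(scores, labels)
        assert abs(auc - 0.5) < 0.05
        assert lo <= auc <= hi

    def test_constant_scores_warn(self):
        with pytest.warns(UserWarning, match="constant"):
            auc, _ = auc_roc(np.ones(10), [1] * 5 + [0] * 5)
        assert auc == 0.5

    def test_tied_toy_set_matches_enumeration(self):
        scores = [1, 2, 2, 3, 3, 3, 4, 5]
        labels = [0, 0, 1, 0, 1, 1, 0, 1]
        auc, _ = auc_roc(scores, labels)
        assert auc == pytest.approx(auc_pairwise_oracle(scores, labels))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)
        labels = rng.binomial(1, 0.5, size=40)
        a1, _ = auc_roc(scores, labels)
        a2, _ = auc_roc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)

    @settings(deadline=None, max_examples=200)
    @given(
        n=st.integers(4, 50),
        seed=st.integers(0, 10_000),
    )
    def test_property_sweep_against_pairwise_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        labels = rng.binomial(1, 0.5, size=n).astype(bool)
        if labels.all() or not labels.any() or np.ptp(scores) == 0:
            return
        auc, _ = auc_roc(scores, labels)
        assert auc == pytest.approx(auc_pairwise_oracle(scores, labels), abs=1e-12)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        m = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (1, 1, 1)

    def test_complement_prediction(self):
        m = confusion_metrics([0, 1, 0], [1, 0, 1])
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (0, 0, 0)

    def test_constructed_two_by_two(self):
        # TP=29, FN=11, TN=24, FP=6
        actual = [1] * 40 + [0] * 30
        predicted = [1] * 29 + [0] * 11 + [0] * 24 + [1] * 6
        m = confusion_metrics(predicted, actual)
        assert m["accuracy"] == pytest.approx(53 / 70)
        assert m["sensitivity"] == pytest.approx(29 / 40)
        assert m["specificity"] == pytest.approx(24 / 30)
        lo, hi = m["accuracy_ci"]
        assert 0 <= lo < 53 / 70 < hi <= 1

    def test_no_positives_gives_nan_sensitivity(self):
        m = confusion_metrics([0, 0], [0, 0])
        assert np.isnan(m["sensitivity"])


class TestCrossValidate:
    def test_perfectly_separating_grs(self, default_cohort):
        """A GRS that cleanly separates the groups yields test accuracy 1."""
        labels = default_cohort.labels()
        labels = labels[labels != ResponseLabel.unclassified.value]
        grs = pd.Series(
            [-5.0 if v == "responder" else 5.0 for v in labels],
            index=labels.index,
        )
        plan = stratified_split(labels, seed=3)
        with pytest.warns(UserWarning, match="separation"):
            cv_rep, test_rep, train_rep = cross_validate(
                default_cohort, None, (), plan, grs=grs
            )
        assert test_rep.accuracy == 1.0
        assert test_rep.auc == 1.0

    def test_bitwise_reproducibility(self, default_cohort, base_variant_ids):
        runs = [
            run_prediction_protocol(
                default_cohort, variant_ids=base_variant_ids, seed=17
            )
            for _ in range(2)
        ]
        assert runs[0].plan == runs[1].plan
        assert runs[0].test_report == runs[1].test_report
        assert runs[0].cv_report == runs[1].cv_report

    def test_train_metrics_exceed_test_on_average(self, base_variant_ids):
        """Optimism: training discrimination is on average at least the
        held-out discrimination over repeated splits."""
        from trigrs.synthetic import GeneratorConfig, generate_cohort

        cohort = generate_cohort(GeneratorConfig(seed=23, base_maf_responders=0.25,
                                                 base_maf_nonresponders=0.35))
        gaps = []
        for seed in range(8):
            res = run_prediction_protocol(cohort, variant_ids=base_variant_ids,
                                          seed=seed)
            gaps.append(res.train_report.auc - res.test_report.auc)
        assert np.mean(gaps) > 0

    def test_metric_panel_within_bounds(self, default_cohort, base_variant_ids):
        res = run_prediction_protocol(default_cohort, variant_ids=base_variant_ids,
                                      seed=29)
        for rep in (res.cv_report, res.test_report, res.train_report):
            for value in (rep.accuracy, rep.auc, rep.sensitivity, rep.specificity,
                          rep.mcfadden):
                assert 0.0 <= value <= 1.0
        lo, hi = res.test_report.accuracy_ci
        assert 0 <= lo <= res.test_report.accuracy <= hi <= 1
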