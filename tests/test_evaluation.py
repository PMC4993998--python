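import itertools

import numpy as np
import pytest

from fcfmtex.evaluation import (
    annotation_feature_baseline,
    auc,
    concat_baseline,
    cross_val_probabilities,
    evaluate_features,
    make_cv_plan,
    null_auc_band,
    repeated_split_signtest,
)


# -- CV plan ------------------------------------------------------------------

def test_plan_fold_sizes_91_into_5():
    y = np.r_[np.ones(25), np.zeros(66)].astype(int)
    plan = make_cv_plan(y, k=5, seed=0)
    sizes = sorted(np.bincount(plan.assignment), reverse=True)
    assert sizes == [19, 18, 18, 18, 18]


def test_plan_partition_and_determinism():
    y = np.r_[np.ones(10), np.zeros(20)].astype(int)
    a = make_cv_plan(y, seed=3)
    b = make_cv_plan(y, seed=3)
    np.testing.assert_array_equal(a.assignment, b.assignment)
    assert np.bincount(a.assignment).sum() == 30
    # stratification: every fold holds both classes
    for f in range(5):
        assert len(np.unique(y[a.assignment == f])) == 2


def test_plan_rejects_single_class():
    with pytest.raises(ValueError):
        make_cv_plan(np.zeros(20, dtype=int))


# -- AUC ----------------------------------------------------------------------

def test_auc_reference_values():
    assert auc([0.1, 0.2, 0.9, 0.8], [0, 0, 1, 1]) == 1.0
    assert auc([0.9, 0.8, 0.3], [1, 0, 1]) == 0.5  # 1 concordant of 2 pairs
    assert auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5  # all ties


def _auc_pair_oracle(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    c = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return c / (len(pos) * len(neg))


def test_auc_exhaustive_pair_counting_all_short_vectors(rng):
    # every labeling of random distinct scores for n <= 8
    for n in range(2, 9):
        scores = rng.permutation(np.linspace(0.1, 0.9, n))
        for labels in itertools.product([0, 1], repeat=n):
            if 0 < sum(labels) < n:
                assert auc(scores, labels) == pytest.approx(
                    _auc_pair_oracle(scores, labels), abs=1e-12
                )


def test_auc_complement_under_score_negation(rng):
    scores = rng.uniform(size=20)
    labels = (rng.uniform(size=20) < 0.4).astype(int)
    assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    scores = rng.choice(np.linspace(0, 1, 11), size=50)  # with ties
    labels = (rng.uniform(size=50) < 0.3).astype(int)
    assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


# -- null band ----------------------------------------------------------------

def test_null_band_contains_half_and_shrinks_with_n():
    y91 = np.r_[np.ones(25), np.zeros(66)].astype(int)
    y910 = np.repeat(y91, 10)
    lo1, hi1 = null_auc_band(y91, n_draws=4000, seed=0)
    lo2, hi2 = null_auc_band(y910, n_draws=4000, seed=0)
    assert lo1 < 0.5 < hi1
    assert (hi2 - lo2) < (hi1 - lo1)
    assert null_auc_band(y91, seed=5) == null_auc_band(y91, seed=5)


# -- sign test ----------------------------------------------------------------

def test_signtest_binomial_tails():
    assert repeated_split_signtest(np.full(16, 0.8), 0.7) == pytest.approx(0.5**16)
    mixed = np.r_[np.full(8, 0.8), np.full(8, 0.6)]
    assert repeated_split_signtest(mixed, 0.7) == pytest.approx(0.5984, abs=1e-3)
    # 0 of 16 above: the exact one-sided p-value P[X >= 0] is 1
    assert repeated_split_signtest(np.full(16, 0.6), 0.7) == 1.0
    assert repeated_split_signtest(np.full(4, 0.7), 0.7) == 1.0  # all ties dropped


# -- cross-validated probabilities -------------------------------------------

def test_cv_probabilities_cover_everyone_once(rng):
    X = rng.normal(size=(40, 3))
    y = (X[:, 0] > 0).astype(int)
    plan = make_cv_plan(y, seed=0)
    p = cross_val_probabilities(X, y, "rf", plan, seed=0)
    assert p.shape == (40,) and np.all((p >= 0) & (p <= 1))


def test_cv_informative_feature_high_auc(rng):
    X = rng.normal(size=(100, 2))
    y = (X[:, 0] + 0.1 * rng.normal(size=100) > 0).astype(int)
    plan = make_cv_plan(y, seed=1)
    p = cross_val_probabilities(X, y, "rf", plan, seed=1)
    assert auc(p, y) >= 0.95


def test_cv_label_independent_feature_near_chance():
    aucs = []
    for s in range(10):
        r = np.random.default_rng(70 + s)
        X = r.normal(size=(60, 5))
        y = (r.uniform(size=60) < 0.35).astype(int)
        plan = make_cv_plan(y, seed=s)
        aucs.append(auc(cross_val_probabilities(X, y, "rf", plan, seed=s), y))
    lo, hi = null_auc_band(y, seed=0)
    assert lo - 0.05 < np.median(aucs) < hi + 0.05


# -- baselines ----------------------------------------------------------------

def test_concat_baseline_dimension_and_coverage(rng):
    n = 40
    clin = rng.normal(size=(n, 12))
    img = rng.normal(size=(n, 30))
    y = (clin[:, 0] > 0).astype(int)
    plan = make_cv_plan(y, seed=0)
    res = concat_baseline(clin, img, y, "rf", plan, seed=0)
    assert res.meta["dim"] == 42
    assert res.per_item_probability.shape == (n,)


def test_annotation_identical_to_label_leaks_to_perfect_auc(rng):
    n = 60
    clin = rng.normal(size=(n, 12))
    y = (rng.uniform(size=n) < 0.4).astype(int)
    ann = y.astype(float)
    res = annotation_feature_baseline(clin, ann, y, seed=0)
    assert res["clinical_13"].auc > 0.95
    assert res["clinical_13"].meta["dim"] == 13


def test_annotation_independent_of_label_does_not_help(rng):
    deltas = []
    for s in range(5):
        r = np.random.default_rng(80 + s)
        n = 80
        clin = r.normal(size=(n, 12))
        y = (clin[:, 0] + r.normal(size=n) > 0).astype(int)
        ann = (r.uniform(size=n) < 0.5).astype(float)
        res = annotation_feature_baseline(clin, ann, y, seed=s)
        deltas.append(res["clinical_13"].auc - res["clinical_12"].auc)
    assert np.median(deltas) <= 0.05


def test_annotation_subset_restriction(rng):
    n = 50
    clin = rng.normal(size=(n, 12))
    y = np.r_[np.ones(20), np.zeros(30)].astype(int)
    ann = np.full(n, np.nan)
    ann[:40] = y[:40]
    res = annotation_feature_baseline(clin, ann, y, seed=0)
    assert res["clinical_12"].meta["n"] == 40


def test_evaluate_features_repeats_and_signtest(rng):
    X = rng.normal(size=(60, 4))
    y = (X[:, 0] > 0).astype(int)
    res = evaluate_features(X, y, "rf", seed=0, n_repeats=4, baseline_auc=0.5)
    assert res.splits_auc.shape == (4,)
    assert res.signtest_p is not None and res.signtest_p < 0.1
    assert res.in_null_band() is False  # strong signal sits above the band


def test_evaluation_result_serialization(tmp_path, rng):
    X = rng.normal(size=(40, 3))
    y = (X[:, 0] > 0).astype(int)
    res = evaluate_features(X, y, "rf", seed=0, n_repeats=2, baseline_auc=0.5)
    res.save(tmp_path / "eval", patient_ids=[f"P{i}" for i in range(40)])
    import json

    summary = json.loads((tmp_path / "eval.json").read_text())
    assert summary["auc"] == pytest.approx(res.auc)
    import pandas as pd

    tsv = pd.read_csv(tmp_path / "eval.tsv", sep="\t")
    assert len(tsv) == 40 and tsv["patient_id"][0] == "P0"


def test_concat_with_uninformative_imaging_below_risk_model():
    # a locally trained classifier on [12 clinical | 80 noise] columns at small
    # n cannot match the published calculator evaluated with no training
    from fcfmtex.risk import cohort_risk_probabilities
    from fcfmtex.synthetic import SyntheticConfig, generate_cohort

    deltas = []
    for s in range(5):
        c = generate_cohort(
            SyntheticConfig(n_patients=60, frame_size=32, frames_median=3,
                            frames_sigma=0.0, seed=200 + s)
        )
        r = np.random.default_rng(s)
        clin = c.clinical_matrix()
        img = r.normal(size=(60, 80))  # label-independent imaging stand-in
        plan = make_cv_plan(c.labels, seed=s)
        res = concat_baseline(clin, img, c.labels, "rf", plan, seed=s)
        a_clin = auc(cohort_risk_probabilities(c.clinical, "mayo"), c.labels)
        deltas.append(res.auc - a_clin)
    assert np.median(deltas) <= 0.0
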