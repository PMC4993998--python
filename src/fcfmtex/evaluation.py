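"""Cross-validated evaluation: AUC, random-classifier null band, sign test, baselines.

The protocol evaluated here: patients are split into 5 groups (stratified by
label; one patient — hence one video — never straddles train and test), the
imaging classifier is trained on four groups and scores the fifth, and the
pooled out-of-fold probabilities are summarized by the area under the ROC
curve. Because an AUC on ~91 patients is noisy, two calibration devices frame
every comparison:

* a **null band** — Monte-Carlo (0.05, 0.95) quantiles of the AUC when scores
  are uniform random, i.e. the interval a chance-level classifier lands in;
* a **repeated-split sign test** — the 5-fold split is redrawn (default 16
  times) and an exact one-sided binomial sign test asks whether the median
  AUC is genuinely above a fixed baseline (ties dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import binom, rankdata
from sklearn.model_selection import StratifiedKFold

from .classifiers import TrainedModel, train_classifier, train_plain_logistic

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# CV plan
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Fold assignment of patients (videos); grouping unit = patient."""

    n_items: int
    k_folds: int
    assignment: np.ndarray  # item -> fold index
    seed: int

    def folds(self):
        for f in range(self.k_folds):
            te = np.where(self.assignment == f)[0]
            tr = np.where(self.assignment != f)[0]
            yield tr, te


def make_cv_plan(labels: np.ndarray, k: int = 5, seed: int = 0,
                 stratified: bool = True) -> CVPlan:
    """Random k-fold partition of patients, stratified by label by default.

    Stratification keeps each fold near the 3:1 cohort imbalance and avoids
    one-class test folds.
    """
    labels = np.asarray(labels).astype(int)
    n = labels.size
    if n < k:
        raise ValueError("fewer items than folds")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    assignment = np.empty(n, dtype=int)
    if stratified:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (_, te) in enumerate(skf.split(np.zeros((n, 1)), labels)):
            assignment[te] = f
    else:
        rng = np.random.default_rng(seed)
        assignment = np.array_split(rng.permutation(n), k)
        a = np.empty(n, dtype=int)
        for f, idx in enumerate(assignment):
            a[idx] = f
        assignment = a
    return CVPlan(n_items=n, k_folds=k, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# AUC and null band
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: (concordant + 0.5·tied) / (n_pos · n_neg), via midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def null_auc_band(
    labels: np.ndarray,
    n_draws: int = 10000,
    quantiles: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo quantiles of the AUC under uniform-random classifier output."""
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    scores = rng.uniform(size=(n_draws, labels.size))
    ranks = rankdata(scores, axis=1)
    u = ranks[:, labels == 1].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    aucs = u / (n_pos * n_neg)
    lo, hi = np.quantile(aucs, quantiles)
    return float(lo), float(hi)


def repeated_split_signtest(splits_auc: np.ndarray, baseline_auc: float) -> float:
    """Exact one-sided sign test: are the per-split AUCs above the baseline?

    Ties (AUC == baseline) are dropped; p = P[Bin(n, 1/2) >= k] where k is the
    number of splits strictly above the baseline.
    """
    splits_auc = np.asarray(splits_auc, dtype=float)
    if splits_auc.size < 1:
        raise ValueError("need at least one repeat")
    above = int((splits_auc > baseline_auc).sum())
    below = int((splits_auc < baseline_auc).sum())
    n = above + below
    if n == 0:
        return 1.0
    return float(binom.sf(above - 1, n, 0.5))  # P[X >= above]


# ---------------------------------------------------------------------------
# cross-validated probabilities
# ---------------------------------------------------------------------------

TrainFn = Callable[[np.ndarray, np.ndarray], TrainedModel]


def cross_val_probabilities(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str | TrainFn,
    plan: CVPlan,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold malignancy probabilities for every patient.

    ``classifier`` is a trainer name ("lasso", "gpc", "rf", "plain_logistic")
    or a callable ``(X_train, y_train) -> TrainedModel``. For fold-dependent
    feature construction (bag-of-words codebooks) see
    :func:`cross_val_probabilities_dynamic`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    out = np.full(y.size, np.nan)
    for tr, te in plan.folds():
        if len(np.unique(y[tr])) < 2:
            logger.warning("one-class training fold; classifier contract decides")
        model = (
            train_classifier(classifier, X[tr], y[tr], seed=seed)
            if isinstance(classifier, str)
            else classifier(X[tr], y[tr])
        )
        out[te] = model.predict_proba(X[te])
    assert not np.isnan(out).any()
    return out


def cross_val_probabilities_dynamic(
    build_features: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]],
    y: np.ndarray,
    classifier: str | TrainFn,
    plan: CVPlan,
    seed: int = 0,
) -> np.ndarray:
    """As :func:`cross_val_probabilities`, but features are rebuilt inside each
    fold: ``build_features(train_idx, test_idx) -> (X_train, X_test)``.

    This is how bag-of-words evaluation preserves fold discipline — the
    codebook is clustered from training-fold descriptors only.
    """
    y = np.asarray(y).astype(int)
    out = np.full(y.size, np.nan)
    for tr, te in plan.folds():
        X_tr, X_te = build_features(tr, te)
        model = (
            train_classifier(classifier, X_tr, y[tr], seed=seed)
            if isinstance(classifier, str)
            else classifier(X_tr, y[tr])
        )
        out[te] = model.predict_proba(X_te)
    assert not np.isnan(out).any()
    return out


# ---------------------------------------------------------------------------
# results container and baselines
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Out-of-fold probabilities and their AUC summary for one configuration."""

    per_item_probability: np.ndarray
    auc: float
    null_band: tuple[float, float] | None = None
    splits_auc: np.ndarray | None = None
    signtest_p: float | None = None
    meta: dict = field(default_factory=dict)

    def in_null_band(self) -> bool | None:
        if self.null_band is None:
            return None
        lo, hi = self.null_band
        return lo <= self.auc <= hi

    def save(self, path_prefix, patient_ids: list[str] | None = None) -> None:
        """Serialize: JSON summary + per-patient probability TSV."""
        import json
        from pathlib import Path

        import pandas as pd

        prefix = Path(path_prefix)
        summary = {
            "auc": self.auc,
            "null_band": self.null_band,
            "splits_auc": None if self.splits_auc is None else list(self.splits_auc),
            "signtest_p": self.signtest_p,
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (str, int, float, bool, type(None)))},
        }
        prefix.with_suffix(".json").write_text(json.dumps(summary, default=float))
        ids = patient_ids or [str(i) for i in range(self.per_item_probability.size)]
        pd.DataFrame(
            {"patient_id": ids, "probability": self.per_item_probability}
        ).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)


def evaluate_features(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str,
    seed: int = 0,
    k: int = 5,
    n_repeats: int = 1,
    baseline_auc: float | None = None,
    compute_null_band: bool = True,
) -> EvaluationResult:
    """Full CV evaluation of one feature matrix + classifier.

    With ``n_repeats > 1`` the 5-fold split is redrawn with seeds
    ``seed + repeat`` and the sign test against ``baseline_auc`` is attached.
    The reported probabilities and AUC come from the first split.
    """
    y = np.asarray(y).astype(int)
    split_aucs, first_probs = [], None
    for rep in range(n_repeats):
        plan = make_cv_plan(y, k=k, seed=seed + rep)
        probs = cross_val_probabilities(X, y, classifier, plan, seed=seed + rep)
        if first_probs is None:
            first_probs = probs
        split_aucs.append(auc(probs, y))
    band = null_auc_band(y, seed=seed) if compute_null_band else None
    p = (
        repeated_split_signtest(np.array(split_aucs), baseline_auc)
        if (baseline_auc is not None and n_repeats > 1)
        else None
    )
    return EvaluationResult(
        per_item_probability=first_probs,
        auc=split_aucs[0],
        null_band=band,
        splits_auc=np.array(split_aucs),
        signtest_p=p,
        meta={"classifier": classifier, "k": k, "seed": seed,
              "median_auc": float(np.median(split_aucs))},
    )


def concat_baseline(
    clinical_features: np.ndarray,
    imaging_features: np.ndarray,
    y: np.ndarray,
    classifier: str,
    plan: CVPlan,
    seed: int = 0,
) -> EvaluationResult:
    """Classifier on [clinical | imaging] concatenated, same CV protocol.

    The alternative to probability fusion: a single classifier must find the
    12 relevant clinical columns among hundreds of imaging ones.
    """
    X = np.concatenate([np.asarray(clinical_features, float),
                        np.asarray(imaging_features, float)], axis=1)
    probs = cross_val_probabilities(X, y, classifier, plan, seed=seed)
    return EvaluationResult(
        per_item_probability=probs,
        auc=auc(probs, y),
        meta={"dim": X.shape[1], "classifier": classifier},
    )


def annotation_feature_baseline(
    clinical_features: np.ndarray,
    expert_annotation: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    k: int = 5,
) -> dict[str, EvaluationResult]:
    """Plain-logistic CV with 12 features vs 13 (expert call appended).

    Patients with no annotation (NaN) are dropped from *both* evaluations so
    the two AUCs are computed on the same subset.
    """
    ann = np.asarray(expert_annotation, dtype=float)
    keep = ~np.isnan(ann)
    Xc = np.asarray(clinical_features, float)[keep]
    ya = np.asarray(y).astype(int)[keep]
    X13 = np.concatenate([Xc, ann[keep][:, None]], axis=1)
    plan = make_cv_plan(ya, k=k, seed=seed)
    out = {}
    for key, X in (("clinical_12", Xc), ("clinical_13", X13)):
        probs = cross_val_probabilities(
            X, ya, lambda A, b: train_plain_logistic(A, b, seed=seed), plan
        )
        out[key] = EvaluationResult(
            per_item_probability=probs, auc=auc(probs, ya),
            meta={"n": int(keep.sum()), "dim": X.shape[1]},
        )
    return out
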