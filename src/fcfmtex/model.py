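"""Model/Results interface for the full fusion analysis.

:class:`NoduleFusionModel` bundles the whole protocol — imaging features,
cross-validated probabilistic classifier, clinical risk calculator, probability
fusion, null band and repeated-split sign test — behind a statsmodels-like
``model.fit() -> results`` pair.

    >>> cohort = generate_cohort(SyntheticConfig(n_patients=60, seed=1))
    >>> model = NoduleFusionModel.from_cohort(cohort, scheme="lbp", classifier="rf")
    >>> res = model.fit(seed=0)
    >>> print(res.summary())

The scientific question the results answer: does video texture add predictive
value over the clinical calculator alone? ``res.auc_fused - res.auc_clinical``
is the headline difference, read against ``res.null_band`` (chance-level AUC
fluctuation) and ``res.signtest_p`` (is the median fused AUC over redrawn CV
splits genuinely above the clinical baseline?).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bow as _bow
from .evaluation import (
    CVPlan,
    auc,
    cross_val_probabilities,
    cross_val_probabilities_dynamic,
    make_cv_plan,
    null_auc_band,
    repeated_split_signtest,
)
from .fusion import FusionConfig, choose_best_rule, default_candidates
from .io import ClinicalRecord
from .lbp import video_lbp_feature
from .risk import cohort_risk_probabilities
from .scattering import video_scattering_feature
from .synthetic import SyntheticCohort


class NoduleFusionModel:
    """Fusion analysis of one cohort: imaging features + clinical risk model.

    Parameters
    ----------
    imaging : (n, d) array or list of per-video DescriptorSet
        Precomputed video features, or descriptor sets when ``scheme='bow'``
        (the codebook must be rebuilt inside each training fold).
    clinical : list of ClinicalRecord
    labels : (n,) 0/1 array
    classifier : {"lasso", "gpc", "rf"}
    risk_model : {"mayo", "brock"}
    """

    def __init__(
        self,
        imaging,
        clinical: list[ClinicalRecord],
        labels: np.ndarray,
        classifier: str = "rf",
        risk_model: str = "mayo",
        scheme: str = "precomputed",
        k_folds: int = 5,
        bow_k: int = _bow.DEFAULT_K,
    ):
        self.labels = np.asarray(labels).astype(int)
        self.clinical = clinical
        self.classifier = classifier
        self.risk_model = risk_model
        self.scheme = scheme
        self.k_folds = k_folds
        self.bow_k = bow_k
        if scheme == "bow":
            self.descriptor_sets = list(imaging)
            self.X = None
            n = len(self.descriptor_sets)
        else:
            self.X = np.asarray(imaging, dtype=float)
            self.descriptor_sets = None
            n = self.X.shape[0]
        if not (n == len(clinical) == self.labels.size):
            raise ValueError("imaging, clinical and labels must be aligned")

    # ------------------------------------------------------------------
    @classmethod
    def from_cohort(
        cls,
        cohort: SyntheticCohort,
        scheme: str = "lbp",
        classifier: str = "rf",
        risk_model: str = "mayo",
        seed: int = 0,
        bow_cap: int = _bow.DEFAULT_CAP,
        bow_k: int = _bow.DEFAULT_K,
        scattering_config=None,
    ) -> "NoduleFusionModel":
        """Extract features of one scheme from a cohort and build the model."""
        if scheme == "lbp":
            imaging = np.stack(
                [video_lbp_feature(v).vector for v in cohort.videos]
            )
        elif scheme == "scattering":
            imaging = np.stack(
                [video_scattering_feature(v, scattering_config).vector
                 for v in cohort.videos]
            )
        elif scheme == "bow":
            rng = np.random.default_rng(seed)
            imaging = [
                _bow.sample_descriptors(v, rng, cap=bow_cap) for v in cohort.videos
            ]
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        return cls(
            imaging, cohort.clinical, cohort.labels,
            classifier=classifier, risk_model=risk_model, scheme=scheme,
            bow_k=bow_k,
        )

    # ------------------------------------------------------------------
    def _imaging_probs(self, plan: CVPlan, seed: int) -> np.ndarray:
        if self.scheme != "bow":
            return cross_val_probabilities(
                self.X, self.labels, self.classifier, plan, seed=seed
            )

        def build(tr, te):
            book = _bow.build_codebook(
                [self.descriptor_sets[i] for i in tr], k=self.bow_k, seed=seed
            )
            X_tr = np.stack(
                [_bow.bow_histogram(self.descriptor_sets[i], book).vector for i in tr]
            )
            X_te = np.stack(
                [_bow.bow_histogram(self.descriptor_sets[i], book).vector for i in te]
            )
            return X_tr, X_te

        return cross_val_probabilities_dynamic(
            build, self.labels, self.classifier, plan, seed=seed
        )

    def fit(self, seed: int = 0, n_repeats: int = 16) -> "NoduleFusionResults":
        """Run the full protocol.

        The fusion rule is chosen by AUC on the first split only (the selection
        is not nested, hence potentially optimistic — the summary flags it);
        the sign test then compares the fused AUC across ``n_repeats`` redrawn
        splits against the fixed clinical-only baseline.
        """
        y = self.labels
        p_clinical = cohort_risk_probabilities(self.clinical, self.risk_model)
        auc_clinical = auc(p_clinical, y)
        prevalence = float(y.mean())
        priors = (1.0 - prevalence, prevalence)

        imaging_aucs, fused_aucs = [], []
        best_rule: FusionConfig | None = None
        first = {}
        for rep in range(n_repeats):
            plan = make_cv_plan(y, k=self.k_folds, seed=seed + rep)
            p_img = self._imaging_probs(plan, seed=seed + rep)
            imaging_aucs.append(auc(p_img, y))
            if best_rule is None:
                cands = [
                    (cfg, auc(cfg.combine(p_clinical, p_img), y))
                    for cfg in default_candidates(priors)
                ]
                best_rule = choose_best_rule(cands)
                first = {
                    "p_imaging": p_img,
                    "p_fused": best_rule.combine(p_clinical, p_img),
                    "candidates": cands,
                }
            fused_aucs.append(auc(best_rule.combine(p_clinical, p_img), y))

        band = null_auc_band(y, seed=seed)
        p_sign = (
            repeated_split_signtest(np.array(fused_aucs), auc_clinical)
            if n_repeats > 1 else None
        )
        return NoduleFusionResults(
            model=self,
            p_clinical=p_clinical,
            p_imaging=first["p_imaging"],
            p_fused=first["p_fused"],
            auc_clinical=auc_clinical,
            imaging_aucs=np.array(imaging_aucs),
            fused_aucs=np.array(fused_aucs),
            best_rule=best_rule,
            rule_candidates=first["candidates"],
            null_band=band,
            signtest_p=p_sign,
            seed=seed,
        )


@dataclass
class NoduleFusionResults:
    """Fitted fusion analysis: probabilities, AUCs, null band, sign test."""

    model: NoduleFusionModel
    p_clinical: np.ndarray
    p_imaging: np.ndarray
    p_fused: np.ndarray
    auc_clinical: float
    imaging_aucs: np.ndarray
    fused_aucs: np.ndarray
    best_rule: FusionConfig
    rule_candidates: list
    null_band: tuple[float, float]
    signtest_p: float | None
    seed: int = 0
    _extra: dict = field(default_factory=dict)

    @property
    def auc_imaging(self) -> float:
        return float(np.median(self.imaging_aucs))

    @property
    def auc_fused(self) -> float:
        return float(np.median(self.fused_aucs))

    @property
    def improvement(self) -> float:
        """Median fused AUC minus the clinical-only AUC."""
        return self.auc_fused - self.auc_clinical

    def summary(self) -> str:
        m = self.model
        lo, hi = self.null_band
        lines = [
            "Nodule malignancy fusion analysis",
            "=" * 54,
            f"n patients            {m.labels.size:>6d}   (malignant {int(m.labels.sum())})",
            f"imaging scheme        {m.scheme:>12s}   classifier {m.classifier}",
            f"risk calculator       {m.risk_model:>12s}",
            "-" * 54,
            f"AUC clinical (risk model)      {self.auc_clinical:7.3f}",
            f"AUC imaging  (median/{len(self.imaging_aucs)} splits) {self.auc_imaging:7.3f}",
            f"AUC fused    (median/{len(self.fused_aucs)} splits) {self.auc_fused:7.3f}",
            f"chance-level AUC band (5-95%)  ({lo:.3f}, {hi:.3f})",
            f"fusion rule (chosen on split 1, not nested): {self.best_rule.describe()}",
        ]
        if self.signtest_p is not None:
            lines.append(
                f"sign test fused > clinical     p = {self.signtest_p:.3f}"
                f" ({'not ' if self.signtest_p > 0.05 else ''}significant)"
            )
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_aucs(self, ax=None):
        """Bar chart of the three AUCs against the chance-level band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        names = ["clinical", "imaging", "fused"]
        vals = [self.auc_clinical, self.auc_imaging, self.auc_fused]
        ax.bar(names, vals, color=["#888", "#4878a8", "#b8503c"])
        ax.axhspan(*self.null_band, alpha=0.2, color="gray", label="chance band")
        ax.axhline(0.5, ls=":", color="k", lw=0.8)
        ax.set_ylabel("AUC")
        ax.set_ylim(0, 1)
        ax.legend(frameon=False)
        return ax
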