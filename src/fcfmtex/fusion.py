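"""Probability fusion of the clinical risk calculator and the imaging classifier.

Two parameter-light rules combine the clinical malignancy probability
p(y1|x1) with the imaging probability p(y1|x2):

* **product-over-prior** — per class k, score_k = p(y_k|x1)·p(y_k|x2)/P(y_k),
  renormalized over the two classes (the Bayes combination under conditional
  independence of the two information sources given the class).
* **α-mean** — per class, the one-parameter mean family m_α applied to the two
  class probabilities, then renormalized. m_α is realized as the power mean of
  order t = (1-α)/2, the family containing all four stated special cases:
  arithmetic mean (α = -1), geometric mean (α = 1, the t→0 limit),
  min (α = +∞) and max (α = -∞).

Probabilities are clipped to [1e-6, 1-1e-6] before product/geometric forms so
a classifier that emits exactly 0 or 1 cannot annihilate the combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

CLIP = 1e-6

#: candidate α grid evaluated when choosing the best rule
DEFAULT_ALPHA_GRID = (-math.inf, -4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0, math.inf)


@dataclass(frozen=True)
class FusionConfig:
    rule: str  # "product_prior" | "alpha_mean"
    alpha: float = 1.0
    priors: tuple[float, float] = (0.5, 0.5)  # (P(y0)=benign, P(y1)=malignant)

    def __post_init__(self) -> None:
        if self.rule not in ("product_prior", "alpha_mean"):
            raise ValueError(f"unknown fusion rule {self.rule!r}")
        p0, p1 = self.priors
        if not (p0 > 0 and p1 > 0 and abs(p0 + p1 - 1.0) < 1e-9):
            raise ValueError("priors must be strictly positive and sum to 1")

    def combine(self, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
        if self.rule == "product_prior":
            return product_prior_combine(p1, p2, self.priors)
        return alpha_mean_combine(p1, p2, self.alpha)

    def describe(self) -> str:
        if self.rule == "product_prior":
            return f"product/prior (P(y1)={self.priors[1]:.3f})"
        return f"alpha-mean (alpha={self.alpha:g})"


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), CLIP, 1.0 - CLIP)


def product_prior_combine(
    p1: np.ndarray | float, p2: np.ndarray | float, priors: tuple[float, float]
) -> np.ndarray | float:
    """Product-of-posteriors-over-prior rule; returns p(y1 | x1, x2)."""
    prior0, prior1 = priors
    if prior0 <= 0 or prior1 <= 0:
        raise ValueError("degenerate priors")
    p1c, p2c = _clip(p1), _clip(p2)
    s1 = p1c * p2c / prior1
    s0 = (1 - p1c) * (1 - p2c) / prior0
    out = s1 / (s0 + s1)
    return float(out) if np.isscalar(p1) and np.isscalar(p2) else out


def power_mean(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Two-point power mean of order t; t=0 geometric, t=±inf max/min."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if t == 0.0:
        return np.sqrt(a * b)
    if math.isinf(t):
        return np.maximum(a, b) if t > 0 else np.minimum(a, b)
    return (0.5 * (a**t + b**t)) ** (1.0 / t)


def alpha_mean(a, b, alpha: float):
    """m_α: power mean of order (1-α)/2 (α=-1 arithmetic, 1 geometric, ±∞ min/max)."""
    if math.isinf(alpha):
        t = -math.inf if alpha > 0 else math.inf
    else:
        t = (1.0 - alpha) / 2.0
    return power_mean(a, b, t)


def alpha_mean_combine(
    p1: np.ndarray | float, p2: np.ndarray | float, alpha: float
) -> np.ndarray | float:
    """Per-class α-mean of the two posteriors, renormalized across classes."""
    p1c, p2c = _clip(p1), _clip(p2)
    s1 = alpha_mean(p1c, p2c, alpha)
    s0 = alpha_mean(1 - p1c, 1 - p2c, alpha)
    out = s1 / (s0 + s1)
    return float(out) if np.isscalar(p1) and np.isscalar(p2) else out


def default_candidates(priors: tuple[float, float]) -> list[FusionConfig]:
    """The rule grid searched by :func:`choose_best_rule`."""
    cands = [FusionConfig(rule="product_prior", priors=priors)]
    cands += [FusionConfig(rule="alpha_mean", alpha=a, priors=priors)
              for a in DEFAULT_ALPHA_GRID]
    return cands


def choose_best_rule(rule_aucs: list[tuple[FusionConfig, float]]) -> FusionConfig:
    """Pick the rule with the highest evaluation AUC.

    Chosen on the same split it is evaluated on (not nested-cross-validated),
    so the selection is potentially optimistic — callers should treat the
    winning rule's AUC accordingly. Ties break to the product rule, then to
    the α-mean with the smallest |α|.
    """
    if not rule_aucs:
        raise ValueError("empty candidate set")

    def key(item):
        cfg, auc = item
        is_alpha = cfg.rule == "alpha_mean"
        return (-auc, 1 if is_alpha else 0, abs(cfg.alpha) if is_alpha else 0.0)

    return sorted(rule_aucs, key=key)[0][0]
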