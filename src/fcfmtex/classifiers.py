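"""Probabilistic classifiers for video features: lasso GLM, GP classifier, random forest.

All three share one contract: ``train_*`` returns a :class:`TrainedModel` whose
``predict_proba(X)`` gives the malignancy probability per row. The class
imbalance of a nodule cohort (~3:1 benign:malignant) is modest, so no explicit
imbalance correction is applied anywhere.

* **Lasso logistic GLM** — Bernoulli likelihood, logit link, L1 penalty; the
  penalty λ is chosen by 5-fold cross-validated deviance over a grid of 100
  values: 99 geometrically spaced in [0.001·λ_max, λ_max] plus the unpenalized
  endpoint λ=0, where λ_max = max|X_std^T (y - ȳ)|/n is the smallest λ with
  all coefficients zero. Features are standardized internally; the intercept is
  unpenalized. The sparse penalty is what makes a 1401-dim feature vector
  workable at n ≈ 91.
* **GP classifier** — constant mean m, isotropic squared-exponential kernel
  κ(x, x') = s·exp(-||x-x'||²/(2σ²)), probit likelihood, expectation
  propagation (EP) posterior. Hyperparameters (m, σ, s) maximize the EP
  marginal likelihood from the initial guesses (mean output value, median
  inter-sample distance, 1).
* **Random forest** — 100 bagged trees, minimum 3 samples per leaf,
  ceil(sqrt(d)) candidate features per split; the predicted probability is the
  fraction of tree votes.
* **Plain logistic** — unpenalized maximum likelihood, for the small clinical
  feature sets (12/13 features) where no sparsity is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import pdist
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold


@dataclass
class TrainedModel:
    """A fitted classifier with a uniform predict contract."""

    scheme: str  # lasso_glm | gpc | rf | plain_logistic
    feature_dim: int
    _predict: Callable[[np.ndarray], np.ndarray]
    training_meta: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Malignancy probability per row of X (values in [0, 1])."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.feature_dim:
            raise ValueError(
                f"expected {self.feature_dim} features, got {X.shape[1]}"
            )
        p = self._predict(X)
        return np.clip(p, 0.0, 1.0)


def _check_Xy(X: np.ndarray, y: np.ndarray, min_n: int = 10) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, d) aligned with y")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if X.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    return X, y


# ---------------------------------------------------------------------------
# lasso logistic GLM
# ---------------------------------------------------------------------------

def lasso_lambda_max(X_std: np.ndarray, y: np.ndarray) -> float:
    """Smallest λ at which every (standardized) coefficient is zero."""
    r = y - y.mean()
    return float(np.max(np.abs(X_std.T @ r)) / y.size)


def _lambda_grid(lam_max: float, n_lambda: int = 100) -> np.ndarray:
    grid = np.geomspace(1e-3 * lam_max, lam_max, n_lambda - 1)
    return np.concatenate([[0.0], grid])


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, mu, sd


def _l1_logistic_path(C: float) -> LogisticRegression:
    # fast path solver for the λ-grid search; its slight intercept shrinkage
    # (intercept_scaling spreads the L1 weight 1:100) does not move the CV
    # deviance argmin materially
    return LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", intercept_scaling=100.0,
        random_state=0,
    )


def _l1_logistic_final(C: float) -> LogisticRegression:
    # exact fit at the chosen λ: saga leaves the intercept unpenalized, so at
    # λ >= λ_max the model predicts exactly the class prevalence
    return LogisticRegression(
        l1_ratio=1.0, C=C, solver="saga", max_iter=5000, tol=1e-6, random_state=0
    )


def train_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    n_lambda: int = 100,
    seed: int = 0,
) -> TrainedModel:
    """L1-penalized logistic regression with CV-selected λ (see module docstring)."""
    X, y = _check_Xy(X, y)
    Xs, mu, sd = _standardize(X)
    n = y.size
    lam_max = lasso_lambda_max(Xs, y)
    lambdas = _lambda_grid(lam_max, n_lambda)
    # descending λ for warm starts along the path
    order = np.argsort(lambdas)[::-1]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    deviance = np.zeros(lambdas.size)
    for tr, te in skf.split(Xs, y):
        for li in order:
            lam = lambdas[li]
            C = 1e12 if lam == 0 else 1.0 / (tr.size * lam)
            clf = _l1_logistic_path(C).fit(Xs[tr], y[tr])
            p = np.clip(clf.predict_proba(Xs[te])[:, 1], 1e-12, 1 - 1e-12)
            deviance[li] += -2.0 * np.sum(
                y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p)
            )

    best = int(np.argmin(deviance))
    lam = lambdas[best]
    C = 1e12 if lam == 0 else 1.0 / (n * lam)
    final = _l1_logistic_final(C).fit(Xs, y)
    coef, intercept = final.coef_[0].copy(), float(final.intercept_[0])

    def predict(Xnew: np.ndarray) -> np.ndarray:
        Z = (Xnew - mu) / sd
        from scipy.special import expit

        return expit(Z @ coef + intercept)

    return TrainedModel(
        scheme="lasso_glm",
        feature_dim=X.shape[1],
        _predict=predict,
        training_meta={
            "seed": seed,
            "lambda": float(lam),
            "lambda_max": lam_max,
            "n_nonzero": int(np.count_nonzero(coef)),
            "cv_deviance": deviance[best] / n,
            "coef": coef,
            "intercept": intercept,
        },
    )


# ---------------------------------------------------------------------------
# Gaussian process classifier (EP)
# ---------------------------------------------------------------------------

def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    d2 = (
        (A**2).sum(axis=1)[:, None]
        - 2.0 * A @ B.T
        + (B**2).sum(axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def _ep_fit(K: np.ndarray, y_pm: np.ndarray, m: float, max_sweeps: int = 15,
            tol: float = 1e-5) -> dict:
    """Expectation propagation for probit-likelihood GP classification.

    Works on the zero-mean part g = f - m; the constant prior mean enters only
    through the probit moment matching. Returns site parameters, the EP
    approximate log marginal likelihood, and the quantities needed to predict.
    """
    n = K.shape[0]
    nu, tau = np.zeros(n), np.zeros(n)
    Sigma, mu = K.copy(), np.zeros(n)
    logZ = -np.inf
    for _ in range(max_sweeps):
        nu_old, tau_old = nu.copy(), tau.copy()
        for i in range(n):
            tau_cav = 1.0 / Sigma[i, i] - tau[i]
            nu_cav = mu[i] / Sigma[i, i] - nu[i]
            if tau_cav <= 1e-12:
                continue
            s2_cav = 1.0 / tau_cav
            mu_cav = nu_cav * s2_cav
            denom = np.sqrt(1.0 + s2_cav)
            z = y_pm[i] * (mu_cav + m) / denom
            ratio = np.exp(norm.logpdf(z) - norm.logcdf(z))
            mu_hat = mu_cav + y_pm[i] * s2_cav * ratio / denom
            s2_hat = s2_cav - s2_cav**2 * ratio * (z + ratio) / (1.0 + s2_cav)
            s2_hat = max(s2_hat, 1e-10)
            d_tau = 1.0 / s2_hat - tau_cav - tau[i]
            tau[i] = max(tau[i] + d_tau, 1e-10)
            nu[i] = mu_hat / s2_hat - nu_cav
            # rank-1 refresh of (Sigma, mu)
            si = Sigma[:, i]
            Sigma = Sigma - (d_tau / (1.0 + d_tau * si[i])) * np.outer(si, si)
            mu = Sigma @ nu
        # full refresh for numerical stability
        sqrt_tau = np.sqrt(tau)
        B = np.eye(n) + sqrt_tau[:, None] * K * sqrt_tau[None, :]
        Lb = cholesky(B, lower=True)
        V = solve_triangular(Lb, sqrt_tau[:, None] * K, lower=True)
        Sigma = K - V.T @ V
        mu = Sigma @ nu

        if max(np.abs(nu - nu_old).max(), np.abs(tau - tau_old).max()) < tol:
            break

    # EP evidence: sum of site normalizers + Gaussian overlap of sites & prior
    s2_site = 1.0 / tau
    mu_site = nu * s2_site
    diagS = Sigma.diagonal()
    tau_cav = 1.0 / diagS - tau
    tau_cav = np.maximum(tau_cav, 1e-12)
    nu_cav = mu / diagS - nu
    s2_cav = 1.0 / tau_cav
    mu_cav = nu_cav * s2_cav
    z = y_pm * (mu_cav + m) / np.sqrt(1.0 + s2_cav)
    A = K + np.diag(s2_site)
    cf = cho_factor(A, lower=True)
    alpha = cho_solve(cf, mu_site)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    log_overlap = -0.5 * (mu_site @ alpha) - 0.5 * logdet - 0.5 * K.shape[0] * np.log(2 * np.pi)
    logZ = float(
        np.sum(
            norm.logcdf(z)
            + 0.5 * np.log(2 * np.pi * (s2_cav + s2_site))
            + (mu_cav - mu_site) ** 2 / (2.0 * (s2_cav + s2_site))
        )
        + log_overlap
    )
    return {"nu": nu, "tau": tau, "alpha": alpha, "cho": cf, "logZ": logZ,
            "mu_site": mu_site}


def train_gp_classifier(
    X: np.ndarray,
    y: np.ndarray,
    optimize: bool = True,
    max_opt_iter: int = 30,
) -> TrainedModel:
    """EP Gaussian process classifier with marginal-likelihood hyperparameters.

    Initial guesses: m = mean of the ±1 outputs, σ = median pairwise Euclidean
    distance of X, s = 1. Optimization is bounded quasi-Newton (L-BFGS-B) on
    (m, log σ, log s).
    """
    X, y = _check_Xy(X, y)
    y_pm = np.where(y == 1, 1.0, -1.0)
    n = X.shape[0]
    D2 = _sq_dists(X, X)

    med = float(np.median(pdist(X))) if n > 1 else 1.0
    med = max(med, 1e-6)
    theta0 = np.array([y_pm.mean(), np.log(med), 0.0])  # (m, log sigma, log s)

    def kernel_from(D2_: np.ndarray, log_sigma: float, log_s: float) -> np.ndarray:
        return np.exp(log_s) * np.exp(-D2_ / (2.0 * np.exp(2.0 * log_sigma)))

    def neg_logZ(theta: np.ndarray) -> float:
        m, ls, lh = theta
        K = kernel_from(D2, ls, lh) + 1e-8 * np.eye(n)
        try:
            return -_ep_fit(K, y_pm, m)["logZ"]
        except np.linalg.LinAlgError:
            return 1e10

    theta = theta0
    if optimize:
        res = minimize(
            neg_logZ,
            theta0,
            method="L-BFGS-B",
            bounds=[(-3, 3), (np.log(med) - 5, np.log(med) + 5), (-5, 5)],
            options={"maxiter": max_opt_iter, "eps": 1e-3, "gtol": 1e-3, "ftol": 1e-7},
        )
        if np.isfinite(res.fun):
            theta = res.x

    m, ls, lh = theta
    K = kernel_from(D2, ls, lh) + 1e-8 * np.eye(n)
    fit = _ep_fit(K, y_pm, m)
    alpha, cf = fit["alpha"], fit["cho"]

    def predict(Xnew: np.ndarray) -> np.ndarray:
        Ks = kernel_from(_sq_dists(Xnew, X), ls, lh)
        mean_g = Ks @ alpha
        v = cho_solve(cf, Ks.T)
        var = np.maximum(np.exp(lh) - np.einsum("ij,ji->i", Ks, v), 1e-12)
        return norm.cdf((mean_g + m) / np.sqrt(1.0 + var))

    return TrainedModel(
        scheme="gpc",
        feature_dim=X.shape[1],
        _predict=predict,
        training_meta={
            "m": float(m),
            "sigma": float(np.exp(ls)),
            "s": float(np.exp(lh)),
            "sigma_init": med,
            "m_init": float(y_pm.mean()),
            "log_marginal_likelihood": fit["logZ"],
        },
    )


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

def train_random_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    min_leaf: int = 3,
    seed: int = 0,
) -> TrainedModel:
    """Bagged decision trees: 100 trees, min 3 samples/leaf, ceil(sqrt(d))
    candidate variables per split; probability = fraction of tree votes."""
    X, y = _check_Xy(X, y)
    d = X.shape[1]
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        min_samples_leaf=min_leaf,
        max_features=int(np.ceil(np.sqrt(d))),
        bootstrap=True,
        random_state=seed,
    ).fit(X, y)
    classes = list(rf.classes_)
    pos_label = rf.classes_[classes.index(1)]

    def predict(Xnew: np.ndarray) -> np.ndarray:
        # probability = fraction of tree votes (not averaged leaf posteriors)
        votes = np.stack([t.predict(Xnew) == pos_label for t in rf.estimators_])
        return votes.mean(axis=0)

    return TrainedModel(
        scheme="rf",
        feature_dim=d,
        _predict=predict,
        training_meta={"seed": seed, "n_trees": n_trees, "min_leaf": min_leaf,
                       "mtry": int(np.ceil(np.sqrt(d))), "estimator": rf},
    )


# ---------------------------------------------------------------------------
# plain logistic (for small clinical feature sets)
# ---------------------------------------------------------------------------

def train_plain_logistic(X: np.ndarray, y: np.ndarray, seed: int = 0) -> TrainedModel:
    X, y = _check_Xy(X, y)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000).fit(X, y)
    pos = list(clf.classes_).index(1)

    def predict(Xnew: np.ndarray) -> np.ndarray:
        return clf.predict_proba(Xnew)[:, pos]

    return TrainedModel(
        scheme="plain_logistic",
        feature_dim=X.shape[1],
        _predict=predict,
        training_meta={"coef": clf.coef_[0], "intercept": float(clf.intercept_[0])},
    )


TRAINERS = {
    "lasso": train_lasso_logistic,
    "lasso_glm": train_lasso_logistic,
    "gpc": train_gp_classifier,
    "rf": train_random_forest,
    "plain_logistic": train_plain_logistic,
}


def train_classifier(name: str, X: np.ndarray, y: np.ndarray, seed: int = 0) -> TrainedModel:
    """Uniform entry point; ``seed`` is ignored by the deterministic GPC."""
    if name not in TRAINERS:
        raise ValueError(f"unknown classifier {name!r}")
    if name == "gpc":
        return train_gp_classifier(X, y)
    return TRAINERS[name](X, y, seed=seed)
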