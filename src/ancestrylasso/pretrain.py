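"""Two-stage pretrained lasso for ancestry-diverse groups.

Stage one fits an overall L1-penalized logistic model on the pooled
multi-ancestry training data and keeps the cross-validation-minimizing
coefficients ``beta0`` (intercept ``mu0``, support ``S``).  Stage two fits,
for each ancestry group k, a lasso on that group's rows only, guided by the
overall model through

* an offset ``(1 - alpha) * (X_k beta0 + mu0)`` added to the linear
  predictor with coefficient frozen at one, and
* penalty factors ``pf_j = (1 - alpha) * [I(j not in S)/alpha + I(j in S)]``,

where ``alpha in [0, 1]`` mixes between fully shared (alpha=0: offset is
the whole pooled prediction, off-support features excluded) and fully
group-specific (alpha=1: zero offset).  At alpha=1 the printed formula
zeroes every penalty factor; with the default mean-one penalty-factor
normalization of the lasso solver this reduces to an ordinary lasso, while
``normalize_pf=False`` applies the all-zero factors literally (an
unpenalized second stage).  Both behaviors are selectable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import lasso as _lasso

__all__ = [
    "PretrainBasis",
    "GroupAdjustment",
    "PretrainedModel",
    "fit_overall",
    "compute_offset",
    "compute_penalty_factors",
    "fit_group_models",
    "predict_group",
]


@dataclass
class PretrainBasis:
    """Stage-one artifacts: overall coefficients, support and alpha."""

    beta0: np.ndarray
    mu0: float
    support: np.ndarray  # indices j with beta0_j != 0
    alpha: float
    lambda_chosen: float = np.nan

    def __post_init__(self):
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        implied = np.flatnonzero(self.beta0)
        if not np.array_equal(np.sort(self.support), implied):
            raise ValueError("support inconsistent with beta0")


@dataclass
class GroupAdjustment:
    """Offset and penalty factors for one ancestry group's second stage."""

    group: str
    offset: np.ndarray
    penalty_factors: np.ndarray


@dataclass
class PretrainedModel:
    """Stage-one basis plus per-ancestry second-stage fits."""

    basis: PretrainBasis
    group_fits: dict  # ancestry -> dict(mu, beta, lambda, cv)
    fallback_groups: list = field(default_factory=list)
    normalize_pf: bool = True

    def to_json(self) -> str:
        def _fit(d):
            beta = d["beta"]
            nz = np.flatnonzero(beta)
            return {
                "mu": float(d["mu"]),
                "beta_sparse": [[int(j), float(beta[j])] for j in nz],
                "p": int(beta.size),
                "lambda": float(d["lambda"]),
            }

        return json.dumps(
            {
                "alpha": self.basis.alpha,
                "mu0": self.basis.mu0,
                "beta0_sparse": [
                    [int(j), float(self.basis.beta0[j])] for j in self.basis.support
                ],
                "p": int(self.basis.beta0.size),
                "normalize_pf": self.normalize_pf,
                "group_fits": {k: _fit(v) for k, v in self.group_fits.items()},
                "fallback_groups": list(self.fallback_groups),
            }
        )


def fit_overall(X, y, alpha: float = 0.5, cv_seed: int = 0, k_folds: int = 3,
                n_lambda: int = 100) -> PretrainBasis:
    """Stage one: pooled lasso, coefficients at the CV-minimizing lambda."""
    problem = _lasso.LassoProblem(X, y)
    lambdas = _lasso.default_lambda_grid(problem, n_lambda)
    cv = _lasso.cross_validate(problem, lambdas=lambdas, k_folds=k_folds, seed=cv_seed)
    path = _lasso.fit_lasso_path(problem, lambdas=lambdas)
    mu0, beta0 = path.coef_at(cv.index_min)
    return PretrainBasis(
        beta0=beta0,
        mu0=mu0,
        support=np.flatnonzero(beta0),
        alpha=alpha,
        lambda_chosen=cv.lambda_min,
    )


def compute_offset(basis: PretrainBasis, X_k) -> np.ndarray:
    """Second-stage offset: exactly ``(1 - alpha) * (X_k beta0 + mu0)``."""
    X_k = np.asarray(X_k, dtype=float)
    if X_k.shape[1] != basis.beta0.size:
        raise ValueError("X_k column count does not match beta0")
    return (1.0 - basis.alpha) * (X_k @ basis.beta0 + basis.mu0)


def compute_penalty_factors(basis: PretrainBasis, p: int | None = None) -> np.ndarray:
    """Second-stage penalty factors from the stage-one support.

    ``pf_j = (1 - alpha) * [I(j not in S)/alpha + I(j in S)]``; at alpha=0
    the off-support limit is +inf (feature excluded), at alpha=1 every
    factor is 0 (see the module docstring for how the lasso solver's
    penalty-factor normalization treats that literal edge).
    """
    alpha = basis.alpha
    p = basis.beta0.size if p is None else p
    in_s = np.zeros(p, dtype=bool)
    in_s[basis.support] = True
    pf = np.empty(p)
    pf[in_s] = 1.0 - alpha
    if alpha == 0.0:
        pf[~in_s] = np.inf
    else:
        pf[~in_s] = (1.0 - alpha) / alpha
    return pf


def fit_group_models(basis: PretrainBasis, X, y, groups, cv_seed: int = 0,
                     k_folds: int = 3, n_lambda: int = 100,
                     normalize_pf: bool = True) -> PretrainedModel:
    """Stage two: one offset-guided lasso per ancestry group.

    ``groups`` is the per-row ancestry label vector.  Each group's lambda
    is chosen by its own stratified CV.  A group whose rows contain a
    single outcome class falls back to the overall model (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    pf = compute_penalty_factors(basis, X.shape[1])
    fits: dict = {}
    fallbacks: list = []
    for g in np.unique(groups):
        rows = groups == g
        yk = y[rows]
        if np.unique(yk).size < 2 or min((yk == 0).sum(), (yk == 1).sum()) < k_folds:
            warnings.warn(f"group {g!r} lacks both classes (or too few); "
                          "falling back to the overall model")
            fallbacks.append(str(g))
            continue
        Xk = X[rows]
        offset = compute_offset(basis, Xk)
        problem = _lasso.LassoProblem(
            Xk, yk, offset=offset, penalty_factors=pf, normalize_pf=normalize_pf
        )
        lambdas = _lasso.default_lambda_grid(problem, n_lambda)
        if lambdas.size == 1 and lambdas[0] == 0.0:
            # nothing penalized constrains the path (all pf zero, literal
            # alpha=1 edge without normalization): single unpenalized fit
            path = _lasso.fit_lasso_path(problem, lambdas=np.array([1e-10]))
            mu_k, beta_k = path.coef_at(0)
            fits[str(g)] = {"mu": mu_k, "beta": beta_k, "lambda": 0.0, "cv": None}
            continue
        cv = _lasso.cross_validate(problem, lambdas=lambdas, k_folds=k_folds, seed=cv_seed)
        path = _lasso.fit_lasso_path(problem, lambdas=lambdas)
        mu_k, beta_k = path.coef_at(cv.index_min)
        fits[str(g)] = {"mu": mu_k, "beta": beta_k, "lambda": cv.lambda_min, "cv": cv}
    return PretrainedModel(
        basis=basis, group_fits=fits, fallback_groups=fallbacks, normalize_pf=normalize_pf
    )


def predict_group(model: PretrainedModel, X_new, group_labels) -> np.ndarray:
    """Route each row to its ancestry's second-stage model and score it.

    Row i gets ``sigmoid(offset_i + mu_k + x_i beta_k)`` with the offset
    recomputed from the stage-one basis.  Unseen ancestries fall back to
    the overall model with a warning.
    """
    X_new = np.asarray(X_new, dtype=float)
    group_labels = np.asarray(group_labels)
    out = np.empty(X_new.shape[0])
    for g in np.unique(group_labels):
        rows = group_labels == g
        Xg = X_new[rows]
        key = str(g)
        if key in model.group_fits:
            fit = model.group_fits[key]
            offset = compute_offset(model.basis, Xg)
            out[rows] = _lasso.predict_proba((fit["mu"], fit["beta"]), Xg, offset)
        else:
            if key not in model.fallback_groups:
                warnings.warn(f"unseen ancestry {key!r}: using the overall model")
            out[rows] = _lasso.predict_proba((model.basis.mu0, model.basis.beta0), Xg)
    return out
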