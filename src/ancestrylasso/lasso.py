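"""L1-penalized logistic regression with offsets and penalty factors.

This is the computational substrate shared by the baseline model and the
two-stage pretrained lasso.  The objective, in the 1/n (sample-size-free)
convention, is::

    (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
        + lambda * sum_j pf_j * |beta_j|,

    eta_i = offset_i + mu + x_i . beta

where ``offset`` is a fixed per-observation term with coefficient frozen at
one, and ``pf_j >= 0`` is a per-feature penalty factor (0 = unpenalized,
+inf = excluded).  Solutions are computed by cyclic coordinate descent on a
quadratic majorizer of the logistic loss (curvature bound 1/4), with soft
thresholding, warm starts along a descending lambda grid, and an internal
variance-1 standardization of the feature columns; coefficients are
reported on the original scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LassoProblem",
    "LassoPath",
    "CVResult",
    "fit_lasso_path",
    "compute_lambda_max",
    "cross_validate",
    "predict_proba",
    "kkt_residuals",
    "objective",
]

_CURVATURE = 0.25  # global bound on the logistic second derivative
_MAX_ITER = 100_000
_TOL = 1e-7  # max coefficient change on the standardized scale


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log1pexp(x):
    out = np.empty_like(x, dtype=float)
    big = x > 33
    out[big] = x[big]
    out[~big] = np.log1p(np.exp(np.minimum(x[~big], 33)))
    return out


# ---------------------------------------------------------------------------
# problem container


@dataclass
class LassoProblem:
    """A penalized logistic regression problem.

    Parameters
    ----------
    X : (n, p) array
        Feature matrix; must be finite.
    y : (n,) array
        Binary response in {0, 1}; both classes must be present.
    offset : (n,) array, optional
        Fixed addition to the linear predictor (coefficient 1, never
        penalized or standardized).  Defaults to zeros.
    penalty_factors : (p,) array, optional
        Nonnegative per-feature multipliers of lambda; +inf excludes a
        feature.  Defaults to ones.
    standardize : bool
        Internally scale penalized columns to unit variance (default).
    normalize_pf : bool
        Rescale finite penalty factors to mean one (the convention of the
        reference lasso ecosystem).  All-equal finite factors — including
        all-zero — rescale to one.  Switch off to apply the factors
        literally.
    """

    X: np.ndarray
    y: np.ndarray
    offset: np.ndarray | None = None
    penalty_factors: np.ndarray | None = None
    standardize: bool = True
    normalize_pf: bool = True

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d array")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        n, p = self.X.shape
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.y.shape[0] != n:
            raise ValueError("y length does not match X")
        uniq = np.unique(self.y)
        if not np.isin(uniq, [0.0, 1.0]).all():
            raise ValueError("y must be binary 0/1")
        if uniq.size < 2:
            raise ValueError("degenerate response: only one class present")
        if self.offset is None:
            self.offset = np.zeros(n)
        else:
            self.offset = np.asarray(self.offset, dtype=float).ravel()
            if self.offset.shape[0] != n:
                raise ValueError("offset length does not match X")
        if self.penalty_factors is None:
            self.penalty_factors = np.ones(p)
        else:
            self.penalty_factors = np.asarray(self.penalty_factors, dtype=float).ravel()
            if self.penalty_factors.shape[0] != p:
                raise ValueError("penalty_factors length does not match X")
            if (self.penalty_factors < 0).any() or np.isnan(self.penalty_factors).any():
                raise ValueError("penalty_factors must be nonnegative")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def effective_pf(self) -> np.ndarray:
        """Penalty factors after the optional mean-one normalization."""
        pf = self.penalty_factors.copy()
        if not self.normalize_pf:
            return pf
        finite = np.isfinite(pf)
        if not finite.any():
            return pf
        fin = pf[finite]
        if np.allclose(fin, fin[0]):
            pf[finite] = 1.0
        else:
            pf[finite] = fin * (fin.size / fin.sum())
        return pf


@dataclass
class LassoPath:
    """Solutions along a descending lambda grid, on the original scale."""

    lambdas: np.ndarray
    intercepts: np.ndarray  # (K,)
    coefficients: np.ndarray  # (K, p)
    n_iter: np.ndarray
    converged: np.ndarray
    pf_used: np.ndarray
    standardize: bool
    center: np.ndarray
    scale: np.ndarray

    def coef_at(self, k: int):
        return float(self.intercepts[k]), self.coefficients[k]

    def to_json(self) -> str:
        """Serialize as JSON with sparse coefficient triplets."""
        rows, cols = np.nonzero(self.coefficients)
        return json.dumps(
            {
                "lambdas": self.lambdas.tolist(),
                "intercepts": self.intercepts.tolist(),
                "shape": list(self.coefficients.shape),
                "coef_triplets": [
                    [int(r), int(c), float(self.coefficients[r, c])]
                    for r, c in zip(rows, cols)
                ],
                "penalty_factors": [
                    None if not np.isfinite(v) else float(v) for v in self.pf_used
                ],
                "standardize": bool(self.standardize),
                "center": self.center.tolist(),
                "scale": self.scale.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LassoPath":
        d = json.loads(text)
        coefs = np.zeros(d["shape"])
        for r, c, v in d["coef_triplets"]:
            coefs[r, c] = v
        pf = np.array([np.inf if v is None else v for v in d["penalty_factors"]])
        K = len(d["lambdas"])
        return cls(
            lambdas=np.asarray(d["lambdas"], dtype=float),
            intercepts=np.asarray(d["intercepts"], dtype=float),
            coefficients=coefs,
            n_iter=np.zeros(K, dtype=int),
            converged=np.ones(K, dtype=bool),
            pf_used=pf,
            standardize=d["standardize"],
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
        )


@dataclass
class CVResult:
    """K-fold cross-validation curve over a lambda grid."""

    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    index_min: int
    fold_assignment: np.ndarray
    seed: int

    @property
    def lambda_min(self) -> float:
        return float(self.lambdas[self.index_min])


# ---------------------------------------------------------------------------
# internals


def _standardize(problem: LassoProblem):
    X = problem.X
    if not problem.standardize:
        return X, np.zeros(problem.p), np.ones(problem.p)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return (X - center) / scale, center, scale


def _fit_null_intercept(y: np.ndarray, offset: np.ndarray) -> float:
    """Intercept of the intercept-plus-offset-only logistic model."""
    ybar = y.mean()
    if np.allclose(offset, 0.0):
        return float(np.log(ybar / (1.0 - ybar)))

    def score(mu):
        return float(np.mean(y - _sigmoid(mu + offset)))

    lo, hi = -30.0, 30.0
    return float(brentq(score, lo, hi, xtol=1e-12))


def compute_lambda_max(problem: LassoProblem) -> float:
    """Smallest lambda at which every penalized coefficient is zero.

    ``lambda_max = max_j |x_j^T (y - p0)| / (n * pf_j)`` over features with
    finite positive penalty factor, where ``p0`` are fitted probabilities of
    the intercept-plus-offset-only model and ``x_j`` are the internally
    standardized columns.  Features with ``pf_j = 0`` are unpenalized and do
    not constrain lambda_max.
    """
    pf = problem.effective_pf()
    finite = np.isfinite(pf)
    if not finite.any():
        raise ValueError("all penalty factors are infinite; nothing to fit")
    Xs, _, _ = _standardize(problem)
    mu0 = _fit_null_intercept(problem.y, problem.offset)
    resid = problem.y - _sigmoid(mu0 + problem.offset)
    grad = np.abs(Xs.T @ resid) / problem.n
    penalized = finite & (pf > 0)
    if not penalized.any():
        return 0.0
    return float(np.max(grad[penalized] / pf[penalized]))


def default_lambda_grid(problem: LassoProblem, n_lambda: int = 100) -> np.ndarray:
    """Log-spaced grid from lambda_max down; ratio 1e-2 if n < p else 1e-4."""
    lmax = compute_lambda_max(problem)
    if lmax <= 0:
        return np.array([0.0])
    ratio = 1e-2 if problem.n < problem.p else 1e-4
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def _penalized_obj(y, lp, lam_vec, beta):
    finite = np.isfinite(lam_vec)
    return float(np.mean(_log1pexp(lp) - y * lp)) + float(
        np.sum(lam_vec[finite] * np.abs(beta[finite]))
    )


def _cd_solve(Xs, y, offset, lam_vec, beta, mu, tol, max_iter):
    """IRLS coordinate descent (penalized weighted least squares).

    Each outer iteration builds the local quadratic approximation of the
    logistic loss (weights ``w = p(1-p)`` floored at 1e-5) and solves it by
    cyclic soft-thresholding over an active set grown by KKT screening; an
    objective backtracking step guards the Newton approximation.
    ``lam_vec[j]`` is the per-coordinate threshold lambda*pf_j (may be +inf
    for excluded features, 0 for unpenalized ones).  Operates on the
    standardized scale; returns (beta, mu, sweeps, converged).
    """
    n, p = Xs.shape
    excluded = ~np.isfinite(lam_vec)
    lp = offset + mu + Xs @ beta
    obj = _penalized_obj(y, lp, lam_vec, beta)
    total_sweeps = 0
    ever_active = beta != 0.0

    while total_sweeps < max_iter:
        prob = _sigmoid(lp)
        w = np.clip(prob * (1.0 - prob), 1e-5, None)
        g = Xs.T @ (prob - y) / n
        viol = np.abs(g) > lam_vec * (1 + 1e-12)
        active = (ever_active | viol | (lam_vec == 0)) & ~excluded
        idx = np.flatnonzero(active)

        beta_old = beta.copy()
        mu_old = mu
        # working residual of the weighted LS problem: r = (y - p)/w
        r = (y - prob) / w
        WX = Xs[:, idx] * w[:, None]
        a = (WX * Xs[:, idx]).sum(axis=0) / n
        a = np.where(a < 1e-12, 1e-12, a)
        wmean = w.mean()
        for _ in range(200):
            max_change = 0.0
            dmu = float(w @ r) / (n * wmean)
            if dmu != 0.0:
                mu += dmu
                r -= dmu
                max_change = abs(dmu)
            for jj, j in enumerate(idx):
                num = (WX[:, jj] @ r) / n + a[jj] * beta[j]
                new = _soft(num, lam_vec[j]) / a[jj]
                delta = new - beta[j]
                if delta != 0.0:
                    beta[j] = new
                    r -= Xs[:, j] * delta
                    max_change = max(max_change, abs(delta))
            total_sweeps += 1
            if max_change < 0.1 * tol or total_sweeps >= max_iter:
                break

        # backtrack toward the previous iterate if the true objective rose
        lp = offset + mu + Xs @ beta
        new_obj = _penalized_obj(y, lp, lam_vec, beta)
        shrink = 0
        while new_obj > obj + 1e-12 and shrink < 30:
            beta = 0.5 * (beta + beta_old)
            mu = 0.5 * (mu + mu_old)
            lp = offset + mu + Xs @ beta
            new_obj = _penalized_obj(y, lp, lam_vec, beta)
            shrink += 1
        obj = new_obj
        ever_active |= beta != 0.0

        outer_change = max(
            float(np.max(np.abs(beta - beta_old), initial=0.0)), abs(mu - mu_old)
        )
        if outer_change < tol:
            prob = _sigmoid(lp)
            g = Xs.T @ (prob - y) / n
            bad = (np.abs(g) > lam_vec * (1 + 1e-6) + 1e-9) & ~excluded & ~ever_active
            if not bad.any():
                return beta, mu, total_sweeps, True
            ever_active |= bad
    return beta, mu, total_sweeps, False


def _soft(z, t):
    if not np.isfinite(t):
        return 0.0
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


# ---------------------------------------------------------------------------
# public fitting API


def fit_lasso_path(
    problem: LassoProblem,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> LassoPath:
    """Fit the L1-penalized logistic path with warm starts.

    ``lambdas`` defaults to a 100-point log-spaced grid from lambda_max.
    Solutions satisfy the KKT conditions of the penalized objective to the
    stated tolerance; features with infinite penalty factor are exactly
    zero everywhere.
    """
    pf = problem.effective_pf()
    if lambdas is None:
        lambdas = default_lambda_grid(problem, n_lambda)
    else:
        lambdas = np.asarray(lambdas, dtype=float).ravel()
        if (lambdas <= 0).any() and lambdas.size > 1:
            raise ValueError("lambda grid must be positive")
        if lambdas.size > 1 and not np.all(np.diff(lambdas) < 0):
            raise ValueError("lambda grid must be strictly decreasing")

    Xs, center, scale = _standardize(problem)
    Xs = np.asfortranarray(Xs)  # fast column access in the CD loop
    y, offset = problem.y, problem.offset
    K, p = lambdas.size, problem.p

    intercepts = np.zeros(K)
    coefs = np.zeros((K, p))
    iters = np.zeros(K, dtype=int)
    conv = np.zeros(K, dtype=bool)

    beta = np.zeros(p)
    mu = _fit_null_intercept(y, offset)
    for k, lam in enumerate(lambdas):
        lam_vec = lam * pf
        beta, mu, it, ok = _cd_solve(Xs, y, offset, lam_vec, beta.copy(), mu, tol, max_iter)
        iters[k] = it
        conv[k] = ok
        if not ok:
            warnings.warn(f"lasso path did not converge at lambda={lam:.3e}")
        # map back to the original scale
        b_orig = beta / scale
        coefs[k] = b_orig
        intercepts[k] = mu - float(b_orig @ center)
    return LassoPath(
        lambdas=lambdas,
        intercepts=intercepts,
        coefficients=coefs,
        n_iter=iters,
        converged=conv,
        pf_used=pf,
        standardize=problem.standardize,
        center=center,
        scale=scale,
    )


def predict_proba(path_point, X_new, offset_new=None) -> np.ndarray:
    """Probabilities ``sigmoid(offset + mu + X beta)`` for one path point."""
    mu, beta = path_point
    X_new = np.asarray(X_new, dtype=float)
    beta = np.asarray(beta, dtype=float).ravel()
    if X_new.shape[1] != beta.shape[0]:
        raise ValueError("dimension mismatch between X_new and coefficients")
    if offset_new is None:
        offset_new = np.zeros(X_new.shape[0])
    else:
        offset_new = np.asarray(offset_new, dtype=float).ravel()
        if offset_new.shape[0] != X_new.shape[0]:
            raise ValueError("offset length does not match X_new")
    return _sigmoid(offset_new + mu + X_new @ beta)


def binomial_deviance(y, prob) -> float:
    """Mean binomial deviance, -2/n * log-likelihood."""
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def cross_validate(
    problem: LassoProblem,
    lambdas: np.ndarray | None = None,
    k_folds: int = 3,
    seed: int = 0,
    n_lambda: int = 100,
) -> CVResult:
    """Stratified K-fold CV of the lasso path; loss is binomial deviance.

    The grid is computed once on the full data and shared across folds.
    Deterministic given the seed; the fold assignment is recorded.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    if lambdas is None:
        lambdas = default_lambda_grid(problem, n_lambda)
    y = problem.y
    n_min_class = int(min((y == 0).sum(), (y == 1).sum()))
    if n_min_class < k_folds:
        raise ValueError(
            f"a class has only {n_min_class} members; use fewer than {k_folds} folds"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = np.empty(problem.n, dtype=int)
    losses = np.zeros((k_folds, lambdas.size))
    for f, (tr, te) in enumerate(skf.split(problem.X, y)):
        folds[te] = f
        sub = LassoProblem(
            X=problem.X[tr],
            y=y[tr],
            offset=problem.offset[tr],
            penalty_factors=problem.penalty_factors,
            standardize=problem.standardize,
            normalize_pf=problem.normalize_pf,
        )
        path = fit_lasso_path(sub, lambdas=lambdas)
        for k in range(lambdas.size):
            prob = predict_proba(path.coef_at(k), problem.X[te], problem.offset[te])
            losses[f, k] = binomial_deviance(y[te], prob)
    mean = losses.mean(axis=0)
    se = losses.std(axis=0, ddof=1) / np.sqrt(k_folds)
    return CVResult(
        lambdas=lambdas,
        mean_deviance=mean,
        se_deviance=se,
        index_min=int(np.argmin(mean)),
        fold_assignment=folds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# diagnostics


def objective(problem: LassoProblem, mu: float, beta: np.ndarray, lam: float) -> float:
    """Penalized objective (1/n log-loss + lambda * sum pf_j |beta_j|).

    Evaluated with the effective (possibly normalized) penalty factors and
    on the scale the solver penalizes: when ``standardize`` is on, the
    penalty applies to the variance-1 coefficients ``beta_j * scale_j``.
    """
    beta = np.asarray(beta, dtype=float)
    eta = problem.offset + mu + problem.X @ beta
    loss = float(np.mean(_log1pexp(eta) - problem.y * eta))
    pf = problem.effective_pf()
    finite = np.isfinite(pf)
    if (~finite & (beta != 0)).any():
        return np.inf
    _, _, scale = _standardize(problem)
    b_pen = beta * scale
    return loss + lam * float(np.sum(pf[finite] * np.abs(b_pen[finite])))


def kkt_residuals(problem: LassoProblem, mu: float, beta: np.ndarray, lam: float) -> np.ndarray:
    """Per-feature KKT violation of a candidate solution, standardized scale.

    For ``beta_j = 0``: ``max(0, |g_j| - lam*pf_j)``; otherwise
    ``|g_j + lam*pf_j*sign(beta_j)|``, with g the gradient of the smooth
    loss.  Excluded features report 0 when their coefficient is 0.
    """
    pf = problem.effective_pf()
    Xs, center, scale = _standardize(problem)
    beta_std = np.asarray(beta, dtype=float) * scale
    mu_std = mu + float(np.asarray(beta) @ center)
    eta = problem.offset + mu_std + Xs @ beta_std
    g = Xs.T @ (_sigmoid(eta) - problem.y) / problem.n
    res = np.zeros(problem.p)
    for j in range(problem.p):
        if not np.isfinite(pf[j]):
            res[j] = 0.0 if beta_std[j] == 0 else np.inf
        elif beta_std[j] == 0:
            res[j] = max(0.0, abs(g[j]) - lam * pf[j])
        else:
            res[j] = abs(g[j] + lam * pf[j] * np.sign(beta_std[j]))
    return res
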