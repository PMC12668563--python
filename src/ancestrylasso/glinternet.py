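"""First-order interaction modeling with strong hierarchy (glinternet).

The model is a logistic regression over main effects and pairwise
interaction (product) terms,

    logit P(Y=1|X) = mu + sum_i X_i theta_i + sum_{i<j} X_{i:j} theta_{i:j},

fitted with an overlapping group-lasso penalty ``lambda * sum_g gamma_g *
||theta_g||_2`` that produces group-wise sparsity.  Interaction pairs are
restricted to a small set of candidate covariates (age, sex, ancestry, the
disease PRS in the study pipeline) crossed with every other column.

Two grouping modes are provided:

* ``per-pair`` (default): one singleton group per main effect plus, for
  each pair, a group holding fresh copies of both main effects and the
  product column (the latent / duplicated-variable formulation).  A nonzero
  interaction forces its group active, so both main effects are nonzero —
  the strong hierarchy.
* ``per-variable``: groups partition the design; group G_i holds the main
  effect of variable i and the products of all pairs whose first (lower
  canonical index) member is i.  Hierarchy holds only at the group level.

A categorical covariate coded as one-hot columns (ancestry) is treated as a
single block: a pair (block, v) contributes one product column per level,
kept together in the group.

All fitting happens on standardized columns (parents standardized, product
of standardized parents re-standardized), and reported effects are on that
standardized scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .lasso import CVResult, _fit_null_intercept, _log1pexp, _sigmoid, binomial_deviance

__all__ = [
    "CandidateSet",
    "GroupStructure",
    "InteractionFit",
    "StopRule",
    "build_candidates",
    "build_groups",
    "fit_glinternet",
    "cv_glinternet",
    "extract_network",
    "interaction_count_by_covariate",
    "predict_proba",
    "group_kkt_residuals",
]


# ---------------------------------------------------------------------------
# candidate construction


@dataclass
class CandidateSet:
    """Main effects plus realized product columns for allowed pairs.

    A *unit* is either a single column or a named block of columns (one-hot
    categorical).  Pairs are unordered unit pairs touching at least one
    candidate covariate, stored in canonical order (by lowest member column
    index).
    """

    feature_names: list
    units: dict  # unit name -> list of column indices
    candidate_covariates: list  # unit names allowed to form interactions
    pairs: list  # list of (unit_a, unit_b) names, canonical order
    M: np.ndarray  # (n, p) standardized main-effect columns
    center: np.ndarray
    scale: np.ndarray
    P: np.ndarray  # (n, q) standardized product columns
    product_parents: list  # per product column: (col_i, col_j) indices
    product_pair_index: np.ndarray  # per product column: index into pairs
    p_center: np.ndarray
    p_scale: np.ndarray

    @property
    def n(self) -> int:
        return self.M.shape[0]

    def transform(self, X_new):
        """Standardize new raw data with the stored training moments."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != len(self.feature_names):
            raise ValueError("column count mismatch with candidate set")
        M = (X_new - self.center) / self.scale
        if self.P.shape[1]:
            raw = np.column_stack([M[:, i] * M[:, j] for i, j in self.product_parents])
            P = (raw - self.p_center) / self.p_scale
        else:
            P = np.zeros((X_new.shape[0], 0))
        return M, P


def _std_cols(X):
    c = X.mean(axis=0)
    s = X.std(axis=0)
    s = np.where(s < 1e-12, 1.0, s)
    return (X - c) / s, c, s


def build_candidates(X, feature_names, candidate_covariates, blocks: dict | None = None) -> CandidateSet:
    """Materialize the candidate set: every (candidate, other-column) pair.

    Parameters
    ----------
    X : (n, p) array
        Raw feature matrix.
    feature_names : list of str
        Unique column names.
    candidate_covariates : list of str
        Unit names allowed to form interactions (e.g. ``["age", "sex",
        "ancestry", "PRS_DIA"]``); each must be a column name or a key of
        ``blocks``.
    blocks : dict, optional
        Mapping of block name to its member column names (one-hot levels).
    """
    X = np.asarray(X, dtype=float)
    feature_names = list(feature_names)
    if len(set(feature_names)) != len(feature_names):
        raise ValueError("feature names must be unique")
    name_to_idx = {nm: i for i, nm in enumerate(feature_names)}
    blocks = dict(blocks or {})

    units: dict = {}
    claimed = set()
    for bname, members in blocks.items():
        idxs = []
        for m in members:
            if m not in name_to_idx:
                raise ValueError(f"block {bname!r} names unknown column {m!r}")
            idxs.append(name_to_idx[m])
        units[bname] = idxs
        claimed.update(idxs)
    for nm, i in name_to_idx.items():
        if i not in claimed:
            units[nm] = [i]

    for c in candidate_covariates:
        if c not in units:
            raise ValueError(f"candidate covariate {c!r} not found among columns/blocks")

    unit_order = {u: min(ix) for u, ix in units.items()}
    seen = set()
    pairs = []
    for c in candidate_covariates:
        for other in units:
            if other == c:
                continue
            key = frozenset((c, other))
            if key in seen:
                continue
            seen.add(key)
            a, b = sorted((c, other), key=lambda u: unit_order[u])
            pairs.append((a, b))
    pairs.sort(key=lambda ab: (unit_order[ab[0]], unit_order[ab[1]]))

    M, center, scale = _std_cols(X)
    prod_cols, parents, pair_idx = [], [], []
    for k, (a, b) in enumerate(pairs):
        for i in units[a]:
            for j in units[b]:
                prod_cols.append(M[:, i] * M[:, j])
                parents.append((i, j))
                pair_idx.append(k)
    if prod_cols:
        P, pc, ps = _std_cols(np.column_stack(prod_cols))
    else:
        P = np.zeros((X.shape[0], 0))
        pc, ps = np.zeros(0), np.ones(0)
    return CandidateSet(
        feature_names=feature_names,
        units=units,
        candidate_covariates=list(candidate_covariates),
        pairs=pairs,
        M=M,
        center=center,
        scale=scale,
        P=P,
        product_parents=parents,
        product_pair_index=np.asarray(pair_idx, dtype=int),
        p_center=pc,
        p_scale=ps,
    )


# ---------------------------------------------------------------------------
# group structure


@dataclass
class GroupStructure:
    """Groups over the (possibly duplicated) design columns.

    ``design_map`` records, for each design column, its source: ("main", i)
    for a copy of main column i or ("prod", k) for product column k of the
    candidate set.  In per-pair mode main columns appear multiple times and
    the model effect is the sum of copies.
    """

    mode: str
    groups: list  # list of np.ndarray of design-column indices
    gammas: np.ndarray
    design_map: list
    group_pairs: list  # per group: pair index or None (main-only group)


def build_groups(candidates: CandidateSet, mode: str = "per-pair") -> GroupStructure:
    if mode not in ("per-pair", "per-variable"):
        raise ValueError(f"unknown grouping mode {mode!r}")
    p = len(candidates.feature_names)
    q = candidates.P.shape[1]
    design_map: list = []
    groups: list = []
    group_pairs: list = []

    if mode == "per-variable":
        design_map = [("main", i) for i in range(p)] + [("prod", k) for k in range(q)]
        pair_lead = {pi: ab[0] for pi, ab in enumerate(candidates.pairs)}
        for uname, cols in candidates.units.items():
            members = list(cols)
            for k in range(q):
                pi = int(candidates.product_pair_index[k])
                if pair_lead[pi] == uname:
                    members.append(p + k)
            groups.append(np.asarray(members, dtype=int))
            group_pairs.append(None)
    else:
        for i in range(p):  # singleton group per main-column copy
            design_map.append(("main", i))
            groups.append(np.asarray([len(design_map) - 1], dtype=int))
            group_pairs.append(None)
        for pi, (a, b) in enumerate(candidates.pairs):
            members = []
            for i in candidates.units[a] + candidates.units[b]:
                design_map.append(("main", i))
                members.append(len(design_map) - 1)
            for k in np.flatnonzero(candidates.product_pair_index == pi):
                design_map.append(("prod", int(k)))
                members.append(len(design_map) - 1)
            groups.append(np.asarray(members, dtype=int))
            group_pairs.append(pi)

    gammas = np.sqrt(np.array([len(g) for g in groups], dtype=float))
    return GroupStructure(
        mode=mode, groups=groups, gammas=gammas, design_map=design_map, group_pairs=group_pairs
    )


def _design_matrix(candidates, structure, M=None, P=None):
    M = candidates.M if M is None else M
    P = candidates.P if P is None else P
    cols = [M[:, idx] if kind == "main" else P[:, idx] for kind, idx in structure.design_map]
    return np.column_stack(cols) if cols else np.zeros((M.shape[0], 0))


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class InteractionFit:
    """A glinternet solution at one lambda, on the standardized scale."""

    intercept: float
    theta_main: dict  # column name -> summed main effect
    theta_int: dict  # (unit_a, unit_b) -> np.ndarray of product coefficients
    lambda_value: float
    group_norms: np.ndarray
    mode: str
    converged: bool
    coef_design: np.ndarray = field(repr=False, default=None)

    def active_interactions(self, threshold: float = 0.0):
        out = []
        for pair, coefs in self.theta_int.items():
            mag = float(np.linalg.norm(coefs))
            if mag > threshold:
                out.append((pair, mag))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "theta_main": {k: float(v) for k, v in self.theta_main.items()},
                "theta_int": {
                    f"{a}|{b}": [float(x) for x in v] for (a, b), v in self.theta_int.items()
                },
                "lambda": self.lambda_value,
                "mode": self.mode,
            }
        )


# ---------------------------------------------------------------------------
# group-lasso logistic solver (FISTA with group soft-thresholding)


def _group_prox(c, groups, thresholds):
    for g, t in zip(groups, thresholds):
        block = c[g]
        nrm = np.linalg.norm(block)
        if nrm <= t:
            c[g] = 0.0
        elif t > 0:
            c[g] = block * (1.0 - t / nrm)
    return c


_GL_CURVATURE = 0.25  # global bound on the logistic second derivative

try:  # compiled inner kernel; the numpy sweep below is the fallback
    from numba import njit as _njit

    @_njit(cache=True)
    def _bcd_quad_kernel(Z, w, g_full, g0, b, v, wv, group_ptr, group_idx,
                         act, a_arr, gammas, lam, a_mu, tol, max_sweeps, zb):
        n, _m = Z.shape
        dmu = 0.0
        sweeps = 0
        while sweeps < max_sweeps:
            maxch = 0.0
            gv = 0.0
            for i in range(n):
                gv += wv[i]
            step = -(g0 + gv / n) / a_mu
            if step != 0.0:
                dmu += step
                for i in range(n):
                    v[i] += step
                    wv[i] += w[i] * step
                maxch = abs(step)
            for t in range(act.size):
                gi = act[t]
                s = group_ptr[gi]
                e = group_ptr[gi + 1]
                nrm2 = 0.0
                for k in range(e - s):
                    j = group_idx[s + k]
                    acc = 0.0
                    for i in range(n):
                        acc += Z[i, j] * wv[i]
                    gb = g_full[j] + acc / n
                    zk = b[j] - gb / a_arr[gi]
                    zb[k] = zk
                    nrm2 += zk * zk
                nrm = np.sqrt(nrm2)
                thr = lam * gammas[gi] / a_arr[gi]
                scale = 0.0 if nrm <= thr else 1.0 - thr / nrm
                for k in range(e - s):
                    j = group_idx[s + k]
                    newv = scale * zb[k]
                    d = newv - b[j]
                    if d != 0.0:
                        b[j] = newv
                        for i in range(n):
                            v[i] += Z[i, j] * d
                            wv[i] += w[i] * Z[i, j] * d
                        if abs(d) > maxch:
                            maxch = abs(d)
            sweeps += 1
            if maxch < tol:
                break
        return sweeps, dmu

except ImportError:  # pragma: no cover - numba is an optional accelerator
    _bcd_quad_kernel = None


def fit_group_lasso_logistic(Z, y, groups, gammas, lambdas, offset=None,
                             tol: float = 1e-7, max_iter: int = 20000):
    """Group-lasso-penalized logistic path by majorized block descent.

    Minimizes ``(1/n) logistic loss + lambda * sum_g gamma_g ||c_g||_2``
    with an unpenalized intercept.  Each outer iteration majorizes the
    loss by the 1/4-curvature quadratic and sweeps active groups with
    per-group step sizes ``n / s_max(Z_g)^2`` and group soft-thresholding;
    KKT screening grows the active set.  Returns per-lambda ``(mu, c,
    converged)``, warm-started down the grid; convergence is declared on
    the group KKT conditions (max violation below ``tol``, measured in
    gradient units).
    """
    Z = np.asfortranarray(np.asarray(Z, dtype=float))
    n, m = Z.shape
    y = np.asarray(y, dtype=float)
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    groups = [np.asarray(g, dtype=int) for g in groups]
    Zg_list = [np.ascontiguousarray(Z[:, gr]) for gr in groups]
    group_ptr = np.zeros(len(groups) + 1, dtype=np.int64)
    for gi, gr in enumerate(groups):
        group_ptr[gi + 1] = group_ptr[gi] + gr.size
    group_idx = np.concatenate(groups).astype(np.int64) if groups else np.zeros(0, np.int64)
    max_gsize = int(max((gr.size for gr in groups), default=1))

    def _objective(lp, c, lam):
        pen = sum(gam * np.linalg.norm(c[gr]) for gr, gam in zip(groups, gammas))
        return float(np.mean(_log1pexp(lp) - y * lp)) + lam * float(pen)

    mu = _fit_null_intercept(y, offset)
    c = np.zeros(m)
    lp = offset + mu + Z @ c
    out = []
    for lam in np.atleast_1d(lambdas):
        obj = _objective(lp, c, lam)
        ever_active = np.array([bool(np.any(c[gr])) for gr in groups])
        converged = False
        sweeps = 0
        while sweeps < max_iter:
            # IRLS quadratic model: weights w = p(1-p), per-group curvature
            # from the weighted Gram's largest eigenvalue; a backtracking
            # step below guards the local (non-global) majorization
            p = _sigmoid(lp)
            w = np.clip(p * (1.0 - p), 1e-5, None)
            g_full = Z.T @ (p - y) / n
            g0 = float(np.mean(p - y))
            for gi, gr in enumerate(groups):
                if not ever_active[gi] and np.linalg.norm(g_full[gr]) > lam * gammas[gi]:
                    ever_active[gi] = True
            act = np.flatnonzero(ever_active)

            a_arr = np.zeros(len(groups))
            WZg = {}
            for gi in act:
                Zg = Zg_list[gi]
                WZ = Zg * w[:, None]
                gram = Zg.T @ WZ
                s2 = float(np.linalg.eigvalsh(gram)[-1]) if gram.shape[0] > 1 else float(gram[0, 0])
                WZg[gi] = WZ
                a_arr[gi] = max(s2, 1e-12) / n
            a_mu = float(w.mean())

            c_old, mu_old = c.copy(), mu
            inner_cap = min(100, max_iter - sweeps)
            if _bcd_quad_kernel is not None:
                b = c.copy()
                v = np.zeros(n)
                wv = np.zeros(n)
                zb = np.empty(max_gsize)
                done, dmu = _bcd_quad_kernel(
                    Z, w, g_full, g0, b, v, wv, group_ptr, group_idx,
                    act.astype(np.int64), a_arr, gammas, lam, a_mu,
                    0.1 * tol, inner_cap, zb,
                )
                sweeps += int(done)
                c = b
                mu = mu + dmu
            else:
                # numpy fallback: same quadratic sweeps, v tracks Z@dc + dmu
                v = np.zeros(n)
                dc = np.zeros(m)
                dmu = 0.0
                for _ in range(inner_cap):
                    max_change = 0.0
                    step = -(g0 + float(w @ v) / n) / a_mu
                    if step != 0.0:
                        dmu += step
                        v += step
                        max_change = abs(step)
                    for gi in act:
                        gr = groups[gi]
                        grad_b = g_full[gr] + WZg[gi].T @ v / n
                        zb = (c[gr] + dc[gr]) - grad_b / a_arr[gi]
                        t = lam * gammas[gi] / a_arr[gi]
                        nrm = np.linalg.norm(zb)
                        new = np.zeros(gr.size) if nrm <= t else zb * (1.0 - t / nrm)
                        delta = new - (c[gr] + dc[gr])
                        chg = float(np.max(np.abs(delta), initial=0.0))
                        if chg > 0.0:
                            v += Zg_list[gi] @ delta
                            dc[gr] += delta
                            max_change = max(max_change, chg)
                    sweeps += 1
                    if max_change < 0.1 * tol:
                        break
                c = c + dc
                mu = mu + dmu
            lp = offset + mu + Z @ c
            new_obj = _objective(lp, c, lam)
            shrink = 0
            while new_obj > obj + 1e-12 and shrink < 30:
                c = 0.5 * (c + c_old)
                mu = 0.5 * (mu + mu_old)
                lp = offset + mu + Z @ c
                new_obj = _objective(lp, c, lam)
                shrink += 1
            obj = new_obj

            outer_change = max(float(np.max(np.abs(c - c_old), initial=0.0)),
                               abs(mu - mu_old))
            if outer_change < tol:
                if _kkt_violation(Z, y, offset, mu, c, groups, gammas, lam) < tol * 10:
                    converged = True
                    break
        if not converged:
            viol = _kkt_violation(Z, y, offset, mu, c, groups, gammas, lam)
            converged = viol < tol * 10
            if not converged:
                warnings.warn(
                    f"group lasso did not reach KKT tolerance at lambda={lam:.3e} "
                    f"(violation {viol:.2e})"
                )
        out.append((mu, c.copy(), converged))
    return out


def _kkt_violation(Z, y, offset, mu, c, groups, gammas, lam):
    n = Z.shape[0]
    p = _sigmoid(offset + mu + Z @ c)
    g = Z.T @ (p - y) / n
    viol = abs(float(np.mean(p - y)))
    for gr, gam in zip(groups, gammas):
        block = c[gr]
        gb = g[gr]
        if np.all(block == 0.0):
            v = max(0.0, float(np.linalg.norm(gb)) - lam * gam)
        else:
            nrm = np.linalg.norm(block)
            v = float(np.linalg.norm(gb + lam * gam * block / nrm))
        viol = max(viol, v)
    return viol


def group_kkt_residuals(Z, y, mu, c, groups, gammas, lam, offset=None):
    """Max group KKT violation of a candidate solution (diagnostic)."""
    Z = np.asarray(Z, dtype=float)
    offset = np.zeros(Z.shape[0]) if offset is None else np.asarray(offset, dtype=float)
    return _kkt_violation(Z, np.asarray(y, float), offset, mu, np.asarray(c, float),
                          list(groups), np.asarray(gammas, float), lam)


def compute_lambda_max_groups(Z, y, groups, gammas, offset=None) -> float:
    """Smallest lambda with all groups zero: max_g ||Z_g' r0|| / (n gamma_g)."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    y = np.asarray(y, dtype=float)
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    mu0 = _fit_null_intercept(y, offset)
    r = y - _sigmoid(mu0 + offset)
    g = Z.T @ r / n
    return float(max(np.linalg.norm(g[gr]) / gam for gr, gam in zip(groups, gammas)))


# ---------------------------------------------------------------------------
# public glinternet API


@dataclass
class StopRule:
    """Stop the path once this many interaction pairs are selected."""

    max_interactions: int | None = None


def _extract_fit(candidates, structure, mu, c, lam, converged) -> InteractionFit:
    p = len(candidates.feature_names)
    q = candidates.P.shape[1]
    theta_main = np.zeros(p)
    theta_prod = np.zeros(q)
    for col, (kind, idx) in enumerate(structure.design_map):
        if kind == "main":
            theta_main[idx] += c[col]
        else:
            theta_prod[idx] += c[col]
    tmain = {nm: float(theta_main[i]) for i, nm in enumerate(candidates.feature_names)}
    tint = {
        pair: theta_prod[candidates.product_pair_index == pi]
        for pi, pair in enumerate(candidates.pairs)
    }
    norms = np.array([np.linalg.norm(c[g]) for g in structure.groups])
    return InteractionFit(
        intercept=float(mu),
        theta_main=tmain,
        theta_int=tint,
        lambda_value=float(lam),
        group_norms=norms,
        mode=structure.mode,
        converged=converged,
        coef_design=c,
    )


def fit_glinternet(candidates: CandidateSet, structure: GroupStructure, y,
                   lambdas=None, n_lambda: int = 50, lambda_min_ratio: float = 1e-2,
                   stop_rule: StopRule | None = None, offset=None,
                   tol: float = 1e-7, max_iter: int = 20000):
    """Fit the interaction model along a descending lambda path.

    Returns a list of :class:`InteractionFit`.  The path starts at the
    computed lambda_max (all groups zero) and stops at the grid end or as
    soon as the stop rule's interaction count is reached.
    """
    y = np.asarray(y, dtype=float)
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all() or uniq.size < 2:
        raise ValueError("y must be binary with both classes present")
    Z = _design_matrix(candidates, structure)
    if lambdas is None:
        lmax = compute_lambda_max_groups(Z, y, structure.groups, structure.gammas, offset)
        lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
    else:
        lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))

    sols = fit_group_lasso_logistic(
        Z, y, structure.groups, structure.gammas, lambdas, offset=offset,
        tol=tol, max_iter=max_iter,
    )
    fits = []
    for lam, (mu, c, conv) in zip(lambdas, sols):
        fit = _extract_fit(candidates, structure, mu, c, lam, conv)
        fits.append(fit)
        if stop_rule is not None and stop_rule.max_interactions is not None:
            if len(fit.active_interactions()) >= stop_rule.max_interactions:
                break
    return fits


def predict_proba(fit: InteractionFit, candidates: CandidateSet, X_new) -> np.ndarray:
    """Score new raw data with a fitted interaction model."""
    M, P = candidates.transform(X_new)
    theta_main = np.array([fit.theta_main[nm] for nm in candidates.feature_names])
    q = candidates.P.shape[1]
    if q:
        theta_prod = np.zeros(q)
        for pi, pair in enumerate(candidates.pairs):
            theta_prod[candidates.product_pair_index == pi] = fit.theta_int[pair]
        eta = fit.intercept + M @ theta_main + P @ theta_prod
    else:
        eta = fit.intercept + M @ theta_main
    return _sigmoid(eta)


def cv_glinternet(X, feature_names, candidate_covariates, y, blocks=None,
                  mode: str = "per-pair", k_folds: int = 3, seed: int = 0,
                  n_lambda: int = 50, lambda_min_ratio: float = 1e-2,
                  tol: float = 1e-6, max_iter: int = 20000):
    """Cross-validated glinternet: returns (fits, CVResult, candidates).

    The lambda grid is set on the full data; each fold rebuilds its own
    candidate standardization from the fold-training rows only.  The loss
    is held-out binomial deviance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cand_full = build_candidates(X, feature_names, candidate_covariates, blocks)
    struct_full = build_groups(cand_full, mode)
    Z = _design_matrix(cand_full, struct_full)
    lmax = compute_lambda_max_groups(Z, y, struct_full.groups, struct_full.gammas)
    lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)

    n_min_class = int(min((y == 0).sum(), (y == 1).sum()))
    if n_min_class < k_folds:
        raise ValueError("too few members of a class for the requested folds")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = np.empty(X.shape[0], dtype=int)
    losses = np.zeros((k_folds, lambdas.size))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        folds[te] = f
        cand = build_candidates(X[tr], feature_names, candidate_covariates, blocks)
        struct = build_groups(cand, mode)
        fold_fits = fit_glinternet(cand, struct, y[tr], lambdas=lambdas, tol=tol, max_iter=max_iter)
        for k, fit in enumerate(fold_fits):
            prob = predict_proba(fit, cand, X[te])
            losses[f, k] = binomial_deviance(y[te], prob)
    mean = losses.mean(axis=0)
    se = losses.std(axis=0, ddof=1) / np.sqrt(k_folds)
    cv = CVResult(
        lambdas=lambdas,
        mean_deviance=mean,
        se_deviance=se,
        index_min=int(np.argmin(mean)),
        fold_assignment=folds,
        seed=seed,
    )
    fits = fit_glinternet(cand_full, struct_full, y, lambdas=lambdas, tol=tol, max_iter=max_iter)
    return fits, cv, cand_full


# ---------------------------------------------------------------------------
# reporting


def extract_network(fit: InteractionFit, threshold: float = 0.0):
    """Nonzero interactions as ((unit_a, unit_b), magnitude), sorted.

    Magnitudes are L2 norms of the pair's product coefficients on the
    standardized scale (plain absolute values for scalar pairs).  Sorted by
    descending magnitude; ties broken lexicographically by pair.
    """
    edges = fit.active_interactions(threshold)
    edges.sort(key=lambda e: (-e[1], e[0]))
    return edges


def interaction_count_by_covariate(fit: InteractionFit, candidate_covariates=None) -> dict:
    """Count nonzero interaction pairs per candidate covariate they touch.

    A pair of two candidate covariates is counted once under each.
    """
    if candidate_covariates is None:
        cands = sorted({u for pair in fit.theta_int for u in pair})
        candidate_covariates = cands
    counts = {c: 0 for c in candidate_covariates}
    for (a, b), _mag in fit.active_interactions():
        if a in counts:
            counts[a] += 1
        if b in counts:
            counts[b] += 1
    return counts


def export_network(fit: InteractionFit, path, threshold: float = 0.0):
    """Write the interaction edge list as tab-delimited text."""
    edges = extract_network(fit, threshold)
    with open(path, "w") as fh:
        fh.write("covariate_a\tcovariate_b\tcoefficient\n")
        for (a, b), mag in edges:
            fh.write(f"{a}\t{b}\t{mag:.10g}\n")
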