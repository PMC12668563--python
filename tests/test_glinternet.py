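"""Unit tests for candidate construction and the hierarchical group lasso."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from ancestrylasso import glinternet as gl, lasso as pl

from conftest import make_logistic_problem


def make_candidates(seed, n=150, p=5, cands=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    names = [f"v{i}" for i in range(p)]
    cands = cands if cands is not None else [names[0]]
    return X, names, gl.build_candidates(X, names, cands)


class TestBuildCandidates:
    def test_single_candidate_enumeration(self):
        _, names, cand = make_candidates(0, p=5)
        assert cand.pairs == [("v0", "v1"), ("v0", "v2"), ("v0", "v3"), ("v0", "v4")]
        assert cand.P.shape[1] == 4

    def test_all_candidates_give_all_pairs(self):
        _, names, cand = make_candidates(1, p=6, cands=[f"v{i}" for i in range(6)])
        brute = set(itertools.combinations(names, 2))
        assert set(cand.pairs) == brute
        assert len(cand.pairs) == 15

    def test_two_candidates_count(self):
        # 2 candidates x 8 non-candidates + the candidate-candidate pair
        _, _, cand = make_candidates(2, p=10, cands=["v0", "v1"])
        assert len(cand.pairs) == 2 * 8 + 1

    def test_products_are_elementwise_products_of_standardized_parents(self):
        X, _, cand = make_candidates(3, p=4)
        for k, (i, j) in enumerate(cand.product_parents):
            raw = cand.M[:, i] * cand.M[:, j]
            rebuilt = (raw - cand.p_center[k]) / cand.p_scale[k]
            np.testing.assert_allclose(cand.P[:, k], rebuilt, atol=1e-12)

    def test_missing_candidate_named(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="nope"):
            gl.build_candidates(X, ["a", "b"], ["nope"])

    def test_block_candidate_expands_per_level(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 4))
        names = ["x", "anc_A", "anc_B", "z"]
        cand = gl.build_candidates(
            X, names, ["ancestry"], blocks={"ancestry": ["anc_A", "anc_B"]}
        )
        assert ("x", "ancestry") in cand.pairs or ("ancestry", "x") in cand.pairs
        pair_idx = {p: i for i, p in enumerate(cand.pairs)}
        for pair, pi in pair_idx.items():
            n_prods = int(np.sum(cand.product_pair_index == pi))
            assert n_prods == 2  # one product per ancestry level


class TestGroupStructure:
    def test_per_variable_partitions_design(self):
        _, _, cand = make_candidates(5, p=4)
        st = gl.build_groups(cand, "per-variable")
        all_cols = np.concatenate(st.groups)
        assert sorted(all_cols) == list(range(len(st.design_map)))

    def test_per_pair_triples(self):
        _, _, cand = make_candidates(6, p=4)
        st = gl.build_groups(cand, "per-pair")
        pair_groups = [g for g, pi in zip(st.groups, st.group_pairs) if pi is not None]
        assert all(len(g) == 3 for g in pair_groups)
        # gamma = sqrt(group size)
        np.testing.assert_allclose(
            st.gammas, [np.sqrt(len(g)) for g in st.groups]
        )

    def test_unknown_mode_rejected(self):
        _, _, cand = make_candidates(7)
        with pytest.raises(ValueError, match="mode"):
            gl.build_groups(cand, "whatever")


class TestGroupLassoSolver:
    def test_null_model_at_lambda_max(self):
        X, names, cand = make_candidates(8, n=200, p=4)
        st = gl.build_groups(cand)
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=200).astype(float)
        y[:2] = [0, 1]
        Z = gl._design_matrix(cand, st)
        lmax = gl.compute_lambda_max_groups(Z, y, st.groups, st.gammas)
        fits = gl.fit_glinternet(cand, st, y, lambdas=[lmax * 1.0001])
        fit = fits[0]
        assert all(v == 0.0 for v in fit.theta_main.values())
        assert all(np.all(v == 0.0) for v in fit.theta_int.values())
        ybar = y.mean()
        assert fit.intercept == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)

    def test_singleton_groups_match_lasso_path(self):
        X, y, _, _ = make_logistic_problem(9, n=250, p=6)
        Z = (X - X.mean(0)) / X.std(0)
        groups = [np.array([j]) for j in range(6)]
        gammas = np.ones(6)
        lmax = gl.compute_lambda_max_groups(Z, y, groups, gammas)
        lams = np.geomspace(lmax, lmax * 0.01, 15)
        sols = gl.fit_group_lasso_logistic(Z, y, groups, gammas, lams, tol=1e-9)
        path = pl.fit_lasso_path(pl.LassoProblem(X, y), lambdas=lams)
        scale = X.std(0)
        for k in range(15):
            np.testing.assert_allclose(
                sols[k][1], path.coefficients[k] * scale, atol=1e-5
            )

    def test_matches_cone_oracle_on_small_problem(self):
        rng = np.random.default_rng(10)
        n = 60
        X = rng.normal(size=(n, 5))
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.9 * X[:, 0] - 0.7 * X[:, 1])))).astype(float)
        y[:2] = [0, 1]
        groups = [np.array([0, 1]), np.array([2, 3, 4])]
        gammas = np.sqrt([2.0, 3.0])
        lam = 0.04
        mu, c, _ = gl.fit_group_lasso_logistic(X, y, groups, gammas, [lam], tol=1e-11)[0]

        def obj(z):
            eta = z[0] + X @ z[1:6]
            pen = gammas[0] * np.linalg.norm(z[1:3]) + gammas[1] * np.linalg.norm(z[3:6])
            return float(np.mean(np.logaddexp(0, eta) - y * eta) + lam * pen)

        ours = obj(np.concatenate(([mu], c)))
        cold = minimize(obj, np.zeros(6), method="Powell",
                        options=dict(maxiter=200000, xtol=1e-12, ftol=1e-14)).fun
        polished = minimize(obj, np.concatenate(([mu], c)), method="Powell",
                            options=dict(maxiter=200000, xtol=1e-12, ftol=1e-14)).fun
        assert ours <= cold + 1e-6
        assert abs(ours - min(cold, polished)) < 1e-6

    def test_group_kkt_along_path(self):
        X, names, cand = make_candidates(11, n=200, p=5)
        st = gl.build_groups(cand)
        rng = np.random.default_rng(11)
        eta = 0.8 * X[:, 0] + 0.6 * X[:, 1] + 0.9 * X[:, 0] * X[:, 2]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        Z = gl._design_matrix(cand, st)
        lmax = gl.compute_lambda_max_groups(Z, y, st.groups, st.gammas)
        lams = np.geomspace(lmax, lmax * 0.01, 10)
        sols = gl.fit_group_lasso_logistic(Z, y, st.groups, st.gammas, lams, tol=1e-8)
        for lam, (mu, c, conv) in zip(lams, sols):
            assert conv
            viol = gl.group_kkt_residuals(Z, y, mu, c, st.groups, st.gammas, lam)
            assert viol < 1e-6

    def test_activity_roughly_monotone_down_the_path(self):
        X, names, cand = make_candidates(12, n=300, p=5)
        st = gl.build_groups(cand)
        rng = np.random.default_rng(12)
        eta = 0.7 * X[:, 0] - 0.5 * X[:, 3]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        fits = gl.fit_glinternet(cand, st, y, n_lambda=25)
        active = [int(np.sum(f.group_norms > 0)) for f in fits]
        drops = sum(1 for a, b in zip(active, active[1:]) if b < a)
        assert active[0] == 0 or active[0] <= active[-1]
        assert drops <= 2  # re-entry is rare, logged not failed

    def test_stop_rule_truncates_path(self):
        X, names, cand = make_candidates(13, n=300, p=5)
        st = gl.build_groups(cand)
        rng = np.random.default_rng(13)
        eta = 0.8 * X[:, 0] + 0.8 * X[:, 1] + X[:, 0] * X[:, 1] + 0.8 * X[:, 0] * X[:, 2]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        fits = gl.fit_glinternet(cand, st, y, n_lambda=40,
                                 stop_rule=gl.StopRule(max_interactions=1))
        assert len(fits) < 40
        assert len(fits[-1].active_interactions()) >= 1
        assert all(len(f.active_interactions()) == 0 for f in fits[:-1])


class TestReporting:
    def _fit_with(self, theta_int):
        return gl.InteractionFit(
            intercept=0.0,
            theta_main={"a": 1.0, "b": 0.5, "c": -0.2, "d": 0.0},
            theta_int={k: np.atleast_1d(v) for k, v in theta_int.items()},
            lambda_value=0.1, group_norms=np.zeros(1), mode="per-pair", converged=True,
        )

    def test_empty_network(self):
        fit = self._fit_with({("a", "b"): 0.0})
        assert gl.extract_network(fit) == []

    def test_magnitude_sort(self):
        fit = self._fit_with({("a", "b"): -3.0, ("a", "c"): 2.0})
        net = gl.extract_network(fit)
        assert [p for p, _ in net] == [("a", "b"), ("a", "c")]
        assert net[0][1] == 3.0

    def test_tie_breaks_lexicographic(self):
        fit = self._fit_with({("a", "d"): 1.0, ("a", "b"): -1.0})
        net = gl.extract_network(fit)
        assert [p for p, _ in net] == [("a", "b"), ("a", "d")]

    def test_counts_match_exhaustive_tabulation(self):
        rng = np.random.default_rng(14)
        pairs = [("age", f"v{i}") for i in range(6)] + [
            ("prs", f"v{i}") for i in range(6)] + [("age", "prs")]
        vals = {p: (rng.normal() if rng.random() < 0.5 else 0.0) for p in pairs}
        fit = self._fit_with(vals)
        counts = gl.interaction_count_by_covariate(fit, ["age", "prs"])
        expect = {"age": 0, "prs": 0}
        for (a, b), v in vals.items():
            if v != 0:
                for c in ("age", "prs"):
                    if c in (a, b):
                        expect[c] += 1
        assert counts == expect

    def test_empty_fit_counts_zero(self):
        fit = self._fit_with({("a", "b"): 0.0})
        assert gl.interaction_count_by_covariate(fit, ["a"]) == {"a": 0}

    def test_network_export(self, tmp_path):
        fit = self._fit_with({("a", "b"): -2.0, ("a", "c"): 1.0})
        path = tmp_path / "net.tsv"
        gl.export_network(fit, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "covariate_a\tcovariate_b\tcoefficient"
        assert lines[1].startswith("a\tb\t2")


class TestHierarchy:
    def test_per_pair_mode_enforces_strong_hierarchy(self):
        # planted interaction whose mains are weak: the hierarchy must hold
        # on every returned fit anyway
        rng = np.random.default_rng(15)
        n = 400
        X = rng.normal(size=(n, 5))
        eta = 0.2 * X[:, 0] + 1.2 * X[:, 0] * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        cand = gl.build_candidates(X, [f"v{i}" for i in range(5)], ["v0", "v1"])
        st = gl.build_groups(cand, "per-pair")
        fits = gl.fit_glinternet(cand, st, y, n_lambda=25)
        any_interaction = False
        for fit in fits:
            for (a, b), mag in fit.active_interactions():
                any_interaction = True
                assert fit.theta_main[a] != 0.0
                assert fit.theta_main[b] != 0.0
        assert any_interaction

    def test_per_variable_mode_group_level_hierarchy(self):
        rng = np.random.default_rng(16)
        n = 300
        X = rng.normal(size=(n, 4))
        eta = 0.8 * X[:, 0] + X[:, 0] * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        cand = gl.build_candidates(X, [f"v{i}" for i in range(4)], ["v0"])
        st = gl.build_groups(cand, "per-variable")
        fits = gl.fit_glinternet(cand, st, y, n_lambda=20)
        name_of_unit = {u: i for i, u in enumerate(cand.units)}
        for fit in fits:
            for pi, pair in enumerate(cand.pairs):
                if np.any(fit.theta_int[pair] != 0):
                    lead = pair[0]
                    gi = list(cand.units).index(lead)
                    assert fit.group_norms[gi] > 0  # lead unit's group active
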