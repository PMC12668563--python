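"""Unit tests for dataset construction, splitting and study orchestration."""

import json

import numpy as np
import pandas as pd
import pytest

from ancestrylasso import cohort as ch, study as st


@pytest.fixture(scope="module")
def study_manifest(two_ancestry_spec_module):
    cfg = st.StudyConfig(
        cohort_spec=two_ancestry_spec_module,
        focal_ancestries=["SA"],
        seed_split=1,
        seed_cv=2,
        n_lambda_lasso=40,
        n_lambda_glinternet=15,
    )
    return st.run_study(cfg)


@pytest.fixture(scope="module")
def two_ancestry_spec_module():
    return ch.CohortSpec(
        n_total=900,
        ancestry_proportions={"WB": 0.72, "SA": 0.28},
        n_metabolites=6,
        n_pcs_global=4,
        n_pcs_local=1,
        diseases=[
            ch.DiseaseSpec(
                name="DIA",
                target_prevalence={"WB": 0.12, "SA": 0.25},
                shared_effects={"age": 0.3, "MET1": 0.4},
                interaction_effects={("PRS_DIA", "GPC4"): 0.4},
                prs_liability_correlation=0.35,
            )
        ],
        metabolite_block_sizes=[3],
        metabolite_block_correlation=0.4,
        seed=21,
    )


class TestBuildDataset:
    def test_modes(self, two_ancestry_cohort):
        c = two_ancestry_cohort
        all_rows = st.build_dataset(c, st.DatasetConfig("All"))
        mix = st.build_dataset(c, st.DatasetConfig("Mix", focal_ancestry="SA"))
        spec_rows = st.build_dataset(c, st.DatasetConfig("Specific", focal_ancestry="SA"))
        assert all_rows.size == c.n
        assert set(c.ancestry[mix]) == {"WB", "SA"}
        assert set(c.ancestry[spec_rows]) == {"SA"}
        # containment: Specific subset of Mix subset of All
        assert set(spec_rows) <= set(mix) <= set(all_rows)

    def test_set_algebra_against_brute_force(self, two_ancestry_cohort):
        c = two_ancestry_cohort
        mix = set(st.build_dataset(c, st.DatasetConfig("Mix", focal_ancestry="SA")))
        spec_rows = set(st.build_dataset(c, st.DatasetConfig("Specific", focal_ancestry="SA")))
        complement = mix - spec_rows
        brute = set(np.flatnonzero(c.ancestry == "WB"))
        assert complement == brute

    def test_absent_focal_rejected(self, two_ancestry_cohort):
        with pytest.raises(ValueError, match="EA"):
            st.build_dataset(two_ancestry_cohort, st.DatasetConfig("Mix", focal_ancestry="EA"))

    def test_modes_validated(self):
        with pytest.raises(ValueError, match="mode"):
            st.DatasetConfig("Half")
        with pytest.raises(ValueError, match="focal"):
            st.DatasetConfig("Mix")


class TestSplit:
    def test_basic_80_20(self, two_ancestry_cohort):
        tr, te = st.split_train_test(two_ancestry_cohort, 0.8, seed=0)
        assert tr.size + te.size == two_ancestry_cohort.n
        assert np.intersect1d(tr, te).size == 0
        assert te.size == pytest.approx(0.2 * two_ancestry_cohort.n, rel=0.05)

    def test_deterministic_and_seed_sensitive(self, two_ancestry_cohort):
        tr1, te1 = st.split_train_test(two_ancestry_cohort, 0.8, seed=4)
        tr2, te2 = st.split_train_test(two_ancestry_cohort, 0.8, seed=4)
        tr3, _ = st.split_train_test(two_ancestry_cohort, 0.8, seed=5)
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
        assert not np.array_equal(tr1, tr3)

    def test_stratum_proportions_within_one_row(self, two_ancestry_cohort):
        c = two_ancestry_cohort
        tr, te = st.split_train_test(c, 0.8, seed=1)
        pattern = c.Y["DIA"].to_numpy().astype(str)
        strata = np.char.add(c.ancestry.astype(str), pattern)
        te_mask = np.zeros(c.n, dtype=bool)
        te_mask[te] = True
        for s in np.unique(strata):
            rows = strata == s
            n_s = rows.sum()
            n_te = (rows & te_mask).sum()
            assert abs(n_te - 0.2 * n_s) <= 1.0

    def test_small_stratum_raises_without_merge(self):
        # hand-built cohort with a singleton (SA, y=1) stratum
        import pandas as pd

        n = 40
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"age": rng.normal(size=n)})
        ancestry = np.array(["WB"] * (n - 1) + ["SA"])
        y = np.zeros(n, dtype=int)
        y[:10] = 1
        y[-1] = 1
        c = ch.Cohort(
            X=X, column_meta=[("age", "demographic")], ancestry=ancestry,
            Y=pd.DataFrame({"D": y}),
        )
        with pytest.raises(ValueError, match="stratum"):
            st.split_train_test(c, 0.8, seed=0)
        tr, te = st.split_train_test(c, 0.8, seed=0, merge_small=True)
        assert tr.size + te.size == n


class TestDesign:
    def test_prs_leakage_guard(self):
        spec = ch.CohortSpec(
            n_total=300, ancestry_proportions={"WB": 0.7, "SA": 0.3},
            n_metabolites=4, n_pcs_global=4, n_pcs_local=1,
            diseases=[
                ch.DiseaseSpec(name="DIA", target_prevalence={"WB": 0.2, "SA": 0.2}),
                ch.DiseaseSpec(name="ART", target_prevalence={"WB": 0.2, "SA": 0.2}),
            ],
            seed=3,
        )
        c = ch.generate_cohort(spec)
        X, names, blocks = st.design_for_disease(c, "DIA")
        assert "PRS_DIA" in names
        assert "PRS_ART" not in names
        assert blocks == {"ancestry": ["anc_SA"]}
        assert X.shape[1] == len(names)

    def test_onehot_reference_is_majority(self):
        spec = ch.CohortSpec(
            n_total=300, ancestry_proportions={"WB": 0.6, "SA": 0.2, "AF": 0.2},
            n_metabolites=2, n_pcs_global=4, n_pcs_local=1,
            diseases=[ch.DiseaseSpec(name="D", target_prevalence={"WB": 0.2, "SA": 0.2, "AF": 0.2})],
            seed=4,
        )
        c = ch.generate_cohort(spec)
        X, names, blocks = st.design_for_disease(c, "D", majority="WB")
        assert set(blocks["ancestry"]) == {"anc_SA", "anc_AF"}
        assert "anc_WB" not in names


class TestRunStudy:
    def test_grid_bookkeeping(self, study_manifest):
        res = study_manifest.results
        combos = set(zip(res["dataset"], res["method"]))
        assert combos == {
            ("All", "lasso"), ("All", "glinternet"), ("All", "pretrain"),
            ("Mix", "lasso"), ("Mix", "glinternet"), ("Mix", "pretrain"),
            ("Specific", "lasso"),
        }
        assert len(res) == 7  # one disease x one focal ancestry
        assert study_manifest.wins is not None
        assert sum(study_manifest.wins.wins.values()) == 1

    def test_baselines_have_no_p_values_and_candidates_do(self, study_manifest):
        res = study_manifest.results
        assert res.loc[res["method"] == "lasso", "p_one_sided"].isna().all()
        assert res.loc[res["method"] != "lasso", "p_one_sided"].notna().all()

    def test_report_stars_match_stored_p_values(self, study_manifest):
        report = st.render_report(study_manifest)
        for _, row in study_manifest.results.iterrows():
            if pd.notna(row["p_one_sided"]):
                from ancestrylasso.evaluation import significance_tier

                assert row["tier"] == significance_tier(row["p_one_sided"])
        assert "Win counts" in report

    def test_manifest_json_roundtrip(self, study_manifest):
        blob = json.loads(study_manifest.to_json())
        assert blob["seeds"]["split"] == 1
        assert len(blob["results"]) == len(study_manifest.results)
        assert "wins" in blob and blob["wins"]["total_combinations"] == 7

    def test_min_case_filter_skips_rare_disease(self):
        spec = ch.CohortSpec(
            n_total=600, ancestry_proportions={"WB": 0.8, "SA": 0.2},
            n_metabolites=4, n_pcs_global=4, n_pcs_local=1,
            diseases=[ch.DiseaseSpec(name="RARE",
                                     target_prevalence={"WB": 0.05, "SA": 0.05})],
            seed=5,
        )
        cfg = st.StudyConfig(cohort_spec=spec, focal_ancestries=["SA"],
                             min_positive_cases=20, n_lambda_lasso=10,
                             n_lambda_glinternet=5)
        man = st.run_study(cfg)
        assert man.results.empty
        assert any("positive cases" in s["reason"] for s in man.skipped)

    def test_config_from_dict(self):
        d = {
            "cohort_spec": {"n_total": 500, "diseases": ["DIA"], "seed": 1,
                            "n_metabolites": 6, "n_pcs_global": 4, "n_pcs_local": 2},
            "focal_ancestries": ["SA"],
            "split_fraction": 0.8,
            "model_families": ["lasso"],
        }
        cfg = st.StudyConfig.from_dict(d)
        assert cfg.cohort_spec.n_total == 500
        assert cfg.model_families == ("lasso",)
        with pytest.raises(ValueError, match="unknown study config"):
            st.StudyConfig.from_dict({"cohort_spec": {"n_total": 10}, "bogus": 1})


class TestAgainstGroundTruth:
    def test_null_cohort_models_score_near_chance(self):
        """With all effect coefficients zero every model's test AUC ~ 0.5."""
        spec = ch.CohortSpec(
            n_total=1500, ancestry_proportions={"WB": 0.75, "SA": 0.25},
            n_metabolites=6, n_pcs_global=4, n_pcs_local=1,
            diseases=[ch.DiseaseSpec(
                name="D", target_prevalence={"WB": 0.2, "SA": 0.2},
                prs_liability_correlation=0.0,
            )],
            seed=31,
        )
        cfg = st.StudyConfig(cohort_spec=spec, focal_ancestries=["SA"],
                             model_families=("lasso",), n_lambda_lasso=30)
        man = st.run_study(cfg)
        aucs = man.results["auc"].to_numpy()
        assert np.all(np.abs(aucs - 0.5) < 0.12)  # ~3 SD at ~75 test rows

    def test_bayes_auc_bounds_fitted_models(self, two_ancestry_spec,
                                            two_ancestry_cohort):
        """No fitted model systematically beats the true-liability score."""
        from ancestrylasso import evaluation as ev, lasso as pl

        bayes, se = ch.bayes_auc(two_ancestry_spec, "DIA", "SA",
                                 n_mc=30000, seed=5)
        c = two_ancestry_cohort
        y = c.Y["DIA"].to_numpy(float)
        X, names, blocks = st.design_for_disease(c, "DIA")
        tr, te = st.split_train_test(c, 0.8, seed=3)
        prob = pl.LassoProblem(X[tr], y[tr])
        lambdas = pl.default_lambda_grid(prob, 40)
        cv = pl.cross_validate(prob, lambdas=lambdas, seed=0)
        path = pl.fit_lasso_path(prob, lambdas=lambdas)
        sa_te = te[c.ancestry[te] == "SA"]
        scores = pl.predict_proba(path.coef_at(cv.index_min), X[sa_te])
        model_auc = ev.auc(scores, y[sa_te].astype(int))
        # the model's finite-sample AUC has its own SE (~0.07 at ~60 rows);
        # allow 3 combined SEs
        n_pos = int(y[sa_te].sum())
        n_neg = int(len(sa_te) - n_pos)
        model_se = np.sqrt(model_auc * (1 - model_auc) / min(n_pos, n_neg))
        assert bayes >= model_auc - 3 * (se + model_se)


class TestCli:
    def test_simulate_run_report(self, tmp_path):
        from click.testing import CliRunner

        from ancestrylasso.cli import main

        runner = CliRunner()
        cohort_path = tmp_path / "c.tsv"
        r = runner.invoke(main, ["simulate", "--n-total", "500", "--seed", "3",
                                 "--out", str(cohort_path)])
        assert r.exit_code == 0, r.output
        assert cohort_path.exists()

        cfg = {
            "cohort_path": str(cohort_path),
            "diseases": ["DIA"],
            "focal_ancestries": ["SA"],
            "model_families": ["lasso"],
            "n_lambda_lasso": 15,
        }
        cfg_path = tmp_path / "study.json"
        cfg_path.write_text(json.dumps(cfg))
        out_dir = tmp_path / "run"
        r = runner.invoke(main, ["run", "--config", str(cfg_path),
                                 "--out-dir", str(out_dir)])
        assert r.exit_code == 0, r.output
        assert (out_dir / "manifest.json").exists()
        assert (out_dir / "results.tsv").exists()

        r = runner.invoke(main, ["report", "--manifest",
                                 str(out_dir / "manifest.json")])
        assert r.exit_code == 0, r.output
        assert "Ancestry" in r.output or "No evaluation" in r.output
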