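"""Study orchestration: dataset construction, shared splits, model runs.

The study design compares three model families per (disease, focal
ancestry) cell:

* baseline L1-penalized logistic regression, trained on three dataset
  configurations — Specific (focal ancestry only), Mix (majority + focal),
  and All (every ancestry);
* glinternet (hierarchical interaction model), trained on Mix and All;
* pretrained lasso (two-stage transfer), trained on Mix and All;

giving 3 + 2 + 2 = 7 method-dataset combinations per cell.  Every model is
evaluated on the focal ancestry's held-out test rows; candidate models are
compared against the baseline trained on the *same* dataset configuration
with one-sided DeLong tests.  A single stratified 80/20 train/test split of
the full cohort is reused everywhere, so all comparisons are paired.

The trained disease's PRS column is appended to the design; other
diseases' PRS columns are excluded by default (leakage guard).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation, glinternet as gl, lasso as pl, pretrain as pt
from .cohort import Cohort, CohortSpec, generate_cohort, read_cohort, ukb_like_spec

__all__ = [
    "DatasetConfig",
    "StudyConfig",
    "RunManifest",
    "build_dataset",
    "split_train_test",
    "design_for_disease",
    "run_study",
    "render_report",
]

DATASETS_PER_METHOD = {"lasso": 3, "glinternet": 2, "pretrain": 2}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class DatasetConfig:
    """Which ancestries a training set includes."""

    mode: str  # "All" | "Mix" | "Specific"
    focal_ancestry: str | None = None
    majority_ancestry: str = "WB"

    def __post_init__(self):
        if self.mode not in ("All", "Mix", "Specific"):
            raise ValueError(f"unknown dataset mode {self.mode!r}")
        if self.mode in ("Mix", "Specific") and not self.focal_ancestry:
            raise ValueError(f"{self.mode} dataset requires a focal ancestry")


@dataclass
class StudyConfig:
    """Full study recipe: cohort source, models, CV and seeds."""

    cohort_spec: CohortSpec | None = None
    cohort_path: str | None = None
    diseases: list | None = None  # default: all in the cohort
    focal_ancestries: list | None = None  # default: all minorities
    model_families: tuple = ("lasso", "glinternet", "pretrain")
    majority_ancestry: str = "WB"
    split_fraction: float = 0.8
    cv_folds: int = 3
    seed_split: int = 1
    seed_cv: int = 2
    alpha: float = 0.5
    alpha_sweep: bool = False
    interaction_candidates: tuple = ("age", "sex", "ancestry", "prs")
    n_lambda_lasso: int = 100
    n_lambda_glinternet: int = 30
    glinternet_mode: str = "per-pair"
    min_positive_cases: int = 20

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must be in (0, 1)")
        if self.cohort_spec is None and self.cohort_path is None:
            raise ValueError("a cohort spec or path is required")

    def load_cohort(self) -> Cohort:
        if self.cohort_path is not None:
            return read_cohort(self.cohort_path)
        return generate_cohort(self.cohort_spec)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        spec = None
        if "cohort_spec" in d:
            spec_d = d.pop("cohort_spec")
            if "ancestry_proportions" in spec_d:
                from .cohort import DiseaseSpec

                diseases = [
                    DiseaseSpec(**ds) if isinstance(ds, dict) else ds
                    for ds in spec_d.pop("diseases", [])
                ]
                # JSON/YAML maps use lists for tuple keys; normalize
                for ds in diseases:
                    ds.ancestry_specific_effects = {
                        tuple(k) if not isinstance(k, str) else tuple(k.split("|")): v
                        for k, v in ds.ancestry_specific_effects.items()
                    }
                    ds.interaction_effects = {
                        tuple(k) if not isinstance(k, str) else tuple(k.split("|")): v
                        for k, v in ds.interaction_effects.items()
                    }
                spec = CohortSpec(diseases=diseases, **spec_d)
            else:
                spec = ukb_like_spec(**spec_d)
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown study config keys: {sorted(extra)}")
        for key in ("model_families", "interaction_candidates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(cohort_spec=spec, **d)


@dataclass
class RunManifest:
    """Everything a run produced: config echo, fits, evaluation grid."""

    config: dict
    seeds: dict
    results: pd.DataFrame  # long grid: ancestry, disease, method, dataset, auc, ...
    fit_summaries: list
    networks: dict  # (ancestry, disease, dataset) -> edge list
    wins: evaluation.WinCount | None
    skipped: list
    version: str
    timing: dict

    def to_json(self) -> str:
        wins = None
        if self.wins is not None:
            wins = {
                "n_results": self.wins.n_results,
                "wins": self.wins.wins,
                "datasets": self.wins.datasets,
                "total_combinations": self.wins.total_combinations,
                "expected": {m: self.wins.expected(m) for m in self.wins.datasets},
                "p_values": {m: self.wins.p_value(m) for m in self.wins.datasets},
            }
        return json.dumps(
            {
                "config": self.config,
                "seeds": self.seeds,
                "results": self.results.to_dict(orient="records"),
                "fit_summaries": self.fit_summaries,
                "networks": {
                    "|".join(k): [[a, b, m] for (a, b), m in v]
                    for k, v in self.networks.items()
                },
                "wins": wins,
                "skipped": self.skipped,
                "version": self.version,
                "timing": self.timing,
            },
            indent=1,
            default=_json_default,
        )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# dataset construction and splitting


def build_dataset(cohort: Cohort, config: DatasetConfig) -> np.ndarray:
    """Row indices of the cohort belonging to the dataset configuration."""
    anc = cohort.ancestry
    present = set(anc)
    if config.mode == "All":
        return np.arange(cohort.n)
    if config.focal_ancestry not in present:
        raise ValueError(f"focal ancestry {config.focal_ancestry!r} absent from cohort")
    if config.mode == "Specific":
        return np.flatnonzero(anc == config.focal_ancestry)
    wanted = {config.majority_ancestry, config.focal_ancestry}
    return np.flatnonzero(np.isin(anc, list(wanted)))


def split_train_test(cohort: Cohort, fraction: float = 0.8, seed: int = 0,
                     stratify_by=("ancestry", "outcome"),
                     merge_small: bool = False):
    """One stratified train/test split shared by every model and dataset.

    Strata are ancestry crossed with the joint outcome pattern (when
    "outcome" is in ``stratify_by``).  Within each stratum the test count
    is ``round(n_s * (1 - fraction))``, so per-stratum proportions are
    within one row of the requested fraction.  A stratum with fewer than
    two rows raises, unless ``merge_small`` merges it into its ancestry's
    largest stratum.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    keys = []
    if "ancestry" in stratify_by:
        keys.append(pd.Series(cohort.ancestry, name="ancestry").astype(str))
    if "outcome" in stratify_by:
        pattern = cohort.Y.astype(int).astype(str).agg("".join, axis=1)
        keys.append(pattern.rename("outcome"))
    if not keys:
        keys = [pd.Series(np.zeros(cohort.n, dtype=int), name="all")]
    strata = pd.concat(keys, axis=1).agg("/".join, axis=1).to_numpy()

    sizes = pd.Series(strata).value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small and not merge_small:
        raise ValueError(f"stratum too small to split: {small[0]!r}")
    if small:
        for s in small:
            anc = s.split("/")[0]
            candidates = [t for t in sizes.index if t.startswith(anc + "/") and t not in small]
            target = max(candidates, key=lambda t: sizes[t]) if candidates else sizes.idxmax()
            strata[strata == s] = target
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for s in np.unique(strata):
        rows = np.flatnonzero(strata == s)
        rows = rows[rng.permutation(rows.size)]
        n_test = int(round(rows.size * (1.0 - fraction)))
        n_test = min(max(n_test, 1), rows.size - 1)
        test_idx.append(rows[:n_test])
        train_idx.append(rows[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def design_for_disease(cohort: Cohort, disease: str, majority: str = "WB"):
    """Feature matrix for one disease: base columns + its PRS + ancestry.

    Returns ``(X, names, blocks)`` where ``blocks`` maps the "ancestry"
    unit to its one-hot columns (reference level = majority ancestry).
    Other diseases' PRS columns are excluded.
    """
    drop = [f"PRS_{d}" for d in cohort.diseases if d != disease]
    names = [nm for nm, _t in cohort.column_meta if nm not in drop]
    X = cohort.X[names].to_numpy(dtype=float)
    levels = [a for a in sorted(set(map(str, cohort.ancestry))) if a != majority]
    anc_cols = []
    anc_names = []
    for a in levels:
        anc_cols.append((cohort.ancestry == a).astype(float))
        anc_names.append(f"anc_{a}")
    if anc_cols:
        X = np.column_stack([X] + anc_cols)
        names = names + anc_names
    blocks = {"ancestry": anc_names} if anc_names else {}
    return X, names, blocks


# ---------------------------------------------------------------------------
# model runners


def _fit_lasso_cv(X, y, seed, k_folds, n_lambda):
    problem = pl.LassoProblem(X, y)
    lambdas = pl.default_lambda_grid(problem, n_lambda)
    cv = pl.cross_validate(problem, lambdas=lambdas, k_folds=k_folds, seed=seed)
    path = pl.fit_lasso_path(problem, lambdas=lambdas)
    mu, beta = path.coef_at(cv.index_min)
    return {
        "mu": mu,
        "beta": beta,
        "lambda": cv.lambda_min,
        "nonzero": int(np.count_nonzero(beta)),
    }


def _resolve_candidates(config: StudyConfig, disease: str, names, blocks):
    cands = []
    for c in config.interaction_candidates:
        if c == "prs":
            cands.append(f"PRS_{disease}")
        elif c == "ancestry":
            if blocks.get("ancestry"):
                cands.append("ancestry")
        else:
            cands.append(c)
    return [c for c in cands if c in names or c in blocks]


def run_study(config: StudyConfig) -> RunManifest:
    """Execute the full design and collect the evaluation grid.

    Failures in individual cells are recorded and the run continues.
    """
    t0 = time.time()
    cohort = config.load_cohort()
    diseases = config.diseases or cohort.diseases
    majority = config.majority_ancestry
    ancestries = sorted(set(map(str, cohort.ancestry)))
    focals = config.focal_ancestries or [a for a in ancestries if a != majority]

    train_idx, test_idx = split_train_test(
        cohort, config.split_fraction, config.seed_split, merge_small=True
    )
    assert np.intersect1d(train_idx, test_idx).size == 0

    records = []
    fit_summaries = []
    networks = {}
    skipped = []
    timing = {}

    for disease in diseases:
        td = time.time()
        y_all = cohort.Y[disease].to_numpy(dtype=float)
        X_all, names, blocks = design_for_disease(cohort, disease, majority)
        cands = _resolve_candidates(config, disease, names, blocks)

        eligible_focals = []
        for focal in focals:
            pos = int(y_all[cohort.ancestry == focal].sum())
            if pos < config.min_positive_cases:
                skipped.append(
                    {"disease": disease, "ancestry": focal,
                     "reason": f"only {pos} positive cases (<{config.min_positive_cases})"}
                )
            else:
                eligible_focals.append(focal)
        if not eligible_focals:
            continue

        # All-trained models are shared across focal ancestries
        all_rows = np.intersect1d(build_dataset(cohort, DatasetConfig("All")), train_idx)
        shared = _train_on_rows(
            config, cohort, disease, X_all, y_all, names, blocks, cands, all_rows, "All"
        )

        for focal in eligible_focals:
            cell_models = {("All", m): f for (m, f) in shared.items()}
            for mode in ("Mix", "Specific"):
                cfg = DatasetConfig(mode, focal_ancestry=focal, majority_ancestry=majority)
                rows = np.intersect1d(build_dataset(cohort, cfg), train_idx)
                want = ("lasso",) if mode == "Specific" else config.model_families
                try:
                    fits = _train_on_rows(
                        config, cohort, disease, X_all, y_all, names, blocks, cands,
                        rows, mode, families=want,
                    )
                except Exception as err:  # keep the grid going
                    skipped.append({"disease": disease, "ancestry": focal,
                                    "dataset": mode, "reason": str(err)})
                    fits = {}
                for m, f in fits.items():
                    cell_models[(mode, m)] = f

            te = np.intersect1d(np.flatnonzero(cohort.ancestry == focal), test_idx)
            assert np.intersect1d(te, train_idx).size == 0
            y_te = y_all[te]
            if np.unique(y_te).size < 2:
                skipped.append({"disease": disease, "ancestry": focal,
                                "reason": "test rows contain a single class"})
                continue
            scores = {}
            for (ds, m), f in cell_models.items():
                scores[(ds, m)] = _predict(f, m, cohort, X_all, te)

            for (ds, m), sc in scores.items():
                rec = {
                    "ancestry": focal, "disease": disease, "method": m, "dataset": ds,
                    "auc": evaluation.auc(sc, y_te),
                    "delta": np.nan, "p_one_sided": np.nan, "tier": "",
                }
                if m != "lasso" and (ds, "lasso") in scores:
                    cmp = evaluation.delong_test(sc, scores[(ds, "lasso")], y_te)
                    rec.update(delta=cmp.delta, p_one_sided=cmp.p_one_sided, tier=cmp.tier)
                records.append(rec)

            for ds in ("Mix", "All"):
                f = cell_models.get((ds, "glinternet"))
                if f is not None:
                    networks[(focal, disease, ds)] = gl.extract_network(f["fit"])

            for (ds, m), f in cell_models.items():
                fit_summaries.append({
                    "disease": disease, "focal": focal, "dataset": ds, "method": m,
                    "nonzero": f.get("nonzero"), "lambda": f.get("lambda"),
                    "alpha": f.get("alpha"),
                })
        timing[disease] = time.time() - td

    results = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["ancestry", "disease", "method", "dataset", "auc", "delta",
                 "p_one_sided", "tier"]
    )
    wins = None
    if len(results):
        wins = evaluation.count_wins(results, DATASETS_PER_METHOD)
    from . import __version__

    return RunManifest(
        config=_config_to_dict(config),
        seeds={"generation": getattr(config.cohort_spec, "seed", None),
               "split": config.seed_split, "cv": config.seed_cv},
        results=results,
        fit_summaries=fit_summaries,
        networks=networks,
        wins=wins,
        skipped=skipped,
        version=__version__,
        timing={**timing, "total": time.time() - t0},
    )


def _train_on_rows(config, cohort, disease, X_all, y_all, names, blocks, cands,
                   rows, dataset_label, families=None):
    """Fit the requested families on one training subset."""
    families = families if families is not None else config.model_families
    X = X_all[rows]
    y = y_all[rows]
    if np.unique(y).size < 2:
        raise ValueError(f"{dataset_label} training rows contain a single class")
    out = {}
    if "lasso" in families:
        out["lasso"] = _fit_lasso_cv(X, y, config.seed_cv, config.cv_folds,
                                     config.n_lambda_lasso)
    if "glinternet" in families and dataset_label != "Specific":
        fits, cv, cand = gl.cv_glinternet(
            X, names, cands, y, blocks=blocks, mode=config.glinternet_mode,
            k_folds=config.cv_folds, seed=config.seed_cv,
            n_lambda=config.n_lambda_glinternet, tol=1e-6,
        )
        fit = fits[cv.index_min]
        out["glinternet"] = {
            "fit": fit, "candidates": cand, "lambda": cv.lambda_min,
            "nonzero": int(sum(v != 0 for v in fit.theta_main.values())
                           + len(fit.active_interactions())),
        }
    if "pretrain" in families and dataset_label != "Specific":
        alphas = (0.0, 0.25, 0.5, 0.75, 1.0) if config.alpha_sweep else (config.alpha,)
        best = None
        for alpha in alphas:
            basis = pt.fit_overall(X, y, alpha=alpha, cv_seed=config.seed_cv,
                                   k_folds=config.cv_folds,
                                   n_lambda=config.n_lambda_lasso)
            model = pt.fit_group_models(basis, X, y, cohort.ancestry[rows],
                                        cv_seed=config.seed_cv,
                                        k_folds=config.cv_folds,
                                        n_lambda=config.n_lambda_lasso)
            score = _pretrain_cv_score(model)
            if best is None or score < best[0]:
                best = (score, model, alpha)
        _, model, alpha = best
        nnz = int(np.count_nonzero(model.basis.beta0))
        out["pretrain"] = {"model": model, "alpha": alpha, "lambda": None,
                           "nonzero": nnz}
    return out


def _pretrain_cv_score(model: pt.PretrainedModel) -> float:
    """Mean second-stage CV deviance at each group's chosen lambda."""
    vals = []
    for fit in model.group_fits.values():
        cv = fit.get("cv")
        if cv is not None:
            vals.append(cv.mean_deviance[cv.index_min])
    return float(np.mean(vals)) if vals else np.inf


def _predict(fitted, method, cohort, X_all, test_rows):
    X_te = X_all[test_rows]
    if method == "lasso":
        return pl.predict_proba((fitted["mu"], fitted["beta"]), X_te)
    if method == "glinternet":
        return gl.predict_proba(fitted["fit"], fitted["candidates"], X_te)
    if method == "pretrain":
        return pt.predict_group(fitted["model"], X_te, cohort.ancestry[test_rows])
    raise ValueError(f"unknown method {method!r}")


def _config_to_dict(config: StudyConfig) -> dict:
    d = {
        "diseases": config.diseases,
        "focal_ancestries": config.focal_ancestries,
        "model_families": list(config.model_families),
        "majority_ancestry": config.majority_ancestry,
        "split_fraction": config.split_fraction,
        "cv_folds": config.cv_folds,
        "alpha": config.alpha,
        "alpha_sweep": config.alpha_sweep,
        "interaction_candidates": list(config.interaction_candidates),
        "n_lambda_lasso": config.n_lambda_lasso,
        "n_lambda_glinternet": config.n_lambda_glinternet,
        "glinternet_mode": config.glinternet_mode,
        "min_positive_cases": config.min_positive_cases,
        "cohort_path": config.cohort_path,
    }
    if config.cohort_spec is not None:
        from .cohort import _spec_to_dict

        d["cohort_spec"] = _spec_to_dict(config.cohort_spec)
        # dict keys that are tuples are not JSON-representable; flatten
        for ds in d["cohort_spec"]["diseases"]:
            ds["ancestry_specific_effects"] = {
                "|".join(k): v for k, v in ds["ancestry_specific_effects"].items()
            }
            ds["interaction_effects"] = {
                "|".join(k): v for k, v in ds["interaction_effects"].items()
            }
    return d


# ---------------------------------------------------------------------------
# reporting


def render_report(manifest: RunManifest) -> str:
    """Human-readable report: per-ancestry tables, win counts, networks."""
    lines = []
    res = manifest.results
    if res.empty:
        lines.append("No evaluation cells were produced.")
    else:
        for anc in sorted(res["ancestry"].unique()):
            lines.append(f"=== Ancestry {anc} ===")
            tbl = evaluation.tabulate_results(res[res["ancestry"] == anc])
            lines.append(tbl.to_string())
            lines.append("")
    if manifest.wins is not None:
        w = manifest.wins
        lines.append("=== Win counts ===")
        for m in w.datasets:
            lines.append(
                f"{m}: observed {w.wins.get(m, 0)} of {w.n_results}, "
                f"expected {w.expected(m):.1f}, one-tailed binomial p = {w.p_value(m):.3f}"
            )
        lines.append("")
    if manifest.networks:
        lines.append("=== Interaction networks (top edges) ===")
        for key, edges in manifest.networks.items():
            anc, disease, ds = key
            lines.append(f"[{disease} / {anc} / {ds}]")
            for (a, b), mag in edges[:10]:
                lines.append(f"  {a} x {b}: {mag:.4f}")
        lines.append("")
    if manifest.skipped:
        lines.append("=== Skipped cells ===")
        for s in manifest.skipped:
            lines.append(f"  {s}")
    return "\n".join(lines)
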