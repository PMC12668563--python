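"""Synthetic multi-ancestry cohort generation.

Emulates the statistical structure of a large biobank cohort used for
ancestry-stratified disease prediction: a handful of ancestry groups with
strong imbalance, demographic columns (standardized age, 0/1 sex),
per-disease polygenic risk scores correlated with the outcome liability,
genotype principal components that separate ancestries (with within-
ancestry substructure on the fourth global PC), local PCs, and correlated
metabolite blocks.  Binary outcomes follow a logistic liability model with
shared, ancestry-specific, and interaction effects; per-ancestry intercepts
are calibrated by root finding so realized prevalences match their targets.

The generator is deterministic given the spec's seed and is the ground
truth against which the package's models are tested: the effects written
into a :class:`DiseaseSpec` are exactly what support-recovery and
interaction-recovery checks expect the models to find.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "DiseaseSpec",
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "calibrate_intercept",
    "bayes_auc",
    "write_cohort",
    "read_cohort",
    "largest_remainder_counts",
    "ukb_like_spec",
]

COLUMN_TYPES = ("demographic", "prs", "pc_global", "pc_local", "metabolite")


# ---------------------------------------------------------------------------
# specs


@dataclass
class DiseaseSpec:
    """Ground-truth outcome model for one disease.

    ``shared_effects`` maps column names to liability coefficients applied
    to every row; ``ancestry_specific_effects`` maps ``(ancestry, column)``
    to additional coefficients applied only within that ancestry;
    ``interaction_effects`` maps column pairs to coefficients on their
    elementwise product.  The disease's PRS column receives a main-effect
    coefficient derived from ``prs_liability_correlation`` (the target
    correlation between the PRS and the total liability).
    """

    name: str
    target_prevalence: dict  # ancestry -> fraction in (0, 1)
    shared_effects: dict = field(default_factory=dict)
    ancestry_specific_effects: dict = field(default_factory=dict)
    interaction_effects: dict = field(default_factory=dict)
    prs_liability_correlation: float = 0.3

    def validate(self, ancestries):
        for a, prev in self.target_prevalence.items():
            if not 0.0 < prev < 1.0:
                raise ValueError(
                    f"disease {self.name}: prevalence for {a} must be in (0,1)"
                )
        for a in ancestries:
            if a not in self.target_prevalence:
                raise ValueError(
                    f"disease {self.name}: no target prevalence for ancestry {a}"
                )
        if not 0.0 <= self.prs_liability_correlation < 1.0:
            raise ValueError(f"disease {self.name}: PRS correlation must be in [0,1)")


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort."""

    n_total: int
    ancestry_proportions: dict  # ancestry code -> fraction
    n_metabolites: int = 20
    n_pcs_global: int = 6
    n_pcs_local: int = 4
    diseases: list = field(default_factory=list)
    metabolite_block_sizes: list = field(default_factory=lambda: [5])
    metabolite_block_correlation: float = 0.5
    seed: int = 0
    # structural constants of the feature model
    pc_separation: float = 2.5  # ancestry centroid distance on global PCs
    pc4_substructure: float = 1.2  # within-ancestry shift on global PC 4
    age_effect_sd: float = 1.0

    def validate(self):
        if self.n_total < 1:
            raise ValueError("n_total must be at least 1")
        total = sum(self.ancestry_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ancestry proportions must sum to 1 (got {total})")
        if any(v <= 0 for v in self.ancestry_proportions.values()):
            raise ValueError("ancestry proportions must be positive")
        for name, cnt in (
            ("n_metabolites", self.n_metabolites),
            ("n_pcs_global", self.n_pcs_global),
            ("n_pcs_local", self.n_pcs_local),
        ):
            if cnt < 1:
                raise ValueError(f"{name} must be at least 1")
        if not 0.0 <= self.metabolite_block_correlation < 1.0:
            raise ValueError("metabolite block correlation must be in [0,1)")
        if any(b < 1 for b in self.metabolite_block_sizes):
            raise ValueError("metabolite block sizes must be at least 1")
        for d in self.diseases:
            d.validate(list(self.ancestry_proportions))

    @property
    def ancestries(self):
        return list(self.ancestry_proportions)

    def column_names(self):
        names = ["age", "sex"]
        names += [f"PRS_{d.name}" for d in self.diseases]
        names += [f"GPC{i + 1}" for i in range(self.n_pcs_global)]
        names += [f"PC{i + 1}" for i in range(self.n_pcs_local)]
        names += [f"MET{i + 1}" for i in range(self.n_metabolites)]
        return names

    def column_types(self):
        types = ["demographic", "demographic"]
        types += ["prs"] * len(self.diseases)
        types += ["pc_global"] * self.n_pcs_global
        types += ["pc_local"] * self.n_pcs_local
        types += ["metabolite"] * self.n_metabolites
        return types


@dataclass
class Cohort:
    """A generated (or loaded) cohort: features, labels and outcomes."""

    X: pd.DataFrame  # n x p numeric features
    column_meta: list  # list of (name, type)
    ancestry: np.ndarray  # length-n ancestry codes
    Y: pd.DataFrame  # n x D binary outcomes, columns = disease names
    provenance: dict = field(default_factory=dict)
    liabilities: dict | None = None  # disease -> true linear predictor (incl. intercept)

    def __post_init__(self):
        if self.X.shape[0] == 0:
            raise ValueError("empty cohort (0 rows) is invalid")
        if self.X.isna().any().any() or self.Y.isna().any().any():
            raise ValueError("cohort contains missing values")
        if not self.Y.isin([0, 1]).all().all():
            raise ValueError("outcomes must be 0/1")
        names = [nm for nm, _t in self.column_meta]
        if names != list(self.X.columns):
            raise ValueError("column_meta does not match X columns")
        if len(set(names)) != len(names):
            raise ValueError("column names must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def diseases(self):
        return list(self.Y.columns)

    def column_type(self, name: str) -> str:
        for nm, t in self.column_meta:
            if nm == name:
                return t
        raise KeyError(name)


# ---------------------------------------------------------------------------
# helpers


def largest_remainder_counts(n_total: int, proportions: dict) -> dict:
    """Integer counts summing to n_total, by the largest-remainder rule."""
    keys = list(proportions)
    raw = np.array([n_total * proportions[k] for k in keys])
    base = np.floor(raw).astype(int)
    short = n_total - int(base.sum())
    remainders = raw - base
    order = np.argsort(-remainders, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def calibrate_intercept(linear_predictors, target_prevalence: float,
                        tol: float = 1e-8) -> float:
    """Intercept making mean(sigmoid(intercept + lp)) equal the target.

    The mean sigmoid is strictly increasing in the intercept, so a unique
    root exists; found by Brent's method on [-40, 40].
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    lp = np.asarray(linear_predictors, dtype=float)

    def f(mu):
        return float(np.mean(_sigmoid(mu + lp))) - target_prevalence

    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"target prevalence {target_prevalence} unreachable for the given "
            "linear predictors within calibration bounds"
        )
    return float(brentq(f, lo, hi, xtol=tol))


# ---------------------------------------------------------------------------
# feature generation internals


def _gen_features(spec: CohortSpec, ancestry: np.ndarray, rng: np.random.Generator):
    """Generate the raw feature frame for given per-row ancestry labels."""
    n = ancestry.shape[0]
    codes = spec.ancestries
    anc_idx = np.array([codes.index(a) for a in ancestry])

    cols = {}
    cols["age"] = rng.normal(0.0, spec.age_effect_sd, size=n)
    cols["sex"] = rng.integers(0, 2, size=n).astype(float)

    for d in spec.diseases:
        cols[f"PRS_{d.name}"] = rng.normal(size=n)

    # global PCs: ancestry centroids + isotropic noise; the first group
    # (majority, by convention) sits at the origin.  Global PC 4 carries
    # within-ancestry substructure (two subclusters per ancestry).
    npc = spec.n_pcs_global
    centroids = np.zeros((len(codes), npc))
    for i in range(1, len(codes)):
        centroids[i, (i - 1) % npc] = spec.pc_separation
    gpc = centroids[anc_idx] + rng.normal(size=(n, npc))
    if npc >= 4:
        sub = rng.integers(0, 2, size=n)
        gpc[:, 3] += spec.pc4_substructure * (2.0 * sub - 1.0)
    for i in range(npc):
        cols[f"GPC{i + 1}"] = gpc[:, i]

    for i in range(spec.n_pcs_local):
        cols[f"PC{i + 1}"] = rng.normal(size=n)

    # metabolites: exchangeable (compound-symmetry) correlation within
    # blocks; the block-size pattern cycles until all columns are covered
    rho = spec.metabolite_block_correlation
    sizes = []
    k = 0
    while sum(sizes) < spec.n_metabolites:
        sizes.append(spec.metabolite_block_sizes[k % len(spec.metabolite_block_sizes)])
        k += 1
    if sum(sizes) > spec.n_metabolites:
        sizes[-1] -= sum(sizes) - spec.n_metabolites
    met_idx = 0
    for size in sizes:
        factor = rng.normal(size=n)
        for _ in range(size):
            noise = rng.normal(size=n)
            cols[f"MET{met_idx + 1}"] = math.sqrt(rho) * factor + math.sqrt(1 - rho) * noise
            met_idx += 1

    X = pd.DataFrame({nm: cols[nm] for nm in spec.column_names()})
    return X


def _liability_base(spec: CohortSpec, disease: DiseaseSpec, X: pd.DataFrame,
                    ancestry: np.ndarray) -> np.ndarray:
    """Liability from explicit effects (everything except the PRS main term)."""
    names = set(X.columns)
    eta = np.zeros(X.shape[0])
    for col, coef in disease.shared_effects.items():
        if col not in names:
            raise ValueError(f"disease {disease.name}: unknown column {col!r}")
        eta += coef * X[col].to_numpy()
    for (anc, col), coef in disease.ancestry_specific_effects.items():
        if anc not in spec.ancestry_proportions:
            raise ValueError(f"disease {disease.name}: unknown ancestry {anc!r}")
        if col not in names:
            raise ValueError(f"disease {disease.name}: unknown column {col!r}")
        eta += coef * X[col].to_numpy() * (ancestry == anc)
    for (ca, cb), coef in disease.interaction_effects.items():
        if ca not in names or cb not in names:
            raise ValueError(
                f"disease {disease.name}: interaction ({ca}, {cb}) references "
                "a missing column"
            )
        eta += coef * X[ca].to_numpy() * X[cb].to_numpy()
    return eta


def _prs_coefficient(disease: DiseaseSpec, eta_base: np.ndarray) -> float:
    """Main-effect coefficient giving the PRS its target liability correlation.

    With PRS ~ N(0,1) independent of the remaining liability ``eta_base``,
    ``corr(PRS, eta_base + c*PRS) = c / sqrt(var(eta_base) + c^2)``, so
    ``c = rho * sd(eta_base) / sqrt(1 - rho^2)`` (sd floor of 1 keeps the
    PRS informative when no other effects are present).
    """
    rho = disease.prs_liability_correlation
    if rho == 0.0:
        return 0.0
    sd = float(np.std(eta_base))
    sd = max(sd, 1.0)
    return rho * sd / math.sqrt(1.0 - rho**2)


def _simulate(spec: CohortSpec, ancestry: np.ndarray, rng: np.random.Generator):
    """Features, outcomes and true liabilities for given ancestry labels."""
    X = _gen_features(spec, ancestry, rng)
    Y = {}
    liab = {}
    intercepts = {}
    for d in spec.diseases:
        eta = _liability_base(spec, d, X, ancestry)
        c = _prs_coefficient(d, eta)
        eta = eta + c * X[f"PRS_{d.name}"].to_numpy()
        full = np.empty_like(eta)
        mus = {}
        for a in spec.ancestries:
            rows = ancestry == a
            if not rows.any():
                continue
            try:
                mu = calibrate_intercept(eta[rows], d.target_prevalence[a])
            except ValueError as err:
                raise ValueError(
                    f"disease {d.name}, ancestry {a}: {err}"
                ) from None
            mus[a] = mu
            full[rows] = mu + eta[rows]
        Y[d.name] = (rng.random(ancestry.shape[0]) < _sigmoid(full)).astype(int)
        liab[d.name] = full
        intercepts[d.name] = mus
    return X, pd.DataFrame(Y), liab, intercepts


# ---------------------------------------------------------------------------
# public API


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort deterministically from the spec and its seed.

    Ancestry counts follow largest-remainder rounding of the proportions;
    outcomes are Bernoulli draws from the logistic liability model with
    per-ancestry intercepts calibrated to the target prevalences.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = largest_remainder_counts(spec.n_total, spec.ancestry_proportions)
    labels = np.concatenate([np.repeat(a, c) for a, c in counts.items()])
    ancestry = labels[rng.permutation(spec.n_total)]
    X, Y, liab, intercepts = _simulate(spec, ancestry, rng)
    meta = list(zip(spec.column_names(), spec.column_types()))
    provenance = {
        "seed": spec.seed,
        "n_total": spec.n_total,
        "ancestry_counts": counts,
        "intercepts": intercepts,
        "spec": _spec_to_dict(spec),
    }
    return Cohort(
        X=X,
        column_meta=meta,
        ancestry=ancestry,
        Y=Y,
        provenance=provenance,
        liabilities=liab,
    )


def bayes_auc(spec: CohortSpec, disease: str, ancestry: str, n_mc: int = 50000,
              seed: int | None = None):
    """Monte-Carlo AUC of the true liability score within one ancestry.

    Simulates ``n_mc`` individuals of the given ancestry through the same
    feature and liability machinery, draws outcomes, and scores them with
    the true liability — an upper-bound reference for any fitted model's
    AUC on that ancestry.  Returns ``(auc, standard_error)``.
    """
    spec.validate()
    names = [d.name for d in spec.diseases]
    if disease not in names:
        raise ValueError(f"unknown disease {disease!r}")
    if ancestry not in spec.ancestry_proportions:
        raise ValueError(f"unknown ancestry {ancestry!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = np.repeat(ancestry, n_mc)
    sub = CohortSpec(**{**_spec_to_dict(spec, raw=True), "n_total": n_mc})
    X, Y, liab, _ = _simulate(sub, labels, rng)
    y = Y[disease].to_numpy()
    score = liab[disease]
    if y.min() == y.max():  # no outcome variation at this MC size
        return 0.5, float("inf")
    from .evaluation import auc as _auc, _placements

    a = _auc(score, y)
    v10, v01 = _placements(np.asarray(score, float), y)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    return float(a), float(np.sqrt(var))


def _spec_to_dict(spec: CohortSpec, raw: bool = False):
    d = {
        "n_total": spec.n_total,
        "ancestry_proportions": dict(spec.ancestry_proportions),
        "n_metabolites": spec.n_metabolites,
        "n_pcs_global": spec.n_pcs_global,
        "n_pcs_local": spec.n_pcs_local,
        "diseases": [asdict(x) for x in spec.diseases] if not raw else list(spec.diseases),
        "metabolite_block_sizes": list(spec.metabolite_block_sizes),
        "metabolite_block_correlation": spec.metabolite_block_correlation,
        "seed": spec.seed,
        "pc_separation": spec.pc_separation,
        "pc4_substructure": spec.pc4_substructure,
        "age_effect_sd": spec.age_effect_sd,
    }
    return d


# ---------------------------------------------------------------------------
# serialization: tab-delimited matrix + JSON sidecar


def _sidecar_path(path: str) -> str:
    base = str(path)
    if base.endswith(".gz"):
        base = base[: -len(".gz")]
    return base + ".meta.json"


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write the cohort as TSV (gzip if the path ends in .gz) + JSON sidecar."""
    table = pd.DataFrame({"ancestry": cohort.ancestry})
    for d in cohort.diseases:
        table[f"y_{d}"] = cohort.Y[d].to_numpy()
    for nm in cohort.X.columns:
        table[nm] = cohort.X[nm].to_numpy()
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "columns": [{"name": nm, "type": t} for nm, t in cohort.column_meta],
        "ancestry_levels": sorted(set(map(str, cohort.ancestry))),
        "diseases": cohort.diseases,
        "n": cohort.n,
        "provenance": _jsonable(cohort.provenance),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_cohort(path: str) -> Cohort:
    """Read a cohort written by :func:`write_cohort`, validating the sidecar."""
    sidecar = _sidecar_path(path)
    try:
        with open(sidecar) as fh:
            meta = json.load(fh)
    except (OSError, json.JSONDecodeError) as err:
        raise ValueError(f"malformed or missing metadata sidecar {sidecar}: {err}")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        table = pd.read_csv(fh, sep="\t")
    if table.shape[0] == 0:
        raise ValueError("empty cohort table (0 rows) is invalid")
    feat_cols = [c["name"] for c in meta["columns"]]
    for nm in feat_cols:
        if nm not in table.columns:
            raise ValueError(f"metadata names column {nm!r} absent from the table")
    diseases = meta["diseases"]
    for d in diseases:
        if f"y_{d}" not in table.columns:
            raise ValueError(f"outcome column for disease {d!r} absent from the table")
    if "ancestry" not in table.columns:
        raise ValueError("ancestry column absent from the table")
    extra = set(table.columns) - set(feat_cols) - {f"y_{d}" for d in diseases} - {"ancestry"}
    if extra:
        raise ValueError(f"table has columns not described by the sidecar: {sorted(extra)}")
    X = table[feat_cols].astype(float)
    Y = table[[f"y_{d}" for d in diseases]].copy()
    Y.columns = diseases
    return Cohort(
        X=X,
        column_meta=[(c["name"], c["type"]) for c in meta["columns"]],
        ancestry=table["ancestry"].astype(str).to_numpy(),
        Y=Y,
        provenance=meta.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# study-condition defaults


#: Case / total counts per ancestry and disease in the emulated biobank
#: cohort (the generator's prevalence targets are their ratios).
UKB_CASE_COUNTS = {
    "WB": {"total": 80810, "DIA": 5479, "MI": 3234, "AST": 10909, "GS": 4103,
            "OST": 7579, "ART": 4969, "CYS": 2725, "CRF": 2862},
    "SA": {"total": 1911, "DIA": 460, "MI": 151, "AST": 285, "GS": 69,
            "OST": 101, "ART": 122, "CYS": 56, "CRF": 93},
    "AF": {"total": 1499, "DIA": 232, "MI": 30, "AST": 201, "GS": 36,
            "OST": 86, "ART": 103, "CYS": 24, "CRF": 83},
    "AD": {"total": 6783, "DIA": 632, "MI": 268, "AST": 932, "GS": 285,
            "OST": 492, "ART": 379, "CYS": 234, "CRF": 213},
    "NBE": {"total": 5910, "DIA": 419, "MI": 197, "AST": 768, "GS": 262,
             "OST": 433, "ART": 279, "CYS": 178, "CRF": 165},
}

UKB_DISEASES = ("DIA", "MI", "AST", "GS", "OST", "ART", "CYS", "CRF")


def ukb_prevalences(disease: str) -> dict:
    """Per-ancestry prevalence targets from the emulated cohort's case table."""
    return {
        a: UKB_CASE_COUNTS[a][disease] / UKB_CASE_COUNTS[a]["total"]
        for a in UKB_CASE_COUNTS
    }


def ukb_ancestry_proportions() -> dict:
    totals = {a: UKB_CASE_COUNTS[a]["total"] for a in UKB_CASE_COUNTS}
    grand = sum(totals.values())
    return {a: t / grand for a, t in totals.items()}


def default_disease_spec(name: str, n_metabolites: int,
                         minority: str = "SA") -> DiseaseSpec:
    """A disease with shared metabolite/age effects, an ancestry-specific
    effect, and interactions of the PRS with the substructure PC and of
    sex with a metabolite — the effect classes the three model families
    are designed to pick up."""
    mets = [f"MET{i + 1}" for i in range(min(5, n_metabolites))]
    shared = {"age": 0.3}
    for i, m in enumerate(mets):
        shared[m] = 0.35 * (-1.0) ** i
    return DiseaseSpec(
        name=name,
        target_prevalence=ukb_prevalences(name) if name in UKB_DISEASES else {},
        shared_effects=shared,
        ancestry_specific_effects={(minority, mets[0]): -0.5} if mets else {},
        interaction_effects={
            (f"PRS_{name}", "GPC4"): 0.3,
            ("sex", mets[1] if len(mets) > 1 else "age"): 0.25,
        },
        prs_liability_correlation=0.3,
    )


def ukb_like_spec(n_total: int = 96913, diseases=("DIA", "ART"), seed: int = 0,
                  n_metabolites: int = 249, n_pcs_global: int = 40,
                  n_pcs_local: int = 10) -> CohortSpec:
    """A cohort spec emulating the UK-Biobank-scale study conditions.

    Defaults reproduce the real cohort's ancestry imbalance and column
    composition (p = 2 demographics + 40 global PCs + 10 local PCs + 249
    metabolites + one PRS per disease).  Pass a smaller ``n_total`` /
    column counts for desk-scale runs.
    """
    return CohortSpec(
        n_total=n_total,
        ancestry_proportions=ukb_ancestry_proportions(),
        n_metabolites=n_metabolites,
        n_pcs_global=n_pcs_global,
        n_pcs_local=n_pcs_local,
        diseases=[default_disease_spec(d, n_metabolites) for d in diseases],
        metabolite_block_sizes=[5],
        metabolite_block_correlation=0.5,
        seed=seed,
    )
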