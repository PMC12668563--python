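"""Shared fixtures: small logistic problems and a two-ancestry cohort."""

import numpy as np
import pytest

from ancestrylasso import cohort as ch


def make_logistic_problem(seed, n=200, p=10, beta=None, offset_sd=0.0,
                          col_scales=None):
    """A random logistic dataset with known coefficients."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if col_scales is not None:
        X = X * np.asarray(col_scales)
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [0.9, -0.7, 0.5][: min(3, p)]
    offset = rng.normal(scale=offset_sd, size=n) if offset_sd else np.zeros(n)
    eta = offset + X @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    if y.min() == y.max():  # pragma: no cover - guard for extreme seeds
        y[0] = 1.0 - y[0]
    return X, y, offset, beta


@pytest.fixture(scope="session")
def two_ancestry_spec():
    return ch.CohortSpec(
        n_total=1200,
        ancestry_proportions={"WB": 0.75, "SA": 0.25},
        n_metabolites=8,
        n_pcs_global=4,
        n_pcs_local=2,
        diseases=[
            ch.DiseaseSpec(
                name="DIA",
                target_prevalence={"WB": 0.10, "SA": 0.22},
                shared_effects={"age": 0.3, "MET1": 0.35, "MET2": -0.35},
                ancestry_specific_effects={("SA", "MET3"): -0.5},
                interaction_effects={("PRS_DIA", "GPC4"): 0.4, ("sex", "MET2"): 0.25},
                prs_liability_correlation=0.3,
            )
        ],
        metabolite_block_sizes=[4],
        metabolite_block_correlation=0.4,
        seed=11,
    )


@pytest.fixture(scope="session")
def two_ancestry_cohort(two_ancestry_spec):
    return ch.generate_cohort(two_ancestry_spec)
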