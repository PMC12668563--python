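"""ROC-AUC evaluation, paired DeLong tests and the win-count meta-analysis.

The central object is :class:`AucComparison`: a paired comparison of two
models scored on the *same* test individuals, summarised by the two AUCs,
their difference, and a one-sided DeLong p-value.  The DeLong test uses the
structural-components (placement value) estimator of the variance of the
AUC difference, which accounts for the correlation induced by scoring the
same subjects with both models.

Ties are handled with the mid-rank convention throughout, so ``auc`` equals
the tie-corrected Mann-Whitney statistic
``(#concordant + 0.5 * #tied) / (n_pos * n_neg)`` exactly.

The win-count analysis treats per-column "best AUC" outcomes across a grid
of method x dataset combinations as Bernoulli trials whose null success
probability is proportional to the number of datasets a method was trained
on, and applies an exact one-tailed binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocCurve",
    "AucComparison",
    "WinCount",
    "auc",
    "delong_test",
    "expected_wins",
    "win_count_binomial_test",
    "tabulate_results",
    "significance_tier",
]


# ---------------------------------------------------------------------------
# basic containers


@dataclass
class RocCurve:
    """ROC curve points for one score vector against binary labels."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int

    @classmethod
    def from_scores(cls, scores, labels) -> "RocCurve":
        scores = np.asarray(scores, dtype=float)
        labels = _check_labels(labels)
        fpr, tpr, thr = _sk_roc_curve(labels, scores)
        return cls(
            thresholds=thr,
            fpr=fpr,
            tpr=tpr,
            n_pos=int(labels.sum()),
            n_neg=int((1 - labels).sum()),
        )


def significance_tier(p: float) -> str:
    """Map a p-value to its annotation: '**' below 0.01, '*' below 0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AucComparison:
    """Paired ROC comparison of a candidate model against a baseline."""

    auc_model: float
    auc_baseline: float
    delta: float
    p_one_sided: float
    variance: float
    var_model: float
    var_baseline: float
    covariance: float
    n_pos: int
    n_neg: int
    alternative: str = "a_greater"
    degenerate: bool = False

    @property
    def tier(self) -> str:
        return significance_tier(self.p_one_sided)


@dataclass
class WinCount:
    """Observed wins per method over a grid of comparison columns."""

    n_results: int
    wins: dict = field(default_factory=dict)
    datasets: dict = field(default_factory=dict)
    total_combinations: int = 0

    def expected(self, method: str) -> float:
        return expected_wins(
            self.n_results, self.datasets[method], self.total_combinations
        )

    def p_value(self, method: str) -> float:
        return win_count_binomial_test(
            self.n_results,
            self.wins.get(method, 0),
            self.datasets[method],
            self.total_combinations,
        )


# ---------------------------------------------------------------------------
# AUC and DeLong


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return labels.astype(int)


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Mid-rank placement values V10 (per positive) and V01 (per negative).

    V10[i] = fraction of negatives scored below positive i (ties count 1/2);
    V01[j] = fraction of positives scored above negative j likewise.  The
    mean of either vector is the tie-corrected Mann-Whitney AUC.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def auc(scores, labels) -> float:
    """Tie-corrected Mann-Whitney ROC-AUC.

    Equals ``(#concordant pairs + 0.5 * #tied pairs) / (n_pos * n_neg)``
    exactly, for any real-valued scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must have equal length")
    v10, _ = _placements(scores, labels)
    return float(v10.mean())


def delong_test(scores_a, scores_b, labels, alternative: str = "a_greater") -> AucComparison:
    """DeLong test for two correlated ROC curves on paired scores.

    Parameters
    ----------
    scores_a, scores_b
        Scores of the candidate model (a) and baseline (b) for the same
        subjects, in the same order.
    labels
        Binary outcomes shared by both score vectors.
    alternative
        ``"a_greater"`` (one-sided, AUC_a > AUC_b — the default directional
        hypothesis), ``"b_greater"``, or ``"two_sided"``.

    Notes
    -----
    The variance of ``AUC_a - AUC_b`` is estimated from the placement-value
    structural components: ``var = S10_aa/m + S01_aa/n + S10_bb/m + S01_bb/n
    - 2*(S10_ab/m + S01_ab/n)`` where S are empirical (co)variances of the
    per-positive and per-negative placements.  With zero estimated variance
    and zero difference the p-value is 0.5 by convention; with a nonzero
    difference it degenerates to 0 or 1 and the result is flagged.
    """
    if alternative not in ("a_greater", "b_greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(labels)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("scores_a, scores_b and labels must be equal-length")

    v10_a, v01_a = _placements(scores_a, labels)
    v10_b, v01_b = _placements(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())

    def _cov(x, y):
        if x.size < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    s10_aa = _cov(v10_a, v10_a)
    s10_bb = _cov(v10_b, v10_b)
    s10_ab = _cov(v10_a, v10_b)
    s01_aa = _cov(v01_a, v01_a)
    s01_bb = _cov(v01_b, v01_b)
    s01_ab = _cov(v01_a, v01_b)

    var_a = s10_aa / m + s01_aa / n
    var_b = s10_bb / m + s01_bb / n
    cov_ab = s10_ab / m + s01_ab / n
    var_delta = var_a + var_b - 2.0 * cov_ab
    delta = auc_a - auc_b

    degenerate = False
    if var_delta <= 0:
        degenerate = True
        if delta == 0.0:
            p_two = 1.0
            z = 0.0
        else:
            z = np.inf if delta > 0 else -np.inf
            p_two = 0.0
    else:
        z = delta / np.sqrt(var_delta)
        p_two = 2.0 * stats.norm.sf(abs(z))

    if alternative == "two_sided":
        p = p_two
    elif alternative == "a_greater":
        p = float(stats.norm.sf(z)) if np.isfinite(z) else (0.0 if z > 0 else 1.0)
    else:
        p = float(stats.norm.cdf(z)) if np.isfinite(z) else (1.0 if z > 0 else 0.0)
    if degenerate and delta == 0.0 and alternative != "two_sided":
        p = 0.5  # identical curves, no information either way

    return AucComparison(
        auc_model=auc_a,
        auc_baseline=auc_b,
        delta=delta,
        p_one_sided=float(p),
        variance=float(max(var_delta, 0.0)),
        var_model=float(var_a),
        var_baseline=float(var_b),
        covariance=float(cov_ab),
        n_pos=m,
        n_neg=n,
        alternative=alternative,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# win-count meta-analysis


def expected_wins(n_results: int, method_datasets: int, total_combinations: int) -> float:
    """Expected number of best-AUC wins for a method under the chance null.

    A method trained on ``method_datasets`` of ``total_combinations``
    method-dataset combinations wins each of ``n_results`` comparison
    columns with probability ``method_datasets / total_combinations``.
    Returned at full precision; display rounding is the caller's choice.
    """
    if n_results <= 0 or method_datasets <= 0 or total_combinations <= 0:
        raise ValueError("counts must be positive")
    if method_datasets > total_combinations:
        raise ValueError("method_datasets cannot exceed total_combinations")
    return n_results * method_datasets / total_combinations


def win_count_binomial_test(
    n_results: int, observed_wins: int, method_datasets: int, total_combinations: int
) -> float:
    """Exact one-tailed binomial upper-tail p-value for an observed win count.

    ``P(X >= observed_wins)`` with ``X ~ Binomial(n_results,
    method_datasets / total_combinations)``.
    """
    if not 0 <= observed_wins <= n_results:
        raise ValueError("observed_wins must lie in [0, n_results]")
    p0 = method_datasets / total_combinations
    if observed_wins == 0:
        return 1.0
    return float(stats.binom.sf(observed_wins - 1, n_results, p0))


# ---------------------------------------------------------------------------
# result tables


def tabulate_results(
    results: pd.DataFrame,
    auc_col: str = "auc",
    p_col: str = "p_one_sided",
) -> pd.DataFrame:
    """Pivot a long results frame into the per-ancestry comparison table.

    ``results`` must have columns ``ancestry, method, dataset, disease``
    plus the AUC column and (optionally, for non-baseline rows) a p-value
    column.  Returns one wide table per call with a row per (method,
    dataset), a column per disease, an ``Average`` column, significance
    stars appended to cells, and the per-column best AUC marked with a
    trailing ``!``.  Missing cells render as ``NA``.
    """
    required = {"ancestry", "method", "dataset", "disease", auc_col}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results frame missing columns: {sorted(missing)}")
    ancestries = results["ancestry"].unique()
    if len(ancestries) != 1:
        raise ValueError("tabulate_results expects a single ancestry per call")

    diseases = list(pd.unique(results["disease"]))
    rows = list(dict.fromkeys(zip(results["method"], results["dataset"])))
    aucs = pd.DataFrame(index=pd.MultiIndex.from_tuples(rows), columns=diseases, dtype=float)
    stars = pd.DataFrame("", index=aucs.index, columns=diseases)
    for _, rec in results.iterrows():
        key = (rec["method"], rec["dataset"])
        aucs.loc[key, rec["disease"]] = rec[auc_col]
        if p_col in results.columns and pd.notna(rec.get(p_col)):
            stars.loc[key, rec["disease"]] = significance_tier(rec[p_col])

    out = pd.DataFrame(index=aucs.index, columns=diseases + ["Average"], dtype=object)
    best = {d: aucs[d].idxmax() for d in diseases if aucs[d].notna().any()}
    for key in aucs.index:
        for d in diseases:
            val = aucs.loc[key, d]
            if pd.isna(val):
                out.loc[key, d] = "NA"
                continue
            cell = f"{val:.3f}{stars.loc[key, d]}"
            if best.get(d) == key:
                cell += "!"
            out.loc[key, d] = cell
        row_vals = aucs.loc[key].dropna()
        out.loc[key, "Average"] = f"{row_vals.mean():.3f}" if len(row_vals) else "NA"
    out.index.names = ["method", "dataset"]
    return out


def count_wins(results: pd.DataFrame, datasets_per_method: dict, auc_col: str = "auc") -> WinCount:
    """Count per-column best-AUC wins across all (ancestry, disease) columns.

    Each (ancestry, disease) pair is one comparison column; the winning
    (method, dataset) combination credits one win to its method.
    """
    wins: dict = {m: 0 for m in datasets_per_method}
    n_results = 0
    for (_, _), grp in results.groupby(["ancestry", "disease"]):
        grp = grp.dropna(subset=[auc_col])
        if grp.empty:
            continue
        n_results += 1
        winner = grp.loc[grp[auc_col].idxmax(), "method"]
        wins[winner] = wins.get(winner, 0) + 1
    total = sum(datasets_per_method.values())
    return WinCount(
        n_results=n_results,
        wins=wins,
        datasets=dict(datasets_per_method),
        total_combinations=total,
    )
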