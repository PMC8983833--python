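"""Predictor evaluation and combination into a per-gene priority rating.

The proximity predictor (``nGene``) is the conventional baseline; regulatory
predictors (cGene/eGene datasets) are kept only if a random-forest permutation
importance rates them no less informative than the baseline.  Surviving
predictor affinities are combined either directly (sum, max, harmonic sum) or
after transformation to empirical p-values by a meta-analysis method
(Fisher's, the logistic method, or the joint order statistic), yielding a
combined score rescaled to a 0-5 priority rating.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "LabelSet",
    "ImportanceTable",
    "assemble_labels",
    "predictor_importance",
    "select_informative",
    "affinity_to_pvalues",
    "combine",
    "rate",
    "COMBINE_METHODS",
]

COMBINE_METHODS = ("sum", "max", "harmonic", "fisher", "logistic", "orderstat")

_P_CLAMP = 1e-16  # logistic method: keep p strictly inside (0,1)


@dataclass(frozen=True)
class LabelSet:
    """Benchmark labels: proof-of-concept positives vs sampled controls."""

    positives: frozenset[str]
    controls: frozenset[str]
    draw_seed: int

    def __post_init__(self) -> None:
        if not self.positives or not self.controls:
            raise ValueError("positives and controls must both be non-empty")
        if self.positives & self.controls:
            raise ValueError("positives and controls must be disjoint")


@dataclass(frozen=True)
class ImportanceTable:
    """Per-predictor mean out-of-bag accuracy decrease, with the baseline name."""

    importances: pd.Series
    baseline_name: str = "nGene"

    def __post_init__(self) -> None:
        if self.baseline_name not in self.importances.index:
            raise ValueError(f"baseline {self.baseline_name!r} missing from importances")


def assemble_labels(
    drug_targets: pd.DataFrame,
    universe: list[str],
    control_ratio: int = 10,
    seed: int = 0,
    *,
    min_phase: int = 2,
) -> LabelSet:
    """Positives = genes with a drug at development phase >= ``min_phase``;
    controls = a seeded uniform sample (without replacement) from the rest.
    """
    universe_set = set(universe)
    positives = sorted(
        set(drug_targets.loc[drug_targets["max_phase"] >= min_phase, "gene"]) & universe_set
    )
    if not positives:
        raise ValueError(f"no gene with max_phase >= {min_phase} in the universe")
    pool = sorted(universe_set - set(positives))
    n_controls = control_ratio * len(positives)
    if n_controls > len(pool):
        raise ValueError(
            f"universe too small: need {n_controls} controls, only {len(pool)} candidates"
        )
    rng = np.random.default_rng(seed)
    controls = rng.choice(pool, size=n_controls, replace=False)
    return LabelSet(frozenset(positives), frozenset(controls.tolist()), seed)


def predictor_importance(
    matrix: pd.DataFrame,
    labels: LabelSet,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceTable:
    """Breiman permutation importance over a bagged decision-tree forest.

    For each tree fit on a bootstrap sample, the importance of a predictor is
    the drop in out-of-bag accuracy when that predictor's out-of-bag values
    are permuted; the table reports the mean over trees.  Constant columns get
    importance 0 with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 predictors to compare importances")
    # sorted so the result is invariant to the row order of the matrix
    rows = sorted(g for g in matrix.index if g in labels.positives or g in labels.controls)
    if not rows:
        raise ValueError("labels do not overlap the predictor matrix")
    X = matrix.loc[rows].to_numpy()
    y = np.array([1 if g in labels.positives else 0 for g in rows])
    n, k = X.shape
    for j, col in enumerate(matrix.columns):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"predictor {col!r} is constant; importance will be 0", stacklevel=2)
    rng = np.random.default_rng(seed)
    drops = np.zeros(k)
    used = np.zeros(k)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(X[boot], y[boot])
        acc = float(np.mean(tree.predict(X[oob]) == y[oob]))
        for j in range(k):
            X_perm = X[oob].copy()
            X_perm[:, j] = X_perm[rng.permutation(oob.size), j]
            acc_perm = float(np.mean(tree.predict(X_perm) == y[oob]))
            drops[j] += acc - acc_perm
            used[j] += 1
    if not used.all():
        raise RuntimeError("no usable out-of-bag sample; increase n_trees or sample size")
    return ImportanceTable(pd.Series(drops / used, index=matrix.columns))


def select_informative(importances: ImportanceTable) -> list[str]:
    """Keep the baseline plus every predictor no less important than it."""
    base = importances.importances[importances.baseline_name]
    kept = [importances.baseline_name]
    for name, value in importances.importances.items():
        if name != importances.baseline_name and value >= base:
            kept.append(name)
    return kept


def affinity_to_pvalues(matrix: pd.DataFrame) -> pd.DataFrame:
    """Empirical per-predictor p-values: rank of the gene by descending
    affinity (average ranks on ties) divided by the number of genes; genes
    with zero affinity get p = 1 exactly.
    """
    N = len(matrix)
    out = {}
    for col in matrix.columns:
        values = matrix[col].to_numpy()
        if np.ptp(values) == 0:
            raise ValueError(f"predictor {col!r} is constant; drop it before combining")
        p = stats.rankdata(-values, method="average") / N
        p[values == 0] = 1.0
        out[col] = p
    return pd.DataFrame(out, index=matrix.index)


def _orderstat_q(r: np.ndarray) -> np.ndarray:
    """Joint cumulative of k sorted uniform order statistics, Q = k! * V_k.

    ``r`` has shape (n, k), each row sorted ascending.  V follows the
    inclusion-exclusion recurrence V_0 = 1,
    V_i = sum_{j=1..i} (-1)^(j-1) (V_{i-j} / j!) r_{k-i+1}^j.
    """
    n, k = r.shape
    V = [np.ones(n)]
    for i in range(1, k + 1):
        acc = np.zeros(n)
        base = r[:, k - i]
        power = np.ones(n)
        for j in range(1, i + 1):
            power = power * base
            acc += (-1.0) ** (j - 1) * V[i - j] / math.factorial(j) * power
        V.append(acc)
    return math.factorial(k) * V[k]


_ORDERSTAT_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _orderstat_null(k: int, n_draws: int, seed: int) -> np.ndarray:
    """Sorted Monte-Carlo null of Q under k independent uniforms (cached)."""
    key = (k, n_draws, seed)
    if key not in _ORDERSTAT_NULL_CACHE:
        rng = np.random.default_rng(seed)
        draws = np.sort(rng.random((n_draws, k)), axis=1)
        _ORDERSTAT_NULL_CACHE[key] = np.sort(_orderstat_q(draws))
    return _ORDERSTAT_NULL_CACHE[key]


def combine(
    matrix: pd.DataFrame,
    method: str = "orderstat",
    *,
    pvalues: pd.DataFrame | None = None,
    n_null: int = 100_000,
    null_seed: int = 20_000_003,
) -> pd.Series:
    """Combine predictors into one score per gene.

    Direct methods take the affinity ``matrix``: ``sum`` adds affinities,
    ``max`` takes the largest, ``harmonic`` adds s_(i)/i^2 over scores sorted
    descending.  Meta methods take per-predictor p-values (computed from the
    matrix if not supplied) and return -log10 of the combined p: ``fisher``
    refers -2*sum(ln p) to chi-squared with 2k df; ``logistic`` refers a
    scaled -sum(ln(p/(1-p))) to Student t with 5k+4 df; ``orderstat``
    evaluates the joint cumulative of the sorted rank ratios and calibrates it
    against ``n_null`` seeded uniform-null draws.
    """
    if method not in COMBINE_METHODS:
        raise ValueError(f"unknown combination method {method!r}")
    if matrix.shape[1] == 0:
        raise ValueError("no informative predictor to combine")
    if method == "sum":
        return matrix.sum(axis=1).rename("combined_score")
    if method == "max":
        return matrix.max(axis=1).rename("combined_score")
    if method == "harmonic":
        values = np.sort(matrix.to_numpy(), axis=1)[:, ::-1]
        weights = 1.0 / np.arange(1, values.shape[1] + 1) ** 2
        return pd.Series(values @ weights, index=matrix.index, name="combined_score")
    P = affinity_to_pvalues(matrix) if pvalues is None else pvalues
    p = P.to_numpy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0,1]")
    k = p.shape[1]
    if method == "fisher":
        X = -2.0 * np.log(p).sum(axis=1)
        combined_p = stats.chi2.sf(X, df=2 * k)
    elif method == "logistic":
        pc = np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)
        L = -np.log(pc / (1.0 - pc)).sum(axis=1)
        scale = math.sqrt(3.0 * (5 * k + 4) / (k * math.pi**2 * (5 * k + 2)))
        combined_p = stats.t.sf(L * scale, df=5 * k + 4)
    else:  # orderstat
        Q = _orderstat_q(np.sort(p, axis=1))
        null = _orderstat_null(k, n_null, null_seed)
        counts = np.searchsorted(null, Q, side="right")
        combined_p = (1.0 + counts) / (1.0 + len(null))
    combined_p = np.clip(combined_p, np.finfo(float).tiny, 1.0)
    return pd.Series(-np.log10(combined_p), index=matrix.index, name="combined_score")


def rate(scores: pd.Series) -> pd.DataFrame:
    """Rescale combined scores to a 0-5 priority rating and rank the genes.

    Rank is by descending score with lexicographic gene tie-break; percentile
    is 100 * rank / N.  All-equal scores are an error (nothing to rank).
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 genes to rate")
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        raise ValueError("all combined scores are equal; rating undefined")
    table = pd.DataFrame({"gene": scores.index.astype(str), "combined_score": scores.to_numpy()})
    table["rating"] = 5.0 * (table["combined_score"] - lo) / (hi - lo)
    table = table.sort_values(
        ["combined_score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["percentile"] = 100.0 * table["rank"] / len(table)
    return table
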