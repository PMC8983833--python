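"""Rank-based target set enrichment and Fisher-exact over-representation.

``leading_enrichment`` asks whether a predefined gene set concentrates at the
top of the priority ranking.  A running score walks down the ranked list,
rising (weighted by rating^theta) at set members and falling uniformly at
non-members; the enrichment score (ES) is the signed extremum and the
"leading prioritization" is the subset of members at or before the positive
peak — the genes accounting for the signal.  Significance is by gene-label
permutation, with NES normalization and the standard NES-based FDR.

``fisher_ora`` is the one-sided hypergeometric over-representation test for a
thresholded gene list (e.g. the top 1% prioritized genes), with
Benjamini-Hochberg FDR across the collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "ranked_from_priority",
    "running_enrichment",
    "leading_enrichment",
    "fisher_ora",
]


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by descending rating, with per-gene weight rating^theta."""

    genes: tuple[str, ...]
    weights: np.ndarray
    theta: float = 1.0

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    pvalue: float
    fdr: float
    leading_genes: list[str] = field(default_factory=list)
    leading_fraction: float = 0.0
    n_overlap: int = 0


def ranked_from_priority(priority: pd.DataFrame, theta: float = 1.0) -> RankedList:
    """Build a RankedList from a priority table (gene/rating/rank columns)."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    ordered = priority.sort_values("rank")
    weights = np.power(ordered["rating"].to_numpy(dtype=float), theta)
    return RankedList(tuple(ordered["gene"]), weights, theta)


def running_enrichment(weights: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Running score P_hit(i) - P_miss(i) along the ranked list.

    P_hit accumulates member weights normalized by the total member weight
    (uniform over members if all member weights are zero); P_miss accumulates
    uniformly over non-members.
    """
    hits = hits.astype(bool)
    n = len(weights)
    n_hits = int(hits.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("hits must contain both members and non-members")
    w_hit = np.where(hits, weights, 0.0)
    total = w_hit.sum()
    if total == 0:
        w_hit = hits.astype(float)
        total = float(n_hits)
    p_hit = np.cumsum(w_hit) / total
    p_miss = np.cumsum(~hits) / (n - n_hits)
    return p_hit - p_miss


def _es_and_peak(running: np.ndarray) -> tuple[float, int]:
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def leading_enrichment(
    ranked: RankedList,
    sets: dict[str, set[str]],
    theta: float | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = 3,
) -> list[EnrichmentResult]:
    """GSEA-style enrichment of each gene set at the leading prioritization.

    Sets overlapping the ranked list in fewer than ``min_overlap`` genes are
    skipped (reported with NaN statistics).  Nominal p-values come from
    ``n_perm`` seeded permutations of gene labels; NES divides ES by the mean
    same-sign permuted |ES|, and FDR follows the standard pooled-NES
    procedure.
    """
    if theta is not None and theta != ranked.theta:
        raise ValueError("theta must match the RankedList weighting")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse", stacklevel=2)
    rng = np.random.default_rng(seed)
    genes = np.array(ranked.genes)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    results: list[EnrichmentResult] = []
    perm_nes_pool: list[np.ndarray] = []
    computed: list[int] = []
    for pos, (name, members) in enumerate(sorted(sets.items())):
        overlap = [index[g] for g in members if g in index]
        if len(overlap) < min_overlap or len(overlap) == n:
            results.append(
                EnrichmentResult(name, np.nan, np.nan, np.nan, np.nan, [], np.nan, len(overlap))
            )
            continue
        hits = np.zeros(n, dtype=bool)
        hits[overlap] = True
        running = running_enrichment(ranked.weights, hits)
        es, peak = _es_and_peak(running)
        leading: list[str] = []
        if es > 0:
            leading = [g for i, g in enumerate(genes) if hits[i] and i <= peak]
        # permutation null: random member positions of the same size
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            ph = np.zeros(n, dtype=bool)
            ph[rng.choice(n, size=len(overlap), replace=False)] = True
            perm_es[b], _ = _es_and_peak(running_enrichment(ranked.weights, ph))
        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_sign = int(same_sign.sum())
        if n_sign:
            exceed = int(np.sum(np.abs(perm_es[same_sign]) >= abs(es)))
            pvalue = (1 + exceed) / (1 + n_sign)
            denom = float(np.mean(np.abs(perm_es[same_sign])))
        else:
            pvalue = 1.0 / (1 + n_perm)
            denom = float(np.mean(np.abs(perm_es))) or 1.0
        nes = es / denom if denom > 0 else 0.0
        # normalize permuted ES the same way for the pooled FDR null
        pos_mean = np.mean(np.abs(perm_es[perm_es >= 0])) if (perm_es >= 0).any() else 1.0
        neg_mean = np.mean(np.abs(perm_es[perm_es < 0])) if (perm_es < 0).any() else 1.0
        perm_nes = np.where(perm_es >= 0, perm_es / pos_mean, perm_es / neg_mean)
        perm_nes_pool.append(perm_nes)
        computed.append(len(results))
        results.append(
            EnrichmentResult(
                name, es, nes, pvalue, np.nan, leading,
                len(leading) / len(overlap), len(overlap),
            )
        )

    if computed:
        pool = np.concatenate(perm_nes_pool)
        obs = np.array([results[i].nes for i in computed])
        for i in computed:
            nes = results[i].nes
            if nes >= 0:
                null_frac = np.mean(pool >= nes) if (pool >= 0).any() else 0.0
                obs_frac = np.mean(obs >= nes)
            else:
                null_frac = np.mean(pool <= nes) if (pool < 0).any() else 0.0
                obs_frac = np.mean(obs <= nes)
            results[i].fdr = float(min(1.0, null_frac / obs_frac)) if obs_frac > 0 else 1.0
    return results


def fisher_ora(
    top_genes: set[str],
    sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided Fisher-exact over-representation of ``top_genes`` in each set.

    The p-value is the hypergeometric upper tail P(X >= overlap) for the 2x2
    table over ``universe``; the odds ratio uses the Haldane half-count
    correction when a denominator cell is zero (overlap 0 gives OR = 0).
    Sets not intersecting the universe are skipped.  FDR is
    Benjamini-Hochberg across the tested sets.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not top_genes <= universe:
        raise ValueError("top_genes must be a subset of the universe")
    M, n_list = len(universe), len(top_genes)
    rows = []
    for name, members in sorted(sets.items()):
        set_u = members & universe
        if not set_u:
            continue
        a = len(top_genes & set_u)
        b = n_list - a
        c = len(set_u) - a
        d = M - len(set_u) - b
        pvalue = float(stats.hypergeom.sf(a - 1, M, len(set_u), n_list))
        if a == 0:
            odds = 0.0
        elif b == 0 or c == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append(
            {
                "set_name": name,
                "odds_ratio": odds,
                "pvalue": pvalue,
                "overlap": a,
                "set_size": len(set_u),
                "list_size": n_list,
                "universe_size": M,
            }
        )
    result = pd.DataFrame(rows)
    if not result.empty:
        result["fdr"] = multipletests(result["pvalue"], method="fdr_bh")[1]
    return result
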