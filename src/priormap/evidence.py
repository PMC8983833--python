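"""Per-predictor seed-gene scores from GWAS variants and regulatory links.

Three kinds of evidence connect a GWAS signal to a candidate gene:

* ``nGene`` — physical proximity: genes whose TSS lies within a window of an
  associated variant, scored with a distance decay;
* ``cGene`` — chromatin conformation: genes linked to a promoter-capture Hi-C
  fragment that an associated variant falls into;
* ``eGene`` — expression: genes whose expression the variant regulates (eQTL).

Each evidence kind yields one seed-score vector per dataset, later propagated
over the protein-interaction network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorConfig",
    "SeedScores",
    "select_lead_variants",
    "expand_by_ld",
    "score_seeds",
    "normalize_seeds",
]

#: -log10(p) values are capped here before rescaling to [0,1]
NEGLOG10_CAP = 12.0


@dataclass(frozen=True)
class PredictorConfig:
    """Tunable parameters for evidence scoring.

    p_threshold: genome-wide significance cutoff for lead variants.
    r2_min: minimum LD r-squared for a proxy variant to join a lead.
    ngene_window: window (bp) around a variant within which genes are "nearby".
    decay: distance decay for the proximity score, linear (1 - d/window) or
        exponential (exp(-3 d / window)), both restricted to the window.
    """

    p_threshold: float = 5e-8
    r2_min: float = 0.8
    ngene_window: int = 500_000
    decay: str = "linear"

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0,1)")
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must be in [0,1]")
        if self.ngene_window <= 0:
            raise ValueError("ngene_window must be positive")
        if self.decay not in ("linear", "exponential"):
            raise ValueError("decay must be 'linear' or 'exponential'")


@dataclass
class SeedScores:
    """Named per-gene seed scores for one predictor, values in [0, 1]."""

    name: str
    scores: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        if (self.scores < 0).any():
            raise ValueError("seed scores must be non-negative")


def select_lead_variants(variants: pd.DataFrame, cfg: PredictorConfig) -> pd.DataFrame:
    """Return exactly the variants with ``pvalue`` strictly below the threshold."""
    if variants.empty:
        raise ValueError("variant table is empty")
    leads = variants[variants["pvalue"] < cfg.p_threshold].copy()
    if leads.empty:
        warnings.warn(
            f"no variant below p_threshold={cfg.p_threshold:g}; downstream "
            "predictors will be absent",
            stacklevel=2,
        )
    return leads


def expand_by_ld(leads: pd.DataFrame, ld: pd.DataFrame, cfg: PredictorConfig) -> pd.Series:
    """Expand lead variants with LD proxies at r2 >= r2_min.

    Returns a Series mapping variant_id -> best (smallest) lead p-value among
    the leads it tags.  Leads map to their own p-value.
    """
    if leads.empty:
        raise ValueError("no lead variants to expand")
    best: dict[str, float] = dict(zip(leads["variant_id"], leads["pvalue"]))
    if not ld.empty:
        strong = ld[ld["r2"] >= cfg.r2_min]
        lead_p = dict(zip(leads["variant_id"], leads["pvalue"]))
        for a, b in strong[["variant_a", "variant_b"]].itertuples(index=False):
            for lead, proxy in ((a, b), (b, a)):
                if lead in lead_p:
                    p = lead_p[lead]
                    if proxy not in best or p < best[proxy]:
                        best[proxy] = p
    return pd.Series(best, name="best_lead_pvalue", dtype=float)


def _gwas_weight(pvalues: np.ndarray) -> np.ndarray:
    """min(-log10 p, cap) / cap — bounded GWAS significance weight in (0, 1]."""
    return np.minimum(-np.log10(pvalues), NEGLOG10_CAP) / NEGLOG10_CAP


def _variant_frame(variants: pd.DataFrame, variant_set: pd.Series) -> pd.DataFrame:
    """Rows of the variant table inside the expanded set, carrying best lead p."""
    sub = variants[variants["variant_id"].isin(variant_set.index)].copy()
    sub["lead_pvalue"] = sub["variant_id"].map(variant_set)
    return sub


def score_seeds(
    kind: str,
    variant_set: pd.Series,
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    links: pd.DataFrame | None,
    cfg: PredictorConfig,
    *,
    name: str | None = None,
) -> SeedScores:
    """Score seed genes for one evidence kind.

    Parameters
    ----------
    kind : {"nGene", "cGene", "eGene"}
    variant_set : Series variant_id -> best lead p-value (from expand_by_ld)
    variants : full variant table (for positions)
    genes : gene annotation (for TSS)
    links : HicLinkTable for cGene, EqtlTable for eGene, ignored for nGene
    name : predictor name, default = kind

    Scores are max-normalized to [0, 1]; genes with zero evidence are absent.
    """
    if variant_set.empty:
        raise ValueError("variant_set is empty")
    if kind == "nGene":
        raw = _score_ngene(variant_set, variants, genes, cfg)
    elif kind == "cGene":
        if links is None or "fragment_start" not in links.columns:
            raise ValueError("cGene scoring requires a Hi-C link table")
        raw = _score_cgene(variant_set, variants, links, cfg)
    elif kind == "eGene":
        if links is None or "eqtl_pvalue" not in links.columns:
            raise ValueError("eGene scoring requires an eQTL table")
        raw = _score_egene(variant_set, links)
    else:
        raise ValueError(f"unknown predictor kind {kind!r}")
    seeds = SeedScores(name or kind, raw)
    if seeds.scores.empty or not (seeds.scores > 0).any():
        return seeds
    return normalize_seeds(seeds)


def _score_ngene(
    variant_set: pd.Series, variants: pd.DataFrame, genes: pd.DataFrame, cfg: PredictorConfig
) -> pd.Series:
    sub = _variant_frame(variants, variant_set)
    scores: dict[str, float] = {}
    for chrom, chrom_variants in sub.groupby("chromosome"):
        chrom_genes = genes[genes["chromosome"] == chrom]
        if chrom_genes.empty:
            continue
        pos = chrom_variants["position"].to_numpy()
        weight = _gwas_weight(chrom_variants["lead_pvalue"].to_numpy())
        for gene, tss in zip(chrom_genes["gene"], chrom_genes["tss"]):
            dist = np.abs(pos - tss)
            inside = dist <= cfg.ngene_window
            if not inside.any():
                continue
            if cfg.decay == "linear":
                decay = 1.0 - dist[inside] / cfg.ngene_window
            else:
                decay = np.exp(-3.0 * dist[inside] / cfg.ngene_window)
            score = float(np.max(weight[inside] * decay))
            if score > 0:
                scores[gene] = score
    return pd.Series(scores, dtype=float)


def _score_cgene(
    variant_set: pd.Series, variants: pd.DataFrame, hic: pd.DataFrame, cfg: PredictorConfig
) -> pd.Series:
    sub = _variant_frame(variants, variant_set)
    max_link = hic["link_score"].max()
    rescale = max_link if max_link > 0 else 1.0
    scores: dict[str, float] = {}
    for chrom, frags in hic.groupby("fragment_chrom"):
        chrom_variants = sub[sub["chromosome"] == chrom]
        if chrom_variants.empty:
            continue
        # 1-based point -> 0-based before half-open interval comparison
        pos0 = chrom_variants["position"].to_numpy() - 1
        weight = _gwas_weight(chrom_variants["lead_pvalue"].to_numpy())
        for row in frags.itertuples(index=False):
            inside = (pos0 >= row.fragment_start) & (pos0 < row.fragment_end)
            if not inside.any():
                continue
            score = float(np.max(weight[inside]) * (row.link_score / rescale))
            if score > scores.get(row.gene, 0.0):
                scores[row.gene] = score
    return pd.Series(scores, dtype=float)


def _score_egene(variant_set: pd.Series, eqtl: pd.DataFrame) -> pd.Series:
    sub = eqtl[eqtl["variant_id"].isin(variant_set.index)]
    if sub.empty:
        return pd.Series(dtype=float)
    strength = np.minimum(-np.log10(sub["eqtl_pvalue"].to_numpy()), NEGLOG10_CAP) / NEGLOG10_CAP
    frame = pd.DataFrame({"gene": sub["gene"].to_numpy(), "score": strength})
    return frame.groupby("gene")["score"].max()


def normalize_seeds(seeds: SeedScores) -> SeedScores:
    """Rescale so the maximum seed score is 1, preserving order."""
    if seeds.scores.empty or not (seeds.scores > 0).any():
        raise ValueError(f"predictor {seeds.name!r} has no positive seed score")
    return SeedScores(seeds.name, seeds.scores / seeds.scores.max())
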