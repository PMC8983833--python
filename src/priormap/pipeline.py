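"""End-to-end prioritization: evidence -> propagation -> combination -> rating.

This is the orchestration layer the CLI and the benchmark runs share.  It
takes validated input tables, builds one seed-score predictor per evidence
dataset, propagates each over the network by random walk with restart,
filters predictors by random-forest importance against the proximity
baseline, combines the survivors and rescales to the 0-5 priority rating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import combine as comb
from . import evidence, propagation

logger = logging.getLogger(__name__)

__all__ = ["PrioritizationResult", "run_prioritization", "predictor_matrix_from_tables"]


@dataclass
class PrioritizationResult:
    matrix: pd.DataFrame  # genes x predictors affinities
    importances: comb.ImportanceTable | None
    informative: list[str]
    priority: pd.DataFrame  # gene / combined_score / rating / rank / percentile
    labels: comb.LabelSet | None = None
    seeds: dict = field(default_factory=dict)


def predictor_matrix_from_tables(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    ld: pd.DataFrame,
    hic: pd.DataFrame | None,
    eqtl: pd.DataFrame | None,
    network: nx.Graph,
    cfg: evidence.PredictorConfig,
    restart: float = 0.75,
) -> tuple[pd.DataFrame, dict[str, evidence.SeedScores]]:
    """Build the genes x predictors affinity matrix from raw inputs."""
    leads = evidence.select_lead_variants(variants, cfg)
    variant_set = evidence.expand_by_ld(leads, ld, cfg)
    seed_sets: dict[str, evidence.SeedScores] = {}
    seed_sets["nGene"] = evidence.score_seeds("nGene", variant_set, variants, genes, None, cfg)
    if hic is not None and not hic.empty:
        seed_sets["cGene"] = evidence.score_seeds("cGene", variant_set, variants, genes, hic, cfg)
    if eqtl is not None and not eqtl.empty:
        seed_sets["eGene"] = evidence.score_seeds("eGene", variant_set, variants, genes, eqtl, cfg)
    affinities = []
    for name, seeds in seed_sets.items():
        if not (seeds.scores > 0).any():
            logger.warning("predictor %s has no seeds; skipped", name)
            continue
        affinities.append(propagation.rwr(network, seeds, restart=restart))
    universe = sorted(network.nodes)
    matrix = propagation.build_predictor_matrix(affinities, universe)
    return matrix, seed_sets


def run_prioritization(
    tables: dict,
    cfg: evidence.PredictorConfig | None = None,
    *,
    method: str = "orderstat",
    restart: float = 0.75,
    control_ratio: int = 10,
    n_trees: int = 500,
    min_phase: int = 2,
    seed: int = 0,
    predictors: list[str] | None = None,
) -> PrioritizationResult:
    """Run the full prioritization on a dict of validated input tables.

    ``tables`` needs keys variants, genes, ld, hic, eqtl, network and
    (for importance filtering) drug_targets.  ``predictors`` restricts the
    affinity matrix to the named predictors, bypassing importance selection —
    used for single-evidence baselines.
    """
    cfg = cfg or evidence.PredictorConfig()
    matrix, seed_sets = predictor_matrix_from_tables(
        tables["variants"],
        tables["genes"],
        tables.get("ld", pd.DataFrame(columns=["variant_a", "variant_b", "r2"])),
        tables.get("hic"),
        tables.get("eqtl"),
        tables["network"],
        cfg,
        restart=restart,
    )
    labels = None
    importances = None
    if predictors is not None:
        informative = [p for p in predictors if p in matrix.columns]
        if not informative:
            raise ValueError(f"none of {predictors} present in the matrix")
    elif matrix.shape[1] >= 2 and "drug_targets" in tables:
        labels = comb.assemble_labels(
            tables["drug_targets"],
            list(matrix.index),
            control_ratio=control_ratio,
            seed=seed,
            min_phase=min_phase,
        )
        importances = comb.predictor_importance(matrix, labels, n_trees=n_trees, seed=seed)
        informative = comb.select_informative(importances)
    else:
        informative = list(matrix.columns)
    sub = matrix[informative]
    scores = comb.combine(sub, method)
    priority = comb.rate(scores)
    return PrioritizationResult(
        matrix=matrix,
        importances=importances,
        informative=informative,
        priority=priority,
        labels=labels,
        seeds=seed_sets,
    )
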