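"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator plants causal genes whose GWAS signal reaches them either
proximally (a genome-wide-significant lead variant near the TSS) or only
distally — through a promoter-capture Hi-C fragment or an eQTL record — so
that proximity evidence alone cannot recover them.  Around the signal it lays
down uniform-p background variants in LD blocks, decoy regulatory links, a
scale-free protein network with the planted genes rewired into one dense
module, and a drug-target table marking most planted genes (plus a few
decoys) as clinical-phase positives.  A companion generator emits the
genes x diseases rating matrix with shared-high and disease-specific blocks
used by the cross-disease map.

Every table passes the package's input validation, and a single seed fans out
to independent substreams per table so adding one table never perturbs the
others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FixtureSpec",
    "TruthSet",
    "generate_prioritization_fixture",
    "generate_rating_fixture",
    "generate_toy_graphs",
]

_GENE_SPACING = 50_000  # bp between successive TSS
_WINDOW = 500_000  # proximity window the fixture is built around


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the prioritization fixture."""

    seed: int = 0
    n_genes: int = 2000
    n_chromosomes: int = 4
    n_variants: int = 5000
    n_planted: int = 25
    frac_distal: float = 0.4
    ld_block_size: int = 10
    network_attachment: int = 3
    n_decoy_hic: int = 200
    n_decoy_eqtl: int = 200
    positive_fraction: float = 0.6  # planted genes marked as phase>=2 targets
    n_decoy_positives: int = 5

    def __post_init__(self) -> None:
        if self.n_planted >= self.n_genes:
            raise ValueError("n_planted must be below n_genes")
        if not 0 <= self.frac_distal <= 1:
            raise ValueError("frac_distal must be in [0,1]")
        for name in ("n_genes", "n_chromosomes", "n_variants", "ld_block_size",
                     "network_attachment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthSet:
    """Planted genes with their wiring labels, and rating-block memberships."""

    planted: dict[str, str] = field(default_factory=dict)  # gene -> wiring label
    shared_block: list[str] = field(default_factory=list)
    specific_block: list[str] = field(default_factory=list)
    specific_disease: str | None = None

    @property
    def planted_genes(self) -> set[str]:
        return set(self.planted)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_prioritization_fixture(spec: FixtureSpec) -> dict[str, object]:
    """Generate all prioritization inputs plus the truth labels.

    Returns a dict with keys genes, variants, ld, hic, eqtl, network,
    drug_targets, truth.  Deterministic given ``spec.seed``.
    """
    rng_gene, rng_var, rng_ld, rng_link, rng_net, rng_drug = _substreams(spec.seed, 6)

    per_chrom = int(np.ceil(spec.n_genes / spec.n_chromosomes))
    chrom_len = (per_chrom + 2) * _GENE_SPACING
    if chrom_len <= 2 * _WINDOW + 400_000:
        raise ValueError("chromosomes too short for the proximity window; increase n_genes")

    # --- gene annotation: TSS every ~50 kb with jitter ---------------------
    records = []
    g = 0
    for c in range(spec.n_chromosomes):
        for i in range(per_chrom):
            if g >= spec.n_genes:
                break
            tss = (i + 1) * _GENE_SPACING + int(rng_gene.integers(-10_000, 10_000))
            records.append(
                {
                    "gene": f"G{g:04d}",
                    "chromosome": f"chr{c + 1}",
                    "tss": max(1, tss),
                    "strand": "+" if rng_gene.random() < 0.5 else "-",
                }
            )
            g += 1
    genes = pd.DataFrame(records)

    # --- planted genes: spaced so no window captures another gene's lead ---
    spacing = max(1, spec.n_genes // spec.n_planted)
    candidates = genes.iloc[::spacing].head(spec.n_planted)
    # distal leads are placed toward the far chromosome end, so any TSS works
    planted_rows = list(candidates.itertuples(index=False))[: spec.n_planted]
    n_distal = int(round(spec.frac_distal * len(planted_rows)))
    labels = ["proximal"] * (len(planted_rows) - n_distal)
    labels += ["distal_hic"] * ((n_distal + 1) // 2) + ["distal_eqtl"] * (n_distal // 2)
    order = rng_gene.permutation(len(planted_rows))
    truth = TruthSet()
    planted_info = []  # (gene row, label)
    for pos, row in enumerate(planted_rows):
        label = labels[order[pos]]
        truth.planted[row.gene] = label
        planted_info.append((row, label))

    # --- variants: background uniform p in LD blocks, one lead per planted -
    variants = []
    vid = 0
    n_background = spec.n_variants - len(planted_info)
    for _ in range(n_background):
        c = int(rng_var.integers(0, spec.n_chromosomes))
        variants.append(
            {
                "variant_id": f"rs{vid:06d}",
                "chromosome": f"chr{c + 1}",
                "position": int(rng_var.integers(1, chrom_len)),
                "pvalue": float(rng_var.uniform(1e-4, 1.0)),
            }
        )
        vid += 1
    lead_records = {}
    for row, label in planted_info:
        p_lead = float(10.0 ** rng_var.uniform(-12, -8))
        if label == "proximal":
            offset = int(rng_var.integers(-_WINDOW // 2, _WINDOW // 2))
        else:
            side = 1 if row.tss < chrom_len // 2 else -1
            offset = side * (_WINDOW + int(rng_var.integers(200_000, 290_000)))
        position = min(max(1, row.tss + offset), chrom_len - 1)
        variant_id = f"rs{vid:06d}"
        variants.append(
            {
                "variant_id": variant_id,
                "chromosome": row.chromosome,
                "position": position,
                "pvalue": p_lead,
            }
        )
        lead_records[row.gene] = (variant_id, row.chromosome, position)
        vid += 1
    variant_table = pd.DataFrame(variants)

    # --- LD: blocks of consecutive background variants, high within-block --
    ld_rows = []
    lead_ids = {v for v, _, _ in lead_records.values()}
    background = variant_table[~variant_table["variant_id"].isin(lead_ids)]
    by_pos = background.sort_values(["chromosome", "position"]).reset_index(drop=True)
    for _, chrom_block in by_pos.groupby("chromosome"):
        ids = chrom_block["variant_id"].tolist()
        for start in range(0, len(ids), spec.ld_block_size):
            block = ids[start : start + spec.ld_block_size]
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    ld_rows.append(
                        {
                            "variant_a": block[i],
                            "variant_b": block[j],
                            "r2": float(rng_ld.uniform(0.8, 1.0)),
                        }
                    )
    ld_table = pd.DataFrame(ld_rows)

    # --- Hi-C and eQTL links: true distal wiring plus decoys ---------------
    hic_rows, eqtl_rows = [], []
    for row, label in planted_info:
        variant_id, chrom, position = lead_records[row.gene]
        if label == "distal_hic":
            hic_rows.append(
                {
                    "fragment_chrom": chrom,
                    "fragment_start": max(0, position - 2_500),
                    "fragment_end": position + 2_500,
                    "gene": row.gene,
                    "link_score": float(rng_link.uniform(5.0, 10.0)),
                }
            )
        elif label == "distal_eqtl":
            eqtl_rows.append(
                {
                    "variant_id": variant_id,
                    "gene": row.gene,
                    "eqtl_pvalue": float(10.0 ** rng_link.uniform(-10, -6)),
                }
            )
    all_genes = genes["gene"].tolist()
    background_ids = [v["variant_id"] for v in variants]
    for _ in range(spec.n_decoy_hic):
        c = int(rng_link.integers(0, spec.n_chromosomes))
        start = int(rng_link.integers(0, chrom_len - 5_000))
        hic_rows.append(
            {
                "fragment_chrom": f"chr{c + 1}",
                "fragment_start": start,
                "fragment_end": start + 5_000,
                "gene": all_genes[int(rng_link.integers(0, len(all_genes)))],
                "link_score": float(rng_link.uniform(0.1, 3.0)),
            }
        )
    for _ in range(spec.n_decoy_eqtl):
        eqtl_rows.append(
            {
                "variant_id": background_ids[int(rng_link.integers(0, n_background))],
                "gene": all_genes[int(rng_link.integers(0, len(all_genes)))],
                "eqtl_pvalue": float(rng_link.uniform(1e-4, 1.0)),
            }
        )
    hic_table = pd.DataFrame(hic_rows)
    eqtl_table = pd.DataFrame(eqtl_rows)

    # --- network: preferential attachment + dense planted module -----------
    ba_seed = int(rng_net.integers(0, 2**31 - 1))
    ba = nx.barabasi_albert_graph(spec.n_genes, spec.network_attachment, seed=ba_seed)
    network = nx.relabel_nodes(ba, {i: all_genes[i] for i in range(spec.n_genes)})
    planted_list = sorted(truth.planted)
    for i in range(len(planted_list)):
        for j in range(i + 1, len(planted_list)):
            if rng_net.random() < 0.3:
                network.add_edge(planted_list[i], planted_list[j])
    # guarantee the module is connected: chain the planted genes
    for i in range(len(planted_list) - 1):
        network.add_edge(planted_list[i], planted_list[i + 1])
    nx.set_edge_attributes(network, 1.0, "weight")

    # --- drug targets: most planted genes plus decoys at phase >= 2 --------
    n_pos = int(round(spec.positive_fraction * len(planted_list)))
    pos_genes = [planted_list[i] for i in rng_drug.permutation(len(planted_list))[:n_pos]]
    non_planted = [g for g in all_genes if g not in truth.planted]
    decoys = [
        non_planted[i]
        for i in rng_drug.choice(len(non_planted), spec.n_decoy_positives, replace=False)
    ]
    drug_rows = []
    for idx, gene in enumerate(pos_genes + decoys):
        for d in range(int(rng_drug.integers(1, 4))):
            drug_rows.append(
                {
                    "gene": gene,
                    "drug": f"DRUG{idx:03d}_{d}",
                    "max_phase": int(rng_drug.integers(2, 5)),
                    "mechanism": "inhibitor",
                    "indication": "synthetic",
                }
            )
    # some phase-1 noise rows that must not count as positives
    for idx in range(10):
        drug_rows.append(
            {
                "gene": non_planted[int(rng_drug.integers(0, len(non_planted)))],
                "drug": f"EARLY{idx:03d}",
                "max_phase": 1,
                "mechanism": "binder",
                "indication": "synthetic",
            }
        )
    drug_table = pd.DataFrame(drug_rows)

    return {
        "genes": genes,
        "variants": variant_table,
        "ld": ld_table,
        "hic": hic_table,
        "eqtl": eqtl_table,
        "network": network,
        "drug_targets": drug_table,
        "truth": truth,
    }


def generate_rating_fixture(
    seed: int = 0,
    n_genes: int = 689,
    diseases: tuple[str, ...] = ("END", "CRO", "UC", "MS", "RA", "SJO", "SLE"),
    n_shared: int = 80,
    n_specific: int = 80,
    high: float = 4.2,
    background: float = 1.2,
    noise: float = 0.4,
) -> tuple[pd.DataFrame, TruthSet]:
    """Genes x diseases rating matrix with planted blocks.

    A shared-high block is rated highly in every disease; a disease-specific
    block is rated highly only in the first disease; everything else is
    low-rating background noise.  Ratings are clipped to [0, 5].
    """
    if n_shared + n_specific > n_genes:
        raise ValueError("block sizes exceed n_genes")
    rng = np.random.default_rng(seed)
    names = [f"G{i:04d}" for i in range(n_genes)]
    X = background + noise * rng.standard_normal((n_genes, len(diseases)))
    shared = names[:n_shared]
    specific = names[n_shared : n_shared + n_specific]
    X[:n_shared, :] = high + noise * rng.standard_normal((n_shared, len(diseases)))
    X[n_shared : n_shared + n_specific, 0] = high + noise * rng.standard_normal(n_specific)
    matrix = pd.DataFrame(np.clip(X, 0.0, 5.0), index=names, columns=list(diseases))
    truth = TruthSet(shared_block=shared, specific_block=specific, specific_disease=diseases[0])
    return matrix, truth


def generate_toy_graphs() -> dict[str, nx.Graph]:
    """Small named graphs for crosstalk/attack tests.

    star: hub n0 with 4 leaves; path: 5 nodes in a line; cycle: 6 nodes;
    complete: K5; two_community: two K5s sharing the single bridge node "b".
    """
    star = nx.star_graph(4)
    path = nx.path_graph(5)
    cycle = nx.cycle_graph(6)
    complete = nx.complete_graph(5)
    two = nx.Graph()
    left = [f"l{i}" for i in range(4)] + ["b"]
    right = [f"r{i}" for i in range(4)] + ["b"]
    for group in (left, right):
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                two.add_edge(group[i], group[j])
    rename = lambda g, prefix: nx.relabel_nodes(g, {i: f"{prefix}{i}" for i in g.nodes})
    return {
        "star": rename(star, "n"),
        "path": rename(path, "n"),
        "cycle": rename(cycle, "n"),
        "complete": rename(complete, "n"),
        "two_community": two,
    }
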