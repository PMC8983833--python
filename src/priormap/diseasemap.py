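"""Cross-disease comparison of priority ratings.

A genes x diseases rating matrix is compared pairwise (Spearman correlation),
summarized as a self-organizing map on a supra-hexagonal lattice (a central
hexagon plus concentric rings, 1 + 3r(r-1) hexagons at radius r), partitioned
into topology-preserving clusters via the U-height landscape, and condensed
into a bootstrap consensus neighbor-joining tree of the diseases.

The SOM is trained in batch mode with a deterministic principal-plane
initialization, so the trained map depends only on the data and the schedule,
not on a random seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj
from statsmodels.stats.multitest import multipletests

from .enrichment import fisher_ora

__all__ = [
    "SupraLattice",
    "Codebook",
    "MapPartition",
    "ConsensusTree",
    "rating_correlations",
    "build_lattice",
    "train_som",
    "quantization_error",
    "partition_map",
    "assign_genes",
    "nj_tree",
    "consensus_nj",
    "cluster_enrichment",
]

_AXIAL_DIRECTIONS = [(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)]


@dataclass(frozen=True)
class SupraLattice:
    """Supra-hexagonal lattice: center plus ``radius - 1`` complete rings."""

    radius: int
    coords: tuple[tuple[int, int], ...]  # axial (q, r), center first then rings
    neighbors: tuple[tuple[int, ...], ...]

    def __len__(self) -> int:
        return len(self.coords)

    def lattice_distances(self) -> np.ndarray:
        """Pairwise hexagonal grid distances between all hexagons."""
        q = np.array([c[0] for c in self.coords])
        r = np.array([c[1] for c in self.coords])
        dq = q[:, None] - q[None, :]
        dr = r[:, None] - r[None, :]
        return (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) / 2.0

    def cartesian(self) -> np.ndarray:
        """Planar positions of the hexagon centers (pointy-top layout)."""
        q = np.array([c[0] for c in self.coords], dtype=float)
        r = np.array([c[1] for c in self.coords], dtype=float)
        return np.column_stack([q + r / 2.0, r * np.sqrt(3) / 2.0])


@dataclass
class Codebook:
    """One prototype vector per hexagon of the trained map."""

    lattice: SupraLattice
    vectors: np.ndarray  # (n_hexagons, n_diseases)
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.lattice), len(self.columns)):
            raise ValueError("codebook shape mismatch")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("codebook contains non-finite entries")


@dataclass(frozen=True)
class MapPartition:
    cluster_of: tuple[int, ...]  # hexagon index -> cluster id (0-based)
    n_clusters: int


@dataclass(frozen=True)
class ConsensusTree:
    newick: str
    supports: dict[frozenset, float]
    taxa: tuple[str, ...]


def rating_correlations(matrix: pd.DataFrame, reference_disease: str) -> pd.DataFrame:
    """Spearman correlation of the reference disease's ratings with every
    other disease, with Benjamini-Hochberg FDR across the comparisons."""
    if reference_disease not in matrix.columns:
        raise ValueError(f"reference disease {reference_disease!r} not in matrix")
    ref = matrix[reference_disease].to_numpy()
    if np.ptp(ref) == 0:
        raise ValueError(f"column {reference_disease!r} is constant")
    rows = []
    for other in matrix.columns:
        if other == reference_disease:
            continue
        col = matrix[other].to_numpy()
        if np.ptp(col) == 0:
            raise ValueError(f"column {other!r} is constant")
        rho, p = stats.spearmanr(ref, col)
        rows.append({"disease_a": reference_disease, "disease_b": other,
                     "spearman_rho": float(rho), "pvalue": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def build_lattice(radius: int) -> SupraLattice:
    """Build the supra-hexagonal lattice of ``1 + 3 * radius * (radius-1)``
    hexagons: the central hexagon plus ``radius - 1`` complete rings."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    coords: list[tuple[int, int]] = [(0, 0)]
    for k in range(1, radius):
        q, r = -k, k  # start of ring k, then walk the six sides
        for direction in _AXIAL_DIRECTIONS:
            for _ in range(k):
                coords.append((q, r))
                q, r = q + direction[0], r + direction[1]
    index = {c: i for i, c in enumerate(coords)}
    neighbors = []
    for q, r in coords:
        adj = [index[(q + dq, r + dr)] for dq, dr in _AXIAL_DIRECTIONS if (q + dq, r + dr) in index]
        neighbors.append(tuple(sorted(adj)))
    return SupraLattice(radius, tuple(coords), tuple(neighbors))


def _initial_codebook(X: np.ndarray, lattice: SupraLattice) -> np.ndarray:
    """Linear initialization on the plane of the top two principal axes."""
    mean = X.mean(axis=0)
    centered = X - mean
    pos = lattice.cartesian()
    span = np.maximum(np.abs(pos).max(axis=0), 1.0)
    unit = pos / span  # lattice plane normalized to [-1, 1] per axis
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = s / np.sqrt(max(len(X) - 1, 1))
    M = np.tile(mean, (len(lattice), 1))
    for axis in range(min(2, vt.shape[0])):
        M += np.outer(unit[:, axis], scale[axis] * vt[axis])
    return M


def train_som(
    matrix: pd.DataFrame,
    lattice: SupraLattice,
    epochs_rough: int = 50,
    epochs_fine: int = 100,
    seed: int = 0,
) -> Codebook:
    """Batch-train the supra-hexagonal map on the rating matrix.

    Each epoch assigns every gene to its best-matching hexagon (minimum
    Euclidean distance, ties to the lowest index) and replaces each prototype
    by the Gaussian-neighborhood-weighted mean of the assigned genes.  The
    neighborhood radius decays linearly from the lattice radius to 1 over the
    rough phase and from 1 to 0.5 over the fine phase.  Training is
    deterministic; ``seed`` is accepted for interface uniformity only.
    """
    if matrix.empty:
        raise ValueError("rating matrix is empty")
    X = matrix.to_numpy(dtype=float)
    if len(X) < len(lattice):
        import warnings

        warnings.warn(
            f"fewer genes ({len(X)}) than hexagons ({len(lattice)}); map will be sparse",
            stacklevel=2,
        )
    M = _initial_codebook(X, lattice)
    lat_d2 = lattice.lattice_distances() ** 2
    sigmas = np.concatenate(
        [
            np.linspace(float(lattice.radius), 1.0, max(epochs_rough, 1)),
            np.linspace(1.0, 0.5, max(epochs_fine, 1)),
        ]
    )
    H = len(lattice)
    for sigma in sigmas:
        bmu = np.argmin(cdist(X, M), axis=1)  # argmin takes the lowest index on ties
        weights = np.exp(-lat_d2 / (2.0 * sigma**2))  # (H, H) neighborhood kernel
        sums = np.zeros((H, X.shape[1]))
        counts = np.zeros(H)
        np.add.at(sums, bmu, X)
        np.add.at(counts, bmu, 1.0)
        numer = weights @ sums
        denom = weights @ counts
        update = denom > 0
        M[update] = numer[update] / denom[update, None]
    return Codebook(lattice, M, tuple(map(str, matrix.columns)))


def quantization_error(matrix: pd.DataFrame, codebook: Codebook) -> float:
    """Mean distance from each gene to its best-matching hexagon."""
    d = cdist(matrix.to_numpy(dtype=float), codebook.vectors)
    return float(d.min(axis=1).mean())


def partition_map(codebook: Codebook, n_clusters: int | None = None) -> MapPartition:
    """Partition the map into connected clusters on the U-height landscape.

    Each hexagon's U-height is the mean codebook distance to its lattice
    neighbors; hexagons walk by steepest descent to a local minimum (the
    cluster seed), which keeps every cluster a connected patch.  If
    ``n_clusters`` is given, adjacent clusters with the closest mean codebook
    vectors are merged until the count is met.
    """
    lattice = codebook.lattice
    H = len(lattice)
    u = np.array(
        [
            np.mean(
                [np.linalg.norm(codebook.vectors[i] - codebook.vectors[j]) for j in lattice.neighbors[i]]
            )
            if lattice.neighbors[i]
            else 0.0
            for i in range(H)
        ]
    )
    descend = np.arange(H)
    for i in range(H):
        best, best_u = i, u[i]
        for j in lattice.neighbors[i]:
            if u[j] < best_u - 1e-12:
                best, best_u = j, u[j]
        if best == i:
            # plateau: drain toward the lowest-index equal-height neighbor so
            # flat regions form one cluster (pointers strictly decrease index)
            for j in lattice.neighbors[i]:
                if j < i and abs(u[j] - u[i]) <= 1e-12:
                    best = j
                    break
        descend[i] = best
    # follow descent pointers to the seed (fixed point)
    seed_of = np.arange(H)
    for i in range(H):
        j = i
        while descend[j] != j:
            j = descend[j]
        seed_of[i] = j
    seeds = sorted(set(seed_of.tolist()))
    cluster_of = np.array([seeds.index(seed_of[i]) for i in range(H)])
    n = len(seeds)
    if n_clusters is not None and n_clusters >= 1:
        while n > n_clusters:
            means = np.array(
                [codebook.vectors[cluster_of == c].mean(axis=0) for c in range(n)]
            )
            adjacent = set()
            for i in range(H):
                for j in lattice.neighbors[i]:
                    a, b = cluster_of[i], cluster_of[j]
                    if a != b:
                        adjacent.add((min(a, b), max(a, b)))
            pair = min(adjacent, key=lambda ab: (np.linalg.norm(means[ab[0]] - means[ab[1]]), ab))
            keep, drop = pair
            cluster_of[cluster_of == drop] = keep
            cluster_of[cluster_of > drop] -= 1
            n -= 1
    return MapPartition(tuple(int(c) for c in cluster_of), n)


def assign_genes(
    matrix: pd.DataFrame, codebook: Codebook, partition: MapPartition
) -> pd.DataFrame:
    """Map each gene to its best-matching hexagon and that hexagon's cluster."""
    d = cdist(matrix.to_numpy(dtype=float), codebook.vectors)
    bmu = np.argmin(d, axis=1)
    return pd.DataFrame(
        {
            "gene": matrix.index.astype(str),
            "hexagon": bmu,
            "cluster": [partition.cluster_of[h] for h in bmu],
        }
    )


def _correlation_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Disease-by-disease distance 1 - Spearman rho over genes."""
    cols = list(matrix.columns)
    d = np.zeros((len(cols), len(cols)))
    X = matrix.to_numpy(dtype=float)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rho, _ = stats.spearmanr(X[:, i], X[:, j])
            if not np.isfinite(rho):
                rho = 0.0
            d[i, j] = d[j, i] = 1.0 - rho
    return pd.DataFrame(d, index=cols, columns=cols)


def nj_tree(distances: pd.DataFrame) -> TreeNode:
    """Neighbor-joining tree (Q-criterion agglomeration) from a distance matrix."""
    dm = DistanceMatrix(distances.to_numpy(dtype=float), ids=list(distances.columns))
    return nj(dm)


def _splits(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, keyed by the side not
    containing the lexicographically first taxon."""
    anchor = min(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


def consensus_nj(matrix: pd.DataFrame, n_boot: int = 100, seed: int = 0) -> ConsensusTree:
    """Bootstrap majority-rule consensus of neighbor-joining disease trees.

    The disease distance is 1 - Spearman rho over genes; bootstrap replicates
    resample genes with replacement.  Splits present in more than half the
    replicates enter the consensus with their bootstrap fraction as support.
    """
    diseases = tuple(map(str, matrix.columns))
    if len(diseases) < 3:
        raise ValueError("need at least 3 diseases")
    taxa = frozenset(diseases)
    if len(diseases) == 3:
        newick = "(" + ",".join(sorted(diseases)) + ");"
        return ConsensusTree(newick, {}, diseases)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    n = len(matrix)
    for _ in range(n_boot):
        sample = matrix.iloc[rng.integers(0, n, n)]
        tree = nj_tree(_correlation_distance(sample))
        for split in _splits(tree, taxa):
            counts[split] = counts.get(split, 0) + 1
    supports = {s: c / n_boot for s, c in counts.items() if c / n_boot > 0.5}
    newick = _consensus_newick(taxa, supports)
    return ConsensusTree(newick, supports, diseases)


def _consensus_newick(taxa: frozenset, supports: dict[frozenset, float]) -> str:
    """Build a rooted representation of the consensus: clusters are the
    majority splits (sides away from the anchor taxon), nested by inclusion."""
    anchor = min(taxa)
    clusters = sorted(supports, key=lambda s: (len(s), sorted(s)))

    def render(members: frozenset, inner: list[frozenset]) -> str:
        direct = [c for c in inner if not any(c < o for o in inner if o != c)]
        covered = frozenset().union(*direct) if direct else frozenset()
        parts = [
            render(c, [o for o in inner if o < c]) + f"{supports[c]:g}" for c in direct
        ]
        parts += sorted(members - covered)
        return "(" + ",".join(sorted(parts)) + ")"

    return render(taxa, clusters) + ";"


def cluster_enrichment(
    cluster_genes: set[str],
    annotations: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Fisher-exact over-representation of a map cluster's genes, with the
    universe fixed to the genes on the map."""
    return fisher_ora(cluster_genes & universe, annotations, universe)
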