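"""Random walk with restart (RWR) over the protein-interaction network.

Seed scores are spread over the network by iterating

    p  <-  (1 - r) * W p  +  r * p0

where ``W`` is the column-stochastic (degree-normalized) adjacency of the
undirected network and ``p0`` the seed vector normalized to sum 1.  The fixed
point is the affinity distribution: every gene receives a non-negative
affinity and the vector sums to one, so predictors are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .evidence import SeedScores

__all__ = ["AffinityVector", "transition_matrix", "rwr", "build_predictor_matrix"]


@dataclass
class AffinityVector:
    """Stationary RWR affinities for one predictor; entries sum to 1."""

    name: str
    affinities: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        self.affinities = self.affinities.astype(float)
        if len(self.affinities) and abs(self.affinities.sum() - 1.0) > 1e-10:
            raise ValueError("affinities must sum to 1")


def transition_matrix(network: nx.Graph, nodes: list[str] | None = None) -> sp.csr_matrix:
    """Column-stochastic transition operator of the (weighted) network.

    Every column sums to 1; isolated nodes get self-transition 1.
    """
    if nodes is None:
        nodes = sorted(network.nodes)
    adj = nx.to_scipy_sparse_array(network, nodelist=nodes, weight="weight", format="csc")
    adj = adj.astype(float)
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    isolated = col_sums == 0
    inv = np.where(isolated, 1.0, 1.0 / np.where(isolated, 1.0, col_sums))
    W = adj @ sp.diags(inv)
    if isolated.any():
        idx = np.flatnonzero(isolated)
        W = W.tolil()
        for i in idx:
            W[i, i] = 1.0
        W = W.tocsc()
    return sp.csr_matrix(W)


def rwr(
    network: nx.Graph,
    seeds: SeedScores,
    restart: float = 0.75,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> AffinityVector:
    """Propagate seed scores by random walk with restart.

    Seeds off the network are dropped (an error if none remain); the seed
    vector is renormalized to sum 1.  Iteration stops when the L1 change falls
    below ``tol``; non-convergence within ``max_iter`` raises.
    """
    if not 0 < restart <= 1:
        raise ValueError("restart must be in (0,1]")
    nodes = sorted(network.nodes)
    on_network = seeds.scores[seeds.scores.index.isin(nodes)]
    on_network = on_network[on_network > 0]
    if on_network.empty:
        dropped = sorted(seeds.scores.index)
        raise ValueError(
            f"no seed gene of predictor {seeds.name!r} is on the network; "
            f"dropped seeds: {dropped[:10]}"
        )
    index = {g: i for i, g in enumerate(nodes)}
    p0 = np.zeros(len(nodes))
    for gene, score in on_network.items():
        p0[index[gene]] = score
    p0 /= p0.sum()
    if restart == 1.0:
        return AffinityVector(seeds.name, pd.Series(p0, index=nodes))
    W = transition_matrix(network, nodes)
    p = p0.copy()
    for _ in range(max_iter):
        p_next = (1.0 - restart) * (W @ p) + restart * p0
        if np.abs(p_next - p).sum() < tol:
            p_next /= p_next.sum()  # guard drift at machine precision
            return AffinityVector(seeds.name, pd.Series(p_next, index=nodes))
        p = p_next
    raise RuntimeError(f"RWR did not converge within {max_iter} iterations (tol={tol:g})")


def build_predictor_matrix(
    affinities: list[AffinityVector], universe: list[str]
) -> pd.DataFrame:
    """Assemble affinity vectors into a genes x predictors matrix.

    Genes absent from a vector get 0; column order is fixed with ``nGene``
    first, remaining predictors in input order.  Duplicate names error.
    """
    if not affinities:
        raise ValueError("need at least one affinity vector")
    names = [a.name for a in affinities]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate predictor names in {names}")
    ordered = sorted(affinities, key=lambda a: (a.name != "nGene", names.index(a.name)))
    matrix = pd.DataFrame(0.0, index=list(universe), columns=[a.name for a in ordered])
    for vec in ordered:
        common = vec.affinities.index.intersection(matrix.index)
        matrix.loc[common, vec.name] = vec.affinities[common]
    return matrix
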