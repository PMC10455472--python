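"""Dimensions as Walktrap communities of the weighted network.

Communities of the regularized partial-correlation network play the role of
factors: each dense subgraph is one dimension.  The random walk runs on the
absolute edge weights (Walktrap requires non-negative weights; the signed
weights stay on the network object for reporting).  The dendrogram is cut
at the level maximizing weighted modularity, ties going to fewer
communities, and dimensions are numbered 1..K by the position of their
first item in the input label order so reports are stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .corr import LabeledCorrelationMatrix
from .glasso import EDGE_EPS, EstimationSettings, GgmNetwork, estimate_network

DEFAULT_STEPS = 4  # canonical Walktrap random-walk length


@dataclass(frozen=True)
class DimensionSolution:
    """Assignment of every item to one dimension (1-based, contiguous)."""

    labels: tuple[str, ...]
    membership: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.membership):
            raise ValueError("one membership entry per label required")
        ks = sorted(set(self.membership))
        if ks != list(range(1, len(ks) + 1)):
            raise ValueError(f"dimension indices must be contiguous from 1, got {ks}")
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(self, "membership", tuple(int(m) for m in self.membership))

    @property
    def n_dims(self) -> int:
        return max(self.membership)

    @property
    def assignment(self) -> dict[str, int]:
        return dict(zip(self.labels, self.membership))

    def items_in(self, dim: int) -> tuple[str, ...]:
        return tuple(l for l, m in zip(self.labels, self.membership) if m == dim)

    def item_sets(self) -> list[frozenset[str]]:
        """Item sets of dimensions 1..K, in index order."""
        return [frozenset(self.items_in(d)) for d in range(1, self.n_dims + 1)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"item": list(self.labels), "dimension": list(self.membership)})

    @classmethod
    def from_membership(cls, labels, raw_membership) -> "DimensionSolution":
        """Renumber an arbitrary labelling to 1-based first-occurrence order."""
        remap: dict[int, int] = {}
        out = []
        for m in raw_membership:
            if m not in remap:
                remap[m] = len(remap) + 1
            out.append(remap[m])
        return cls(tuple(labels), tuple(out))


def weighted_modularity(weights: np.ndarray, membership) -> float:
    """Newman's modularity Q for a weighted undirected graph.

    Q = (1/2m) sum_ij (w_ij - k_i k_j / 2m) delta(c_i, c_j), with w the
    non-negative weight matrix (zero diagonal) and k the weighted degrees.
    Returns 0 for an empty graph.
    """
    w = np.abs(np.asarray(weights, dtype=float))
    np.fill_diagonal(w, 0.0)
    two_m = w.sum()
    if two_m <= 0:
        return 0.0
    k = w.sum(axis=1)
    mem = np.asarray(list(membership))
    same = mem[:, None] == mem[None, :]
    return float(np.sum((w - np.outer(k, k) / two_m)[same]) / two_m)


def walktrap_dimensions(network: GgmNetwork, steps: int = DEFAULT_STEPS) -> DimensionSolution:
    """Walktrap communities of the absolute-weight graph.

    The merge level maximizing modularity is selected (ties toward fewer
    communities); isolated nodes become singleton dimensions, and a fully
    empty network yields all-singletons.
    """
    p = network.p
    if p == 0:
        raise ValueError("network has no nodes")
    w = np.abs(np.array(network.weights))
    w[w <= EDGE_EPS] = 0.0
    if w.sum() == 0:
        return DimensionSolution.from_membership(network.labels, range(p))
    g = ig.Graph.Weighted_Adjacency(w.tolist(), mode="undirected", attr="weight", loops=False)
    dendro = g.community_walktrap(weights="weight", steps=int(steps))
    # cut the dendrogram ourselves: max modularity, ties -> fewer communities
    n_merges = len(dendro.merges)
    best_mem: list[int] | None = None
    best_q = -np.inf
    for k in range(p - n_merges, p + 1):
        mem = dendro.as_clustering(k).membership
        q = weighted_modularity(w, mem)
        if q > best_q + 1e-12:
            best_q, best_mem = q, mem
    assert best_mem is not None
    return DimensionSolution.from_membership(network.labels, best_mem)


def ega(
    corr: LabeledCorrelationMatrix,
    settings: EstimationSettings | None = None,
    steps: int = DEFAULT_STEPS,
) -> tuple[GgmNetwork, DimensionSolution]:
    """One exploratory graph analysis: EBIC-selected graphical lasso
    network followed by Walktrap community detection.  This is the unit
    applied to the observed sample and to every bootstrap replicate."""
    network = estimate_network(corr, settings)
    return network, walktrap_dimensions(network, steps)
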