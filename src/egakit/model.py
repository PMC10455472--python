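"""The EGA model object: network estimation plus community detection.

Usage follows the fit-then-inspect pattern::

    model = EGA(corr)                      # or EGA.from_scores(df)
    res = model.fit()                      # EGAResults
    res.n_dims, res.solution.assignment
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import DEFAULT_STEPS, DimensionSolution, walktrap_dimensions
from .corr import LabeledCorrelationMatrix
from .glasso import EstimationSettings, GgmNetwork, estimate_network


class EGA:
    """Exploratory graph analysis of one labeled correlation matrix.

    Parameters
    ----------
    corr : LabeledCorrelationMatrix
        Observed correlations with a known sample size n.
    settings : EstimationSettings, optional
        Penalty-path and EBIC hyperparameters (gamma defaults to 0.50).
    steps : int
        Walktrap random-walk length (default 4).
    """

    def __init__(
        self,
        corr: LabeledCorrelationMatrix,
        settings: EstimationSettings | None = None,
        steps: int = DEFAULT_STEPS,
    ):
        self.corr = corr
        self.settings = settings or EstimationSettings()
        self.steps = steps

    @classmethod
    def from_scores(cls, scores, labels=None, **kwargs) -> "EGA":
        """Build from an n x p raw-score array or DataFrame."""
        return cls(LabeledCorrelationMatrix.from_scores(scores, labels), **kwargs)

    @classmethod
    def from_csv(cls, path, n: int, **kwargs) -> "EGA":
        """Build from a correlation CSV (label header + leading label column)."""
        return cls(LabeledCorrelationMatrix.from_csv(path, n=n), **kwargs)

    def fit(self) -> "EGAResults":
        network = estimate_network(self.corr, self.settings)
        solution = walktrap_dimensions(network, self.steps)
        return EGAResults(model=self, network=network, solution=solution)


@dataclass(frozen=True)
class EGAResults:
    """Selected network and its dimension solution."""

    model: EGA
    network: GgmNetwork
    solution: DimensionSolution

    @property
    def n_dims(self) -> int:
        return self.solution.n_dims

    def summary(self) -> str:
        net, sol = self.network, self.solution
        lines = []
        lines.append("Exploratory Graph Analysis")
        lines.append("=" * 52)
        lines.append(f"items: {net.p}   n: {self.model.corr.n}   "
                     f"edges: {net.edge_count}")
        lines.append(f"selected lambda: {net.lam:.4f}   gamma: {net.gamma:.2f}   "
                     f"EBIC: {net.ebic:.2f}")
        lines.append(f"dimensions: {sol.n_dims}")
        for d in range(1, sol.n_dims + 1):
            lines.append(f"  dim{d}: {', '.join(sol.items_in(d))}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_dims": self.n_dims,
            "assignment": self.solution.assignment,
            "lambda": self.network.lam,
            "gamma": self.network.gamma,
            "ebic": self.network.ebic,
            "edge_count": self.network.edge_count,
        }

    def plot(self, ax=None, layout_seed: int = 0):
        """Draw the network with nodes colored by dimension.

        Edge width is proportional to the absolute partial correlation;
        solid edges are positive, dashed negative.
        """
        import matplotlib.pyplot as plt
        import networkx as nx

        net, sol = self.network, self.solution
        g = nx.Graph()
        g.add_nodes_from(net.labels)
        for _, row in net.edge_list().iterrows():
            g.add_edge(row.node_a, row.node_b, weight=float(row.weight))
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        pos = nx.spring_layout(g, seed=layout_seed, weight=None)
        cmap = plt.get_cmap("tab10")
        colors = [cmap((sol.assignment[v] - 1) % 10) for v in g.nodes]
        nx.draw_networkx_nodes(g, pos, node_color=colors, ax=ax, node_size=600)
        nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
        for u, v, data in g.edges(data=True):
            w = data["weight"]
            nx.draw_networkx_edges(
                g, pos, edgelist=[(u, v)], ax=ax,
                width=1 + 6 * abs(w),
                style="solid" if w >= 0 else "dashed",
                alpha=min(1.0, 0.25 + 2 * abs(w)),
            )
        ax.set_axis_off()
        return ax
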