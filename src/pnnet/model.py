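"""Model/Results interface over the network-estimation pipeline.

``PartialCorrelationNetwork`` is built from a per-patient variable panel
and ``fit()`` runs the full pipeline -- listwise complete-case
selection, nonparanormal transformation, sample covariance, targeted
ridge precision estimation (with cross-validated penalty selection when
none is given), conversion to partial correlations, and absolute
thresholding -- returning a ``NetworkResults`` that carries the
estimates and exposes the graph-level summaries (centrality indices,
edge-betweenness communities, a seeded force-directed layout, plotting,
and a text summary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import ggm, metrics, preprocess
from .variables import DISPLAY_LABELS, validate_panel

__all__ = ["PartialCorrelationNetwork", "NetworkResults"]


class PartialCorrelationNetwork:
    """Gaussian-copula partial-correlation network model of a variable panel.

    Parameters
    ----------
    panel : DataFrame
        One row per patient.  Must contain the 12 analysis columns
        (symptom scores, biomarkers, covariates); other columns are
        ignored.  Missing values are allowed and handled listwise.
    npn : bool
        Apply the nonparanormal (rank-Gaussian) transform before
        covariance estimation (default True).

    Examples
    --------
    >>> from pnnet import synthetic
    >>> from pnnet.model import PartialCorrelationNetwork
    >>> panel = synthetic.sample_cohort(500, seed=1).panel
    >>> res = PartialCorrelationNetwork(panel).fit(seed=1)
    >>> res.graph.number_of_edges() > 0
    True
    """

    def __init__(self, panel: pd.DataFrame, npn: bool = True):
        self.raw_panel = panel
        self.npn = npn
        self.panel = preprocess.listwise_complete(validate_panel(panel))
        if len(self.panel) < 2:
            raise ValueError("fewer than two complete cases")
        self.n_dropped = len(panel) - len(self.panel)

    @classmethod
    def from_dataframe(cls, panel: pd.DataFrame, **kwargs) -> "PartialCorrelationNetwork":
        return cls(panel, **kwargs)

    def fit(
        self,
        penalty: float | None = None,
        penalty_grid=None,
        cv_folds: int = 5,
        cutoff: float = 0.1,
        target="scaled-identity",
        seed: int = 0,
    ) -> "NetworkResults":
        """Estimate the thresholded partial-correlation network.

        When ``penalty`` is None it is selected by ``cv_folds``-fold
        cross-validated held-out Gaussian log-likelihood over
        ``penalty_grid`` (default log-spaced 1e-4..1e2), with seeded fold
        assignment.  ``cutoff`` is the inclusive absolute
        partial-correlation threshold for an edge.
        """
        transformed = preprocess.npn_transform(self.panel) if self.npn else self.panel
        S = ggm.sample_covariance(transformed)
        if penalty is None:
            penalty = ggm.select_penalty(
                transformed, grid=penalty_grid, k=cv_folds, seed=seed, target=target
            )
        precision = ggm.ridge_precision(S, penalty, target=target)
        pcor = ggm.precision_to_pcor(precision)
        graph = ggm.sparsify_threshold(pcor, cutoff=cutoff, names=S.names)
        return NetworkResults(
            model=self,
            covariance=S,
            precision=precision,
            pcor=pd.DataFrame(pcor, index=list(S.names), columns=list(S.names)),
            graph=graph,
            penalty=float(penalty),
            cutoff=float(cutoff),
        )


@dataclass
class NetworkResults:
    """Fitted partial-correlation network and its graph-level summaries."""

    model: PartialCorrelationNetwork
    covariance: ggm.CovarianceEstimate
    precision: ggm.PrecisionEstimate
    pcor: pd.DataFrame
    graph: nx.Graph
    penalty: float
    cutoff: float
    _centrality: pd.DataFrame | None = field(default=None, repr=False)
    _communities: metrics.CommunityPartition | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.covariance.n

    @property
    def edges(self) -> pd.DataFrame:
        """Surviving edges with signed weights, strongest first."""
        rows = [
            {"source": a, "target": b, "weight": d["weight"], "sign": d["sign"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        out = pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])
        return out.reindex(out["weight"].abs().sort_values(ascending=False).index).reset_index(drop=True)

    def centrality(self) -> pd.DataFrame:
        if self._centrality is None:
            self._centrality = metrics.centrality_indices(self.graph)
        return self._centrality

    def communities(self) -> metrics.CommunityPartition:
        if self._communities is None:
            self._communities = metrics.girvan_newman_communities(self.graph)
        return self._communities

    def layout(self, seed: int = 0, iterations: int = 50) -> dict:
        return metrics.fruchterman_reingold_layout(self.graph, seed=seed, iterations=iterations)

    def plot(self, ax=None, seed: int = 0):
        """Draw the network: solid edges positive, dashed negative."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        pos = self.layout(seed=seed)
        role_color = {"symptom": "#9467bd", "biomarker": "#ff9896", "covariate": "#98df8a"}
        colors = [role_color.get(self.graph.nodes[v].get("role"), "#cccccc") for v in self.graph.nodes]
        styles = ["solid" if d["sign"] > 0 else "dashed" for _, _, d in self.graph.edges(data=True)]
        widths = [6.0 * abs(d["weight"]) for _, _, d in self.graph.edges(data=True)]
        nx.draw_networkx_nodes(self.graph, pos, ax=ax, node_color=colors, node_size=900)
        nx.draw_networkx_edges(self.graph, pos, ax=ax, style=styles, width=widths)
        nx.draw_networkx_labels(
            self.graph, pos, ax=ax,
            labels={v: DISPLAY_LABELS.get(v, v) for v in self.graph.nodes},
            font_size=7,
        )
        ax.set_axis_off()
        return ax

    def summary(self) -> str:
        """Human-readable fit summary with the centrality table."""
        cent = self.centrality().copy()
        cent.index = [DISPLAY_LABELS.get(v, v) for v in cent.index]
        cent["betweenness"] = cent["betweenness"].round(2)
        cent["closeness"] = cent["closeness"].round(3)
        comm = self.communities()
        lines = [
            "Partial-correlation network (targeted ridge, nonparanormal input)",
            "=" * 66,
            f"complete cases: {self.n}   (dropped {self.model.n_dropped} incomplete)",
            f"penalty lambda: {self.penalty:.6g}   target: scaled identity",
            f"edge threshold: |pcor| >= {self.cutoff}",
            f"edges: {self.graph.number_of_edges()}   "
            f"negative: {sum(1 for _, _, d in self.graph.edges(data=True) if d['sign'] < 0)}",
            "",
            "Centrality indices (unweighted graph)",
            "-" * 66,
            cent.to_string(),
            "",
            f"Communities (edge betweenness, modularity {comm.modularity:.3f}):",
        ]
        for i, members in enumerate(comm.communities, 1):
            names = ", ".join(sorted(DISPLAY_LABELS.get(v, v) for v in members))
            lines.append(f"  cluster {i}: {names}")
        return "\n".join(lines)
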