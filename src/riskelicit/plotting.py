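"""Aggregation graphs and the bipartite risk network.

The aggregation graph — a step plot of the agreement function with the
crisp summary statistics marked — is the method's main communication
device: experts and stakeholders can read off where the panel agrees,
how strongly, and how the headline likelihood was extracted.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx

from .agreement import AgreementFunction
from .intervals import ElicitationError
from .risk import RiskReport, PAIR_SEP
from .summary import summarize

__all__ = ["plot_agreement", "plot_risk_network"]


def plot_agreement(
    af: AgreementFunction,
    path: str | Path | None = None,
    title: str | None = None,
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Step plot of agreement level vs likelihood with summary markers.

    Vertical markers show the min-max, centroid and max-max statistics.
    Deterministic for a given function.
    """
    if af.is_empty:
        raise ElicitationError("cannot plot an identically-zero agreement function")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))

    stats = summarize(af, title or "item")
    b = af.breakpoints
    xs = [0.0, b[0]]
    ys = [0.0, 0.0]
    for j in range(b.size - 1):
        level = float(af.levels[j])
        xs.extend([b[j], b[j + 1]])
        ys.extend([level, level])
    xs.extend([b[-1], 1.0])
    ys.extend([0.0, 0.0])
    ax.plot(xs, ys, drawstyle="steps-post", color="0.2", lw=1.5)
    ax.scatter(b, af.point_levels, s=12, color="0.2", zorder=3)

    for name, value, colour in (
        ("min-max", stats.min_max, "tab:blue"),
        ("centroid", stats.centroid, "tab:green"),
        ("max-max", stats.max_max, "tab:red"),
    ):
        ax.axvline(value, color=colour, ls="--", lw=1, label=f"{name} = {value:.3g}")

    ax.set_xlim(0, 1)
    ax.set_ylim(bottom=0)
    ax.set_xlabel("likelihood of management target failure")
    ax.set_ylabel("agreement level")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)

    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_risk_network(
    report: RiskReport,
    path: str | Path | None = None,
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Bipartite factor → element graph, edge width ∝ headline likelihood.

    Pairs at or below the headline threshold are not drawn, mirroring
    how screened-out combinations are omitted from the report.
    """
    edges = [
        (s.item_id.split(PAIR_SEP, 1)[0], s.item_id.split(PAIR_SEP, 1)[1], s.headline)
        for s in report.per_item
        if s.headline > report.headline_threshold
    ]
    if not edges:
        raise ElicitationError("no pairs exceed the headline threshold; nothing to plot")

    graph = nx.Graph()
    factors = sorted({f for f, _, _ in edges})
    elements = sorted({e for _, e, _ in edges})
    graph.add_nodes_from(factors, bipartite=0)
    graph.add_nodes_from(elements, bipartite=1)
    for f, e, w in edges:
        graph.add_edge(f, e, weight=w)

    span = float(max(len(factors), len(elements)) - 1) or 1.0

    def _column(names: list[str], x: float) -> dict[str, tuple[float, float]]:
        step = span / (len(names) - 1) if len(names) > 1 else 0.0
        offset = (span - step * (len(names) - 1)) / 2.0
        return {n: (x, -(offset + i * step)) for i, n in enumerate(names)}

    pos = {**_column(factors, 0.0), **_column(elements, 1.0)}

    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(3, 0.4 * max(len(factors), len(elements)))))
    widths = [6.0 * graph[f][e]["weight"] for f, e in graph.edges]
    nx.draw_networkx_edges(graph, pos, ax=ax, width=widths, edge_color="0.1")
    nx.draw_networkx_nodes(
        graph, pos, nodelist=factors, node_shape="s", node_color="0.85",
        node_size=900, ax=ax,
    )
    nx.draw_networkx_nodes(
        graph, pos, nodelist=elements, node_shape="o", node_color="white",
        edgecolors="0.3", node_size=900, ax=ax,
    )
    nx.draw_networkx_labels(graph, pos, font_size=7, ax=ax)
    ax.set_axis_off()
    ax.set_title(
        f"risk factors → affected elements "
        f"({report.headline_statistic}, {report.variant} estimates)"
    )

    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
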