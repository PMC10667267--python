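"""PPI graph construction, centralities, and key-target filtering.

The potential targets are screened topologically on their protein-protein
interaction network: a target is a *key target* when its degree, normalized
betweenness centrality and normalized closeness centrality all reach the
cutoffs (defaults 4 / 0.01 / 0.5, inclusive).

Centrality conventions follow the NetworkAnalyzer tool the cutoffs were
designed for: betweenness is Brandes' statistic divided by (n-1)(n-2)/2 with
n the full graph's node count (isolated nodes included); closeness is
component-local, (|component|-1) / (sum of distances to co-component nodes),
so the 0.01 and 0.5 cutoffs live on [0, 1] scales. A flag switches closeness
to the Wasserman-Faust globally-rescaled variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from .target_sets import TargetSet, normalize_symbol

__all__ = [
    "InteractionGraph",
    "CentralityReport",
    "build_graph",
    "centralities",
    "filter_key_targets",
    "subgraph",
]

DEGREE_MIN_DEFAULT = 4
BETWEENNESS_MIN_DEFAULT = 0.01
CLOSENESS_MIN_DEFAULT = 0.5


@dataclass
class InteractionGraph:
    """A simple undirected graph of gene symbols (thin wrapper over networkx)."""

    graph: nx.Graph

    @property
    def nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> List[Tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class CentralityReport:
    """Per-node degree, normalized betweenness, normalized closeness."""

    degree: Dict[str, int]
    betweenness: Dict[str, float]
    closeness: Dict[str, float]

    def row(self, node: str) -> Tuple[int, float, float]:
        return (self.degree[node], self.betweenness[node], self.closeness[node])


def build_graph(
    edge_rows: Iterable[Sequence],
    restrict_to: Optional[TargetSet] = None,
    score_min: Optional[float] = None,
) -> InteractionGraph:
    """Build a simple undirected graph from 2- or 3-column edge rows.

    Self-loops are dropped and duplicate/reversed pairs collapse. A third
    column is a confidence score and rows below ``score_min`` are skipped.
    With ``restrict_to``, only edges with both endpoints in the set are kept
    and set members absent from any kept edge remain as degree-0 nodes.
    """
    g = nx.Graph()
    keep = {normalize_symbol(x) for x in restrict_to.genes} if restrict_to is not None else None
    if keep is not None:
        g.add_nodes_from(sorted(keep))
    for lineno, row in enumerate(edge_rows, start=1):
        if row is None or len(row) < 2 or not str(row[0]).strip() or not str(row[1]).strip():
            raise ValueError(f"edge row {lineno}: expected two gene symbols, got {row!r}")
        a, b = normalize_symbol(str(row[0])), normalize_symbol(str(row[1]))
        if len(row) >= 3 and score_min is not None and float(row[2]) < score_min:
            continue
        if a == b:
            continue
        if keep is not None and (a not in keep or b not in keep):
            continue
        g.add_edge(a, b)
    return InteractionGraph(g)


def centralities(ig: InteractionGraph, wf_closeness: bool = False) -> CentralityReport:
    """Degree, normalized betweenness, and closeness for every node.

    Betweenness uses Brandes' algorithm normalized by (n-1)(n-2)/2 over the
    whole graph. Closeness is component-local by default (degree-0 nodes get
    0); ``wf_closeness=True`` applies the Wasserman-Faust rescaling by
    (|component|-1)/(n-1) instead.
    """
    g = ig.graph
    deg = dict(g.degree())
    if g.number_of_nodes() == 0:
        return CentralityReport({}, {}, {})
    bc = nx.betweenness_centrality(g, normalized=True)
    cc = nx.closeness_centrality(g, wf_improved=wf_closeness)
    return CentralityReport(deg, bc, cc)


def filter_key_targets(
    ig: InteractionGraph,
    report: Optional[CentralityReport] = None,
    deg_min: int = DEGREE_MIN_DEFAULT,
    bc_min: float = BETWEENNESS_MIN_DEFAULT,
    cc_min: float = CLOSENESS_MIN_DEFAULT,
) -> TargetSet:
    """Nodes meeting all three inclusive cutoffs (degree, betweenness, closeness).

    With all cutoffs at 0 this returns every node, isolated ones included
    (their closeness of 0 satisfies cc_min = 0).
    """
    if deg_min < 0 or bc_min < 0 or cc_min < 0:
        raise ValueError("centrality thresholds must be non-negative")
    if report is None:
        report = centralities(ig)
    missing = set(ig.graph.nodes) - set(report.degree)
    if missing:
        raise ValueError(f"centrality report missing nodes: {sorted(missing)}")
    keep = {
        n
        for n in ig.graph.nodes
        if report.degree[n] >= deg_min
        and report.betweenness[n] >= bc_min
        and report.closeness[n] >= cc_min
    }
    return TargetSet("key_targets", keep, provenance=f"degree>={deg_min}, bc>={bc_min}, cc>={cc_min}")


def subgraph(ig: InteractionGraph, keep: TargetSet) -> InteractionGraph:
    """Induced subgraph on ``keep``; centralities must be recomputed on it."""
    unknown = keep.genes - set(ig.graph.nodes)
    if unknown:
        raise KeyError(f"nodes not in graph: {sorted(unknown)}")
    return InteractionGraph(nx.Graph(ig.graph.subgraph(keep.genes).copy()))
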