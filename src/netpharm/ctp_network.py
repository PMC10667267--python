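"""The integrated compound - key target - pathway (C-T-P) tripartite network.

Compounds connect to the key targets they are predicted to hit; key targets
connect to the enriched pathways whose overlap genes contain them. No direct
compound-pathway or intra-layer edges exist: a compound relates to a pathway
only transitively through a shared key target. Node degree in this network
summarizes multi-layer connectivity — a target hit by c compounds and
appearing in p pathway overlaps has degree c + p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentRow
from .target_sets import CompoundTargetMap, TargetSet

__all__ = ["TripartiteNetwork", "build_ctp", "degree_table", "to_graphml"]

LAYERS = ("compound", "target", "pathway")


@dataclass
class TripartiteNetwork:
    compound_nodes: List[str]
    target_nodes: List[str]
    pathway_nodes: List[str]
    ct_edges: Set[Tuple[str, str]]
    tp_edges: Set[Tuple[str, str]]

    @property
    def node_degree(self) -> Dict[str, int]:
        deg = {n: 0 for n in self.compound_nodes + self.target_nodes + self.pathway_nodes}
        for a, b in list(self.ct_edges) + list(self.tp_edges):
            deg[a] += 1
            deg[b] += 1
        return deg

    @property
    def isolated_nodes(self) -> List[str]:
        return sorted(n for n, d in self.node_degree.items() if d == 0)

    @property
    def n_edges(self) -> int:
        return len(self.ct_edges) + len(self.tp_edges)

    def layer_of(self, node: str) -> str:
        for layer, pool in zip(LAYERS, (self.compound_nodes, self.target_nodes, self.pathway_nodes)):
            if node in pool:
                return layer
        raise KeyError(node)


def build_ctp(
    eac: Sequence[str],
    key: TargetSet,
    pathways: Sequence[EnrichmentRow],
    m: CompoundTargetMap,
    restrict_to_key: bool = True,
) -> TripartiteNetwork:
    """Merge the EAC roster, key targets, and enriched pathways into one network.

    Compound-target edges are the prediction map restricted to EAC x key
    targets (``restrict_to_key=False`` widens to all mapped targets that
    appear in some pathway or in the key set). Target-pathway edges link each
    pathway to its overlap genes within the key set. Compounds and pathways
    left without edges are retained as isolated nodes (see
    ``isolated_nodes``) so the roster is preserved for reporting.
    """
    eac = list(dict.fromkeys(eac))  # preserve order, drop accidental duplicates
    key_genes = set(key.genes)
    ct = {(c, g) for c, g in m.pairs if c in set(eac) and (g in key_genes or not restrict_to_key)}
    tp = set()
    for row in pathways:
        for g in row.overlap_genes & key_genes:
            tp.add((g, row.term_id))
    target_nodes = sorted(key_genes | ({g for _, g in ct} if not restrict_to_key else set()))
    net = TripartiteNetwork(
        compound_nodes=list(eac),
        target_nodes=target_nodes,
        pathway_nodes=[row.term_id for row in pathways],
        ct_edges=ct,
        tp_edges=tp,
    )
    orphans = [
        t for t in net.target_nodes
        if all(g != t for _, g in ct) and all(g != t for g, _ in tp)
    ]
    if orphans:
        warnings.warn(
            f"key target(s) {orphans} absent from every pathway overlap and compound map",
            stacklevel=2,
        )
    return net


def degree_table(net: TripartiteNetwork) -> pd.DataFrame:
    """(node, layer, degree), sorted by layer then descending degree then node."""
    deg = net.node_degree
    rows = [(n, net.layer_of(n), deg[n]) for n in deg]
    df = pd.DataFrame(rows, columns=["node", "layer", "degree"])
    df["layer"] = pd.Categorical(df["layer"], categories=list(LAYERS), ordered=True)
    return df.sort_values(
        ["layer", "degree", "node"], ascending=[True, False, True], ignore_index=True
    )


def to_graphml(net: TripartiteNetwork, path) -> None:
    """Write GraphML with layer and degree node attributes, byte-stable ordering."""
    g = nx.Graph()
    deg = net.node_degree
    for pool, layer in zip(
        (net.compound_nodes, net.target_nodes, net.pathway_nodes), LAYERS
    ):
        for n in sorted(pool):
            g.add_node(n, layer=layer, degree=deg[n])
    for a, b in sorted(net.ct_edges) + sorted(net.tp_edges):
        g.add_edge(a, b)
    nx.write_graphml(g, path)
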