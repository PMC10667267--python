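"""Over-representation analysis of a gene list against annotation collections.

Given a query gene set (the key targets) and a collection of annotation terms
(GO biological processes, KEGG pathways) over a background universe, each
term's overlap with the query is scored with the hypergeometric upper tail

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n)

or with the more conservative EASE variant, which penalizes the overlap by
one gene before taking the tail (so single-gene overlaps are never
significant). Terms are ranked by ascending p, ties broken by descending
overlap then term id, and the top-k retained — the tabular form of the
enrichment bubble chart (gene ratio k/n on one axis, p as color, k as size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .target_sets import TargetSet, normalize_symbol

__all__ = [
    "AnnotationCollection",
    "EnrichmentRow",
    "hypergeom_upper_tail",
    "ease_p",
    "bh_adjust",
    "enrich",
]

TOP_K_DEFAULT = 20


@dataclass
class AnnotationCollection:
    """term_id -> (term_name, category, member genes), plus the background universe.

    The default universe is the union of all term members (annotation-based
    background); pass ``universe`` to override.
    """

    terms: Dict[str, Tuple[str, str, Set[str]]]
    universe: Optional[Set[str]] = None

    def __post_init__(self) -> None:
        clean: Dict[str, Tuple[str, str, Set[str]]] = {}
        for tid, (name, cat, members) in self.terms.items():
            members = {normalize_symbol(g) for g in members}
            if not members:
                raise ValueError(f"term {tid!r} has no members")
            clean[tid] = (name, cat, members)
        self.terms = clean
        if self.universe is None:
            self.universe = set().union(*(m for _, _, m in self.terms.values()))
        else:
            self.universe = {normalize_symbol(g) for g in self.universe}
        for tid, (_, _, members) in self.terms.items():
            if not members <= self.universe:
                raise ValueError(f"term {tid!r} has members outside the universe")


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    category: str
    k: int  # overlap size
    n: int  # query size (within universe)
    K: int  # term size
    N: int  # universe size
    overlap_genes: Set[str]
    p_value: float
    p_adjusted: float = field(default=float("nan"))

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and 0 < n <= N and 0 < K <= N):
        raise ValueError(f"inconsistent hypergeometric counts k={k}, n={n}, K={K}, N={N}")


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated in log space.

    k = overlap, n = query size, K = term size, N = universe size. k = 0
    covers the whole distribution, so p = 1.
    """
    _check_counts(k, n, K, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ease_p(k: int, n: int, K: int, N: int) -> float:
    """The EASE score: the hypergeometric upper tail with the overlap reduced by one.

    Always >= the plain hypergeometric p; k <= 1 gives 1.0 exactly.
    """
    _check_counts(k, n, K, N)
    return hypergeom_upper_tail(max(k - 1, 0), n, K, N)


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in stats.false_discovery_control(p, method="bh")]


_STATISTICS = {"hypergeom": hypergeom_upper_tail, "ease": ease_p}


def enrich(
    query: TargetSet,
    coll: AnnotationCollection,
    stat: str = "ease",
    top_k: Optional[int] = TOP_K_DEFAULT,
) -> List[EnrichmentRow]:
    """Rank annotation terms by over-representation of the query genes.

    Only terms overlapping the query (k >= 1) are scored; BH adjustment is
    computed across all scored terms before truncation to ``top_k``
    (``None`` keeps everything). Ordering: ascending p, then descending k,
    then term_id — fully deterministic.
    """
    if stat not in _STATISTICS:
        raise ValueError(f"unknown statistic {stat!r}; choose from {sorted(_STATISTICS)}")
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    pfun = _STATISTICS[stat]
    q = query.genes & coll.universe
    if not q:
        raise ValueError(
            "query has no genes in the annotation universe; "
            "check symbol conventions or supply a matching universe"
        )
    n, N = len(q), len(coll.universe)
    rows: List[EnrichmentRow] = []
    for tid, (name, cat, members) in coll.terms.items():
        overlap = q & members
        if not overlap:
            continue
        k, K = len(overlap), len(members)
        rows.append(
            EnrichmentRow(tid, name, cat, k, n, K, N, overlap, pfun(k, n, K, N))
        )
    adjusted = bh_adjust([r.p_value for r in rows])
    for r, adj in zip(rows, adjusted):
        r.p_adjusted = adj
    rows.sort(key=lambda r: (r.p_value, -r.k, r.term_id))
    return rows if top_k is None else rows[:top_k]
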