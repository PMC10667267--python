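"""Gene target sets: compound-predicted targets vs disease-associated genes.

Compound target predictions and disease gene lists come from different
sources with inconsistent casing and whitespace; symbols are normalized to
uppercase HGNC-style strings on ingest (no alias resolution is attempted).
The potential targets of a compound library against a disease are the
intersection of the union of per-compound predicted targets with the
disease-associated set, summarized as Venn counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

__all__ = [
    "TargetSet",
    "CompoundTargetMap",
    "normalize_symbol",
    "union_targets",
    "intersect",
    "venn_counts",
]


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol; empty results are an error."""
    s = symbol.strip().upper()
    if not s or any(c.isspace() for c in s):
        raise ValueError(f"invalid gene symbol {symbol!r}")
    return s


@dataclass
class TargetSet:
    """A named set of uppercase gene symbols with provenance."""

    label: str
    genes: Set[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.genes = {normalize_symbol(g) for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: str) -> bool:
        return normalize_symbol(g) in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))


@dataclass
class CompoundTargetMap:
    """Deduplicated (compound_id, gene) pairs, optionally score-filtered.

    ``scores`` carries a prediction probability/score per pair when the
    source table provides one; ``filter_scores`` drops low-confidence pairs
    (the stand-in for removing "false-positive" predictions).
    """

    pairs: Set[Tuple[str, str]]
    scores: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = {(cid, normalize_symbol(g)) for cid, g in self.pairs}
        self.scores = {(cid, normalize_symbol(g)): s for (cid, g), s in self.scores.items()}

    @property
    def compound_ids(self) -> FrozenSet[str]:
        return frozenset(cid for cid, _ in self.pairs)

    def targets_of(self, compound_id: str) -> Set[str]:
        if compound_id not in self.compound_ids:
            raise KeyError(f"unknown compound_id {compound_id!r}")
        return {g for cid, g in self.pairs if cid == compound_id}

    def filter_scores(self, min_score: float = 0.0) -> "CompoundTargetMap":
        """Keep pairs with score >= min_score; unscored pairs are kept."""
        kept = {p for p in self.pairs if self.scores.get(p, float("inf")) >= min_score}
        return CompoundTargetMap(kept, {p: s for p, s in self.scores.items() if p in kept})


def union_targets(m: CompoundTargetMap, compounds: Optional[Iterable[str]] = None) -> TargetSet:
    """Deduplicated union of predicted targets over the listed compounds.

    ``compounds`` defaults to every compound in the map; unknown ids raise.
    """
    if compounds is None:
        wanted = set(m.compound_ids)
    else:
        wanted = set(compounds)
        unknown = wanted - set(m.compound_ids)
        if unknown:
            raise KeyError(f"unknown compound_id(s): {sorted(unknown)}")
    genes = {g for cid, g in m.pairs if cid in wanted}
    return TargetSet("predicted_targets", genes, provenance=f"union over {len(wanted)} compounds")


def intersect(a: TargetSet, b: TargetSet) -> TargetSet:
    """The potential targets: genes common to both sets (commutative).

    An empty intersection is a valid result and only warns.
    """
    common = a.genes & b.genes
    if not common:
        warnings.warn(
            f"intersection of {a.label!r} and {b.label!r} is empty", stacklevel=2
        )
    return TargetSet(
        "potential_targets", common, provenance=f"{a.label} ∩ {b.label}"
    )


def venn_counts(a: TargetSet, b: TargetSet) -> Tuple[int, int, int]:
    """(|a only|, |b only|, |a ∩ b|) — the two-set Venn diagram counts."""
    inter = len(a.genes & b.genes)
    return (len(a.genes) - inter, len(b.genes) - inter, inter)
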