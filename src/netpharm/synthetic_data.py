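"""Synthetic inputs with planted, recoverable structure for every pipeline stage.

The screening pipeline normally consumes tables exported from live web
databases (descriptor tables, target predictions, disease gene lists,
interactome edges, pathway annotations). This module generates all five
inputs with *known ground truth* so that each stage's selection step can be
checked for exact recovery:

* a 43-compound descriptor table in which each compound is drug-like
  (passes QED >= 0.3 and Veber) or not *by construction*, with the planted
  pass fraction defaulting to 28/43;
* a compound->target map and a disease gene set whose intersection is
  exactly a planted set of 24 genes;
* an interactome over the potential targets in which 9 planted hubs — and
  only they — survive the topological filter (degree >= 4, betweenness
  >= 0.01, closeness >= 0.5), enforced by verify-and-resample;
* a pathway collection with one planted over-represented term covering most
  of the key targets, against a sparse random background.

Everything is driven by one integer seed through independent, fixed-order
child streams, so outputs are byte-reproducible and adding a new
sub-generator never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .enrichment import AnnotationCollection
from .ppi_topology import build_graph, centralities, filter_key_targets
from .screening import CompoundRecord, DescriptorSet, screen_compounds
from .target_sets import CompoundTargetMap, TargetSet

__all__ = [
    "GeneratorConfig",
    "SyntheticBundle",
    "gen_compounds",
    "gen_target_layers",
    "gen_interactome",
    "gen_annotations",
    "generate_bundle",
]

MAX_RETRIES = 50


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study. Defaults mirror the screening study's scale:

    43 isolates with a 28/43 expected pass fraction, a 3000-gene universe,
    265 disease genes sharing 24 with the predicted-target pool, a 24-node
    interactome with 9 planted hubs, and 66 candidate pathways with one
    planted over-represented term.
    """

    seed: int = 0
    n_compounds: int = 43
    frac_druglike: float = 28 / 43
    universe_size: int = 3000
    n_disease_genes: int = 265
    n_overlap: int = 24
    n_hubs: int = 9
    hub_edge_prob: float = 0.95
    background_edge_prob: float = 0.03
    n_pathways: int = 66
    planted_term_coverage: float = 0.8
    compound_target_rate: int = 25
    predicted_pool_size: int = 600
    qed_mode: str = "mean"
    qed_cutoff: float = 0.3

    def __post_init__(self) -> None:
        for name in ("frac_druglike", "hub_edge_prob", "background_edge_prob",
                     "planted_term_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hub_edge_prob <= self.background_edge_prob:
            raise ValueError("hub_edge_prob must exceed background_edge_prob")
        if self.n_overlap > self.n_disease_genes:
            raise ValueError("n_overlap cannot exceed n_disease_genes")
        if self.n_overlap > self.predicted_pool_size:
            raise ValueError("n_overlap cannot exceed the predicted-target pool")
        if self.predicted_pool_size + (self.n_disease_genes - self.n_overlap) > self.universe_size:
            raise ValueError("universe too small for the requested pool and disease set")

    def streams(self, n: int = 4) -> List[np.random.Generator]:
        """Fixed-order independent child streams: compounds, targets, ppi, pathways."""
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


@dataclass
class SyntheticBundle:
    """All five pipeline inputs plus the planted ground truth."""

    compounds: List[CompoundRecord]
    target_map: CompoundTargetMap
    disease: TargetSet
    ppi_edges: List[Tuple[str, str]]
    annotations: AnnotationCollection
    truth: Dict[str, object]


def _sample_druglike(rng: np.random.Generator) -> DescriptorSet:
    return DescriptorSet(
        mw=float(rng.uniform(250, 450)),
        alogp=float(rng.uniform(1.0, 3.5)),
        hba=int(rng.integers(2, 8)),
        hbd=int(rng.integers(0, 4)),
        tpsa=float(rng.uniform(40, 120)),
        rotb=int(rng.integers(0, 9)),
        arom=int(rng.integers(1, 4)),
        alerts=0,
    )


def _sample_non_druglike(rng: np.random.Generator) -> DescriptorSet:
    # two violation styles: fail Veber outright, or stay Veber-passing but
    # score badly on every QED desirability
    if rng.random() < 0.5:
        base = _sample_druglike(rng)
        if rng.random() < 0.5:
            return DescriptorSet(base.mw, base.alogp, base.hba, base.hbd,
                                 base.tpsa, int(rng.integers(11, 21)), base.arom, base.alerts)
        return DescriptorSet(base.mw, base.alogp, base.hba, base.hbd,
                             float(rng.uniform(141, 250)), base.rotb, base.arom, base.alerts)
    return DescriptorSet(
        mw=float(rng.uniform(650, 900)),
        alogp=float(rng.uniform(5.5, 8.0)),
        hba=int(rng.integers(10, 15)),
        hbd=int(rng.integers(5, 9)),
        tpsa=float(rng.uniform(120, 139)),
        rotb=int(rng.integers(9, 11)),
        arom=int(rng.integers(4, 6)),
        alerts=int(rng.integers(3, 6)),
    )


def gen_compounds(cfg: GeneratorConfig, rng: np.random.Generator | None = None
                  ) -> Tuple[List[CompoundRecord], List[str]]:
    """A descriptor table stratified by intended screening verdict.

    Each compound is drug-like with probability ``frac_druglike``; its
    descriptors are drawn from the corresponding stratum and the realized
    verdict is verified with the actual screen (bounded resampling within
    the stratum), so the returned planted-EAC id list is exact ground truth.
    Returns (screened records, planted EAC compound ids).
    """
    rng = rng if rng is not None else cfg.streams()[0]
    records: List[CompoundRecord] = []
    planted: List[str] = []
    for i in range(cfg.n_compounds):
        cid = f"CMP{i + 1:03d}"
        want_pass = bool(rng.random() < cfg.frac_druglike)
        sampler = _sample_druglike if want_pass else _sample_non_druglike
        for attempt in range(MAX_RETRIES + 1):
            desc = sampler(rng)
            rec = screen_compounds(
                [CompoundRecord(cid, f"synthetic-{cid}", desc)],
                qed_cutoff=cfg.qed_cutoff, qed_mode=cfg.qed_mode,
            )[0]
            if rec.is_eac == want_pass:
                break
        else:  # pragma: no cover - strata are built to satisfy their verdicts
            raise RuntimeError(
                f"could not realize verdict {want_pass} for {cid} in {MAX_RETRIES} draws"
            )
        records.append(rec)
        if want_pass:
            planted.append(cid)
    return records, planted


def _gene_universe(cfg: GeneratorConfig) -> List[str]:
    width = len(str(cfg.universe_size))
    return [f"G{i:0{width}d}" for i in range(1, cfg.universe_size + 1)]


def gen_target_layers(
    cfg: GeneratorConfig,
    eac_ids: Sequence[str],
    all_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> Tuple[CompoundTargetMap, TargetSet, Set[str]]:
    """A compound->target map and disease set with an exactly planted overlap.

    Compound targets are drawn from a designated predicted pool; the disease
    set contains ``n_overlap`` genes from that pool (each also planted into
    at least one EAC compound's target list) plus genes sampled strictly
    outside the pool, so ``union(EAC targets) ∩ disease`` equals the planted
    set exactly. Returns (map, disease set, planted overlap genes).
    """
    if not eac_ids:
        raise ValueError("need at least one EAC compound to plant the overlap")
    rng = rng if rng is not None else cfg.streams()[1]
    universe = _gene_universe(cfg)
    pool = list(rng.choice(universe, size=cfg.predicted_pool_size, replace=False))
    planted = set(rng.choice(pool, size=cfg.n_overlap, replace=False))

    pairs: Set[Tuple[str, str]] = set()
    ids = list(all_ids) if all_ids is not None else list(eac_ids)
    for cid in ids:
        k = min(cfg.compound_target_rate, len(pool))
        for g in rng.choice(pool, size=k, replace=False):
            pairs.add((cid, str(g)))
    # guarantee every planted gene is predicted for at least one EAC compound
    eac = list(eac_ids)
    for g in sorted(planted):
        pairs.add((str(rng.choice(eac)), g))

    outside = [g for g in universe if g not in set(pool)]
    n_extra = cfg.n_disease_genes - cfg.n_overlap
    disease_genes = planted | {str(g) for g in rng.choice(outside, size=n_extra, replace=False)}
    disease = TargetSet("disease_genes", disease_genes, provenance="synthetic")
    return CompoundTargetMap(pairs), disease, planted


def gen_interactome(
    cfg: GeneratorConfig,
    potential: TargetSet,
    rng: np.random.Generator | None = None,
) -> Tuple[List[Tuple[str, str]], Set[str]]:
    """Edge rows over the potential targets with a planted hub module.

    ``n_hubs`` nodes form a dense near-clique (pairwise ``hub_edge_prob``);
    every satellite gets one spoke to a random hub plus sparse background
    edges. The draw is accepted only if the topological filter at its default
    cutoffs recovers exactly the hubs; otherwise it resamples (bounded),
    since the cutoffs are global graph properties no local rule guarantees.
    Returns (edge rows, hub genes).
    """
    if cfg.n_hubs > len(potential):
        raise ValueError("n_hubs exceeds the number of potential targets")
    rng = rng if rng is not None else cfg.streams()[2]
    nodes = sorted(potential.genes)
    last_margin = ""
    for attempt in range(MAX_RETRIES):
        hubs = {str(h) for h in rng.choice(nodes, size=cfg.n_hubs, replace=False)}
        hub_list = sorted(hubs)
        satellites = [n for n in nodes if n not in hubs]
        edges: Set[Tuple[str, str]] = set()
        for i, a in enumerate(hub_list):
            for b in hub_list[i + 1:]:
                if rng.random() < cfg.hub_edge_prob:
                    edges.add((a, b))
        for s in satellites:
            edges.add(tuple(sorted((s, str(rng.choice(hub_list))))))
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if a in hubs and b in hubs:
                    continue
                if rng.random() < cfg.background_edge_prob:
                    edges.add((a, b))
        rows = sorted(edges)
        g = build_graph(rows, restrict_to=potential)
        recovered = filter_key_targets(g, centralities(g)).genes
        if recovered == hubs:
            return rows, hubs
        last_margin = (f"attempt {attempt + 1}: recovered {len(recovered)} nodes, "
                       f"planted {cfg.n_hubs}; symmetric diff {sorted(recovered ^ hubs)}")
    raise RuntimeError(
        f"planted hub separation not achieved in {MAX_RETRIES} draws ({last_margin})"
    )


def gen_annotations(
    cfg: GeneratorConfig,
    key: TargetSet,
    category: str = "KEGG",
    rng: np.random.Generator | None = None,
) -> Tuple[AnnotationCollection, str]:
    """A term collection with one planted over-represented pathway.

    The planted term contains ``ceil(coverage * |key|)`` key genes plus
    random background members; the other terms draw members uniformly from
    the universe, hitting key genes only at the background rate. Returns
    (collection, planted term id).
    """
    n_cover = math.ceil(cfg.planted_term_coverage * len(key))
    if n_cover < 2:
        raise ValueError("planted_term_coverage * |key| must be at least 2")
    rng = rng if rng is not None else cfg.streams()[3]
    universe = set(_gene_universe(cfg)) | set(key.genes)
    background = sorted(universe - set(key.genes))

    terms: Dict[str, Tuple[str, str, Set[str]]] = {}
    planted_id = f"{category}:PLANTED"
    covered = {str(g) for g in rng.choice(sorted(key.genes), size=n_cover, replace=False)}
    filler = {str(g) for g in rng.choice(background, size=int(rng.integers(20, 60)), replace=False)}
    terms[planted_id] = (f"{category} planted pathway", category, covered | filler)
    for j in range(1, cfg.n_pathways):
        size = int(rng.integers(10, 80))
        members = {str(g) for g in rng.choice(sorted(universe), size=size, replace=False)}
        terms[f"{category}:{j:04d}"] = (f"{category} pathway {j}", category, members)
    return AnnotationCollection(terms, universe=universe), planted_id


def generate_bundle(cfg: GeneratorConfig) -> SyntheticBundle:
    """Generate all pipeline inputs and the ground truth in one fixed-order pass."""
    r_cmp, r_tgt, r_ppi, r_ann = cfg.streams(4)
    compounds, planted_eac = gen_compounds(cfg, r_cmp)
    all_ids = [c.compound_id for c in compounds]
    target_map, disease, planted_overlap = gen_target_layers(cfg, planted_eac, all_ids, r_tgt)
    potential = TargetSet("potential_targets", planted_overlap, provenance="synthetic truth")
    ppi_edges, hubs = gen_interactome(cfg, potential, r_ppi)
    key = TargetSet("key_targets", hubs, provenance="synthetic truth")
    annotations, planted_term = gen_annotations(cfg, key, rng=r_ann)
    truth = {
        "eac_ids": sorted(planted_eac),
        "overlap_genes": sorted(planted_overlap),
        "hub_genes": sorted(hubs),
        "planted_term": planted_term,
    }
    return SyntheticBundle(compounds, target_map, disease, list(ppi_edges), annotations, truth)
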