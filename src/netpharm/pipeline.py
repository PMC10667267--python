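"""End-to-end orchestration: screen -> intersect -> PPI -> enrich -> C-T-P.

``run_pipeline`` executes the five analysis stages in order on file inputs,
writes each stage's table, and records a manifest (config echo, input
checksums, stage row counts, output checksums, package version). Stage
outputs are pure functions of (inputs, config), so re-running on identical
inputs reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .ctp_network import build_ctp, degree_table, to_graphml
from .enrichment import TOP_K_DEFAULT, enrich
from .io import (
    read_compounds,
    read_edge_list,
    read_gene_list,
    read_gmt,
    read_target_map,
    write_compounds,
    write_enrichment,
    write_gene_list,
    write_node_attributes,
)
from .ppi_topology import (
    BETWEENNESS_MIN_DEFAULT,
    CLOSENESS_MIN_DEFAULT,
    DEGREE_MIN_DEFAULT,
    build_graph,
    centralities,
    filter_key_targets,
    subgraph,
)
from .screening import QED_CUTOFF_DEFAULT, screen_compounds, select_eac
from .target_sets import intersect, union_targets, venn_counts

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths of the five inputs plus the screening/filter/enrichment cutoffs.

    Defaults are the screening study's published cutoffs: QED >= 0.3,
    degree/betweenness/closeness >= 4/0.01/0.5, top 20 terms by p-value.
    """

    compounds: str
    target_map: str
    disease_genes: str
    ppi_edges: str
    annotations: str
    out_dir: str = "netpharm_out"
    qed_cutoff: float = QED_CUTOFF_DEFAULT
    qed_mode: str = "mean"
    score_min: float = 0.0
    deg_min: int = DEGREE_MIN_DEFAULT
    bc_min: float = BETWEENNESS_MIN_DEFAULT
    cc_min: float = CLOSENESS_MIN_DEFAULT
    stat: str = "ease"
    top_k: int = TOP_K_DEFAULT
    ppi_score_min: Optional[float] = None
    seed: Optional[int] = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def input_paths(self) -> Dict[str, str]:
        return {
            "compounds": self.compounds,
            "target_map": self.target_map,
            "disease_genes": self.disease_genes,
            "ppi_edges": self.ppi_edges,
            "annotations": self.annotations,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_stage = {"compounds": "screen", "target_map": "intersect",
                   "disease_genes": "intersect", "ppi_edges": "ppi",
                   "annotations": "enrich"}
    for name, p in cfg.input_paths().items():
        if not Path(p).exists():
            raise PipelineError(input_stage[name], FileNotFoundError(p))

    manifest: dict = {
        "tool": "netpharm",
        "version": __version__,
        "config": asdict(cfg),
        "inputs": {k: {"path": v, "sha256": _sha256(Path(v))}
                   for k, v in cfg.input_paths().items()},
        "stages": {},
        "complete": False,
    }

    def _finish_stage(name: str, counts: dict) -> None:
        manifest["stages"][name] = counts

    try:
        stage = "screen"
        records = screen_compounds(read_compounds(cfg.compounds),
                                   qed_cutoff=cfg.qed_cutoff, qed_mode=cfg.qed_mode)
        eac = select_eac(records, qed_cutoff=cfg.qed_cutoff)
        write_compounds(records, out / "screened_compounds.tsv")
        _finish_stage(stage, {"compounds": len(records), "eac": len(eac)})

        stage = "intersect"
        tmap = read_target_map(cfg.target_map).filter_scores(cfg.score_min)
        predicted = union_targets(tmap, [r.compound_id for r in eac
                                         if r.compound_id in tmap.compound_ids])
        disease = read_gene_list(cfg.disease_genes, label="disease_genes")
        potential = intersect(predicted, disease)
        a_only, b_only, inter = venn_counts(predicted, disease)
        write_gene_list(potential, out / "potential_targets.txt")
        (out / "venn_counts.json").write_text(json.dumps(
            {"predicted_only": a_only, "disease_only": b_only, "intersection": inter},
            indent=2) + "\n")
        _finish_stage(stage, {"predicted": len(predicted), "disease": len(disease),
                              "potential": len(potential)})

        stage = "ppi"
        rows = read_edge_list(cfg.ppi_edges)
        graph = build_graph(rows, restrict_to=potential, score_min=cfg.ppi_score_min)
        report = centralities(graph)
        key = filter_key_targets(graph, report, cfg.deg_min, cfg.bc_min, cfg.cc_min)
        key_graph = subgraph(graph, key)
        write_node_attributes(graph, report, key, out / "ppi_nodes.tsv")
        write_gene_list(key, out / "key_targets.txt")
        _finish_stage(stage, {"nodes": graph.n_nodes, "edges": graph.n_edges,
                              "key_targets": len(key),
                              "key_nodes": key_graph.n_nodes,
                              "key_edges": key_graph.n_edges})

        stage = "enrich"
        coll = read_gmt(cfg.annotations)
        enriched = enrich(key, coll, stat=cfg.stat, top_k=cfg.top_k)
        write_enrichment(enriched, out / "enrichment.tsv")
        _finish_stage(stage, {"terms_tested": len(coll.terms), "reported": len(enriched)})

        stage = "ctp"
        net = build_ctp([r.compound_id for r in eac], key, enriched, tmap)
        to_graphml(net, out / "ctp_network.graphml")
        degree_table(net).to_csv(out / "ctp_degrees.tsv", sep="\t", index=False)
        _finish_stage(stage, {"compounds": len(net.compound_nodes),
                              "targets": len(net.target_nodes),
                              "pathways": len(net.pathway_nodes),
                              "edges": net.n_edges,
                              "isolated": len(net.isolated_nodes)})
    except PipelineError:
        manifest["stages"].setdefault(stage, {})["incomplete"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    except Exception as exc:
        manifest["stages"].setdefault(stage, {})["incomplete"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise PipelineError(stage, exc) from exc

    manifest["complete"] = True
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
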