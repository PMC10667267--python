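"""Readers and writers for the pipeline's plain-text formats.

Compound tables are CSV/TSV with the SwissADME-style descriptor columns;
target maps are (compound_id, gene[, score]) TSV; disease sets are
one-symbol-per-line text or GMT; interactomes are 2/3-column TSV edge lists
or SIF; annotations are GMT. All text is UTF-8 with '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .ctp_network import TripartiteNetwork
from .enrichment import AnnotationCollection, EnrichmentRow
from .mass_spec import parse_formula
from .ppi_topology import CentralityReport, InteractionGraph
from .screening import CompoundRecord, DescriptorSet
from .target_sets import CompoundTargetMap, TargetSet, normalize_symbol

__all__ = [
    "read_compounds",
    "write_compounds",
    "read_target_map",
    "write_target_map",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "write_node_attributes",
    "write_enrichment",
    "descriptors_from_smiles",
]

_DESC_COLS = ["MW", "ALOGP", "HBA", "HBD", "TPSA", "ROTB", "AROM", "ALERTS"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def descriptors_from_smiles(smiles: str) -> DescriptorSet:
    """Compute the eight descriptors from a SMILES string (requires RDKit)."""
    try:
        from rdkit import Chem
        from rdkit.Chem import QED as _QED
    except ImportError as exc:  # pragma: no cover - rdkit present in CI env
        raise ImportError("descriptor computation from SMILES requires rdkit") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    p = _QED.properties(mol)
    return DescriptorSet(mw=p.MW, alogp=p.ALOGP, hba=int(p.HBA), hbd=int(p.HBD),
                         tpsa=p.PSA, rotb=int(p.ROTB), arom=int(p.AROM),
                         alerts=int(p.ALERTS))


def read_compounds(path) -> List[CompoundRecord]:
    """Read a compound descriptor table (TSV or CSV by extension).

    Required columns: compound_id, name, and the eight descriptors — unless a
    SMILES column is present, in which case missing descriptors are computed
    from structure. Table-supplied descriptor values always take precedence.
    Optional column: formula (Hill notation).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in ("compound_id", "name") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    have_desc = [c for c in _DESC_COLS if c in df.columns]
    if len(have_desc) < len(_DESC_COLS) and "SMILES" not in df.columns:
        raise ValueError(
            f"{path}: missing descriptor column(s) "
            f"{sorted(set(_DESC_COLS) - set(have_desc))} and no SMILES column"
        )
    records = []
    for _, row in df.iterrows():
        if all(c in df.columns and pd.notna(row[c]) for c in _DESC_COLS):
            desc = DescriptorSet(
                mw=float(row["MW"]), alogp=float(row["ALOGP"]), hba=int(row["HBA"]),
                hbd=int(row["HBD"]), tpsa=float(row["TPSA"]), rotb=int(row["ROTB"]),
                arom=int(row["AROM"]), alerts=int(row["ALERTS"]),
            )
        else:
            desc = descriptors_from_smiles(str(row["SMILES"]))
        formula = None
        if "formula" in df.columns and pd.notna(row.get("formula")):
            formula = parse_formula(str(row["formula"]))
        records.append(CompoundRecord(str(row["compound_id"]), str(row["name"]), desc, formula))
    return records


def write_compounds(records: Sequence[CompoundRecord], path) -> None:
    """Write the screened table: inputs plus QED, OB_pass, EAC columns."""
    path = Path(path)
    rows = []
    for r in records:
        d = r.descriptors
        rows.append({
            "compound_id": r.compound_id, "name": r.name,
            "MW": d.mw, "ALOGP": d.alogp, "HBA": d.hba, "HBD": d.hbd,
            "TPSA": d.tpsa, "ROTB": d.rotb, "AROM": d.arom, "ALERTS": d.alerts,
            "formula": r.formula.hill_string() if r.formula else "",
            "QED": "" if r.qed is None else round(r.qed, 6),
            "OB_pass": "" if r.ob_pass is None else r.ob_pass,
            "EAC": "" if r.is_eac is None else r.is_eac,
        })
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_target_map(path) -> CompoundTargetMap:
    """Read a (compound_id, gene[, score]) TSV into a deduplicated map."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    if "compound_id" not in df.columns or "gene" not in df.columns:
        raise ValueError(f"{path}: expected columns compound_id, gene[, score]")
    pairs = {(str(c), str(g)) for c, g in zip(df["compound_id"], df["gene"])}
    scores = {}
    if "score" in df.columns:
        scores = {
            (str(c), normalize_symbol(str(g))): float(s)
            for c, g, s in zip(df["compound_id"], df["gene"], df["score"])
            if pd.notna(s)
        }
    return CompoundTargetMap(pairs, scores)


def write_target_map(m: CompoundTargetMap, path) -> None:
    rows = [{"compound_id": c, "gene": g, "score": m.scores.get((c, g), "")}
            for c, g in sorted(m.pairs)]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_gene_list(path, label: str = "gene_list") -> TargetSet:
    """One symbol per line; blank lines and '#' comments skipped."""
    path = Path(path)
    genes = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return TargetSet(label, genes, provenance=str(path))


def write_gene_list(ts: TargetSet, path) -> None:
    Path(path).write_text("\n".join(sorted(ts.genes)) + "\n")


def read_gmt(path, category: str = "") -> AnnotationCollection:
    """GMT: term_id <tab> term_name <tab> gene1 <tab> gene2 ... per line."""
    terms: Dict[str, Tuple[str, str, Set[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs id, name and >= 1 gene")
        tid, name, genes = parts[0], parts[1], {g for g in parts[2:] if g.strip()}
        terms[tid] = (name, category, genes)
    return AnnotationCollection(terms)


def write_gmt(coll: AnnotationCollection, path) -> None:
    lines = [
        "\t".join([tid, name] + sorted(members))
        for tid, (name, _cat, members) in sorted(coll.terms.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path) -> List[Tuple]:
    """2/3-column TSV (gene_a, gene_b[, score]) or SIF ('A pp B') edge rows.

    A header row starting with 'gene' or 'node' is skipped.
    """
    rows: List[Tuple] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if lineno == 1 and parts[0].lower() in ("gene_a", "gene1", "node1", "source"):
            continue
        if len(parts) == 3 and parts[1].lower() in ("pp", "interacts"):
            rows.append((parts[0], parts[2]))
        elif len(parts) >= 3:
            rows.append((parts[0], parts[1], float(parts[2])))
        elif len(parts) == 2:
            rows.append((parts[0], parts[1]))
        else:
            raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {parts!r}")
    return rows


def write_edge_list(edges: Sequence[Tuple[str, str]], path) -> None:
    lines = ["gene_a\tgene_b"] + [f"{a}\t{b}" for a, b in sorted(edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_node_attributes(ig: InteractionGraph, report: CentralityReport,
                          key: TargetSet, path) -> None:
    rows = [{
        "gene": n, "degree": report.degree[n],
        "betweenness": round(report.betweenness[n], 6),
        "closeness": round(report.closeness[n], 6),
        "is_key": n in key.genes,
    } for n in ig.nodes]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def write_enrichment(rows: Sequence[EnrichmentRow], path) -> None:
    df = pd.DataFrame([{
        "term_id": r.term_id, "term_name": r.term_name, "category": r.category,
        "k": r.k, "n": r.n, "K": r.K, "N": r.N,
        "gene_ratio": round(r.gene_ratio, 6),
        "p_value": r.p_value, "p_adjusted": r.p_adjusted,
        "overlap_genes": ",".join(sorted(r.overlap_genes)),
    } for r in rows])
    df.to_csv(Path(path), sep="\t", index=False)


def read_enrichment(path) -> List[EnrichmentRow]:
    df = pd.read_csv(Path(path), sep="\t")
    rows = []
    for _, r in df.iterrows():
        rows.append(EnrichmentRow(
            str(r["term_id"]), str(r["term_name"]), str(r.get("category", "")),
            int(r["k"]), int(r["n"]), int(r["K"]), int(r["N"]),
            set(str(r["overlap_genes"]).split(",")) if pd.notna(r["overlap_genes"]) else set(),
            float(r["p_value"]), float(r["p_adjusted"]),
        ))
    return rows
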