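"""Transcription-factor / metabolic-gene network filtering.

Reimplements the molecular-metabolic circuitry construction as a
deterministic filter over two tables: a regulator→metabolic-gene association
table (GeneHancer-style enhancer/promoter links, or any table in the same
schema) and per-cohort median log2 expression summaries (patients and cell
lines). Genes must clear an expression floor in both cohorts, regulators must
clear their own floor, and regulators must retain a minimum out-degree after
the expression filters. The degree filter is iterated with the edge pruning
to a fixed point, which makes the result independent of filter ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "RegulatoryNetwork",
    "load_association_table",
    "load_expression_summary",
    "filter_network",
    "export_network",
]


@dataclass
class RegulatoryNetwork:
    """Bipartite regulator↔gene graph with expression medians and a stage report."""

    graph: nx.Graph
    stage_report: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def regulators(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "regulator")

    @property
    def genes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene")

    @property
    def edges(self) -> set[tuple[str, str]]:
        out = set()
        for u, v in self.graph.edges():
            if self.graph.nodes[u]["kind"] == "regulator":
                out.add((u, v))
            else:
                out.add((v, u))
        return out


def load_association_table(path: str) -> pd.DataFrame:
    """TSV with columns regulator, gene[, confidence]; duplicates dropped."""
    df = pd.read_csv(path, sep="\t")
    required = {"regulator", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    return df.drop_duplicates(subset=["regulator", "gene"]).reset_index(drop=True)


def load_expression_summary(path: str) -> pd.Series:
    """TSV with columns gene, median_log2 -> Series indexed by gene."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "median_log2"} - set(df.columns)
    if missing:
        raise ValueError(f"expression summary missing columns: {sorted(missing)}")
    return df.set_index("gene")["median_log2"].astype(float)


def filter_network(
    assoc: pd.DataFrame,
    expr_patients: pd.Series,
    expr_lines: pd.Series,
    gene_floor: float = 10.0,
    tf_floor: float = 7.5,
    min_degree: int = 5,
) -> RegulatoryNetwork:
    """Apply the expression and degree filters and build the retained network.

    Keeps metabolic genes whose median log2 expression clears ``gene_floor``
    in BOTH cohorts and regulators clearing ``tf_floor`` in both; drops edges
    to removed nodes; then iterates the regulator degree filter and edge
    pruning to a fixed point. Records counts at every stage. Genes or
    regulators missing from an expression summary are excluded with a warning.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    if assoc.empty:
        raise ValueError("association table is empty")
    assoc = assoc.drop_duplicates(subset=["regulator", "gene"]).reset_index(drop=True)
    report: dict[str, dict[str, int]] = {}
    regulators = sorted(assoc["regulator"].unique())
    genes = sorted(assoc["gene"].unique())
    report["input"] = {
        "edges": len(assoc),
        "regulators": len(regulators),
        "genes": len(genes),
    }

    def _median(expr: pd.Series, node: str) -> float | None:
        return float(expr[node]) if node in expr.index else None

    missing: list[str] = []

    def _passes(node: str, floor: float) -> bool:
        mp, ml = _median(expr_patients, node), _median(expr_lines, node)
        if mp is None or ml is None:
            missing.append(node)
            return False
        return mp >= floor and ml >= floor

    kept_genes = {g for g in genes if _passes(g, gene_floor)}
    report["gene_expression_filter"] = {
        "kept": len(kept_genes),
        "removed": len(genes) - len(kept_genes),
    }
    kept_regs = {r for r in regulators if _passes(r, tf_floor)}
    report["regulator_expression_filter"] = {
        "kept": len(kept_regs),
        "removed": len(regulators) - len(kept_regs),
    }
    if missing:
        warnings.warn(f"nodes missing expression values excluded: {sorted(set(missing))}")

    edges = {
        (r, g)
        for r, g in zip(assoc["regulator"], assoc["gene"])
        if r in kept_regs and g in kept_genes
    }
    report["edge_prune_after_expression"] = {"kept": len(edges), "removed": len(assoc) - len(edges)}

    # iterate degree filter + edge pruning to the fixed point
    rounds = 0
    while True:
        rounds += 1
        degree: dict[str, int] = {}
        for r, _ in edges:
            degree[r] = degree.get(r, 0) + 1
        low = {r for r in kept_regs if degree.get(r, 0) < min_degree}
        if not low:
            break
        kept_regs -= low
        edges = {(r, g) for r, g in edges if r in kept_regs}
    # genes with no remaining edges leave the network
    connected_genes = {g for _, g in edges}
    report["degree_filter"] = {
        "kept_regulators": len(kept_regs),
        "kept_genes": len(connected_genes),
        "kept_edges": len(edges),
        "rounds": rounds,
    }

    g = nx.Graph()
    for r in sorted(kept_regs):
        g.add_node(
            r,
            kind="regulator",
            median_patients=float(expr_patients[r]),
            median_lines=float(expr_lines[r]),
        )
    for gene in sorted(connected_genes):
        g.add_node(
            gene,
            kind="gene",
            median_patients=float(expr_patients[gene]),
            median_lines=float(expr_lines[gene]),
        )
    for r, gene in sorted(edges):
        g.add_edge(r, gene)
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    return RegulatoryNetwork(g, report)


def export_network(net: RegulatoryNetwork, path: str, fmt: str = "graphml") -> None:
    """Write the filtered network as GraphML or SIF; errors on empty networks."""
    if net.graph.number_of_edges() == 0:
        raise ValueError("network is empty after filtering; refusing to write an empty file")
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "sif":
        lines = [f"{r}\tregulates\t{g}" for r, g in sorted(net.edges)]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported format {fmt!r} (use 'graphml' or 'sif')")
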