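"""Regulatory-network assembly and exporters.

The network contains one node per miRNA and per gene occurring in the
selected sub-pathways, a *regulation* edge from each miRNA to each of
its targets, and a *ppi* edge for every pair of network genes that
interact in the source PPI graph — i.e. the PPI edge set is closed over
the network's gene set, linking pairs even when no single sub-pathway
contains both.  Exports: TSV tables, SIF, GraphML and a JSON node/edge
document, all with deterministic (sorted) ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .io import DatasetBundle, InteractionGraph
from .query import ComorbidGene, Mrsp


@dataclass(frozen=True)
class NodeRecord:
    """One network node: a miRNA, a miRNA target gene, or an interactor."""

    id: str
    kind: str  # "mirna" | "target_gene" | "gene"
    cancer_tag: str | None
    tissues: frozenset[str]
    pathways: frozenset[str]
    n_bp_terms: int
    n_mf_terms: int


@dataclass(frozen=True)
class EdgeRecord:
    a: str
    b: str
    kind: str  # "regulation" | "ppi"


@dataclass(frozen=True)
class RegulatoryNetwork:
    nodes: dict[str, NodeRecord]
    edges: frozenset[EdgeRecord]

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(n.id for n in self.nodes.values() if n.kind != "mirna")


def assemble_network(
    mrsps: Sequence[Mrsp], graph: InteractionGraph, bundle: DatasetBundle
) -> RegulatoryNetwork:
    """Build the miRNA regulatory network from selected sub-pathways.

    Nodes carry cancer tags, tissue labels and annotation summaries from
    the bundle.  PPI edges are the closure of the source graph over the
    network's genes, so the path edges themselves are always included.
    """
    mirnas: set[str] = set()
    targets: set[str] = set()
    genes: set[str] = set()
    for m in mrsps:
        mirnas.add(m.mirna)
        targets.add(m.record.rsp.target)
        genes.update(m.record.rsp.genes)

    assoc = bundle.assoc
    nodes: dict[str, NodeRecord] = {}
    for mirna in mirnas:
        nodes[mirna] = NodeRecord(
            mirna, "mirna", None, frozenset(), frozenset(), 0, 0
        )
    for gene in genes:
        nodes[gene] = NodeRecord(
            gene,
            "target_gene" if gene in targets else "gene",
            assoc.cancer_tags.get(gene),
            assoc.gene_tissues.get(gene, frozenset()),
            assoc.pathway_catalog.terms(gene),
            len(bundle.bp.terms(gene)),
            len(bundle.mf.terms(gene)),
        )

    edges: set[EdgeRecord] = set()
    for m in mrsps:
        edges.add(EdgeRecord(m.mirna, m.record.rsp.target, "regulation"))
    gene_list = sorted(genes)
    for i, a in enumerate(gene_list):
        for b in gene_list[i + 1 :]:
            if graph.has_edge(a, b):
                edges.add(EdgeRecord(a, b, "ppi"))
    return RegulatoryNetwork(nodes, frozenset(edges))


# ---------------------------------------------------------------------------
# writers


def write_rsps_tsv(records: Sequence[Mrsp], path: str | Path) -> None:
    """Ranked sub-pathway table: one row per (miRNA, T, G1, G2)."""
    cols = [
        "rank", "mirna", "target", "g1", "g2",
        "js_bp", "js_mf", "p1", "p2", "p_value", "pathways",
    ]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for rank, m in enumerate(records, start=1):
            r = m.record
            fh.write(
                "\t".join(
                    [
                        str(rank),
                        m.mirna,
                        r.rsp.target,
                        r.rsp.g1,
                        r.rsp.g2,
                        f"{r.js_bp:.6g}",
                        f"{r.js_mf:.6g}",
                        f"{r.p1:.6g}",
                        f"{r.p2:.6g}",
                        f"{r.p_value:.6g}",
                        ";".join(sorted(r.pathways)),
                    ]
                )
                + "\n"
            )


def write_comorbid_tsv(genes: Sequence[ComorbidGene], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\tcancer_tag\tpathways\n")
        for g in genes:
            fh.write(f"{g.gene}\t{g.cancer_tag or ''}\t{';'.join(sorted(g.pathways))}\n")


def _sorted_edges(net: RegulatoryNetwork) -> list[EdgeRecord]:
    return sorted(net.edges, key=lambda e: (e.kind, e.a, e.b))


def write_sif(net: RegulatoryNetwork, path: str | Path) -> None:
    """Simple interaction format: ``source<TAB>relation<TAB>target``."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in _sorted_edges(net):
            fh.write(f"{e.a}\t{e.kind}\t{e.b}\n")


def write_node_table(net: RegulatoryNetwork, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("id\tkind\tcancer_tag\ttissues\tpathways\tn_bp_terms\tn_mf_terms\n")
        for nid in sorted(net.nodes):
            n = net.nodes[nid]
            fh.write(
                "\t".join(
                    [
                        n.id,
                        n.kind,
                        n.cancer_tag or "",
                        ";".join(sorted(n.tissues)),
                        ";".join(sorted(n.pathways)),
                        str(n.n_bp_terms),
                        str(n.n_mf_terms),
                    ]
                )
                + "\n"
            )


def to_networkx(net: RegulatoryNetwork) -> nx.Graph:
    g = nx.Graph()
    for nid in sorted(net.nodes):
        n = net.nodes[nid]
        g.add_node(
            n.id,
            kind=n.kind,
            cancer_tag=n.cancer_tag or "",
            tissues=";".join(sorted(n.tissues)),
            pathways=";".join(sorted(n.pathways)),
            n_bp_terms=n.n_bp_terms,
            n_mf_terms=n.n_mf_terms,
        )
    for e in _sorted_edges(net):
        g.add_edge(e.a, e.b, kind=e.kind)
    return g


def write_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    nx.write_graphml(to_networkx(net), str(path))


def write_json(net: RegulatoryNetwork, path: str | Path) -> None:
    doc = {
        "nodes": [
            {
                "id": n.id,
                "kind": n.kind,
                "cancer_tag": n.cancer_tag,
                "tissues": sorted(n.tissues),
                "pathways": sorted(n.pathways),
                "n_bp_terms": n.n_bp_terms,
                "n_mf_terms": n.n_mf_terms,
            }
            for n in (net.nodes[nid] for nid in sorted(net.nodes))
        ],
        "edges": [
            {"source": e.a, "target": e.b, "kind": e.kind} for e in _sorted_edges(net)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")
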