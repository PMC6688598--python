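"""Disease and disease-pair queries over a dataset bundle.

A query selects the miRNAs and target genes associated with a disease,
enumerates and scores every target's regulatory sub-pathways, applies
the interface filters (validation evidence, tissue, cancer-gene status,
p-value threshold, pathway and gene restriction, top-N), and yields the
sorted list of miRNA-specific sub-pathways from which the regulatory
network is assembled.  A miRNA identifier may be given in place of a
disease name to run a miRNA-centric query over the same machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .core import RspRecord, enumerate_rsps, score_rsp
from .io import DIRECT_METHODS, DatasetBundle, Namespace

log = logging.getLogger(__name__)


class QueryError(ValueError):
    """Raised for unknown diseases or invalid filter settings."""


@dataclass(frozen=True)
class QuerySpec:
    """All settings of a single-disease or disease-pair query.

    ``disease`` may also be a miRNA identifier (miRNA-centric search).
    ``namespace`` selects the GO namespace used for the viability gate,
    the p-values and the ranking; both Jaccard scores are reported either
    way.  ``cancer_filter`` is one of ``none`` (no restriction),
    ``target_only`` (the target must carry a cancer tag) or ``all_genes``
    (all three path genes must).
    """

    disease: str
    disease2: str | None = None
    tissue: str | None = None
    tissue2: str | None = None
    namespace: Namespace = Namespace.MF
    p_threshold: float = 0.001
    require_validated: bool = False
    validated_methods: frozenset[str] = DIRECT_METHODS
    cancer_filter: str = "none"
    top_n: int | None = None
    gene_filter: str | None = None
    kegg_filter: str | None = None
    tissue_scope: str = "all_genes"  # or "target_only"
    tail_pvalue: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "namespace", Namespace(self.namespace))
        if not (0.0 < self.p_threshold <= 1.0):
            raise QueryError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if self.top_n is not None and self.top_n < 1:
            raise QueryError(f"top_n must be >= 1, got {self.top_n}")
        if self.cancer_filter not in ("none", "target_only", "all_genes"):
            raise QueryError(f"unknown cancer_filter {self.cancer_filter!r}")
        if self.tissue_scope not in ("all_genes", "target_only"):
            raise QueryError(f"unknown tissue_scope {self.tissue_scope!r}")

    def for_second_disease(self) -> "QuerySpec":
        if self.disease2 is None:
            raise QueryError("query has no second disease")
        return replace(
            self, disease=self.disease2, disease2=None, tissue=self.tissue2, tissue2=None
        )


@dataclass(frozen=True)
class Mrsp:
    """A scored sub-pathway prefixed with the miRNA regulating its target."""

    mirna: str
    record: RspRecord


def _resolve_disease(name: str, bundle: DatasetBundle) -> str | None:
    """Case-insensitive, trimmed exact match against known disease names."""
    wanted = name.strip().casefold()
    for disease in bundle.assoc.disease_mirnas:
        if disease.strip().casefold() == wanted:
            return disease
    return None


def _in_tissue(gene: str, tissue: str | None, bundle: DatasetBundle) -> bool:
    if tissue is None:
        return True
    return tissue in bundle.assoc.gene_tissues.get(gene, frozenset())


def select_disease_inputs(
    query: QuerySpec, bundle: DatasetBundle
) -> dict[str, frozenset[str]]:
    """Per-miRNA target sets for the queried disease, after target filters.

    Applies the validation filter (keep targets with at least one method
    in ``validated_methods`` when ``require_validated``) and the tissue
    filter to the targets.  If ``query.disease`` names a miRNA instead,
    that single miRNA's targets are returned.
    """
    assoc = bundle.assoc
    if query.disease in assoc.mirna_targets:
        mirnas: Sequence[str] = [query.disease]
    else:
        disease = _resolve_disease(query.disease, bundle)
        if disease is None:
            known = ", ".join(sorted(assoc.disease_mirnas))
            raise QueryError(
                f"unknown disease {query.disease!r}; known diseases: {known}"
            )
        mirnas = sorted(assoc.disease_mirnas[disease])
    out: dict[str, frozenset[str]] = {}
    for mirna in mirnas:
        targets = set()
        for gene, ev in assoc.mirna_targets.get(mirna, {}).items():
            if query.require_validated and not (ev.methods & query.validated_methods):
                continue
            if not _in_tissue(gene, query.tissue, bundle):
                continue
            targets.add(gene)
        if targets:
            out[mirna] = frozenset(targets)
    if not out:
        log.warning(
            "query for %r yielded no miRNA targets after filters", query.disease
        )
    return out


def _passes_filters(
    mirna: str, record: RspRecord, query: QuerySpec, bundle: DatasetBundle
) -> bool:
    rsp = record.rsp
    if record.p_value > query.p_threshold:
        return False
    if query.tissue is not None and query.tissue_scope == "all_genes":
        if not all(_in_tissue(g, query.tissue, bundle) for g in (rsp.g1, rsp.g2)):
            return False
    if query.cancer_filter != "none":
        tags = bundle.assoc.cancer_tags
        need = (rsp.target,) if query.cancer_filter == "target_only" else rsp.genes
        if not all(g in tags for g in need):
            return False
    if query.gene_filter is not None and query.gene_filter not in rsp.genes:
        return False
    if query.kegg_filter is not None and query.kegg_filter not in record.pathways:
        return False
    return True


def _sort_key(query: QuerySpec):
    def key(m: Mrsp):
        js = m.record.js_bp if query.namespace is Namespace.BP else m.record.js_mf
        return (m.record.p_value, -js, m.record.rsp.genes, m.mirna)

    return key


def build_mrsp_set(
    inputs: Mapping[str, frozenset[str]],
    bundle: DatasetBundle,
    query: QuerySpec,
    stats: dict | None = None,
) -> list[Mrsp]:
    """All viable, filter-passing miRNA-specific sub-pathways, sorted.

    For each (miRNA, target) pair every two-hop path from the target is
    enumerated and scored in the query namespace; non-viable paths are
    discarded and the remaining records pass through the p-threshold,
    tissue, cancer, gene and pathway filters.  The result is sorted by
    ascending p-value with deterministic tie-breaking (higher selected
    Jaccard score first, then lexicographic gene triple, then miRNA).
    ``stats``, when given, receives raw/viable/post-filter counts.
    """
    raw = viable = 0
    out: list[Mrsp] = []
    record_cache: dict[str, list[RspRecord]] = {}
    for mirna in sorted(inputs):
        for target in sorted(inputs[mirna]):
            if target not in record_cache:
                rsps = enumerate_rsps(target, bundle.ppi)
                records = []
                for rsp in rsps:
                    rec = score_rsp(
                        rsp,
                        bundle.bp,
                        bundle.mf,
                        query.namespace,
                        pathway_catalog=bundle.assoc.pathway_catalog,
                        tail=query.tail_pvalue,
                    )
                    if rec is not None:
                        records.append(rec)
                record_cache[target] = records
                raw += len(rsps)
                viable += len(records)
            for rec in record_cache[target]:
                if _passes_filters(mirna, rec, query, bundle):
                    out.append(Mrsp(mirna, rec))
    out.sort(key=_sort_key(query))
    if stats is not None:
        stats.update(
            raw_rsps=raw, viable_rsps=viable, postfilter_rsps=len(out)
        )
    return out


def top_n(records: Sequence[Mrsp], n: int, query: QuerySpec | None = None) -> list[Mrsp]:
    """First ``n`` records of an ascending-p-value list.

    Re-applies the deterministic ordering (p ascending, selected-namespace
    Jaccard descending, lexicographic gene triple) before truncating so
    ties never depend on input order.
    """
    if n < 1:
        raise QueryError(f"top_n must be >= 1, got {n}")
    ordered = sorted(records, key=_sort_key(query or QuerySpec(disease="", p_threshold=1.0)))
    return ordered[:n]


def mrsp_genes(records: Sequence[Mrsp]) -> frozenset[str]:
    """All genes (T, G1, G2 over every sub-pathway) of a record list."""
    genes: set[str] = set()
    for m in records:
        genes.update(m.record.rsp.genes)
    return frozenset(genes)


@dataclass(frozen=True)
class ComorbidGene:
    """One gene common to both diseases' sub-pathway gene sets."""

    gene: str
    cancer_tag: str | None
    pathways: frozenset[str]


def comorbid_genes(
    records1: Sequence[Mrsp],
    records2: Sequence[Mrsp],
    bundle: DatasetBundle,
) -> list[ComorbidGene]:
    """Genes shared by the sub-pathway gene sets of two disease queries.

    The gene universe of each disease is built from all three path
    positions (target, G1, G2).  Each shared gene is annotated with its
    cancer tag (if any) and pathway memberships; output is lexicographic.
    """
    shared = mrsp_genes(records1) & mrsp_genes(records2)
    catalog = bundle.assoc.pathway_catalog
    return [
        ComorbidGene(g, bundle.assoc.cancer_tags.get(g), catalog.terms(g))
        for g in sorted(shared)
    ]


def run_query(
    query: QuerySpec, bundle: DatasetBundle, stats: dict | None = None
) -> list[Mrsp]:
    """select → build → (optional top-N) for one disease or miRNA."""
    inputs = select_disease_inputs(query, bundle)
    if stats is not None:
        stats.update(
            n_mirnas=len(inputs),
            n_targets=len(set().union(*inputs.values())) if inputs else 0,
        )
    records = build_mrsp_set(inputs, bundle, query, stats=stats)
    if query.top_n is not None:
        records = top_n(records, query.top_n, query)
    return records
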