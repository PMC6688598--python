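"""Domain types and loaders for the seven input tables.

The toolkit consumes plain-text tables emulating the public resources a
miRNA-network study integrates: a disease–miRNA association table, a
miRNA–target table with validation-method evidence, an undirected
protein–protein interaction (PPI) edge list, GO Biological Process /
Molecular Function gene sets and pathway gene sets in GMT format, a
gene–tissue map, and a gene–cancer-tag map (CRG/OCG/TSG).

All tables are UTF-8, tab-separated, with a required header row;
``#``-prefixed lines are skipped.  Gene identity is the case-sensitive
symbol as given — no alias resolution is attempted.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

log = logging.getLogger(__name__)


class Namespace(str, enum.Enum):
    """Annotation namespace a term set belongs to."""

    BP = "BP"
    MF = "MF"
    PATHWAY = "PATHWAY"


#: The seven direct experimental validation methods for miRNA–target pairs.
DIRECT_METHODS = frozenset(
    {
        "HITS-CLIP",
        "PAR-CLIP",
        "IMPACT-Seq",
        "CLASH",
        "Luciferase Reporter Assay",
        "3LIFE",
        "Genetic Testing",
    }
)

#: Default closed vocabulary of validation methods: the seven direct methods
#: plus common indirect evidence types.  Configurable at load time; unknown
#: strings warn but do not fail.
DEFAULT_METHOD_VOCABULARY = DIRECT_METHODS | frozenset(
    {"Microarray", "Western Blot", "qRT-PCR", "Proteomics"}
)

CANCER_TAGS = frozenset({"CRG", "OCG", "TSG"})


class LoadError(ValueError):
    """Raised when an input table is malformed."""


@dataclass(frozen=True)
class AnnotationCatalog:
    """Per-namespace map from gene symbol to its set of annotation terms.

    ``universe_size`` is the number of distinct terms in the namespace
    (the size of the union of all per-gene term sets); it is the ``N`` of
    the overlap p-value.  Lookup of a gene absent from the annotation
    source yields the empty set.
    """

    namespace: Namespace
    term_sets: Mapping[str, frozenset[str]]
    universe_size: int

    @classmethod
    def from_term_sets(
        cls, namespace: Namespace | str, term_sets: Mapping[str, Iterable[str]]
    ) -> "AnnotationCatalog":
        frozen = {g: frozenset(ts) for g, ts in term_sets.items()}
        universe: set[str] = set()
        for ts in frozen.values():
            universe |= ts
        return cls(Namespace(namespace), frozen, len(universe))

    def terms(self, gene: str) -> frozenset[str]:
        return self.term_sets.get(gene, frozenset())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationCatalog):
            return NotImplemented
        return (
            self.namespace == other.namespace
            and dict(self.term_sets) == dict(other.term_sets)
            and self.universe_size == other.universe_size
        )


@dataclass(frozen=True)
class InteractionGraph:
    """Undirected, deduplicated PPI edge set over gene symbols.

    Pairs are stored once as sorted tuples; self-pairs are rejected at
    load time.
    """

    edges: frozenset[tuple[str, str]]
    nodes: frozenset[str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionGraph":
        edges = set()
        nodes = set()
        dropped = 0
        for a, b in pairs:
            if a == b:
                dropped += 1
                continue
            edges.add((a, b) if a < b else (b, a))
            nodes.add(a)
            nodes.add(b)
        if dropped:
            log.info("dropped %d self-loop(s) from PPI input", dropped)
        return cls(frozenset(edges), frozenset(nodes))

    def has_edge(self, a: str, b: str) -> bool:
        return ((a, b) if a < b else (b, a)) in self.edges

    def neighbors(self, gene: str) -> frozenset[str]:
        return self._adjacency.get(gene, frozenset())

    @property
    def _adjacency(self) -> dict[str, frozenset[str]]:
        adj = getattr(self, "_adj_cache", None)
        if adj is None:
            tmp: dict[str, set[str]] = {}
            for a, b in self.edges:
                tmp.setdefault(a, set()).add(b)
                tmp.setdefault(b, set()).add(a)
            adj = {g: frozenset(ns) for g, ns in tmp.items()}
            object.__setattr__(self, "_adj_cache", adj)
        return adj


@dataclass(frozen=True)
class TargetEvidence:
    """Evidence for one miRNA–target association."""

    gene: str
    methods: frozenset[str]
    direction: str  # "positive" or "negative"


@dataclass(frozen=True)
class AssociationBundle:
    """Disease–miRNA and miRNA–target associations plus gene annotations."""

    disease_mirnas: Mapping[str, Mapping[str, str]]  # disease -> mirna -> source
    mirna_targets: Mapping[str, Mapping[str, TargetEvidence]]
    gene_tissues: Mapping[str, frozenset[str]]
    cancer_tags: Mapping[str, str]
    pathway_catalog: AnnotationCatalog

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationBundle):
            return NotImplemented
        return (
            {d: dict(m) for d, m in self.disease_mirnas.items()}
            == {d: dict(m) for d, m in other.disease_mirnas.items()}
            and {m: dict(t) for m, t in self.mirna_targets.items()}
            == {m: dict(t) for m, t in other.mirna_targets.items()}
            and dict(self.gene_tissues) == dict(other.gene_tissues)
            and dict(self.cancer_tags) == dict(other.cancer_tags)
            and self.pathway_catalog == other.pathway_catalog
        )


@dataclass(frozen=True)
class DatasetBundle:
    """The full validated input dataset."""

    bp: AnnotationCatalog
    mf: AnnotationCatalog
    ppi: InteractionGraph
    assoc: AssociationBundle

    def catalog(self, namespace: Namespace | str) -> AnnotationCatalog:
        ns = Namespace(namespace)
        if ns is Namespace.BP:
            return self.bp
        if ns is Namespace.MF:
            return self.mf
        return self.assoc.pathway_catalog


# ---------------------------------------------------------------------------
# loaders


def load_gene_sets(path: str | Path, namespace: Namespace | str) -> AnnotationCatalog:
    """Read a GMT file (term<TAB>description<TAB>gene...) into a catalog.

    The term→genes lines are inverted into a gene→terms map.  Duplicate
    term lines are merged by union.  Lines with fewer than three fields
    raise :class:`LoadError` naming the offending line number.
    """
    path = Path(path)
    gene_terms: dict[str, set[str]] = {}
    n_terms_seen: set[str] = set()
    n_data_lines = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields (term, description, genes...), got {len(fields)}"
                )
            term = fields[0]
            n_terms_seen.add(term)
            n_data_lines += 1
            for gene in fields[2:]:
                if gene:
                    gene_terms.setdefault(gene, set()).add(term)
    if n_data_lines == 0:
        raise LoadError(f"{path}: empty GMT file")
    return AnnotationCatalog.from_term_sets(namespace, gene_terms)


def write_gene_sets(catalog: AnnotationCatalog, path: str | Path) -> None:
    """Write a catalog back to GMT (inverse of :func:`load_gene_sets`)."""
    term_genes: dict[str, set[str]] = {}
    for gene, terms in catalog.term_sets.items():
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    with Path(path).open("w", encoding="utf-8") as fh:
        for term in sorted(term_genes):
            genes = "\t".join(sorted(term_genes[term]))
            fh.write(f"{term}\t{catalog.namespace.value} term\t{genes}\n")


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error surface
        raise LoadError(f"{path}: cannot parse table: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required column(s) {missing}")
    return df


def load_ppi(path: str | Path) -> InteractionGraph:
    """Read a two-column PPI edge list; dedupe symmetric pairs, drop self-loops."""
    df = _read_table(path, ["gene_a", "gene_b"])
    return InteractionGraph.from_pairs(
        (str(a).strip(), str(b).strip()) for a, b in zip(df["gene_a"], df["gene_b"])
    )


def load_disease_mirnas(path: str | Path) -> dict[str, dict[str, str]]:
    df = _read_table(path, ["disease", "mirna", "source"])
    out: dict[str, dict[str, str]] = {}
    for disease, mirna, source in zip(df["disease"], df["mirna"], df["source"]):
        out.setdefault(disease.strip(), {})[mirna.strip()] = source.strip()
    for disease, mirnas in out.items():
        if not mirnas:
            raise LoadError(f"disease {disease!r} has no associated miRNA")
    return out


def load_mirna_targets(
    path: str | Path, vocabulary: frozenset[str] = DEFAULT_METHOD_VOCABULARY
) -> dict[str, dict[str, TargetEvidence]]:
    df = _read_table(path, ["mirna", "gene", "methods", "direction"])
    out: dict[str, dict[str, TargetEvidence]] = {}
    unknown: set[str] = set()
    for mirna, gene, methods, direction in zip(
        df["mirna"], df["gene"], df["methods"], df["direction"]
    ):
        meths = frozenset(m.strip() for m in methods.split(";") if m.strip())
        unknown |= meths - vocabulary
        out.setdefault(mirna.strip(), {})[gene.strip()] = TargetEvidence(
            gene.strip(), meths, direction.strip()
        )
    if unknown:
        log.warning("unknown validation method(s): %s", ", ".join(sorted(unknown)))
    return out


def load_gene_tissues(path: str | Path) -> dict[str, frozenset[str]]:
    df = _read_table(path, ["gene", "tissue"])
    tmp: dict[str, set[str]] = {}
    for gene, tissue in zip(df["gene"], df["tissue"]):
        tmp.setdefault(gene.strip(), set()).add(tissue.strip())
    return {g: frozenset(ts) for g, ts in tmp.items()}


def load_cancer_tags(path: str | Path) -> dict[str, str]:
    df = _read_table(path, ["gene", "tag"])
    out: dict[str, str] = {}
    for gene, tag in zip(df["gene"], df["tag"]):
        tag = tag.strip()
        if tag not in CANCER_TAGS:
            raise LoadError(f"{path}: unknown cancer tag {tag!r} for gene {gene!r}")
        out[gene.strip()] = tag
    return out


#: role name -> config key of each table path
TABLE_ROLES = {
    "bp_gmt": "GO biological-process gene sets",
    "mf_gmt": "GO molecular-function gene sets",
    "pathway_gmt": "pathway gene sets",
    "ppi": "protein-protein interactions",
    "disease_mirna": "disease-miRNA associations",
    "mirna_target": "miRNA-target associations",
    "tissue": "gene-tissue map",
    "cancer_tags": "gene cancer tags",
}


def load_bundle(config: str | Path | Mapping) -> DatasetBundle:
    """Load and validate the full dataset bundle.

    ``config`` is a YAML file (or an already-parsed mapping) with a
    ``paths:`` section naming all table roles of :data:`TABLE_ROLES`.
    Relative paths resolve against the config file's directory.
    """
    base = Path(".")
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        base = cfg_path.parent
        with cfg_path.open(encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    paths = config.get("paths", {})
    missing = [role for role in TABLE_ROLES if role not in paths]
    if missing:
        raise LoadError(
            "config missing path(s) for: "
            + ", ".join(f"{r} ({TABLE_ROLES[r]})" for r in missing)
        )

    def p(role: str) -> Path:
        q = Path(paths[role])
        return q if q.is_absolute() else base / q

    vocab = frozenset(config.get("method_vocabulary", DEFAULT_METHOD_VOCABULARY))

    def wrap(role: str, fn, *args):
        try:
            return fn(p(role), *args)
        except (LoadError, OSError) as exc:
            raise LoadError(f"[{role}: {p(role)}] {exc}") from exc

    bp = wrap("bp_gmt", load_gene_sets, Namespace.BP)
    mf = wrap("mf_gmt", load_gene_sets, Namespace.MF)
    pathway = wrap("pathway_gmt", load_gene_sets, Namespace.PATHWAY)
    ppi = wrap("ppi", load_ppi)
    disease_mirnas = wrap("disease_mirna", load_disease_mirnas)
    mirna_targets = wrap("mirna_target", load_mirna_targets, vocab)
    tissues = wrap("tissue", load_gene_tissues)
    tags = wrap("cancer_tags", load_cancer_tags)

    for disease, mirnas in disease_mirnas.items():
        for mirna in mirnas:
            if mirna not in mirna_targets:
                log.warning(
                    "miRNA %s (disease %s) has no target records", mirna, disease
                )
    log.info(
        "bundle loaded: %d diseases, %d miRNAs, %d PPI edges over %d genes, "
        "BP universe %d, MF universe %d, %d pathways-annotated genes",
        len(disease_mirnas),
        len(mirna_targets),
        len(ppi.edges),
        len(ppi.nodes),
        bp.universe_size,
        mf.universe_size,
        len(pathway.term_sets),
    )
    assoc = AssociationBundle(disease_mirnas, mirna_targets, tissues, tags, pathway)
    return DatasetBundle(bp, mf, ppi, assoc)
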