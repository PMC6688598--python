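"""Enumeration and scoring of target-specific regulatory sub-pathways.

A regulatory sub-pathway (RSP) is an ordered gene triple (T, G1, G2) in
which T–G1 and G1–G2 are protein–protein interaction edges.  Each RSP is
scored in a GO namespace X (BP or MF) by

* the Jaccard score ``JS_X = (JC([T]_X,[G1]_X) + JC([G1]_X,[G2]_X)) / 2``,
  where ``[G]_X`` is the set of X-terms annotating gene G and JC is the
  Jaccard coefficient |A∩B|/|A∪B|; an RSP with either hop-wise JC equal
  to zero is *not viable* and discarded;
* a p-value per hop: the exact hypergeometric point probability of the
  observed term overlap given the namespace's term universe, the RSP
  p-value being the greater of the two hop p-values.

All p-value arithmetic is exact (``fractions.Fraction`` over integer
binomials) and converted to float only at the end.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable

from .io import AnnotationCatalog, InteractionGraph, Namespace


@dataclass(frozen=True, order=True)
class Rsp:
    """An ordered simple path (target, g1, g2) of length two in the PPI graph."""

    target: str
    g1: str
    g2: str

    def __post_init__(self) -> None:
        # adjacent genes are always distinct (the PPI graph has no self-loops);
        # target == g2 (a back-tracking path) is rejected at enumeration time
        # unless explicitly allowed there.
        if self.target == self.g1 or self.g1 == self.g2:
            raise ValueError(
                f"adjacent RSP genes must differ, got ({self.target}, {self.g1}, {self.g2})"
            )

    @property
    def genes(self) -> tuple[str, str, str]:
        return (self.target, self.g1, self.g2)


@dataclass(frozen=True)
class PairOverlap:
    """Term-overlap configuration of one RSP hop.

    ``size_a``/``size_b`` are the annotation-set sizes of the two genes
    (x and y for the T–G1 hop; y and z for G1–G2), ``shared`` the size of
    their intersection (n1, resp. n2) and ``universe`` the number of
    distinct terms N in the namespace.
    """

    size_a: int
    size_b: int
    shared: int
    universe: int

    def feasible(self) -> bool:
        return (
            0 <= self.size_a <= self.universe
            and 0 <= self.size_b <= self.universe
            and max(0, self.size_a + self.size_b - self.universe)
            <= self.shared
            <= min(self.size_a, self.size_b)
        )


@dataclass(frozen=True)
class RspRecord:
    """A scored sub-pathway with both namespace Jaccard scores and its p-value."""

    rsp: Rsp
    js_bp: float
    js_mf: float
    viable_bp: bool
    viable_mf: bool
    p1: float
    p2: float
    p_value: float
    pathways: frozenset[str]


def enumerate_rsps(
    target: str, graph: InteractionGraph, allow_backtrack: bool = False
) -> list[Rsp]:
    """All two-hop paths (target, g1, g2) in the interaction graph.

    Paths are simple by default (g2 != target); ``allow_backtrack=True``
    additionally admits paths returning to the target.  Output is
    deterministic: lexicographic by (g1, g2).  A target absent from the
    graph yields an empty list.
    """
    out: list[Rsp] = []
    for g1 in sorted(graph.neighbors(target)):
        for g2 in sorted(graph.neighbors(g1)):
            if g2 != g1 and (allow_backtrack or g2 != target):
                out.append(Rsp(target, g1, g2))
    return out


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Jaccard coefficient |A∩B| / |A∪B|; 0.0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def js_score(rsp: Rsp, catalog: AnnotationCatalog) -> tuple[float, bool]:
    """Jaccard score of an RSP in one namespace and its viability flag.

    The score is the arithmetic mean of the two hop-wise Jaccard
    coefficients; the RSP is viable iff both are strictly positive.
    """
    jc1 = jaccard(catalog.terms(rsp.target), catalog.terms(rsp.g1))
    jc2 = jaccard(catalog.terms(rsp.g1), catalog.terms(rsp.g2))
    return (jc1 + jc2) / 2.0, jc1 > 0 and jc2 > 0


def pair_pvalue_exact(overlap: PairOverlap, tail: bool = False) -> Fraction:
    """Exact hop p-value as a rational number.

    The point probability of drawing a ``size_b``-subset of an
    ``universe``-term pool that shares exactly ``shared`` terms with a
    fixed ``size_a``-subset:

        C(x, n) * C(N - x, y - n) / C(N, y)

    With ``tail=True`` the upper tail (overlap >= ``shared``) is summed
    instead, for an enrichment-style p-value.
    """
    if not overlap.feasible():
        raise ValueError(f"infeasible overlap configuration: {overlap}")
    x, y, n, N = overlap.size_a, overlap.size_b, overlap.shared, overlap.universe
    denom = comb(N, y)
    if tail:
        num = sum(comb(x, k) * comb(N - x, y - k) for k in range(n, min(x, y) + 1))
    else:
        num = comb(x, n) * comb(N - x, y - n)
    return Fraction(num, denom)


def pair_pvalue(overlap: PairOverlap, tail: bool = False) -> float:
    """Hop p-value as a float in [0, 1]; see :func:`pair_pvalue_exact`."""
    return float(pair_pvalue_exact(overlap, tail=tail))


def hop_overlap(
    gene_a: str, gene_b: str, catalog: AnnotationCatalog
) -> PairOverlap:
    """Overlap configuration of one hop's two annotation sets."""
    a = catalog.terms(gene_a)
    b = catalog.terms(gene_b)
    return PairOverlap(len(a), len(b), len(a & b), catalog.universe_size)


def assign_pathways(
    rsp: Rsp, pathway_catalog: AnnotationCatalog, require_all: bool = True
) -> frozenset[str]:
    """Pathways associated with an RSP.

    By default a pathway qualifies only if its gene set contains all
    three genes of the path; with ``require_all=False`` membership of any
    one gene suffices.
    """
    sets = [pathway_catalog.terms(g) for g in rsp.genes]
    if require_all:
        return frozenset(sets[0] & sets[1] & sets[2])
    return frozenset(sets[0] | sets[1] | sets[2])


def score_rsp(
    rsp: Rsp,
    bp: AnnotationCatalog,
    mf: AnnotationCatalog,
    namespace: Namespace | str,
    pathway_catalog: AnnotationCatalog | None = None,
    tail: bool = False,
    pathway_require_all: bool = True,
) -> RspRecord | None:
    """Score one RSP; return ``None`` (discard) if not viable in ``namespace``.

    Both namespace Jaccard scores are always computed and reported; the
    viability gate and the hop p-values use the namespace selected for
    ranking.  The RSP p-value is the greater of the two hop p-values.
    """
    ns = Namespace(namespace)
    if ns not in (Namespace.BP, Namespace.MF):
        raise ValueError(f"scoring namespace must be BP or MF, got {ns}")
    sel = bp if ns is Namespace.BP else mf
    js_b, viable_b = js_score(rsp, bp)
    js_m, viable_m = js_score(rsp, mf)
    if not (viable_b if ns is Namespace.BP else viable_m):
        return None
    p1 = pair_pvalue(hop_overlap(rsp.target, rsp.g1, sel), tail=tail)
    p2 = pair_pvalue(hop_overlap(rsp.g1, rsp.g2, sel), tail=tail)
    pathways: frozenset[str] = frozenset()
    if pathway_catalog is not None:
        pathways = assign_pathways(rsp, pathway_catalog, require_all=pathway_require_all)
    return RspRecord(
        rsp=rsp,
        js_bp=js_b,
        js_mf=js_m,
        viable_bp=viable_b,
        viable_mf=viable_m,
        p1=p1,
        p2=p2,
        p_value=max(p1, p2),
        pathways=pathways,
    )
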