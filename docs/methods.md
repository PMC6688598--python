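# Methods

## Sub-pathway model

The unit of analysis is the target-specific regulatory sub-pathway (RSP):
an ordered gene triple (T, G1, G2) in which T is a miRNA target and both
T–G1 and G1–G2 are edges of an undirected PPI graph. Prefixed with the
regulating miRNA M it becomes an MRSP (M, T, G1, G2). Enumeration extends
two interaction levels from each target and is exhaustive; paths are simple
by default (G2 ≠ T — no published use of back-tracking paths exists, and a
triangle would otherwise count twice), with `allow_backtrack=True` available
for users who want closed walks. Output order is lexicographic by (G1, G2),
which, together with sorted writers everywhere, makes every run
byte-reproducible.

The biological assumption behind the scoring is that directly interacting
proteins tend to share biological processes (BP) and molecular functions
(MF). Each hop is scored by the Jaccard coefficient of the two genes' GO
term sets, and the RSP's Jaccard score JS is the arithmetic mean of its two
hop coefficients, computed per namespace. A zero coefficient on either hop
means the hop has no annotation support; such RSPs are non-viable and
discarded. JC of two empty sets is defined as 0 (hence non-viable) to avoid
0/0 — the gene simply has no annotation evidence. Genes present in the PPI
graph but absent from GO keep empty term sets rather than being dropped at
load time; the viability gate eliminates them without inventing a
pre-filter.

## Overlap p-value

For a hop whose genes carry x and y terms out of a namespace universe of N,
sharing n of them, the p-value is the hypergeometric point probability

    P = C(x, n) · C(N − x, y − n) / C(N, y)

This is implemented literally as the point mass, not a tail sum; an
optional upper-tail mode (`tail=True`, `--tail-pvalue`) sums k ≥ n for an
enrichment-style p-value. The equivalent triple-binomial form
C(N,n)·C(N−n,x−n)·C(N−x,y−n) / (C(N,x)·C(N,y)) is asserted equal on an
exhaustive grid in the tests (the identity C(N,n)C(N−n,x−n) = C(N,x)C(x,n)
makes the two algebraically identical). The RSP p-value is the larger of
its two hop p-values — a conservative "weakest hop" rule.

Arithmetic is exact: integer binomials via `math.comb` under
`fractions.Fraction`, converted to float only at the API boundary, so
normalization (Σₙ P = 1) holds exactly and no log-gamma approximation error
enters. Infeasible overlap configurations (n outside
[max(0, x+y−N), min(x, y)]) raise an error rather than returning 0, since
they indicate inconsistent inputs. Reported tables round to 6 significant
digits.

Viability and the hop p-values are evaluated in the namespace the user
selects for ranking (BP or MF); both JS values are always reported. No
multiple-testing correction is applied — the p-threshold is a raw cutoff on
per-RSP values, matching the interactive-filter semantics the pipeline
emulates.

## Queries, filters and network assembly

A query resolves its disease name case-insensitively after trimming (no
fuzzy matching); giving a miRNA id instead runs the identical machinery on
that single miRNA. Filters apply in a fixed order: target-level filters
first (validation evidence — at least one method among the selected
vocabulary, defaulting to the seven direct experimental methods; tissue
expression of the target), then RSP-level filters (p-threshold, tissue
expression of G1 and G2, cancer-tag requirement on the target or on all
three genes, containing-gene and pathway restriction), then top-N. Filters
before top-N is a deliberate choice where the order was open: top-N is a
display/size control and should see the final filtered ranking. The tissue
filter constrains all three path genes by default (`tissue_scope=
"target_only"` relaxes it): a tissue-specific network should not contain
genes unexpressed in the tissue.

Pathway association of an RSP requires all three genes to belong to the
pathway's gene set by default (`require_all=False` admits any-gene
membership); the all-three rule is the stricter reading and matches the
idea of the whole path being "part of" a pathway.

Ranking sorts by ascending p-value with deterministic tie-breaks: higher
selected-namespace JS first, then lexicographic (T, G1, G2), then miRNA.

The regulatory network contains one node per miRNA and per sub-pathway
gene, a regulation edge per (miRNA, target), and a PPI edge for every gene
pair of the network interacting in the source graph — the closure step —
so genes from different sub-pathways are linked whenever evidence exists.
Closure adds edges, never nodes. Comorbid genes of a disease pair are the
intersection of the two diseases' full gene sets (T, G1 and G2 all count:
two diseases with disjoint target sets can still share hundreds of
interactors, which is precisely the phenomenon of interest), annotated
with cancer tags and pathway memberships.

## Synthetic fixtures

The generator emulates the seven input tables with controllable sizes:
defaults are 500 background genes, Erdős–Rényi PPI edges at density 0.016
(~2000 expected edges), 150 BP / 100 MF terms with 2–6 terms per gene
drawn uniformly without replacement, 20 pathways of 10–30 genes, 4
diseases × 3 miRNAs × 3 targets, 5 tissues, and a 0.2 cancer-tag fraction.
Correlation between interaction and annotation — the signal the Jaccard
score rewards — enters only through `edge_overlap_boost` (default 0.3),
the probability that an interacting pair is given one extra shared term;
this keeps expected JC values easy to reason about. Each table draws from
its own random stream derived from the master seed, so adding a table
never perturbs the others, and a given seed yields byte-identical files.

Planted structures are injected after background sampling on reserved gene
names excluded from all background draws, so their presence and their
overlap counts are guaranteed, hand-checkable, and recorded in a manifest:
one viable sub-pathway and one zero-Jaccard decoy under a planted miRNA of
the first disease, and a disease pair whose planted sub-pathways share
exactly two branch genes. All planted term chains use x = y = z = 3 terms
with n1 = n2 = 2 shared, so each hop JC is 2/4 = 0.5 and JS = 0.5 in both
namespaces. `expected_scores` recomputes JS and the p-values directly from
the manifest's (x, y, z, n1, n2, N) counts, independent of the pipeline,
and serves as the recovery oracle.

What the fixtures do **not** emulate: real PPI degree distributions
(scale-free hubs), the GO DAG (terms are flat labels, as the scoring
itself assumes), annotation depth bias, or database-release idiosyncrasies.
Passing recovery tests therefore demonstrates correctness of the
computation, not biological performance on real HMDD/TarBase/BioGRID-scale
data, whose headline counts depend on specific releases and are out of
scope.

## Problem sizes and limitations

The default test fixture (500 genes, ~2000 edges) loads and queries in
well under a second; exhaustive verification grids (N ≤ 12 for
normalization and the binomial identity, N ≤ 8 for subset enumeration,
50 random graphs ≤ 30 nodes for the path oracle) each run in seconds.
Enumeration cost grows with the sum over targets of Σ deg(G1) over their
neighbours, i.e. quadratically in dense neighbourhoods; at real-database
scale (millions of RSPs) the per-target loop is still linear in the output
and memory-bounded by the retained records, but no out-of-core storage is
provided. Direction flags of target evidence are stored and exported but
not used as a filter; source reconciliation between association databases
is left to the data preparer.
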