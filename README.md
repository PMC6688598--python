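# rspnet

Construction and scoring of **miRNA regulatory sub-pathway networks** from
protein–protein interaction (PPI) data.

A miRNA regulates a target gene T; the encoded protein interacts with a
protein G1, which interacts with a protein G2. `rspnet` enumerates every such
ordered triple (T, G1, G2) — a *regulatory sub-pathway* (RSP) — from an
undirected PPI graph, scores it with GO-annotation overlap statistics, and
assembles disease- and tissue-specific miRNA–protein regulatory networks,
including comorbid-gene analysis for disease pairs. It is aimed at systems
biologists who want this pipeline scriptable and reproducible offline, on
plain-text tables, without a hosted database.

## Model

Let `[G]_X` be the set of GO terms of namespace X ∈ {BP, MF} annotating gene
G, and N the number of distinct terms in the namespace. For an RSP
(T, G1, G2):

- **Jaccard score** — with JC(S1, S2) = |S1 ∩ S2| / |S1 ∪ S2|,

  `JS_X(T, G1, G2) = ½ · ( JC([T]_X, [G1]_X) + JC([G1]_X, [G2]_X) )`

  An RSP with either hop-wise JC equal to zero is *not viable* and is
  discarded.

- **p-value** — for a hop with annotation-set sizes x and y sharing n terms,
  the exact hypergeometric point probability

  `P = C(x, n) · C(N − x, y − n) / C(N, y)`

  computed in rational arithmetic; the RSP p-value is max(P1, P2) over its
  two hops. An upper-tail (enrichment-style) variant is available behind a
  flag.

A disease query collects the disease's miRNAs and validated targets,
retains each target's viable RSPs under the chosen p-threshold and filters
(tissue, validation method, cancer-gene tags, pathway/gene restriction,
top-N), and assembles the network: miRNA→target regulation edges plus **all**
PPI edges among the selected genes (closure). For a disease pair, the
*comorbid genes* are the intersection of the two diseases' sub-pathway gene
sets (T, G1 and G2 positions all count).

## Worked example

```sh
python examples/score_sub_pathway.py
```

```
sub-pathway: TP53 -> MDM2 -> UBE2D1
JS_BP  = 0.5000   (mean of the two hop-wise Jaccard coefficients)
P1     = 0.214286   (T-G1 overlap probability, universe N=9)
P2     = 0.214286   (G1-G2 overlap probability)
p      = 0.214286   (the greater of P1 and P2)
```

Each hop shares 2 of 4 terms, so both JC values are 2/4 = 0.5 and JS = 0.5;
with only N = 9 terms in the universe, an overlap of 2 is unremarkable
(p ≈ 0.21). `examples/single_disease_network.py` and
`examples/comorbidity.py` run the two full query workflows on a generated
bundle, e.g.:

```
disease: disease_01
miRNAs: 4, targets: 11
sub-pathways: 559 enumerated -> 154 viable -> 3 passing p <= 0.05
network: 12 nodes, 9 edges
```

## Command line

```sh
rspnet genfixture --outdir data --seed 7
rspnet single   --config data/config.yaml --disease disease_01 --pvalue 0.05
rspnet comorbid --config data/config.yaml \
    --disease "comorbid disease A" --disease2 "comorbid disease B" --pvalue 0.05
```

Every run writes a `report.yaml` (query echo, per-stage counts, outputs)
plus the requested exports: ranked `rsps.tsv`, node attribute table,
`network.sif` / `network.graphml` / `network.json` (Cytoscape-compatible),
and `comorbid_genes.tsv` for pair queries.

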