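"""Seeded synthetic dataset bundles with planted, hand-checkable structure.

The generator emulates the input tables a miRNA-network study integrates
— disease–miRNA associations, miRNA targets with validation evidence, a
random PPI graph, GO BP/MF and pathway gene sets, tissue labels and
cancer tags — with controllable sizes and overlap structure, and plants:

* one *viable* sub-pathway (PLT_T, PLT_G1, PLT_G2) with dedicated term
  sets giving hop overlaps x = y = z = 3, n1 = n2 = 2 in both namespaces
  (each hop-wise Jaccard coefficient is 2/4 = 0.5, so JS = 0.5);
* one zero-Jaccard *decoy* path whose middle gene shares no term with
  the target in either namespace, which scoring must discard;
* a disease pair whose planted sub-pathways share exactly the branch
  genes {SHR_G1, SHR_G2}, for comorbidity recovery.

Planted genes are reserved out of all background sampling, so the
manifest's expectations are exact.  Each table draws from its own
pseudo-random stream derived from the master seed, so adding a table
never perturbs the others, and a given seed yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
import yaml

# reserved identifiers of the planted structures
PLANT_SINGLE = ("PLT_T", "PLT_G1", "PLT_G2")
PLANT_DECOY = ("DCY_T", "DCY_G1", "DCY_G2")
PLANT_CO_A = ("CMA_T", "CMA_G1")
PLANT_CO_B = ("CMB_T", "CMB_G1")
SHARED_BRANCH = ("SHR_G1", "SHR_G2")
RESERVED_GENES = PLANT_SINGLE + PLANT_DECOY + PLANT_CO_A + PLANT_CO_B + SHARED_BRANCH

PLANT_MIRNA_SINGLE = "hsa-miR-9001"
PLANT_MIRNA_CO_A = "hsa-miR-9002"
PLANT_MIRNA_CO_B = "hsa-miR-9003"
CO_DISEASE_A = "comorbid disease A"
CO_DISEASE_B = "comorbid disease B"
PLANT_PATHWAY = "PW_PLANT"


@dataclass(frozen=True)
class FixtureSpec:
    """Sizes and probabilities controlling fixture generation."""

    seed: int = 0
    n_genes: int = 500
    n_terms_bp: int = 150
    n_terms_mf: int = 100
    n_pathways: int = 20
    ppi_density: float = 0.016  # ~2000 expected edges at 500 genes
    terms_per_gene: tuple[int, int] = (2, 6)
    edge_overlap_boost: float = 0.3
    n_diseases: int = 4
    mirnas_per_disease: int = 3
    targets_per_mirna: int = 3
    n_tissues: int = 5
    cancer_tag_fraction: float = 0.2

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_terms_bp": self.n_terms_bp,
            "n_terms_mf": self.n_terms_mf,
            "n_pathways": self.n_pathways,
            "n_diseases": self.n_diseases,
            "mirnas_per_disease": self.mirnas_per_disease,
            "targets_per_mirna": self.targets_per_mirna,
            "n_tissues": self.n_tissues,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")
        for name, p in {
            "ppi_density": self.ppi_density,
            "edge_overlap_boost": self.edge_overlap_boost,
            "cancer_tag_fraction": self.cancer_tag_fraction,
        }.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.terms_per_gene
        if not (1 <= lo <= hi):
            raise ValueError(f"terms_per_gene range invalid: {self.terms_per_gene}")
        if hi > min(self.n_terms_bp, self.n_terms_mf):
            raise ValueError(
                f"terms_per_gene upper bound {hi} exceeds term pool size "
                f"{min(self.n_terms_bp, self.n_terms_mf)}"
            )
        if self.n_genes < 20:
            raise ValueError("n_genes must be >= 20 to leave room for background")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), stream])


def _planted_term_sets(prefix: str) -> dict[str, list[str]]:
    """Dedicated chained term sets: x=y=z=3, n1=n2=2, each JC = 0.5."""
    t = [f"{prefix}{i}" for i in range(1, 6)]
    return {"T": t[0:3], "G1": t[1:4], "G2": t[2:5]}


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _write_gmt(path: Path, term_genes: dict[str, list[str]], desc: str) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for term in sorted(term_genes):
            fh.write("\t".join([term, desc] + sorted(term_genes[term])) + "\n")


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write the seven input tables, a config and a ground-truth manifest.

    Returns the manifest (also written as ``manifest.yaml``).  Identical
    specs produce byte-identical directories.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]
    bp_terms = [f"BP{i:04d}" for i in range(1, spec.n_terms_bp + 1)]
    mf_terms = [f"MF{i:04d}" for i in range(1, spec.n_terms_mf + 1)]
    tissues = [f"tissue_{i:02d}" for i in range(1, spec.n_tissues + 1)]
    diseases = [f"disease_{i:02d}" for i in range(1, spec.n_diseases + 1)]

    # --- PPI background (stream 1) + planted edges -------------------------
    rng = _rng(spec, 1)
    edges: set[tuple[str, str]] = set()
    n = len(genes)
    # vectorised Bernoulli draw over the upper triangle
    probs = rng.random(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if probs[k] < spec.ppi_density:
                edges.add((genes[i], genes[j]))
            k += 1
    planted_edges = [
        (PLANT_SINGLE[0], PLANT_SINGLE[1]),
        (PLANT_SINGLE[1], PLANT_SINGLE[2]),
        (PLANT_DECOY[0], PLANT_DECOY[1]),
        (PLANT_DECOY[1], PLANT_DECOY[2]),
        (PLANT_CO_A[0], PLANT_CO_A[1]),
        (PLANT_CO_A[1], SHARED_BRANCH[0]),
        (PLANT_CO_A[1], SHARED_BRANCH[1]),
        (PLANT_CO_B[0], PLANT_CO_B[1]),
        (PLANT_CO_B[1], SHARED_BRANCH[0]),
        (PLANT_CO_B[1], SHARED_BRANCH[1]),
    ]
    edges.update(tuple(sorted(e)) for e in planted_edges)

    # --- term assignment (streams 2, 3) ------------------------------------
    def assign_terms(pool: list[str], stream: int) -> dict[str, set[str]]:
        r = _rng(spec, stream)
        lo, hi = spec.terms_per_gene
        sets: dict[str, set[str]] = {}
        for g in genes:
            size = int(r.integers(lo, hi + 1))
            sets[g] = set(r.choice(pool, size=size, replace=False).tolist())
        # interacting pairs share a term with probability edge_overlap_boost
        for a, b in sorted(edges):
            if a in sets and b in sets and r.random() < spec.edge_overlap_boost:
                shared = str(r.choice(pool))
                sets[a].add(shared)
                sets[b].add(shared)
        return sets

    bp_sets = assign_terms(bp_terms, 2)
    mf_sets = assign_terms(mf_terms, 3)

    # planted term sets override background entirely (dedicated terms)
    bp_p = _planted_term_sets("BPP")
    mf_p = _planted_term_sets("MFP")
    for role, gene in zip(("T", "G1", "G2"), PLANT_SINGLE):
        bp_sets[gene] = set(bp_p[role])
        mf_sets[gene] = set(mf_p[role])
    # both comorbidity sides use one common term chain, so every planted
    # (T, G1, SHR_*) path carries the same x=y=z=3, n1=n2=2 overlaps
    bp_c = _planted_term_sets("BPC")
    mf_c = _planted_term_sets("MFC")
    for t, g1 in (PLANT_CO_A, PLANT_CO_B):
        bp_sets[t], mf_sets[t] = set(bp_c["T"]), set(mf_c["T"])
        bp_sets[g1], mf_sets[g1] = set(bp_c["G1"]), set(mf_c["G1"])
    for shr in SHARED_BRANCH:
        bp_sets[shr], mf_sets[shr] = set(bp_c["G2"]), set(mf_c["G2"])
    # decoy: middle gene disjoint from target in both namespaces
    bp_sets[PLANT_DECOY[0]] = {"BPD1", "BPD2"}
    bp_sets[PLANT_DECOY[1]] = {"BPD3", "BPD4"}
    bp_sets[PLANT_DECOY[2]] = {"BPD3", "BPD4"}
    mf_sets[PLANT_DECOY[0]] = {"MFD1", "MFD2"}
    mf_sets[PLANT_DECOY[1]] = {"MFD3", "MFD4"}
    mf_sets[PLANT_DECOY[2]] = {"MFD3", "MFD4"}

    # --- pathways (stream 4) ------------------------------------------------
    r4 = _rng(spec, 4)
    pathway_genes: dict[str, list[str]] = {}
    for i in range(1, spec.n_pathways + 1):
        size = int(r4.integers(10, 31))
        pathway_genes[f"PW{i:03d}"] = sorted(
            r4.choice(genes, size=min(size, len(genes)), replace=False).tolist()
        )
    extra = sorted(r4.choice(genes, size=3, replace=False).tolist())
    pathway_genes[PLANT_PATHWAY] = sorted(list(PLANT_SINGLE) + extra)

    # --- diseases / miRNAs / targets (stream 5) -----------------------------
    r5 = _rng(spec, 5)
    disease_rows: list[list[str]] = []
    target_rows: list[list[str]] = []
    methods_pool = [
        "HITS-CLIP", "PAR-CLIP", "CLASH", "Luciferase Reporter Assay",
        "Genetic Testing", "Microarray", "Western Blot", "qRT-PCR",
    ]
    mirna_counter = 0
    for disease in diseases:
        for _ in range(spec.mirnas_per_disease):
            mirna_counter += 1
            mirna = f"hsa-miR-{mirna_counter:04d}"
            disease_rows.append([disease, mirna, f"PMID:{10000 + mirna_counter}"])
            targets = r5.choice(genes, size=spec.targets_per_mirna, replace=False)
            for t in sorted(targets.tolist()):
                meths = r5.choice(
                    methods_pool, size=int(r5.integers(1, 4)), replace=False
                )
                direction = "positive" if r5.random() < 0.8 else "negative"
                target_rows.append([mirna, t, ";".join(sorted(meths.tolist())), direction])
    # planted associations
    disease_rows.append([diseases[0], PLANT_MIRNA_SINGLE, "PMID:90001"])
    target_rows.append(
        [PLANT_MIRNA_SINGLE, PLANT_SINGLE[0], "Luciferase Reporter Assay", "positive"]
    )
    target_rows.append([PLANT_MIRNA_SINGLE, PLANT_DECOY[0], "HITS-CLIP", "positive"])
    disease_rows.append([CO_DISEASE_A, PLANT_MIRNA_CO_A, "PMID:90002"])
    target_rows.append(
        [PLANT_MIRNA_CO_A, PLANT_CO_A[0], "Luciferase Reporter Assay", "positive"]
    )
    disease_rows.append([CO_DISEASE_B, PLANT_MIRNA_CO_B, "PMID:90003"])
    target_rows.append(
        [PLANT_MIRNA_CO_B, PLANT_CO_B[0], "Luciferase Reporter Assay", "positive"]
    )

    # --- tissues (stream 6) and cancer tags (stream 7) ----------------------
    r6 = _rng(spec, 6)
    tissue_rows: list[list[str]] = []
    for g in genes:
        k = int(r6.integers(1, min(4, spec.n_tissues + 1)))
        for t in sorted(r6.choice(tissues, size=k, replace=False).tolist()):
            tissue_rows.append([g, t])
    for g in RESERVED_GENES:  # planted genes expressed everywhere
        for t in tissues:
            tissue_rows.append([g, t])

    r7 = _rng(spec, 7)
    tag_rows: list[list[str]] = []
    for g in genes:
        if r7.random() < spec.cancer_tag_fraction:
            tag_rows.append([g, str(r7.choice(["CRG", "OCG", "TSG"]))])
    tag_rows.append([PLANT_SINGLE[0], "CRG"])
    tag_rows.append([PLANT_CO_A[0], "CRG"])
    tag_rows.append([PLANT_CO_B[0], "CRG"])
    tag_rows.append([SHARED_BRANCH[0], "OCG"])

    # --- write files ---------------------------------------------------------
    def invert(sets: dict[str, set[str]]) -> dict[str, list[str]]:
        inv: dict[str, set[str]] = {}
        for g, ts in sets.items():
            for t in ts:
                inv.setdefault(t, set()).add(g)
        return {t: sorted(gs) for t, gs in inv.items()}

    _write_gmt(outdir / "go_bp.gmt", invert(bp_sets), "synthetic BP term")
    _write_gmt(outdir / "go_mf.gmt", invert(mf_sets), "synthetic MF term")
    _write_gmt(outdir / "pathways.gmt", pathway_genes, "synthetic pathway")
    _write_tsv(
        outdir / "ppi.tsv", ["gene_a", "gene_b"], [list(e) for e in sorted(edges)]
    )
    _write_tsv(outdir / "disease_mirna.tsv", ["disease", "mirna", "source"], disease_rows)
    _write_tsv(
        outdir / "mirna_target.tsv", ["mirna", "gene", "methods", "direction"], target_rows
    )
    _write_tsv(outdir / "tissue.tsv", ["gene", "tissue"], tissue_rows)
    _write_tsv(outdir / "cancer_tags.tsv", ["gene", "tag"], tag_rows)

    # universe sizes as the loader will see them
    n_bp = len(set().union(*bp_sets.values()))
    n_mf = len(set().union(*mf_sets.values()))

    def overlaps(triple: tuple[str, str, str]) -> dict:
        out = {}
        for ns, sets, universe in (("BP", bp_sets, n_bp), ("MF", mf_sets, n_mf)):
            t, g1, g2 = (sets[g] for g in triple)
            out[ns] = {
                "x": len(t), "y": len(g1), "z": len(g2),
                "n1": len(t & g1), "n2": len(g1 & g2), "N": universe,
            }
        return out

    manifest = {
        "seed": spec.seed,
        "counts": {
            "n_genes": len(genes) + len(RESERVED_GENES),
            "n_background_genes": len(genes),
            "n_ppi_edges": len(edges),
            "n_diseases": len(diseases) + 2,
            "n_mirnas": mirna_counter + 3,
            "bp_universe": n_bp,
            "mf_universe": n_mf,
            "n_pathways": len(pathway_genes),
        },
        "single_disease": diseases[0],
        "comorbid_pair": [CO_DISEASE_A, CO_DISEASE_B],
        "planted_rsps": [
            {
                "disease": diseases[0],
                "mirna": PLANT_MIRNA_SINGLE,
                "target": PLANT_SINGLE[0],
                "g1": PLANT_SINGLE[1],
                "g2": PLANT_SINGLE[2],
                "overlaps": overlaps(PLANT_SINGLE),
                "pathway": PLANT_PATHWAY,
            },
            {
                "disease": CO_DISEASE_A,
                "mirna": PLANT_MIRNA_CO_A,
                "target": PLANT_CO_A[0],
                "g1": PLANT_CO_A[1],
                "g2": SHARED_BRANCH[0],
                "overlaps": overlaps((PLANT_CO_A[0], PLANT_CO_A[1], SHARED_BRANCH[0])),
            },
            {
                "disease": CO_DISEASE_A,
                "mirna": PLANT_MIRNA_CO_A,
                "target": PLANT_CO_A[0],
                "g1": PLANT_CO_A[1],
                "g2": SHARED_BRANCH[1],
                "overlaps": overlaps((PLANT_CO_A[0], PLANT_CO_A[1], SHARED_BRANCH[1])),
            },
            {
                "disease": CO_DISEASE_B,
                "mirna": PLANT_MIRNA_CO_B,
                "target": PLANT_CO_B[0],
                "g1": PLANT_CO_B[1],
                "g2": SHARED_BRANCH[0],
                "overlaps": overlaps((PLANT_CO_B[0], PLANT_CO_B[1], SHARED_BRANCH[0])),
            },
            {
                "disease": CO_DISEASE_B,
                "mirna": PLANT_MIRNA_CO_B,
                "target": PLANT_CO_B[0],
                "g1": PLANT_CO_B[1],
                "g2": SHARED_BRANCH[1],
                "overlaps": overlaps((PLANT_CO_B[0], PLANT_CO_B[1], SHARED_BRANCH[1])),
            },
        ],
        "planted_decoys": [
            {
                "disease": diseases[0],
                "mirna": PLANT_MIRNA_SINGLE,
                "target": PLANT_DECOY[0],
                "g1": PLANT_DECOY[1],
                "g2": PLANT_DECOY[2],
            }
        ],
        "comorbid_shared_genes": sorted(SHARED_BRANCH),
        "recommended_query": {"namespace": "MF", "p_threshold": 0.05},
    }
    with (outdir / "manifest.yaml").open("w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    config = {
        "paths": {
            "bp_gmt": "go_bp.gmt",
            "mf_gmt": "go_mf.gmt",
            "pathway_gmt": "pathways.gmt",
            "ppi": "ppi.tsv",
            "disease_mirna": "disease_mirna.tsv",
            "mirna_target": "mirna_target.tsv",
            "tissue": "tissue.tsv",
            "cancer_tags": "cancer_tags.tsv",
        },
        "defaults": {"namespace": "MF", "p_threshold": 0.05},
    }
    with (outdir / "config.yaml").open("w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return manifest


def _point_pvalue(x: int, y: int, n: int, N: int) -> float:
    """Independent reference: hypergeometric point mass, direct Fractions."""
    return float(Fraction(comb(x, n) * comb(N - x, y - n), comb(N, y)))


def expected_scores(manifest: dict) -> list[dict]:
    """Reference scores for each planted sub-pathway, from manifest counts only.

    Computed directly from the recorded (x, y, z, n1, n2, N) overlap
    configurations without touching the enumeration/scoring pipeline;
    used as the parameter-recovery oracle.
    """
    out = []
    for rsp in manifest["planted_rsps"]:
        entry = {k: rsp[k] for k in ("mirna", "target", "g1", "g2")}
        for ns, ov in rsp["overlaps"].items():
            x, y, z = ov["x"], ov["y"], ov["z"]
            n1, n2, N = ov["n1"], ov["n2"], ov["N"]
            jc1 = n1 / (x + y - n1)
            jc2 = n2 / (y + z - n2)
            p1 = _point_pvalue(x, y, n1, N)
            p2 = _point_pvalue(y, z, n2, N)
            entry[ns] = {
                "js": (jc1 + jc2) / 2.0,
                "p1": p1,
                "p2": p2,
                "p": max(p1, p2),
            }
        out.append(entry)
    return out
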