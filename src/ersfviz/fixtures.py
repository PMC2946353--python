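"""Packaged toy inputs: the reference ontology graphs and synthetic data.

``make_g1`` builds the small reference tree used throughout the docs and
tests: eight leaf pathways under five categories.  ``make_g2`` adds four
non-tree edges to it, making four nodes multi-parented, which exercises
the orbit/downlink machinery; two of those edges (C over AA1 and AA2) are
fixed, the other two are a synthetic completion chosen so that orbits
land on two different layers.  ``synth_expression`` draws a reproducible
gene x condition matrix with known additive effects on chosen terms, and
``synth_pathway`` builds small typed pathway graphs (a metabolic cycle
with catalysing proteins, or a signalling hub) for the tiered layout.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .ontology import OntologyGraph
from .stats import ExpressionMatrix, write_annotation
from .tiered import PathwayGraph

#: baseline expression level (log2-like scale) and gene-level noise sd
MU0 = 8.0
SIGMA0 = 0.5

G1_EDGES: list[tuple[str, str]] = [
    ("R", "A"),
    ("R", "B"),
    ("R", "C"),
    ("A", "AA"),
    ("A", "A1"),
    ("A", "A2"),
    ("AA", "AA1"),
    ("AA", "AA2"),
    ("B", "B1"),
    ("B", "B2"),
    ("C", "C1"),
    ("C", "C2"),
]

#: the four non-tree edges of G2; G1 edges come first so that first-listed
#: major-parent selection keeps the original tree parents as major parents
#: and C as the minor parent of both AA1 and AA2
G2_EXTRA_EDGES: list[tuple[str, str]] = [
    ("C", "AA1"),
    ("C", "AA2"),
    ("B", "C1"),
    ("A", "B1"),
]


def make_g1() -> OntologyGraph:
    """The pure-tree fixture: 13 nodes, 12 edges, root R, 8 leaves."""
    return OntologyGraph(edges=list(G1_EDGES))


def make_g2() -> OntologyGraph:
    """G1 plus four non-tree edges; 4 nodes gain a second (minor) parent."""
    return OntologyGraph(edges=list(G1_EDGES) + list(G2_EXTRA_EDGES))


# ---------------------------------------------------------------------------
# Synthetic expression data
# ---------------------------------------------------------------------------

def synth_expression(
    n_genes: int = 800,
    conditions: list[str] | None = None,
    effect: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    mu0: float = MU0,
    sigma0: float = SIGMA0,
) -> tuple[ExpressionMatrix, dict[str, set[str]]]:
    """Generate an expression matrix with known effects, plus annotations.

    Genes are assigned uniformly (round-robin) to the eight leaves of the
    G2 fixture.  Every value is drawn i.i.d. Normal(mu0, sigma0); the
    ``effect`` spec ``{node: {condition: shift}}`` adds the shift to the
    named node's genes in the named condition.  Fully reproducible for a
    given seed.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    conditions = ["control", "treatment"] if conditions is None else list(conditions)
    effect = {} if effect is None else effect

    leaves = sorted(make_g2().leaves)
    unknown = sorted(set(effect) - set(leaves))
    if unknown:
        raise ValueError(f"effect spec names unknown leaf node(s): {unknown}")
    for node, shifts in effect.items():
        bad = sorted(set(shifts) - set(conditions))
        if bad:
            raise ValueError(f"effect on {node!r} names unknown condition(s): {bad}")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    annotation: dict[str, set[str]] = {leaf: set() for leaf in leaves}
    gene_leaf: dict[str, str] = {}
    for i, gene in enumerate(genes):
        leaf = leaves[i % len(leaves)]
        annotation[leaf].add(gene)
        gene_leaf[gene] = leaf

    values = rng.normal(mu0, sigma0, size=(n_genes, len(conditions)))
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=conditions)
    for node, shifts in effect.items():
        rows = [g for g in genes if gene_leaf[g] == node]
        for cond, shift in shifts.items():
            df.loc[rows, cond] += shift
    return ExpressionMatrix(values=df), annotation


# ---------------------------------------------------------------------------
# Synthetic pathway graphs
# ---------------------------------------------------------------------------

def synth_pathway(kind: str = "cycle", n: int = 6) -> PathwayGraph:
    """Small typed pathway graphs for the tiered layout.

    ``cycle``: ``n`` metabolites in a ring, with ceil(n/2) proteins each
    catalysing one ring reaction (linked to its two substrate
    metabolites) and one RNA and one DNA beneath each protein — the
    central-dogma column under the metabolic flow.

    ``signaling``: one hub metabolite regulating ``n`` proteins, each
    translated from one RNA — a star that stresses the alignment of many
    nodes onto one anchor.
    """
    if n < 3:
        raise ValueError("n must be at least 3")
    node_types: dict[str, str] = {}
    edges: list[tuple[str, str, str]] = []

    if kind == "cycle":
        mets = [f"M{i + 1}" for i in range(n)]
        for m in mets:
            node_types[m] = "metabolite"
        for i, m in enumerate(mets):
            edges.append((m, mets[(i + 1) % n], "conversion"))
        n_prot = math.ceil(n / 2)
        for j in range(n_prot):
            protein, rna, dna = f"P{j + 1}", f"RNA{j + 1}", f"DNA{j + 1}"
            node_types[protein] = "polypeptide"
            node_types[rna] = "RNA"
            node_types[dna] = "DNA"
            a, b = mets[(2 * j) % n], mets[(2 * j + 1) % n]
            edges.append((protein, a, "catalysis"))
            edges.append((protein, b, "catalysis"))
            edges.append((rna, protein, "translation"))
            edges.append((dna, rna, "transcription"))
    elif kind == "signaling":
        node_types["HUB"] = "metabolite"
        for j in range(n):
            protein, rna = f"P{j + 1}", f"RNA{j + 1}"
            node_types[protein] = "polypeptide"
            node_types[rna] = "RNA"
            edges.append(("HUB", protein, "regulation"))
            edges.append((rna, protein, "translation"))
    else:
        raise ValueError(f"unknown pathway kind {kind!r}")
    return PathwayGraph(node_types=node_types, edges=edges)


# ---------------------------------------------------------------------------
# On-disk fixture emission
# ---------------------------------------------------------------------------

def write_fixtures(out_dir: str | Path, seed: int = 0, n_genes: int = 800) -> list[Path]:
    """Write every packaged fixture to ``out_dir`` in its standard format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .ontology import write_edge_list

    written = []
    for name, graph in (("g1.tsv", make_g1()), ("g2.tsv", make_g2())):
        write_edge_list(graph, out / name)
        written.append(out / name)

    matrix, annotation = synth_expression(
        n_genes=n_genes,
        conditions=["control", "treatment"],
        effect={"C1": {"treatment": 2.0}},
        seed=seed,
    )
    matrix.write_csv(out / "expr.csv")
    write_annotation(annotation, out / "annotation.tsv")
    synth_pathway("cycle", 6).write_tsv(out / "pathway.tsv")
    written += [out / "expr.csv", out / "annotation.tsv", out / "pathway.tsv"]
    return written
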