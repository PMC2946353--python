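"""Map gene-level experimental values onto ontology terms and into style.

Every region of the sunburst stands for a term that owns a set of genes
(direct annotations plus everything annotated below it in the tree), so
per-term summaries — mean or median expression, the coefficient of
variation CoV = sigma/mu (population sigma), counts of differentially
expressed genes, or a one-sided Fisher/hypergeometric overrepresentation
p-value — can be encoded as region color, extrusion height, and
transparency, and a series of conditions becomes an animation, one frame
per condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .ontology import SpanningTree

logger = logging.getLogger("ersfviz")

RGBA = tuple[float, float, float, float]

#: default differential-expression threshold on the value change,
#: the default suggested by bench biologists for log-scale data
DE_THRESHOLD = 0.7
#: regions with fewer DE genes than this are left transparent
MIN_DE = 5
GREY: RGBA = (0.5, 0.5, 0.5, 1.0)


class DataError(ValueError):
    """Raised for inconsistent expression/annotation input."""


@dataclass
class ExpressionMatrix:
    """Gene x condition table of expression values.

    ``values`` is a DataFrame indexed by gene id with one column per
    condition, on whatever scale the user supplies (feed log-scale data
    for fold-change semantics of the DE threshold).  Missing values are
    NaN and are excluded pairwise from all summaries.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()])
            raise DataError(f"duplicate gene ids: {dupes}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ExpressionMatrix":
        """Read the expression CSV: first column ``gene``, then conditions."""
        df = pd.read_csv(path, na_values=["NA", ""])
        if df.columns[0] != "gene":
            raise DataError(f"{Path(path).name}: first column must be 'gene'")
        return cls(values=df.set_index("gene"))

    def write_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="gene")


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a ``node_id<TAB>gene_id`` TSV into node -> gene-set form."""
    out: dict[str, set[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(
                    f"{Path(path).name}:{lineno}: expected 'node_id<TAB>gene_id'"
                )
            if parts == ["node_id", "gene_id"]:
                continue
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_annotation(annotation: dict[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("node_id\tgene_id\n")
        for node in sorted(annotation):
            for gene in sorted(annotation[node]):
                fh.write(f"{node}\t{gene}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain gene list (one id per line) for the Fisher workflow."""
    with Path(path).open(encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


@dataclass
class NodeStats:
    """Per-term aggregates over its gene set."""

    node: str
    n_genes: int
    mean: dict[str, float] = field(default_factory=dict)  # per condition
    median: dict[str, float] = field(default_factory=dict)
    cov: float | None = None
    n_up: int = 0
    n_down: int = 0
    p_value: float | None = None

    @property
    def n_de(self) -> int:
        return self.n_up + self.n_down


@dataclass
class NodeStyle:
    fill: RGBA
    height: float
    visible: bool = True


#: StyleMap: node id -> NodeStyle
StyleMap = dict[str, NodeStyle]


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_gene_sets(
    annotation: dict[str, set[str]], tree: SpanningTree
) -> dict[str, set[str]]:
    """Propagate annotations up the spanning tree by set union.

    A term's gene set is its direct annotations united with all of its
    tree descendants' sets — a union, not a multiset, so a gene shared by
    two child pathways counts once in the parent.
    """
    unknown = sorted(set(annotation) - tree.nodes)
    if unknown:
        raise DataError(f"annotations to unknown node ids: {unknown}")

    sets: dict[str, set[str]] = {}

    def collect(node: str) -> set[str]:
        if node not in sets:
            genes = set(annotation.get(node, ()))
            for child in tree.tree_children(node):
                genes |= collect(child)
            sets[node] = genes
        return sets[node]

    collect(tree.root)
    return sets


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def compute_cov(values) -> float | None:
    """Population coefficient of variation, sigma/mu with divisor N.

    Undefined (returns None, logged) when the mean is zero or negative:
    the formula is literal sigma/mu and a non-positive mean makes the
    ratio meaningless for expression data.  NaNs are excluded.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return None
    mu = x.mean()
    if mu <= 0:
        logger.warning("CoV undefined for non-positive mean %.4g", mu)
        return None
    return float(x.std(ddof=0) / mu)


def classify_differential(
    control: float, treatment: float, threshold: float = DE_THRESHOLD
) -> str:
    """Classify one gene as ``up`` / ``down`` / ``unchanged``.

    A gene is differentially expressed when the value change is strictly
    more than the threshold; it is down-regulated when the treatment value
    is lower, otherwise up-regulated.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if control is None or treatment is None or math.isnan(control) or math.isnan(treatment):
        logger.debug("missing value in DE classification; treated as unchanged")
        return "unchanged"
    delta = treatment - control
    if abs(delta) > threshold:
        return "up" if delta > 0 else "down"
    return "unchanged"


def fisher_overrepresentation(
    selected: set[str], node_genes: set[str], universe: set[str]
) -> float:
    """One-sided overrepresentation p-value, P(X >= k) hypergeometric.

    Drawing ``|selected|`` genes from a universe containing
    ``|node_genes|`` successes, the p-value is the upper tail at the
    observed overlap k — the one-sided Fisher's exact test on the 2x2
    membership table.
    """
    if not universe:
        raise DataError("empty gene universe")
    if not node_genes <= universe or not selected <= universe:
        raise DataError("selected and node gene sets must be subsets of the universe")
    k = len(selected & node_genes)
    return float(hypergeom.sf(k - 1, len(universe), len(node_genes), len(selected)))


def adjust_p_values(p_values: dict[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg FDR adjustment of per-term p-values.

    An opt-in extension: raw Fisher p-values are reported by default, and
    this converts them to q-values when many terms are tested at once.
    """
    from statsmodels.stats.multitest import multipletests

    keys = sorted(k for k, v in p_values.items() if v is not None)
    if not keys:
        return {}
    _, q, _, _ = multipletests([p_values[k] for k in keys], method="fdr_bh")
    return dict(zip(keys, (float(x) for x in q)))


def compute_node_stats(
    gene_sets: dict[str, set[str]],
    matrix: ExpressionMatrix,
    condition_pair: tuple[str, str] | None = None,
    threshold: float = DE_THRESHOLD,
    selected: set[str] | None = None,
) -> dict[str, NodeStats]:
    """Compute per-term summaries for every node with a gene set.

    Per condition: mean and median over the node's genes present in the
    matrix.  The CoV is the average over genes of each gene's CoV across
    conditions.  Given a ``condition_pair`` (control, treatment), genes
    are classified into up/down/unchanged at ``threshold``.  Given a
    ``selected`` gene list, a Fisher overrepresentation p-value is
    computed against the universe of genes in the matrix.
    """
    universe = set(matrix.genes)
    absent = sorted(set().union(*gene_sets.values()) - universe) if gene_sets else []
    if absent:
        logger.info("%d annotated gene(s) absent from the expression matrix", len(absent))

    out: dict[str, NodeStats] = {}
    for node, genes in gene_sets.items():
        present = sorted(genes & universe)
        sub = matrix.values.loc[present]
        stats = NodeStats(node=node, n_genes=len(present))
        for cond in matrix.conditions:
            col = sub[cond].dropna()
            stats.mean[cond] = float(col.mean()) if len(col) else float("nan")
            stats.median[cond] = float(col.median()) if len(col) else float("nan")
        covs = [c for c in (compute_cov(sub.loc[g]) for g in present) if c is not None]
        stats.cov = float(np.mean(covs)) if covs else None
        if condition_pair is not None:
            control, treatment = condition_pair
            for g in present:
                call = classify_differential(
                    sub.at[g, control], sub.at[g, treatment], threshold
                )
                if call == "up":
                    stats.n_up += 1
                elif call == "down":
                    stats.n_down += 1
        if selected is not None:
            stats.p_value = fisher_overrepresentation(
                selected & universe, set(present), universe
            )
        out[node] = stats
    return out


# ---------------------------------------------------------------------------
# Style maps
# ---------------------------------------------------------------------------

def _ramp_green_yellow_red(s: float) -> RGBA:
    """Linear green -> yellow -> red ramp for s in [0, 1]."""
    s = min(max(s, 0.0), 1.0)
    if s <= 0.5:
        return (2.0 * s, 1.0, 0.0, 1.0)
    return (1.0, 2.0 * (1.0 - s), 0.0, 1.0)


def style_by_value(
    values: dict[str, float | None],
    encoding: str = "color",
    value_range: tuple[float, float] | None = None,
    h_max: float = 50.0,
    base_height: float = 0.0,
) -> StyleMap:
    """Map one statistic per node onto color or height linearly.

    ``encoding='color'`` maps the range onto a green->yellow->red ramp;
    ``encoding='height'`` maps it onto [0, h_max].  Nodes with a missing
    statistic are rendered grey and flat.  The range defaults to the data
    min/max; pass a fixed range for cross-frame comparability.
    """
    if encoding not in ("color", "height"):
        raise ValueError(f"unknown encoding {encoding!r}")
    present = [v for v in values.values() if v is not None and not math.isnan(v)]
    if value_range is None:
        if not present:
            value_range = (0.0, 1.0)
        else:
            value_range = (min(present), max(present))
    lo, hi = value_range
    degenerate = not (hi > lo)
    if degenerate and present:
        logger.warning("degenerate style range [%g, %g]; using mid-palette", lo, hi)

    style: StyleMap = {}
    for node, v in values.items():
        if v is None or math.isnan(v):
            style[node] = NodeStyle(fill=GREY, height=base_height, visible=True)
            continue
        s = 0.5 if degenerate else (v - lo) / (hi - lo)
        s = min(max(s, 0.0), 1.0)
        if encoding == "color":
            style[node] = NodeStyle(fill=_ramp_green_yellow_red(s), height=base_height)
        else:
            style[node] = NodeStyle(fill=GREY, height=s * h_max)
    return style


def style_differential_view(
    stats: dict[str, NodeStats],
    min_de: int = MIN_DE,
    h0: float = 5.0,
) -> StyleMap:
    """The differential view: DE count as height, up/down ratio as color.

    height = h0 * log2(n_de + 1) — the logarithm accommodates the large
    dynamic range of cumulative DE counts up the hierarchy.  The color
    scalar s = log2((n_up+1)/(n_down+1)), clipped to [-3, 3], runs green
    (mostly down) through white (balanced) to red (mostly up).  Regions
    with fewer than ``min_de`` DE genes are left fully transparent so the
    interesting ones stand out.
    """
    style: StyleMap = {}
    for node, st in stats.items():
        height = h0 * math.log2(st.n_de + 1)
        s = math.log2((st.n_up + 1) / (st.n_down + 1))
        s = min(max(s, -3.0), 3.0)
        t = abs(s) / 3.0
        if s >= 0:
            fill = (1.0, 1.0 - t, 1.0 - t, 1.0)  # white -> red
        else:
            fill = (1.0 - t, 1.0, 1.0 - t, 1.0)  # white -> green
        style[node] = NodeStyle(fill=fill, height=height, visible=st.n_de >= min_de)
    return style


def build_animation_frames(
    matrix: ExpressionMatrix,
    gene_sets: dict[str, set[str]],
    statistic: str = "mean",
    conditions: list[str] | None = None,
    value_range: tuple[float, float] | None = None,
) -> list[tuple[str, StyleMap]]:
    """One styled frame per condition, in matrix column order.

    ``conditions`` may reorder or subset the matrix columns.  All frames
    share one color range (default: global min/max of the per-node
    statistic across the chosen conditions) so a given value has the same
    color in every frame.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    order = list(matrix.conditions) if conditions is None else list(conditions)
    unknown = [c for c in order if c not in matrix.conditions]
    if unknown:
        raise DataError(f"unknown condition label(s): {unknown}")
    if not order:
        raise DataError("at least one condition is required")

    stats = compute_node_stats(gene_sets, matrix)
    per_frame: dict[str, dict[str, float | None]] = {}
    for cond in order:
        per_frame[cond] = {
            n: getattr(st, statistic)[cond] for n, st in stats.items()
        }
    if value_range is None:
        pool = [
            v
            for frame in per_frame.values()
            for v in frame.values()
            if v is not None and not math.isnan(v)
        ]
        value_range = (min(pool), max(pool)) if pool else (0.0, 1.0)
    return [
        (cond, style_by_value(per_frame[cond], "color", value_range))
        for cond in order
    ]


def dump_node_genes(
    node: str,
    gene_sets: dict[str, set[str]],
    matrix: ExpressionMatrix,
    path: str | Path,
) -> None:
    """Write one term's genes x conditions to CSV (region gene dump)."""
    if node not in gene_sets:
        raise DataError(f"unknown node id {node!r}")
    genes = sorted(gene_sets[node] & set(matrix.genes))
    matrix.values.loc[genes].to_csv(path, index_label="gene")
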