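"""Ontology DAG model: parsing, validation, and spanning-tree extraction.

Controlled vocabularies such as the Gene Ontology (GO) or a pathway
ontology (PO) are rooted directed acyclic graphs: a term may have several
parents ("multiple inheritance").  The radial space-filling layout is drawn
on a spanning tree of the DAG; for each multi-parent term one parent — the
*major parent* — carries the term in the tree, and every other in-edge
becomes a *non-tree edge* from a *minor parent*.  The major parent is the
parent whose edge appears first in input order, which makes the
decomposition deterministic and reproducible from the input file alone.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger("ersfviz")

VIRTUAL_ROOT = "__ROOT__"


class OntologyError(ValueError):
    """Raised for malformed or inconsistent ontology input."""


@dataclass
class OntologyGraph:
    """A rooted ontology DAG.

    Parameters
    ----------
    edges:
        Ordered list of directed ``(parent, child)`` pairs.  Edge order is
        semantic: it breaks ties when the spanning tree picks major parents.
    names:
        Optional term id -> human-readable name mapping; a missing name
        defaults to the id itself.
    """

    edges: list[tuple[str, str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for parent, child in self.edges:
            if parent == child:
                raise OntologyError(f"self-loop on node {parent!r}")
            if (parent, child) in seen:
                raise OntologyError(f"duplicate edge {parent!r} -> {child!r}")
            seen.add((parent, child))
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology contains a cycle through {cycle[0][0]!r}")

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set(self.names)
        for parent, child in self.edges:
            out.add(parent)
            out.add(child)
        return out

    @property
    def roots(self) -> list[str]:
        """Node ids with no parents, in sorted order."""
        children = {c for _, c in self.edges}
        return sorted(n for n in self.nodes if n not in children)

    @property
    def leaves(self) -> set[str]:
        parents = {p for p, _ in self.edges}
        return {n for n in self.nodes if n not in parents}

    def name_of(self, node: str) -> str:
        return self.names.get(node, node)

    def parents_of(self, node: str) -> list[str]:
        return [p for p, c in self.edges if c == node]

    def children_of(self, node: str) -> list[str]:
        return [c for p, c in self.edges if p == node]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class SpanningTree:
    """Spanning-tree decomposition of an ontology DAG.

    ``major_parent`` maps every non-root node to the parent carrying it in
    the tree; every remaining DAG edge is recorded in ``non_tree_edges`` as
    a ``(minor_parent, child)`` pair, preserving input order.  ``depth`` is
    measured along tree edges only, with the root at depth 0.
    """

    root: str
    major_parent: dict[str, str]
    depth: dict[str, int]
    non_tree_edges: list[tuple[str, str]]
    leaves: set[str]
    names: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.depth)

    def name_of(self, node: str) -> str:
        return self.names.get(node, node)

    def tree_children(self, node: str) -> list[str]:
        return [c for c, p in self.major_parent.items() if p == node]

    def minor_parents(self, node: str) -> list[str]:
        return [p for p, c in self.non_tree_edges if c == node]

    def multi_parent_nodes(self) -> list[str]:
        """Distinct children of non-tree edges, i.e. nodes with >= 2 parents."""
        seen: list[str] = []
        for _, child in self.non_tree_edges:
            if child not in seen:
                seen.append(child)
        return seen

    def max_depth(self) -> int:
        return max(self.depth.values())

    def to_tsv(self) -> str:
        """Debug dump: ``node<TAB>depth<TAB>major_parent`` sorted by node id."""
        lines = ["node\tdepth\tmajor_parent"]
        for node in sorted(self.depth):
            parent = self.major_parent.get(node, "")
            lines.append(f"{node}\t{self.depth[node]}\t{parent}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

def parse_edge_list(path: str | Path) -> OntologyGraph:
    """Read a ``parent<TAB>child`` edge list into an :class:`OntologyGraph`.

    Lines starting with ``#`` and blank lines are skipped; an optional
    header line ``parent\\tchild`` is recognised and dropped.  Edge order in
    the file is preserved.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise OntologyError(
                    f"{path.name}:{lineno}: expected 'parent<TAB>child', got {line!r}"
                )
            if not edges and parts == ["parent", "child"]:
                continue  # optional header line
            edges.append((parts[0], parts[1]))
    try:
        return OntologyGraph(edges=edges)
    except OntologyError as exc:
        raise OntologyError(f"{path.name}: {exc}") from exc


_TAG_RE = re.compile(r"^([A-Za-z_]+):\s*(.*?)\s*(?:!.*)?$")


def parse_obo(path: str | Path) -> OntologyGraph:
    """Parse the id/name/is_a subset of an OBO 1.2 file.

    Each ``[Term]`` stanza must carry an ``id:``; ``is_a:`` assertions
    become parent->child edges (the OBO arrow points child-to-parent).
    Obsolete terms are skipped.  Relationship types other than ``is_a``
    (``part_of``, ``regulates``, ...) are ignored with a logged count, as
    only one hierarchy relation is drawn.
    """
    path = Path(path)
    stanzas: list[dict[str, list[str]]] = []
    current: dict[str, list[str]] | None = None
    in_term = False
    with path.open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                in_term = line == "[Term]"
                current = {} if in_term else None
                if in_term:
                    stanzas.append(current)
                continue
            if not in_term or not line or line.startswith("!"):
                continue
            m = _TAG_RE.match(line)
            if m:
                current.setdefault(m.group(1), []).append(m.group(2))

    edges: list[tuple[str, str]] = []
    names: dict[str, str] = {}
    ignored_relationships = 0
    for i, stanza in enumerate(stanzas):
        if "id" not in stanza:
            raise OntologyError(f"{path.name}: [Term] stanza #{i + 1} has no id")
        term = stanza["id"][0]
        if stanza.get("is_obsolete", ["false"])[0].lower() == "true":
            continue
        names[term] = stanza.get("name", [term])[0]
        for target in stanza.get("is_a", []):
            edges.append((target.split()[0], term))
        ignored_relationships += len(stanza.get("relationship", []))

    dangling = sorted({p for p, _ in edges} - set(names))
    if dangling:
        raise OntologyError(f"{path.name}: is_a targets not defined: {dangling}")
    if ignored_relationships:
        logger.warning(
            "%s: ignored %d non-is_a relationship assertion(s)",
            path.name,
            ignored_relationships,
        )
    try:
        return OntologyGraph(edges=edges, names=names)
    except OntologyError as exc:
        raise OntologyError(f"{path.name}: {exc}") from exc


# ---------------------------------------------------------------------------
# Restructuring
# ---------------------------------------------------------------------------

def normalize_root(g: OntologyGraph) -> OntologyGraph:
    """Ensure a single root, inserting a virtual root over multiple roots.

    GO, for instance, has three namespace roots; a virtual root named
    ``__ROOT__`` with an edge to each former root unifies them.  A graph
    that already has one root is returned unchanged.
    """
    if not g.nodes:
        raise OntologyError("empty ontology graph")
    roots = g.roots
    if len(roots) == 1:
        return g
    new_edges = [(VIRTUAL_ROOT, r) for r in roots] + list(g.edges)
    names = dict(g.names)
    names.setdefault(VIRTUAL_ROOT, VIRTUAL_ROOT)
    return OntologyGraph(edges=new_edges, names=names)


def extract_spanning_tree(g: OntologyGraph) -> SpanningTree:
    """Decompose a single-root DAG into a spanning tree plus non-tree edges.

    The major parent of each node is the parent whose edge appears first in
    the input edge order; every later in-edge becomes a non-tree edge from a
    minor parent.  Depths are computed over tree edges only.
    """
    roots = g.roots
    if len(roots) != 1:
        raise OntologyError(
            f"expected exactly one root, found {roots!r}; call normalize_root first"
        )
    root = roots[0]

    major_parent: dict[str, str] = {}
    non_tree: list[tuple[str, str]] = []
    for parent, child in g.edges:
        if child not in major_parent:
            major_parent[child] = parent
        else:
            non_tree.append((parent, child))

    depth: dict[str, int] = {root: 0}
    children: dict[str, list[str]] = {}
    for child, parent in major_parent.items():
        children.setdefault(parent, []).append(child)
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children.get(node, ()):
            depth[child] = depth[node] + 1
            stack.append(child)
    missing = g.nodes - set(depth)
    if missing:  # unreachable under acyclicity + single root, kept as a guard
        raise OntologyError(f"nodes unreachable from root {root!r}: {sorted(missing)}")

    return SpanningTree(
        root=root,
        major_parent=major_parent,
        depth=depth,
        non_tree_edges=non_tree,
        leaves=g.leaves,
        names=dict(g.names),
    )


def write_edge_list(g: OntologyGraph, path: str | Path) -> None:
    """Serialize a graph back to the ``parent<TAB>child`` TSV format."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("parent\tchild\n")
        for parent, child in g.edges:
            fh.write(f"{parent}\t{child}\n")
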