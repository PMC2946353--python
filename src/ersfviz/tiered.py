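"""Aligned 3D tiered layout for a single typed pathway graph.

Nodes of a pathway (metabolites, polypeptides/complexes, RNAs, DNAs) are
separated into horizontal planes by entity type, one z-plane per type.
Rather than laying out each plane independently, a user-selected *major
plane* (for metabolic pathways, naturally the metabolite layer) is laid
out first with a deterministic spring embedding; every other node is then
placed at the centroid of its already-placed neighbours, cascading plane
by plane, so proteins line up under the metabolites they act on and RNAs
and DNAs line up under their polypeptides.  The alignment pass never
moves a major-plane node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

#: canonical plane order, top to bottom
PLANE_ORDER = ["metabolite", "polypeptide", "RNA", "DNA", "other"]
#: vertical spacing between planes, layout units
DZ = 20.0
#: nodes closer than this in one plane are fanned apart
R_MIN = 0.5
SPRING_ITERATIONS = 500
DEFAULT_SEED = 42

#: input entity types folded into canonical planes; reactions ride the
#: metabolite plane so metabolite-reaction-metabolite chains stay flat
TYPE_ALIASES = {
    "protein": "polypeptide",
    "complex": "polypeptide",
    "polypeptide/complex": "polypeptide",
    "reaction": "metabolite",
    "rna": "RNA",
    "dna": "DNA",
}


class PathwayError(ValueError):
    """Raised for malformed pathway input."""


@dataclass
class PathwayGraph:
    """Typed interaction network: nodes carry an entity type."""

    node_types: dict[str, str]  # node id -> entity type
    edges: list[tuple[str, str, str]]  # (source, target, interaction label)
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, t, _ in self.edges:
            for endpoint in (s, t):
                if endpoint not in self.node_types:
                    raise PathwayError(f"edge endpoint {endpoint!r} has no node record")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.node_types)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n, t in self.node_types.items():
            g.add_node(n, entity_type=t)
        for s, t, label in self.edges:
            g.add_edge(s, t, interaction=label)
        return g

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PathwayGraph":
        """Read ``source<TAB>target<TAB>source_type<TAB>target_type<TAB>interaction``."""
        node_types: dict[str, str] = {}
        edges: list[tuple[str, str, str]] = []
        with Path(path).open(encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "source" and parts[1] == "target":
                    continue
                if len(parts) != 5:
                    raise PathwayError(
                        f"{Path(path).name}:{lineno}: expected 5 tab-separated fields"
                    )
                s, t, st, tt, label = parts
                for node, typ in ((s, st), (t, tt)):
                    if node_types.get(node, typ) != typ:
                        raise PathwayError(
                            f"{Path(path).name}:{lineno}: conflicting type for {node!r}"
                        )
                    node_types[node] = typ
                edges.append((s, t, label))
        return cls(node_types=node_types, edges=edges)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tsource_type\ttarget_type\tinteraction\n")
            for s, t, label in self.edges:
                fh.write(
                    f"{s}\t{t}\t{self.node_types[s]}\t{self.node_types[t]}\t{label}\n"
                )


@dataclass
class TieredPositions:
    """Per-node 3D coordinates plus the plane bookkeeping."""

    xyz: dict[str, tuple[float, float, float]]
    plane_order: list[str]
    dz: float

    def plane_of(self, z: float) -> int:
        return round(-z / self.dz)


def canonical_type(t: str, aliases: dict[str, str] | None = None) -> str:
    table = TYPE_ALIASES if aliases is None else aliases
    return table.get(t, table.get(t.lower(), t))


# ---------------------------------------------------------------------------
# Plane assignment
# ---------------------------------------------------------------------------

def assign_planes(
    g: PathwayGraph,
    order: list[str] | None = None,
    dz: float = DZ,
    aliases: dict[str, str] | None = None,
) -> dict[str, float]:
    """z = -dz * rank of the node's (aliased) type in the plane order."""
    order = PLANE_ORDER if order is None else order
    z: dict[str, float] = {}
    for node, typ in g.node_types.items():
        canon = canonical_type(typ, aliases)
        if canon not in order:
            raise PathwayError(
                f"entity type {typ!r} of node {node!r} is not in the plane order; "
                "alias it in the type table"
            )
        z[node] = -dz * order.index(canon)
    return z


# ---------------------------------------------------------------------------
# Major-plane spring layout
# ---------------------------------------------------------------------------

def _major_plane_graph(
    g: PathwayGraph, major: str, aliases: dict[str, str] | None = None
) -> nx.Graph:
    """Induced graph on major-type nodes, collapsing one-hop intermediaries.

    An edge is added between two major-plane nodes when they are directly
    linked or linked through a single non-major node (e.g. a
    metabolite-reaction-metabolite chain collapses to one edge), so the
    spring layout sees the pathway's actual connectivity.
    """
    full = g.to_networkx()
    majors = {
        n for n, t in g.node_types.items() if canonical_type(t, aliases) == major
    }
    sub = nx.Graph()
    sub.add_nodes_from(sorted(majors))
    for u, v in full.edges:
        if u in majors and v in majors:
            sub.add_edge(u, v)
    for mid in set(full.nodes) - majors:
        neigh = sorted(set(full.neighbors(mid)) & majors)
        for i, u in enumerate(neigh):
            for v in neigh[i + 1:]:
                sub.add_edge(u, v)
    return sub


def layout_major_plane(
    g: PathwayGraph,
    major: str = "metabolite",
    seed: int = DEFAULT_SEED,
    aliases: dict[str, str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Deterministic spring embedding of the major plane at z = 0."""
    sub = _major_plane_graph(g, major, aliases)
    if sub.number_of_nodes() == 0:
        present = sorted({canonical_type(t, aliases) for t in g.node_types.values()})
        raise PathwayError(
            f"no nodes on major plane {major!r}; present planes: {present}"
        )
    pos = nx.spring_layout(sub, seed=seed, iterations=SPRING_ITERATIONS)
    return {n: (float(p[0]), float(p[1])) for n, p in pos.items()}


# ---------------------------------------------------------------------------
# Cascade alignment
# ---------------------------------------------------------------------------

def _spread_collisions(
    plane_nodes: list[str],
    xy: dict[str, tuple[float, float]],
    r_min: float,
    frozen: set[str],
) -> None:
    """Fan stacked nodes apart on a small circle, deterministic by id.

    Nodes closer than ``r_min`` are clustered (transitively), and each
    cluster is spread on a radius-``r_min`` circle around its centroid in
    id order.  Frozen (major-plane) nodes are never moved.
    """
    nodes = sorted(plane_nodes)
    parent = {n: n for n in nodes}

    def find(n: str) -> str:
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if math.dist(xy[u], xy[v]) < r_min:
                parent[find(v)] = find(u)

    clusters: dict[str, list[str]] = {}
    for n in nodes:
        clusters.setdefault(find(n), []).append(n)
    for members in clusters.values():
        movable = [n for n in members if n not in frozen]
        if len(members) < 2 or not movable:
            continue
        cx = sum(xy[n][0] for n in members) / len(members)
        cy = sum(xy[n][1] for n in members) / len(members)
        for i, n in enumerate(sorted(movable)):
            angle = 2.0 * math.pi * i / len(movable)
            xy[n] = (cx + r_min * math.cos(angle), cy + r_min * math.sin(angle))


def cascade_align(
    g: PathwayGraph,
    major_xy: dict[str, tuple[float, float]],
    order: list[str] | None = None,
    dz: float = DZ,
    r_min: float = R_MIN,
    aliases: dict[str, str] | None = None,
) -> TieredPositions:
    """Place the remaining planes under the major plane.

    Planes are processed in order; each unplaced node takes the centroid
    of its already-placed neighbours' (x, y).  Nodes with no placed
    neighbour wait for the next pass; whatever remains after the passes
    settle is parked on a grid at the plane margin.  Per-plane collision
    resolution then fans nodes closer than ``r_min`` apart on a small
    deterministic circle — never touching major-plane nodes.
    """
    order = PLANE_ORDER if order is None else order
    z = assign_planes(g, order, dz, aliases)
    full = g.to_networkx()

    xy: dict[str, tuple[float, float]] = dict(major_xy)
    unplaced = [n for n in g.nodes if n not in xy]
    while unplaced:
        progressed = False
        next_round: list[str] = []
        # process plane by plane in order so upper planes anchor lower ones
        for plane in order:
            for node in unplaced:
                if canonical_type(g.node_types[node], aliases) != plane:
                    continue
                placed_neigh = [m for m in sorted(full.neighbors(node)) if m in xy]
                if placed_neigh:
                    xy[node] = (
                        sum(xy[m][0] for m in placed_neigh) / len(placed_neigh),
                        sum(xy[m][1] for m in placed_neigh) / len(placed_neigh),
                    )
                    progressed = True
                else:
                    next_round.append(node)
        unplaced = next_round
        if not progressed:
            break

    if unplaced:  # orphans: grid at the margin of the layout
        margin_x = max((p[0] for p in xy.values()), default=0.0) + 4.0 * r_min
        min_y = min((p[1] for p in xy.values()), default=0.0)
        for i, node in enumerate(sorted(unplaced)):
            xy[node] = (margin_x + 4.0 * r_min * (i % 5), min_y + 4.0 * r_min * (i // 5))

    frozen = set(major_xy)
    for plane in order:
        plane_nodes = [
            n for n in g.nodes if canonical_type(g.node_types[n], aliases) == plane
        ]
        if plane_nodes:
            _spread_collisions(plane_nodes, xy, r_min, frozen)

    xyz = {n: (xy[n][0], xy[n][1], z[n]) for n in g.nodes}
    return TieredPositions(xyz=xyz, plane_order=list(order), dz=dz)


def compute_tiered_layout(
    g: PathwayGraph,
    major: str = "metabolite",
    seed: int = DEFAULT_SEED,
    order: list[str] | None = None,
    dz: float = DZ,
    aliases: dict[str, str] | None = None,
) -> TieredPositions:
    """Major-plane spring layout followed by the cascade alignment."""
    major_xy = layout_major_plane(g, major, seed, aliases)
    return cascade_align(g, major_xy, order, dz, aliases=aliases)
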