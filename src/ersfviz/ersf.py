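"""Enhanced radial space-filling (ERSF) layout geometry.

The classic radial space-filling ("sunburst") layout draws a rooted tree as
nested annuli: each node owns an angular sector nested inside its parent's,
each tree depth is one ring, and a node's sweep angle is the sum of its
children's sweeps.  The *enhanced* layout adds three elements so that the
non-tree edges of an ontology DAG become visible instead of being dropped:

* an **orbit** — a circle drawn in the middle band of a multi-parent
  node's ring, at its own altitude, advertising that node to minor parents;
* a **downlink ray** — a single radial ray from a minor parent's region to
  the farthest orbit it links (all of one parent's downlinks share this one
  ray, so total ink equals the longest link);
* **access points** — the ray/orbit intersections, one per non-tree edge.

Orbits in one layer are kept distinguishable by sorting them by downlink
count: the orbit with the most downlinks is placed farthest from the centre
and highest.

All geometry is deterministic: siblings are laid out in lexicographic id
order and all tie-breaks are documented, so identical inputs yield
byte-identical serialized layouts.
"""

from __future__ import annotations

import colorsys
import json
import math
from dataclasses import dataclass, field, asdict

from .ontology import SpanningTree

RGBA = tuple[float, float, float, float]

#: default ring width in layout units
RING_WIDTH = 10.0
#: default extrusion height unit
H0 = 5.0
#: orbits live in this fractional band of their ring ("middle area")
ORBIT_BAND = (0.3, 0.7)


@dataclass
class AngularRegion:
    """Annular sector owned by one node: angle x ring -> region."""

    node: str
    start_angle: float  # degrees in [0, 360)
    sweep_angle: float  # degrees > 0
    layer: int  # == tree depth
    inner_radius: float
    outer_radius: float
    height: float = 0.0
    color: RGBA = (0.5, 0.5, 0.5, 1.0)

    @property
    def mid_angle(self) -> float:
        return self.start_angle + self.sweep_angle / 2.0

    @property
    def mid_radius(self) -> float:
        return (self.inner_radius + self.outer_radius) / 2.0

    def anchor_point(self) -> tuple[float, float]:
        """2D point at the angular midpoint and radial centre of the region."""
        theta = math.radians(self.mid_angle)
        return (self.mid_radius * math.cos(theta), self.mid_radius * math.sin(theta))


@dataclass
class Orbit:
    child: str
    layer: int
    radius: float
    altitude: float
    color: RGBA
    downlink_count: int


@dataclass
class DownlinkRay:
    minor_parent: str
    origin: tuple[float, float]
    terminus: tuple[float, float]
    access_points: list[tuple[str, tuple[float, float]]]


@dataclass
class ErsfLayout:
    regions: dict[str, AngularRegion]
    orbits: list[Orbit]
    rays: list[DownlinkRay]
    ring_width: float = RING_WIDTH
    height_unit: float = H0
    orbit_band: tuple[float, float] = ORBIT_BAND

    def region(self, node: str) -> AngularRegion:
        return self.regions[node]

    def to_json(self) -> str:
        """Stable JSON dump of the full layout (sorted keys, fixed order)."""
        doc = {
            "params": {
                "ring_width": self.ring_width,
                "height_unit": self.height_unit,
                "orbit_band": list(self.orbit_band),
            },
            "regions": {n: asdict(r) for n, r in sorted(self.regions.items())},
            "orbits": [asdict(o) for o in self.orbits],
            "rays": [asdict(r) for r in self.rays],
        }
        return json.dumps(doc, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------

def assign_angles(
    tree: SpanningTree,
    leaf_weights: dict[str, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """Assign ``(start_angle, sweep_angle)`` in degrees to every node.

    Each leaf sweeps an angle proportional to its weight (default: equal
    weights, every pathway spans the same angle); a non-leaf node sweeps
    the sum of its children's sweeps, so angle is conserved bottom-up and
    the root spans the full 360 degrees.  Siblings are laid out
    contiguously in lexicographic id order starting at the parent's start
    angle.

    Angular weight is carried by *tree* leaves — nodes with no children in
    the spanning tree.  For a pure tree these are exactly the DAG leaves;
    in a DAG a node can lose all its children to other major parents, and
    it still needs a nonzero sweep to be drawn.
    """
    leaves = sorted(n for n in tree.depth if not tree.tree_children(n))
    weights = {leaf: 1.0 for leaf in leaves}
    if leaf_weights:
        weights.update({k: float(v) for k, v in leaf_weights.items() if k in weights})
        for k, v in leaf_weights.items():
            if float(v) <= 0:
                raise ValueError(f"non-positive weight {v} for leaf {k!r}")
    total = sum(weights[leaf] for leaf in leaves)

    sweep: dict[str, float] = {}

    def subtree_sweep(node: str) -> float:
        kids = sorted(tree.tree_children(node))
        if not kids:
            sweep[node] = 360.0 * weights[node] / total
        else:
            sweep[node] = sum(subtree_sweep(c) for c in kids)
        return sweep[node]

    subtree_sweep(tree.root)

    start: dict[str, float] = {tree.root: 0.0}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        cursor = start[node]
        for child in sorted(tree.tree_children(node)):
            start[child] = cursor
            cursor += sweep[child]
            stack.append(child)
    return {n: (start[n], sweep[n]) for n in sweep}


# ---------------------------------------------------------------------------
# Radii and heights
# ---------------------------------------------------------------------------

def assign_radii(
    tree: SpanningTree, ring_width: float = RING_WIDTH
) -> dict[str, tuple[float, float]]:
    """Map tree depth k to the annulus [k*w, (k+1)*w]; the root is a disc."""
    if ring_width <= 0:
        raise ValueError("ring_width must be positive")
    return {
        n: (d * ring_width, (d + 1) * ring_width) for n, d in tree.depth.items()
    }


def subtree_heights(tree: SpanningTree, h0: float = H0) -> dict[str, float]:
    """Extrusion height proportional to subtree height.

    height(node) = h0 * (1 + longest tree-path to a descendant leaf), so
    leaves get h0 rather than zero and remain visible when extruded.
    """
    if h0 <= 0:
        raise ValueError("h0 must be positive")
    levels: dict[str, int] = {}

    def level(node: str) -> int:
        if node not in levels:
            kids = tree.tree_children(node)
            levels[node] = 0 if not kids else 1 + max(level(c) for c in kids)
        return levels[node]

    return {n: h0 * (1 + level(n)) for n in tree.depth}


# ---------------------------------------------------------------------------
# Structure-based coloring
# ---------------------------------------------------------------------------

def structure_colors(
    tree: SpanningTree, angles: dict[str, tuple[float, float]]
) -> dict[str, RGBA]:
    """Color leaves from the HSV wheel and parents as child averages.

    A leaf's hue is its angular midpoint over 360 at full saturation and
    value; a non-leaf's RGB is the sweep-angle-weighted mean of its
    children's RGB, computed bottom-up, so a category's color summarizes
    where its pathways sit on the wheel.  Alpha is 1 throughout.
    """
    colors: dict[str, RGBA] = {}

    def color(node: str) -> RGBA:
        if node in colors:
            return colors[node]
        start, sweep = angles[node]
        kids = sorted(tree.tree_children(node))
        if not kids:
            hue = ((start + sweep / 2.0) % 360.0) / 360.0
            r, g, b = colorsys.hsv_to_rgb(hue, 1.0, 1.0)
        else:
            total = sum(angles[c][1] for c in kids)
            r = g = b = 0.0
            for c in kids:
                cr, cg, cb, _ = color(c)
                w = angles[c][1] / total
                r += w * cr
                g += w * cg
                b += w * cb
        colors[node] = (r, g, b, 1.0)
        return colors[node]

    color(tree.root)
    return colors


# ---------------------------------------------------------------------------
# Orbits and downlinks
# ---------------------------------------------------------------------------

def place_orbits(
    tree: SpanningTree,
    regions: dict[str, AngularRegion],
    band: tuple[float, float] = ORBIT_BAND,
    h0: float = H0,
) -> list[Orbit]:
    """Place one orbit per multi-parent node in the middle band of its ring.

    Within a layer, orbits are ordered by ``(downlink_count, child id)``
    and given evenly spaced radii across the band and evenly spaced
    altitudes, so the orbit with the most downlinks sits outermost and
    highest.  Altitudes start one height unit above the tallest region of
    the layer so orbits clear the extruded regions beneath them.
    """
    counts: dict[str, int] = {}
    for parent, child in tree.non_tree_edges:
        counts[child] = counts.get(child, 0) + 1
    if not counts:
        return []

    by_layer: dict[int, list[str]] = {}
    for child in counts:
        by_layer.setdefault(regions[child].layer, []).append(child)

    orbits: list[Orbit] = []
    for layer in sorted(by_layer):
        children = sorted(by_layer[layer], key=lambda c: (counts[c], c))
        any_region = regions[children[0]]
        inner, outer = any_region.inner_radius, any_region.outer_radius
        w = outer - inner
        lo, hi = inner + band[0] * w, inner + band[1] * w
        base_alt = max(r.height for r in regions.values() if r.layer == layer) + h0
        n = len(children)
        for i, child in enumerate(children):
            radius = (lo + hi) / 2.0 if n == 1 else lo + (hi - lo) * i / (n - 1)
            orbits.append(
                Orbit(
                    child=child,
                    layer=layer,
                    radius=radius,
                    altitude=base_alt + i * h0,
                    color=regions[child].color,
                    downlink_count=counts[child],
                )
            )
    return orbits


def build_downlinks(
    tree: SpanningTree,
    regions: dict[str, AngularRegion],
    orbits: list[Orbit],
) -> list[DownlinkRay]:
    """Build one radial ray per minor parent, with per-edge access points.

    The ray is anchored at the parent region's angular midpoint and radial
    centre and runs along that angle to the linked orbit radially farthest
    from the anchor; if some linked orbit is nearer the centre than the
    anchor, the ray also has an inward segment at the same angle.  Each
    non-tree edge contributes one access point where the ray's angle
    crosses the child's orbit circle.
    """
    orbit_by_child = {o.child: o for o in orbits}
    linked: dict[str, list[str]] = {}
    for parent, child in tree.non_tree_edges:
        linked.setdefault(parent, []).append(child)

    rays: list[DownlinkRay] = []
    for parent in sorted(linked):
        region = regions[parent]
        theta = math.radians(region.mid_angle)
        anchor_r = region.mid_radius
        origin = region.anchor_point()
        children = linked[parent]
        radii = {c: orbit_by_child[c].radius for c in children}
        far_child = max(children, key=lambda c: (abs(radii[c] - anchor_r), c))
        far_r = radii[far_child]
        terminus = (far_r * math.cos(theta), far_r * math.sin(theta))
        access = [
            (c, (radii[c] * math.cos(theta), radii[c] * math.sin(theta)))
            for c in sorted(children)
        ]
        rays.append(
            DownlinkRay(
                minor_parent=parent,
                origin=origin,
                terminus=terminus,
                access_points=access,
            )
        )
    return rays


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def compute_layout(
    tree: SpanningTree,
    leaf_weights: dict[str, float] | None = None,
    ring_width: float = RING_WIDTH,
    h0: float = H0,
    band: tuple[float, float] = ORBIT_BAND,
) -> ErsfLayout:
    """Run the whole ERSF pipeline on a spanning tree."""
    angles = assign_angles(tree, leaf_weights)
    radii = assign_radii(tree, ring_width)
    heights = subtree_heights(tree, h0)
    colors = structure_colors(tree, angles)
    regions = {
        n: AngularRegion(
            node=n,
            start_angle=angles[n][0],
            sweep_angle=angles[n][1],
            layer=tree.depth[n],
            inner_radius=radii[n][0],
            outer_radius=radii[n][1],
            height=heights[n],
            color=colors[n],
        )
        for n in tree.depth
    }
    orbits = place_orbits(tree, regions, band, h0)
    rays = build_downlinks(tree, regions, orbits)
    return ErsfLayout(
        regions=regions,
        orbits=orbits,
        rays=rays,
        ring_width=ring_width,
        height_unit=h0,
        orbit_band=band,
    )
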