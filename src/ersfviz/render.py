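"""Serialize ERSF and tiered layouts to SVG (2D) and KML (3D).

The top-down projection of the sunburst is already the view users work
with most, so the SVG rendering is a faithful 2D export: annular-sector
paths for regions, dashed circles for orbits, line segments for downlink
rays, small discs for access points.  KML 2.2 output carries the third
dimension — extruded polygons for regions, rings at altitude for orbits —
and a condition series becomes one time-stamped Folder per frame so the
viewer's time slider plays the animation.  Layout coordinates are mapped
to geographic coordinates by a local equirectangular projection about an
anchor point.
"""

from __future__ import annotations

import math
from datetime import date, timedelta
from pathlib import Path

from lxml import etree

from .ersf import ErsfLayout, AngularRegion
from .stats import NodeStyle, StyleMap
from .tiered import PathwayGraph, TieredPositions, canonical_type

SVG_NS = "http://www.w3.org/2000/svg"
KML_NS = "http://www.opengis.net/kml/2.2"

#: arc tessellation step, degrees
ARC_STEP = 4.0
#: metres of ground distance per layout unit
KML_SCALE = 10.0
#: metres per degree of latitude (spherical Earth)
M_PER_DEG = 111_320.0


class RenderError(ValueError):
    pass


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def _rgba_svg(color) -> tuple[str, str]:
    r, g, b, a = color
    return (f"rgb({round(r * 255)},{round(g * 255)},{round(b * 255)})", _fmt(a))


def _kml_color(color, opacity: float = 1.0) -> str:
    """KML colors are aabbggrr hex."""
    r, g, b, a = color
    a = a * opacity
    return "".join(
        f"{round(max(0.0, min(1.0, c)) * 255):02x}" for c in (a, b, g, r)
    )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _arc_points(
    radius: float, start_deg: float, sweep_deg: float, step: float = ARC_STEP
) -> list[tuple[float, float]]:
    n = max(1, math.ceil(sweep_deg / step))
    pts = []
    for i in range(n + 1):
        theta = math.radians(start_deg + sweep_deg * i / n)
        pts.append((radius * math.cos(theta), radius * math.sin(theta)))
    return pts


def _sector_outline(region: AngularRegion, step: float = ARC_STEP) -> list[tuple[float, float]]:
    """Closed outline of an annular sector (or disc/annulus at 360 degrees)."""
    outer = _arc_points(region.outer_radius, region.start_angle, region.sweep_angle, step)
    if region.inner_radius <= 0:
        if region.sweep_angle >= 360.0 - 1e-9:
            return outer  # full disc
        return outer + [(0.0, 0.0)]
    inner = _arc_points(region.inner_radius, region.start_angle, region.sweep_angle, step)
    return outer + inner[::-1]


def _sector_path_d(region: AngularRegion) -> str:
    """SVG path for an annular sector using arc commands."""
    full = region.sweep_angle >= 360.0 - 1e-9
    a0 = math.radians(region.start_angle)
    a1 = math.radians(region.start_angle + region.sweep_angle)
    am = math.radians(region.start_angle + region.sweep_angle / 2.0)
    ro, ri = region.outer_radius, region.inner_radius
    large = 1 if region.sweep_angle % 360.0 > 180.0 else 0

    def pt(r: float, a: float) -> str:
        return f"{_fmt(r * math.cos(a))} {_fmt(r * math.sin(a))}"

    if full:
        # two half arcs to draw a complete circle; subtract inner disc if any
        d = (
            f"M {pt(ro, a0)} A {_fmt(ro)} {_fmt(ro)} 0 1 1 {pt(ro, am)} "
            f"A {_fmt(ro)} {_fmt(ro)} 0 1 1 {pt(ro, a0)} Z"
        )
        if ri > 0:
            d += (
                f" M {pt(ri, a0)} A {_fmt(ri)} {_fmt(ri)} 0 1 0 {pt(ri, am)} "
                f"A {_fmt(ri)} {_fmt(ri)} 0 1 0 {pt(ri, a0)} Z"
            )
        return d
    if ri <= 0:
        return (
            f"M 0 0 L {pt(ro, a0)} A {_fmt(ro)} {_fmt(ro)} 0 {large} 1 {pt(ro, a1)} Z"
        )
    return (
        f"M {pt(ri, a0)} L {pt(ro, a0)} "
        f"A {_fmt(ro)} {_fmt(ro)} 0 {large} 1 {pt(ro, a1)} "
        f"L {pt(ri, a1)} "
        f"A {_fmt(ri)} {_fmt(ri)} 0 {large} 0 {pt(ri, a0)} Z"
    )


# ---------------------------------------------------------------------------
# SVG
# ---------------------------------------------------------------------------

def ersf_to_svg(
    layout: ErsfLayout,
    style: StyleMap | None = None,
    path: str | Path | None = None,
) -> bytes:
    """Render the top-down 2D projection of an ERSF layout to SVG 1.1.

    With no style map, the structure-based colors stored on the layout are
    used.  Elements are emitted in sorted node-id order so output is
    byte-stable for a fixed input.
    """
    extent = max(r.outer_radius for r in layout.regions.values())
    for orbit in layout.orbits:
        extent = max(extent, orbit.radius)
    pad = 0.05 * extent
    size = 2 * (extent + pad)
    svg = etree.Element(
        f"{{{SVG_NS}}}svg",
        nsmap={None: SVG_NS},
        attrib={
            "version": "1.1",
            "viewBox": f"{_fmt(-extent - pad)} {_fmt(-extent - pad)} {_fmt(size)} {_fmt(size)}",
            "width": "800",
            "height": "800",
        },
    )

    regions = etree.SubElement(svg, f"{{{SVG_NS}}}g", attrib={"class": "regions"})
    for node in sorted(layout.regions):
        region = layout.regions[node]
        node_style = (style or {}).get(node)
        if node_style is None:
            fill, opacity = _rgba_svg(region.color)
        elif not node_style.visible:
            fill, opacity = _rgba_svg(node_style.fill)
            opacity = "0.08"
        else:
            fill, opacity = _rgba_svg(node_style.fill)
        path_el = etree.SubElement(
            regions,
            f"{{{SVG_NS}}}path",
            attrib={
                "class": "region",
                "d": _sector_path_d(region),
                "fill": fill,
                "fill-opacity": opacity,
                "fill-rule": "evenodd",
                "stroke": "black",
                "stroke-width": _fmt(0.01 * extent),
            },
        )
        etree.SubElement(path_el, f"{{{SVG_NS}}}title").text = node

    orbit_g = etree.SubElement(svg, f"{{{SVG_NS}}}g", attrib={"class": "orbits"})
    for orbit in sorted(layout.orbits, key=lambda o: o.child):
        fill, _ = _rgba_svg(orbit.color)
        etree.SubElement(
            orbit_g,
            f"{{{SVG_NS}}}circle",
            attrib={
                "class": "orbit",
                "cx": "0",
                "cy": "0",
                "r": _fmt(orbit.radius),
                "fill": "none",
                "stroke": fill,
                "stroke-width": _fmt(0.008 * extent),
                "stroke-dasharray": f"{_fmt(0.02 * extent)} {_fmt(0.01 * extent)}",
            },
        )

    ray_g = etree.SubElement(svg, f"{{{SVG_NS}}}g", attrib={"class": "downlinks"})
    for ray in sorted(layout.rays, key=lambda r: r.minor_parent):
        etree.SubElement(
            ray_g,
            f"{{{SVG_NS}}}line",
            attrib={
                "class": "downlink",
                "x1": _fmt(ray.origin[0]),
                "y1": _fmt(ray.origin[1]),
                "x2": _fmt(ray.terminus[0]),
                "y2": _fmt(ray.terminus[1]),
                "stroke": "green",
                "stroke-width": _fmt(0.01 * extent),
            },
        )
        for child, (x, y) in ray.access_points:
            dot = etree.SubElement(
                ray_g,
                f"{{{SVG_NS}}}circle",
                attrib={
                    "class": "access-point",
                    "cx": _fmt(x),
                    "cy": _fmt(y),
                    "r": _fmt(0.012 * extent),
                    "fill": "red",
                },
            )
            etree.SubElement(dot, f"{{{SVG_NS}}}title").text = f"{ray.minor_parent} -> {child}"

    blob = etree.tostring(svg, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if path is not None:
        Path(path).write_bytes(blob)
    return blob


# ---------------------------------------------------------------------------
# KML
# ---------------------------------------------------------------------------

def _project(
    x: float, y: float, anchor: tuple[float, float], scale: float
) -> tuple[float, float]:
    """Local equirectangular projection: layout units -> (lon, lat)."""
    lat0, lon0 = anchor
    lat = lat0 + y * scale / M_PER_DEG
    lon = lon0 + x * scale / (M_PER_DEG * math.cos(math.radians(lat0)))
    return lon, lat


def _coords(
    points: list[tuple[float, float, float]],
    anchor: tuple[float, float],
    scale: float,
) -> str:
    out = []
    for x, y, alt in points:
        lon, lat = _project(x, y, anchor, scale)
        out.append(f"{lon:.8f},{lat:.8f},{_fmt(alt)}")
    return " ".join(out)


def _check_anchor(anchor: tuple[float, float]) -> None:
    if abs(anchor[0]) >= 85.0:
        raise RenderError(
            f"anchor latitude {anchor[0]} is too close to a pole for the projection"
        )


def _region_placemark(
    parent: etree._Element,
    region: AngularRegion,
    node_style: NodeStyle | None,
    anchor: tuple[float, float],
    scale: float,
    step: float,
) -> None:
    if node_style is None:
        color = _kml_color(region.color)
        height = region.height
    else:
        color = _kml_color(node_style.fill, 1.0 if node_style.visible else 0.08)
        height = node_style.height
    pm = etree.SubElement(parent, f"{{{KML_NS}}}Placemark")
    etree.SubElement(pm, f"{{{KML_NS}}}name").text = region.node
    style_el = etree.SubElement(pm, f"{{{KML_NS}}}Style")
    poly_style = etree.SubElement(style_el, f"{{{KML_NS}}}PolyStyle")
    etree.SubElement(poly_style, f"{{{KML_NS}}}color").text = color
    poly = etree.SubElement(pm, f"{{{KML_NS}}}Polygon")
    etree.SubElement(poly, f"{{{KML_NS}}}extrude").text = "1"
    etree.SubElement(poly, f"{{{KML_NS}}}altitudeMode").text = "relativeToGround"
    boundary = etree.SubElement(poly, f"{{{KML_NS}}}outerBoundaryIs")
    ring = etree.SubElement(boundary, f"{{{KML_NS}}}LinearRing")
    outline = _sector_outline(region, step)
    outline = outline + outline[:1]  # close the ring
    etree.SubElement(ring, f"{{{KML_NS}}}coordinates").text = _coords(
        [(x, y, max(height, 0.1)) for x, y in outline], anchor, scale
    )


def ersf_to_kml(
    layout: ErsfLayout,
    frames: list[tuple[str, StyleMap]] | None = None,
    anchor: tuple[float, float] = (0.0, 0.0),
    scale: float = KML_SCALE,
    path: str | Path | None = None,
    step: float = ARC_STEP,
) -> bytes:
    """Render an ERSF layout as an extruded KML 2.2 scene.

    Regions become extruded polygons (altitude = height, relative to
    ground), orbits become rings at their altitude, and downlink rays
    become line strings rising from the parent region to each orbit.
    With multiple frames, each frame is a Folder carrying a TimeSpan (one
    synthetic day per frame) so the time slider animates the series; with
    one frame (or none) no TimeSpan is emitted.
    """
    _check_anchor(anchor)
    kml = etree.Element(f"{{{KML_NS}}}kml", nsmap={None: KML_NS})
    doc = etree.SubElement(kml, f"{{{KML_NS}}}Document")
    etree.SubElement(doc, f"{{{KML_NS}}}name").text = "ERSF ontology layout"

    frame_list: list[tuple[str, StyleMap | None]]
    if not frames:
        frame_list = [("structure", None)]
    else:
        frame_list = list(frames)
    animated = len(frame_list) > 1

    epoch = date(2000, 1, 1)
    for i, (label, style_map) in enumerate(frame_list):
        folder = etree.SubElement(doc, f"{{{KML_NS}}}Folder")
        etree.SubElement(folder, f"{{{KML_NS}}}name").text = str(label)
        if animated:
            span = etree.SubElement(folder, f"{{{KML_NS}}}TimeSpan")
            etree.SubElement(span, f"{{{KML_NS}}}begin").text = (
                epoch + timedelta(days=i)
            ).isoformat()
            etree.SubElement(span, f"{{{KML_NS}}}end").text = (
                epoch + timedelta(days=i + 1)
            ).isoformat()
        for node in sorted(layout.regions):
            _region_placemark(
                folder,
                layout.regions[node],
                None if style_map is None else style_map.get(node),
                anchor,
                scale,
                step,
            )

    orbit_folder = etree.SubElement(doc, f"{{{KML_NS}}}Folder")
    etree.SubElement(orbit_folder, f"{{{KML_NS}}}name").text = "orbits"
    for orbit in sorted(layout.orbits, key=lambda o: o.child):
        pm = etree.SubElement(orbit_folder, f"{{{KML_NS}}}Placemark")
        etree.SubElement(pm, f"{{{KML_NS}}}name").text = f"orbit:{orbit.child}"
        style_el = etree.SubElement(pm, f"{{{KML_NS}}}Style")
        line_style = etree.SubElement(style_el, f"{{{KML_NS}}}LineStyle")
        etree.SubElement(line_style, f"{{{KML_NS}}}color").text = _kml_color(orbit.color)
        etree.SubElement(line_style, f"{{{KML_NS}}}width").text = "2"
        ls = etree.SubElement(pm, f"{{{KML_NS}}}LineString")
        etree.SubElement(ls, f"{{{KML_NS}}}altitudeMode").text = "relativeToGround"
        circle = _arc_points(orbit.radius, 0.0, 360.0, step)
        etree.SubElement(ls, f"{{{KML_NS}}}coordinates").text = _coords(
            [(x, y, orbit.altitude) for x, y in circle], anchor, scale
        )

    orbit_alt = {o.child: o.altitude for o in layout.orbits}
    ray_folder = etree.SubElement(doc, f"{{{KML_NS}}}Folder")
    etree.SubElement(ray_folder, f"{{{KML_NS}}}name").text = "downlinks"
    for ray in sorted(layout.rays, key=lambda r: r.minor_parent):
        pm = etree.SubElement(ray_folder, f"{{{KML_NS}}}Placemark")
        etree.SubElement(pm, f"{{{KML_NS}}}name").text = f"downlink:{ray.minor_parent}"
        style_el = etree.SubElement(pm, f"{{{KML_NS}}}Style")
        line_style = etree.SubElement(style_el, f"{{{KML_NS}}}LineStyle")
        etree.SubElement(line_style, f"{{{KML_NS}}}color").text = "ff00aa00"
        etree.SubElement(line_style, f"{{{KML_NS}}}width").text = "3"
        ls = etree.SubElement(pm, f"{{{KML_NS}}}LineString")
        etree.SubElement(ls, f"{{{KML_NS}}}altitudeMode").text = "relativeToGround"
        pts = [(ray.origin[0], ray.origin[1], layout.regions[ray.minor_parent].height)]
        pts += [
            (x, y, orbit_alt[child]) for child, (x, y) in ray.access_points
        ]
        etree.SubElement(ls, f"{{{KML_NS}}}coordinates").text = _coords(
            pts, anchor, scale
        )

    blob = etree.tostring(kml, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if path is not None:
        Path(path).write_bytes(blob)
    return blob


def tiered_to_kml(
    positions: TieredPositions,
    g: PathwayGraph,
    anchor: tuple[float, float] = (0.0, 0.0),
    scale: float = KML_SCALE,
    path: str | Path | None = None,
) -> bytes:
    """Render a tiered 3D pathway layout as KML point/line placemarks.

    Each entity plane becomes a sub-Folder of point placemarks; every
    interaction edge becomes a 3D line string.  Altitudes are shifted so
    the lowest plane sits on the ground.
    """
    _check_anchor(anchor)
    if not g.node_types:
        raise RenderError("empty pathway graph")
    z_offset = -min(z for _, _, z in positions.xyz.values())

    kml = etree.Element(f"{{{KML_NS}}}kml", nsmap={None: KML_NS})
    doc = etree.SubElement(kml, f"{{{KML_NS}}}Document")
    etree.SubElement(doc, f"{{{KML_NS}}}name").text = "tiered pathway layout"

    planes_present = []
    for plane in positions.plane_order:
        members = [
            n for n in g.nodes if canonical_type(g.node_types[n]) == plane
        ]
        if members:
            planes_present.append((plane, members))

    for plane, members in planes_present:
        folder = etree.SubElement(doc, f"{{{KML_NS}}}Folder")
        etree.SubElement(folder, f"{{{KML_NS}}}name").text = plane
        for node in members:
            x, y, z = positions.xyz[node]
            pm = etree.SubElement(folder, f"{{{KML_NS}}}Placemark")
            etree.SubElement(pm, f"{{{KML_NS}}}name").text = g.labels.get(node, node)
            point = etree.SubElement(pm, f"{{{KML_NS}}}Point")
            etree.SubElement(point, f"{{{KML_NS}}}altitudeMode").text = "relativeToGround"
            etree.SubElement(point, f"{{{KML_NS}}}coordinates").text = _coords(
                [(x, y, z + z_offset)], anchor, scale
            )

    edge_folder = etree.SubElement(doc, f"{{{KML_NS}}}Folder")
    etree.SubElement(edge_folder, f"{{{KML_NS}}}name").text = "interactions"
    for s, t, label in g.edges:
        pm = etree.SubElement(edge_folder, f"{{{KML_NS}}}Placemark")
        etree.SubElement(pm, f"{{{KML_NS}}}name").text = f"{s} -[{label}]-> {t}"
        ls = etree.SubElement(pm, f"{{{KML_NS}}}LineString")
        etree.SubElement(ls, f"{{{KML_NS}}}altitudeMode").text = "relativeToGround"
        sx, sy, sz = positions.xyz[s]
        tx, ty, tz = positions.xyz[t]
        etree.SubElement(ls, f"{{{KML_NS}}}coordinates").text = _coords(
            [(sx, sy, sz + z_offset), (tx, ty, tz + z_offset)], anchor, scale
        )

    blob = etree.tostring(kml, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if path is not None:
        Path(path).write_bytes(blob)
    return blob
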