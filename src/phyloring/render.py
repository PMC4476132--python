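"""Scene-graph construction and deterministic SVG serialization.

Rendering is split in two pure steps.  :func:`build_scene` turns a tree, a
resolved stylesheet and a polar layout into an ordered list of
renderer-neutral primitives (the determinism boundary); :func:`render_svg`
serializes a scene byte-identically, with all coordinates printed at six
decimals.  Drawing order is fixed: background wedges, ring cells, branches,
node markers, labels, legend.

Branches are drawn as the classic circular-cladogram elbow: a radial
segment at the child's angle from the child's radius up to the parent's
radius, plus a circular arc at the parent's radius over to the parent's
angle.

Biomarker coloring follows the effect-size convention used for LDA scores:
node color interpolates linearly from black at the low end of the score
range to the class's full color at the high end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple
from xml.sax.saxutils import escape

from .annotations import StyleSheet
from .colors import BLACK, ColorSpec, lerp, resolve_color
from .errors import LayoutError, PhyloringError
from .layout import PolarLayout, Wedge, clade_wedge, polar_to_cartesian, ring_intervals
from .tree import Tree, TreeNode

__all__ = [
    "SceneGraph",
    "CanvasConfig",
    "LabelLegend",
    "build_scene",
    "render_svg",
    "effect_size_color",
    "annotation_font_size",
    "make_label_legend",
    "resolve_color",
]


# ---------------------------------------------------------------------------
# primitives


@dataclass(frozen=True)
class WedgeFill:
    wedge: Wedge
    color: ColorSpec


@dataclass(frozen=True)
class BranchPath:
    theta_child: float
    r_child: float
    theta_parent: float
    r_parent: float
    color: ColorSpec
    thickness: float


@dataclass(frozen=True)
class Marker:
    theta: float
    r: float
    shape: str
    size: float
    color: ColorSpec


@dataclass(frozen=True)
class RingCell:
    kind: str  # "sector" | "glyph" | "bar"
    theta0: float
    theta1: float
    r0: float
    r1: float
    color: ColorSpec
    shape: str = ""  # glyph shape code


@dataclass(frozen=True)
class TextLabel:
    content: str
    theta: float
    r: float
    font_size: float
    color: ColorSpec
    follow_tangent: bool = True


@dataclass(frozen=True)
class LegendEntry:
    key: str
    label: str


@dataclass
class LabelLegend:
    entries: List[Tuple[str, str]] = field(default_factory=list)

    def keys(self) -> List[str]:
        return [k for k, _ in self.entries]


@dataclass
class SceneGraph:
    wedges: List[WedgeFill] = field(default_factory=list)
    ring_cells: List[RingCell] = field(default_factory=list)
    branches: List[BranchPath] = field(default_factory=list)
    markers: List[Marker] = field(default_factory=list)
    texts: List[TextLabel] = field(default_factory=list)
    legend: List[LegendEntry] = field(default_factory=list)
    r_extent: float = 1.0


@dataclass(frozen=True)
class CanvasConfig:
    size_px: int = 800
    margin: float = 0.1  # fraction of the half-size kept clear
    background: str = "#ffffff"


# ---------------------------------------------------------------------------
# scalar helpers (each is a documented rendering rule of its own)


def effect_size_color(
    score: float, smin: float, smax: float, full_color: ColorSpec
) -> ColorSpec:
    """Map an LDA-style effect size onto the black -> full-color scale.

    ``smin`` maps exactly to black and ``smax`` exactly to ``full_color``;
    scores outside the range are clamped.
    """
    if smin >= smax:
        raise PhyloringError(f"need smin < smax, got ({smin}, {smax})")
    t = (min(max(score, smin), smax) - smin) / (smax - smin)
    c = lerp(BLACK, ColorSpec(full_color.r, full_color.g, full_color.b, 1.0), t)
    return c


def annotation_font_size(
    level: int, base_size: float = 11.0, decay: float = 0.85, floor: float = 5.0
) -> float:
    """Decreasing font sizes for internal (rootward) label levels.

    ``level`` counts labeled ranks inward from the leaf-most labeled rank
    (level 0); the size decays geometrically and is clamped at ``floor``.
    """
    if base_size <= 0 or floor <= 0:
        raise PhyloringError("base_size and floor must be positive")
    if not (0 < decay <= 1):
        raise PhyloringError(f"decay must be in (0, 1], got {decay}")
    return max(floor, base_size * decay**level)


def _legend_key(i: int) -> str:
    out = []
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out.append(chr(ord("a") + rem))
    return "".join(reversed(out))


def make_label_legend(
    labels: Sequence[Tuple[str, Wedge]],
    max_inline_chars: int = 20,
    min_wedge_degrees: float = 10.0,
) -> Tuple[Set[int], LabelLegend]:
    """Decide which clade labels stay inline and which move to the legend.

    A label stays inline when it is short enough and its wedge is wide
    enough; everything else gets the next free key ("a", "b", ..., "z",
    "aa", ...), assigned in wedge angular order.  Returns the set of inline
    indices (into ``labels``) and the legend.
    """
    inline: Set[int] = set()
    keyed: List[int] = []
    order = sorted(range(len(labels)), key=lambda i: (labels[i][1].theta_min, i))
    for i in order:
        label, wedge = labels[i]
        if (
            len(label) <= max_inline_chars
            and (wedge.theta_max - wedge.theta_min) >= min_wedge_degrees
        ):
            inline.add(i)
        else:
            keyed.append(i)
    legend = LabelLegend(
        entries=[(_legend_key(k), labels[i][0]) for k, i in enumerate(keyed)]
    )
    return inline, legend


def ring_cell_primitive(
    kind: str,
    slot: Tuple[float, float],
    interval: Tuple[float, float],
    color: ColorSpec,
    *,
    heat_value: Optional[float] = None,
    bar_value: Optional[float] = None,
    bar_max: float = 1.0,
    shape: str = "circle",
) -> RingCell:
    """One external-ring cell.

    ``sector`` cells are heatmap sectors whose intensity interpolates from
    blank (fully transparent) at 0 to the full ring color at 1; ``bar``
    cells are radial bars of height (value / ring max) times the band
    height; ``glyph`` cells centre a shape (circle / triangles by
    directional sign) in the cell.
    """
    t0, t1 = slot
    r0, r1 = interval
    if kind == "sector":
        v = 1.0 if heat_value is None else heat_value
        if not (0.0 <= v <= 1.0):
            raise PhyloringError(f"heatmap value {v} outside [0, 1]")
        return RingCell("sector", t0, t1, r0, r1, color.with_alpha(color.a * v))
    if kind == "bar":
        v = 0.0 if bar_value is None else bar_value
        if v < 0:
            raise PhyloringError(f"negative bar value {v}")
        frac = 0.0 if bar_max <= 0 else v / bar_max
        return RingCell("bar", t0, t1, r0, r0 + (r1 - r0) * frac, color)
    if kind == "glyph":
        return RingCell("glyph", t0, t1, r0, r1, color, shape=shape)
    raise PhyloringError(f"unknown ring cell kind {kind!r}")


# ---------------------------------------------------------------------------
# scene construction


def _label_levels(tree: Tree, labeled: Sequence[TreeNode]) -> Dict[TreeNode, int]:
    """Level 0 = leaf-most labeled rank; each labeled ancestor is one level
    further in (its font shrinks accordingly)."""
    labeled_set = set(labeled)
    levels: Dict[TreeNode, int] = {}

    def depth_below(node: TreeNode) -> int:
        best = -1
        for child in node.children:
            d = depth_below(child)
            if d > best:
                best = d
        if node in labeled_set:
            levels[node] = best + 1 if best >= 0 else 0
            return levels[node]
        return best

    depth_below(tree.root)
    return levels


def build_scene(
    tree: Tree,
    sheet: StyleSheet,
    layout: PolarLayout,
    max_inline_chars: int = 20,
    ring_base_gap: float = 0.05,
) -> SceneGraph:
    """Assemble the ordered primitive list for one plot.

    Pure function of its inputs: equal (tree, stylesheet, layout) triples
    yield equal scene graphs.
    """
    if sheet.tree is not tree:
        raise PhyloringError("stylesheet was resolved for a different tree")
    scene = SceneGraph()
    parents = tree.parent_map()

    # external rings -------------------------------------------------------
    indices = sheet.ring_indices()
    heights = {idx: sheet.get_ring(idx, "ring_height") for idx in indices}
    intervals = ring_intervals(heights, base_gap=ring_base_gap)
    leaves = layout.leaf_order
    for idx in indices:
        explicit = [l for l in leaves if sheet.has_ring_cell(idx, l)]
        cell_leaves = explicit if explicit else list(leaves)
        shape_of = {l: sheet.get_ring_cell(idx, l, "ring_shape") for l in cell_leaves}
        bar_max = max(
            (
                sheet.get_ring_cell(idx, l, "ring_height")
                for l in cell_leaves
                if shape_of[l] == "bar"
            ),
            default=1.0,
        )
        for leaf in cell_leaves:
            color = sheet.get_ring_cell(idx, leaf, "ring_color")
            shape = shape_of[leaf]
            slot = layout.leaf_slots[leaf]
            if shape == "sector":
                cell = ring_cell_primitive(
                    "sector",
                    slot,
                    intervals[idx],
                    color,
                    heat_value=sheet.get_ring_cell(idx, leaf, "ring_alpha"),
                )
            elif shape == "bar":
                cell = ring_cell_primitive(
                    "bar",
                    slot,
                    intervals[idx],
                    color,
                    bar_value=sheet.get_ring_cell(idx, leaf, "ring_height"),
                    bar_max=bar_max,
                )
            else:
                cell = ring_cell_primitive(
                    "glyph", slot, intervals[idx], color, shape=shape
                )
            scene.ring_cells.append(cell)
    outer = max((iv[1] for iv in intervals.values()), default=1.0)

    # background wedges and labels ----------------------------------------
    labeled = sheet.labeled_nodes()
    levels = _label_levels(tree, labeled)
    label_items: List[Tuple[str, Wedge, TreeNode]] = []
    for node in labeled:
        wedge = clade_wedge(node, layout, r_outer=1.0)
        bg = sheet.get_node(node, "annotation_background_color")
        if bg is not None:
            scene.wedges.append(WedgeFill(wedge, bg))
        text = sheet.get_node(node, "annotation")
        if text:
            label_items.append((text, wedge, node))
    inline, legend = make_label_legend(
        [(t, w) for t, w, _ in label_items], max_inline_chars=max_inline_chars
    )
    order = sorted(
        range(len(label_items)), key=lambda i: (label_items[i][1].theta_min, i)
    )
    key_by_index = {
        i: _legend_key(k)
        for k, i in enumerate(j for j in order if j not in inline)
    }
    for i, (text, wedge, node) in enumerate(label_items):
        size = sheet.get_node(node, "annotation_font_size")
        if size is None:
            size = annotation_font_size(levels.get(node, 0))
        mid_theta = (wedge.theta_min + wedge.theta_max) / 2.0
        mid_r = (wedge.r_min + wedge.r_max) / 2.0
        content = text if i in inline else key_by_index[i]
        scene.texts.append(
            TextLabel(content, mid_theta, mid_r, size, BLACK)
        )
    scene.legend = [LegendEntry(k, l) for k, l in legend.entries]

    # branches -------------------------------------------------------------
    for node in tree.root.iter_preorder():
        parent = parents[node]
        if parent is None:
            continue
        color = sheet.get_node(node, "branch_color")
        thickness = sheet.get_node(node, "branch_thickness")
        scene.branches.append(
            BranchPath(
                theta_child=layout.node_theta[node],
                r_child=layout.node_r[node],
                theta_parent=layout.node_theta[parent],
                r_parent=layout.node_r[parent],
                color=color,
                thickness=thickness,
            )
        )

    # node markers ---------------------------------------------------------
    for node in tree.root.iter_preorder():
        size = sheet.get_node(node, "clade_marker_size")
        if size > 0:
            scene.markers.append(
                Marker(
                    theta=layout.node_theta[node],
                    r=layout.node_r[node],
                    shape=sheet.get_node(node, "clade_marker_shape"),
                    size=size,
                    color=sheet.get_node(node, "clade_marker_color"),
                )
            )
    scene.r_extent = outer
    return scene


# ---------------------------------------------------------------------------
# SVG serialization


def _f(x: float) -> str:
    s = f"{x:.6f}"
    return "0.000000" if s == "-0.000000" else s


def _rgb(c: ColorSpec) -> str:
    return "#%02x%02x%02x" % (
        round(c.r * 255),
        round(c.g * 255),
        round(c.b * 255),
    )


class _Mapper:
    """Unit-circle -> pixel mapping (y flipped for SVG)."""

    def __init__(self, canvas: CanvasConfig, r_extent: float):
        self.c = canvas.size_px / 2.0
        self.scale = (canvas.size_px / 2.0) * (1.0 - canvas.margin) / max(r_extent, 1e-9)

    def pt(self, theta: float, r: float) -> Tuple[float, float]:
        x, y = polar_to_cartesian(theta, r)
        return self.c + self.scale * x, self.c - self.scale * y


def _sector_path(m: _Mapper, t0, t1, r0, r1) -> str:
    large = 1 if (t1 - t0) % 360 > 180 else 0
    x0, y0 = m.pt(t0, r0)
    x1, y1 = m.pt(t1, r0)
    x2, y2 = m.pt(t1, r1)
    x3, y3 = m.pt(t0, r1)
    ri = m.scale * r0
    ro = m.scale * r1
    return (
        f"M {_f(x0)} {_f(y0)} "
        f"A {_f(ri)} {_f(ri)} 0 {large} 0 {_f(x1)} {_f(y1)} "
        f"L {_f(x2)} {_f(y2)} "
        f"A {_f(ro)} {_f(ro)} 0 {large} 1 {_f(x3)} {_f(y3)} Z"
    )


def _marker_path(shape: str, cx: float, cy: float, radius: float) -> str:
    if shape == "square":
        pts = [(cx - radius, cy - radius), (cx + radius, cy - radius),
               (cx + radius, cy + radius), (cx - radius, cy + radius)]
    elif shape in ("triangle", "triangle-up"):
        pts = [(cx, cy - radius), (cx + radius, cy + radius), (cx - radius, cy + radius)]
    elif shape == "triangle-down":
        pts = [(cx, cy + radius), (cx - radius, cy - radius), (cx + radius, cy - radius)]
    elif shape == "hexagon":
        pts = [
            (cx + radius * math.cos(math.radians(60 * k - 30)),
             cy + radius * math.sin(math.radians(60 * k - 30)))
            for k in range(6)
        ]
    elif shape == "star":
        pts = []
        for k in range(10):
            rr = radius if k % 2 == 0 else radius * 0.45
            ang = math.radians(36 * k - 90)
            pts.append((cx + rr * math.cos(ang), cy + rr * math.sin(ang)))
    else:
        raise PhyloringError(f"unknown marker shape {shape!r}")
    d = "M " + " L ".join(f"{_f(x)} {_f(y)}" for x, y in pts) + " Z"
    return d


def render_svg(scene: SceneGraph, canvas: CanvasConfig = CanvasConfig()) -> str:
    """Serialize a scene as SVG 1.1 text (byte-identical for equal scenes)."""
    m = _Mapper(canvas, scene.r_extent)
    size = canvas.size_px
    out: List[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{size}" height="{size}" viewBox="0 0 {size} {size}">',
        f'<rect class="background" width="{size}" height="{size}" '
        f'fill="{canvas.background}"/>',
        '<g class="plot">',
    ]
    for w in scene.wedges:
        d = _sector_path(m, w.wedge.theta_min, w.wedge.theta_max, w.wedge.r_min, w.wedge.r_max)
        out.append(
            f'<path class="wedge" d="{d}" fill="{_rgb(w.color)}" '
            f'fill-opacity="{_f(w.color.a)}" stroke="none"/>'
        )
    for cell in scene.ring_cells:
        if cell.kind == "glyph":
            mid_t = (cell.theta0 + cell.theta1) / 2.0
            mid_r = (cell.r0 + cell.r1) / 2.0
            cx, cy = m.pt(mid_t, mid_r)
            band_px = m.scale * (cell.r1 - cell.r0)
            arc_px = m.scale * mid_r * math.radians(cell.theta1 - cell.theta0)
            radius = 0.4 * min(band_px, arc_px) if min(band_px, arc_px) > 0 else 1.0
            if cell.shape == "circle":
                out.append(
                    f'<circle class="ring-glyph" cx="{_f(cx)}" cy="{_f(cy)}" '
                    f'r="{_f(radius)}" fill="{_rgb(cell.color)}" '
                    f'fill-opacity="{_f(cell.color.a)}"/>'
                )
            else:
                d = _marker_path(cell.shape, cx, cy, radius)
                out.append(
                    f'<path class="ring-glyph" d="{d}" fill="{_rgb(cell.color)}" '
                    f'fill-opacity="{_f(cell.color.a)}"/>'
                )
        else:
            if cell.r1 <= cell.r0:  # zero-height bar: nothing to draw
                continue
            d = _sector_path(m, cell.theta0, cell.theta1, cell.r0, cell.r1)
            cls = "ring-bar" if cell.kind == "bar" else "ring-cell"
            out.append(
                f'<path class="{cls}" d="{d}" fill="{_rgb(cell.color)}" '
                f'fill-opacity="{_f(cell.color.a)}" stroke="none"/>'
            )
    for b in scene.branches:
        x0, y0 = m.pt(b.theta_child, b.r_child)
        x1, y1 = m.pt(b.theta_child, b.r_parent)
        x2, y2 = m.pt(b.theta_parent, b.r_parent)
        rr = m.scale * b.r_parent
        dt = b.theta_parent - b.theta_child
        sweep = 0 if dt > 0 else 1
        large = 1 if abs(dt) > 180 else 0
        d = f"M {_f(x0)} {_f(y0)} L {_f(x1)} {_f(y1)}"
        if abs(dt) > 1e-12 and rr > 0:
            d += f" A {_f(rr)} {_f(rr)} 0 {large} {sweep} {_f(x2)} {_f(y2)}"
        out.append(
            f'<path class="branch" d="{d}" fill="none" stroke="{_rgb(b.color)}" '
            f'stroke-opacity="{_f(b.color.a)}" stroke-width="{_f(b.thickness)}"/>'
        )
    for mk in scene.markers:
        cx, cy = m.pt(mk.theta, mk.r)
        if mk.shape == "circle":
            out.append(
                f'<circle class="marker" cx="{_f(cx)}" cy="{_f(cy)}" '
                f'r="{_f(mk.size / 2.0)}" fill="{_rgb(mk.color)}" '
                f'fill-opacity="{_f(mk.color.a)}"/>'
            )
        else:
            d = _marker_path(mk.shape, cx, cy, mk.size / 2.0)
            out.append(
                f'<path class="marker" d="{d}" fill="{_rgb(mk.color)}" '
                f'fill-opacity="{_f(mk.color.a)}"/>'
            )
    for t in scene.texts:
        x, y = m.pt(t.theta, t.r)
        rot = (90.0 - t.theta) % 360.0
        if 90.0 < rot <= 270.0:  # flip in the lower half for readability
            rot = (rot + 180.0) % 360.0
        transform = f' transform="rotate({_f(rot)} {_f(x)} {_f(y)})"' if t.follow_tangent else ""
        out.append(
            f'<text class="clade-label" x="{_f(x)}" y="{_f(y)}" '
            f'font-size="{_f(t.font_size)}" fill="{_rgb(t.color)}" '
            f'text-anchor="middle"{transform}>{escape(t.content)}</text>'
        )
    for i, entry in enumerate(scene.legend):
        y = 20.0 + 14.0 * i
        out.append(
            f'<text class="legend" x="10.000000" y="{_f(y)}" font-size="10.000000" '
            f'fill="#000000">{escape(entry.key)}: {escape(entry.label)}</text>'
        )
    out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"
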