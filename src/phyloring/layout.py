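"""Circular geometry, as pure data.

Leaves are laid out depth-first in input child order and each one owns an
equal angular slot; leaf i of n gets

    theta_i = start_rotation + (i + 0.5) * total_degrees / n

(the half-open slot of width ``total_degrees / n`` is centred on it).
Internal nodes sit at the midpoint of their leaf-descendant angular span.
Radius is normalized to the unit circle: ``depth / max_depth`` for
cladograms, cumulative root-path branch length over the maximum for
phylograms (so the layout is invariant under uniform rescaling of branch
lengths).  External rings stack outside r = 1.

Angles are degrees throughout; conversion to radians happens only in
:func:`polar_to_cartesian`, with 0 degrees on the +x axis and angles
increasing counterclockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .errors import LayoutError
from .tree import Tree, TreeNode

__all__ = [
    "PolarLayout",
    "Wedge",
    "assign_leaf_angles",
    "internal_angles",
    "assign_radii",
    "clade_wedge",
    "ring_intervals",
    "polar_to_cartesian",
    "compute_layout",
]


@dataclass(frozen=True)
class Wedge:
    """Angular sector spanned by a clade: used for background highlights."""

    theta_min: float
    theta_max: float
    r_min: float
    r_max: float

    def __post_init__(self):
        if not (self.theta_min < self.theta_max and self.r_min < self.r_max):
            raise LayoutError(f"degenerate wedge {self}")


@dataclass
class PolarLayout:
    node_theta: Dict[TreeNode, float]
    node_r: Dict[TreeNode, float]
    leaf_order: List[TreeNode]
    leaf_slots: Dict[TreeNode, Tuple[float, float]]
    total_degrees: float
    start_rotation: float
    mode: str  # "cladogram" | "phylogram"


def assign_leaf_angles(
    tree: Tree, total_degrees: float = 360.0, start_rotation: float = 0.0
) -> Dict[TreeNode, float]:
    """Equal angular slot per leaf, depth-first input order."""
    if not (0 < total_degrees <= 360):
        raise LayoutError(f"total_degrees must be in (0, 360], got {total_degrees}")
    leaves = tree.leaves()
    if not leaves:
        raise LayoutError("empty tree")
    width = total_degrees / len(leaves)
    return {
        leaf: start_rotation + (i + 0.5) * width for i, leaf in enumerate(leaves)
    }


def leaf_slots(
    tree: Tree, total_degrees: float = 360.0, start_rotation: float = 0.0
) -> Dict[TreeNode, Tuple[float, float]]:
    leaves = tree.leaves()
    width = total_degrees / len(leaves)
    return {
        leaf: (start_rotation + i * width, start_rotation + (i + 1) * width)
        for i, leaf in enumerate(leaves)
    }


def internal_angles(
    tree: Tree, leaf_angles: Mapping[TreeNode, float]
) -> Dict[TreeNode, float]:
    """Each internal node at the midpoint of its leaf-descendant span."""
    thetas: Dict[TreeNode, float] = {}

    def visit(node: TreeNode) -> Tuple[float, float]:
        if node.is_leaf:
            t = leaf_angles[node]
            thetas[node] = t
            return t, t
        spans = [visit(c) for c in node.children]
        lo = min(s[0] for s in spans)
        hi = max(s[1] for s in spans)
        thetas[node] = (lo + hi) / 2.0
        return lo, hi

    visit(tree.root)
    return thetas


def assign_radii(tree: Tree, mode: str = "cladogram") -> Dict[TreeNode, float]:
    """Radius per node, normalized so the deepest node sits at r = 1.

    ``cladogram``: r = depth / max_depth.  ``phylogram``: r = cumulative
    root-path length / maximum cumulative length (requires branch lengths on
    all non-root nodes; zero lengths collapse a node onto its parent's
    radius).
    """
    radii: Dict[TreeNode, float] = {}
    if mode == "cladogram":
        max_depth = tree.max_depth
        if max_depth == 0:
            return {tree.root: 0.0}

        def walk(node: TreeNode, depth: int) -> None:
            radii[node] = depth / max_depth
            for c in node.children:
                walk(c, depth + 1)

        walk(tree.root, 0)
        return radii
    if mode == "phylogram":
        dist: Dict[TreeNode, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            dist[node] = acc
            for c in node.children:
                if c.branch_length is None:
                    raise LayoutError(
                        f"phylogram layout needs branch lengths; {c.name!r} has none"
                    )
                walk(c, acc + c.branch_length)

        walk(tree.root, 0.0)
        maximum = max(dist.values())
        if maximum <= 0:
            raise LayoutError("all branch lengths are zero")
        return {node: d / maximum for node, d in dist.items()}
    raise LayoutError(f"unknown layout mode {mode!r}")


def clade_wedge(
    node: TreeNode,
    layout: PolarLayout,
    r_outer: float = 1.0,
) -> Wedge:
    """Angular extent = [first leaf slot start, last leaf slot end] over the
    node's leaf descendants; radial extent = [node's radius, r_outer]."""
    leaves = list(node.iter_leaves())
    t0 = min(layout.leaf_slots[l][0] for l in leaves)
    t1 = max(layout.leaf_slots[l][1] for l in leaves)
    r_min = layout.node_r[node]
    if r_min >= r_outer:  # leaf at the rim still gets a drawable band
        r_min = max(0.0, r_outer - 1e-6)
    return Wedge(t0, t1, r_min, r_outer)


def ring_intervals(
    heights: Mapping[int, float], base_gap: float = 0.05
) -> Dict[int, Tuple[float, float]]:
    """Stack ring bands outside the unit circle.

    Ring with the lowest index starts at ``1 + base_gap``; each next ring's
    inner radius is the previous ring's outer radius; widths are the given
    heights.
    """
    intervals: Dict[int, Tuple[float, float]] = {}
    r = 1.0 + base_gap
    for idx in sorted(heights):
        h = heights[idx]
        if h <= 0:
            raise LayoutError(f"ring {idx} height must be positive, got {h}")
        intervals[idx] = (r, r + h)
        r += h
    return intervals


def polar_to_cartesian(theta_degrees: float, r: float) -> Tuple[float, float]:
    """Counterclockwise, 0 degrees at the +x axis."""
    t = math.radians(theta_degrees)
    return r * math.cos(t), r * math.sin(t)


def _ladderize(node: TreeNode, ascending: bool) -> None:
    counts = {}

    def count(n: TreeNode) -> int:
        counts[n] = 1 if n.is_leaf else sum(count(c) for c in n.children)
        return counts[n]

    count(node)

    def sort(n: TreeNode) -> None:
        n.children.sort(key=lambda c: counts[c], reverse=not ascending)
        for c in n.children:
            sort(c)

    sort(node)


def compute_layout(
    tree: Tree,
    total_degrees: float = 360.0,
    start_rotation: float = 0.0,
    mode: str = "auto",
    ladderize: Optional[str] = None,
) -> PolarLayout:
    """Full polar layout for a tree.

    ``mode="auto"`` draws a phylogram when every non-root node has a branch
    length, a cladogram otherwise.  ``ladderize`` ("ascending"/"descending")
    reorders children by subtree size before layout; default is the input
    order, for reproducibility.
    """
    if ladderize is not None:
        if ladderize not in ("ascending", "descending"):
            raise LayoutError(f"unknown ladderize mode {ladderize!r}")
        _ladderize(tree.root, ladderize == "ascending")
    if mode == "auto":
        mode = "phylogram" if tree.is_phylogenetic and tree.max_depth > 0 else "cladogram"
    leaf_theta = assign_leaf_angles(tree, total_degrees, start_rotation)
    slots = leaf_slots(tree, total_degrees, start_rotation)
    return PolarLayout(
        node_theta=internal_angles(tree, leaf_theta),
        node_r=assign_radii(tree, mode),
        leaf_order=tree.leaves(),
        leaf_slots=slots,
        total_degrees=total_degrees,
        start_rotation=start_rotation,
        mode=mode,
    )
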