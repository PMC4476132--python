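"""The tab-delimited annotation language and its resolution onto a tree.

An annotation file drives every visual aspect of a plot without ever
touching tree structure.  Grammar (UTF-8, tab-separated, ``#`` comments):

* two fields — a global directive: ``option<TAB>value``;
* three fields — a targeted directive: ``target<TAB>option<TAB>value``.

Targets address nodes by bare name, or by dotted lineage when a bare name is
ambiguous.  Two wildcard suffixes share a directive across a sub-tree:
``path*`` selects the node and all its descendants, ``path+`` only its
terminal (leaf) descendants.  External-ring options fuse a 1-based ring
index into the option field, e.g. ``ring_color:2``.

Resolution is strictly positional: later directives override earlier ones
for the same node+option; directives touching disjoint pairs commute.
Unmatched targets warn rather than fail so one generated annotation file can
serve several trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .colors import ColorSpec, resolve_color
from .errors import AnnotationError
from .tree import LineagePath, Tree, TreeNode

__all__ = [
    "Directive",
    "StyleSheet",
    "parse_annotation_file",
    "resolve_targets",
    "apply_stylesheet",
    "reannotate",
    "GLOBAL_OPTIONS",
    "NODE_OPTIONS",
    "LABEL_OPTIONS",
    "RING_OPTIONS",
]

MARKER_SHAPES = ("circle", "square", "triangle", "star", "hexagon")
RING_SHAPES = ("bar", "circle", "triangle-up", "triangle-down")


def _typed(kind, default, choices=None):
    return {"kind": kind, "default": default, "choices": choices}


#: image-level options (empty target field)
GLOBAL_OPTIONS = {
    "total_plotted_degrees": _typed(float, 360.0),
    "start_rotation": _typed(float, 0.0),
    "branch_color": _typed(ColorSpec, ColorSpec(0.0, 0.0, 0.0, 1.0)),
    "branch_thickness": _typed(float, 0.75),
}

#: per-node marker / branch options
NODE_OPTIONS = {
    "clade_marker_size": _typed(float, 4.0),
    "clade_marker_color": _typed(ColorSpec, ColorSpec(0.2, 0.2, 0.2, 1.0)),
    "clade_marker_shape": _typed(str, "circle", MARKER_SHAPES),
    "branch_color": _typed(ColorSpec, None),  # None -> inherit global
    "branch_thickness": _typed(float, None),
}

#: clade-label options (background wedge + text)
LABEL_OPTIONS = {
    "annotation": _typed(str, ""),
    "annotation_background_color": _typed(ColorSpec, None),
    "annotation_font_size": _typed(float, None),  # None -> auto by level
}

#: external-ring options; each carries a 1-based ring index (``option:k``).
#: A ring cell defaults to a heatmap sector: ``ring_alpha`` is the blank->
#: full-color intensity in [0, 1]; ``ring_shape`` switches the cell to a
#: glyph (circle / triangle-up / triangle-down) or a radial bar, in which
#: case the per-cell ``ring_height`` is the bar value (normalized per ring
#: by its maximum) while the per-ring global ``ring_height`` stays the band
#: width.
RING_OPTIONS = {
    "ring_color": _typed(ColorSpec, ColorSpec(0.2, 0.2, 0.2, 1.0)),
    "ring_height": _typed(float, 0.1),
    "ring_shape": _typed(str, "sector", RING_SHAPES + ("sector",)),
    "ring_alpha": _typed(float, 1.0),
}

_NODE_AND_LABEL = {**NODE_OPTIONS, **LABEL_OPTIONS}


@dataclass(frozen=True)
class Directive:
    """One parsed annotation statement."""

    target: str  # "" for global; may end in "*" or "+"
    option: str
    value: object
    ring_index: Optional[int] = None
    source_line: int = 0

    @property
    def is_global(self) -> bool:
        return self.target == ""

    @property
    def is_ring(self) -> bool:
        return self.ring_index is not None


def _parse_value(option: str, raw: str, spec, line: int):
    kind = spec["kind"]
    try:
        if kind is float:
            value = float(raw)
        elif kind is ColorSpec:
            value = resolve_color(raw)
        else:
            value = raw
    except (ValueError, AnnotationError):
        raise AnnotationError(
            f"value {raw!r} is not a valid {option}", line=line
        ) from None
    choices = spec.get("choices")
    if choices and value not in choices:
        raise AnnotationError(
            f"{option} must be one of {', '.join(choices)}; got {raw!r}", line=line
        )
    return value


def _split_ring_option(field_text: str, line: int) -> Tuple[str, Optional[int]]:
    if ":" in field_text:
        name, _, idx_text = field_text.partition(":")
        if name not in RING_OPTIONS:
            raise AnnotationError(f"unknown ring option {name!r}", line=line)
        try:
            idx = int(idx_text)
        except ValueError:
            raise AnnotationError(
                f"ring index {idx_text!r} is not an integer", line=line
            ) from None
        if idx < 1:
            raise AnnotationError(f"ring index must be >= 1, got {idx}", line=line)
        return name, idx
    return field_text, None


def parse_annotation_file(lines: Sequence[str]) -> List[Directive]:
    """Parse annotation lines into directives, in file order.

    Blank lines and ``#`` comments are skipped; any malformed line raises
    :class:`AnnotationError` naming its line number.
    """
    directives: List[Directive] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 2:
            target, (opt_field, value_raw) = "", fields
        elif len(fields) == 3:
            target, opt_field, value_raw = fields
        else:
            raise AnnotationError(
                f"expected 2 or 3 tab-separated fields, got {len(fields)}",
                line=lineno,
            )
        option, ring_index = _split_ring_option(opt_field, lineno)
        if ring_index is not None:
            spec = RING_OPTIONS[option]
        elif target == "":
            if option not in GLOBAL_OPTIONS:
                raise AnnotationError(f"unknown global option {option!r}", line=lineno)
            spec = GLOBAL_OPTIONS[option]
        else:
            if option not in _NODE_AND_LABEL:
                raise AnnotationError(f"unknown option {option!r}", line=lineno)
            spec = _NODE_AND_LABEL[option]
        value = _parse_value(option, value_raw, spec, lineno)
        directives.append(
            Directive(
                target=target,
                option=option,
                value=value,
                ring_index=ring_index,
                source_line=lineno,
            )
        )
    return directives


# ---------------------------------------------------------------------------
# target resolution


class UnmatchedTargetWarning(UserWarning):
    pass


def resolve_targets(directive: Directive, tree: Tree) -> List[TreeNode]:
    """Nodes selected by a targeted directive.

    ``path`` -> the unique named node; ``path*`` -> it plus all descendants;
    ``path+`` -> its terminal descendants only.  A target that matches no
    node warns and returns the empty set.
    """
    if directive.is_global:
        raise AnnotationError("global directives have no target")
    target = directive.target
    mode = "exact"
    if target.endswith("*"):
        target, mode = target[:-1], "subtree"
    elif target.endswith("+"):
        target, mode = target[:-1], "leaves"
    try:
        path = LineagePath.from_text(target)
    except Exception:
        warnings.warn(
            f"malformed target {directive.target!r}", UnmatchedTargetWarning
        )
        return []
    matches = tree.find_by_lineage(path)
    if not matches:
        warnings.warn(
            f"annotation target {directive.target!r} matches no node",
            UnmatchedTargetWarning,
        )
        return []
    if len(matches) > 1:
        lineages = ", ".join(str(tree.lineage_of(m)) for m in matches)
        raise AnnotationError(
            f"target {directive.target!r} is ambiguous; candidates: {lineages}"
        )
    node = matches[0]
    if mode == "exact":
        return [node]
    if mode == "subtree":
        return list(node.iter_preorder())
    return list(node.iter_leaves())


# ---------------------------------------------------------------------------
# the resolved stylesheet


class StyleSheet:
    """Resolved visual properties for one tree.

    Covers exactly the nodes of the tree it was built from — annotation
    never adds or removes nodes.  Lookups fall back to the option defaults,
    so every node has a defined value for every node/label option.
    """

    def __init__(self, tree: Tree):
        self.tree = tree
        self.global_settings: Dict[str, object] = {}
        self.node_settings: Dict[TreeNode, Dict[str, object]] = {}
        self.ring_defaults: Dict[int, Dict[str, object]] = {}
        self.ring_cells: Dict[Tuple[int, TreeNode], Dict[str, object]] = {}

    # -- lookups ------------------------------------------------------------

    def get_global(self, option: str):
        if option in self.global_settings:
            return self.global_settings[option]
        return GLOBAL_OPTIONS[option]["default"]

    def get_node(self, node: TreeNode, option: str):
        over = self.node_settings.get(node, {})
        if option in over:
            return over[option]
        default = _NODE_AND_LABEL[option]["default"]
        if default is None and option in GLOBAL_OPTIONS:
            return self.get_global(option)  # branch options inherit global
        return default

    def get_ring(self, ring: int, option: str):
        over = self.ring_defaults.get(ring, {})
        if option in over:
            return over[option]
        return RING_OPTIONS[option]["default"]

    def get_ring_cell(self, ring: int, leaf: TreeNode, option: str):
        over = self.ring_cells.get((ring, leaf), {})
        if option in over:
            return over[option]
        return self.get_ring(ring, option)

    def ring_indices(self) -> List[int]:
        indices = set(self.ring_defaults) | {ring for ring, _ in self.ring_cells}
        return sorted(indices)

    def has_ring_cell(self, ring: int, leaf: TreeNode) -> bool:
        return (ring, leaf) in self.ring_cells

    def labeled_nodes(self) -> List[TreeNode]:
        """Nodes with a clade label or background, in pre-order."""
        out = []
        for node in self.tree.root.iter_preorder():
            over = self.node_settings.get(node, {})
            if over.get("annotation") or over.get("annotation_background_color"):
                out.append(node)
        return out

    # -- mutation (module-internal) ----------------------------------------

    def _set(self, directive: Directive, nodes: List[TreeNode]) -> None:
        if directive.is_ring:
            if directive.is_global:
                self.ring_defaults.setdefault(directive.ring_index, {})[
                    directive.option
                ] = directive.value
            else:
                for node in nodes:
                    self.ring_cells.setdefault((directive.ring_index, node), {})[
                        directive.option
                    ] = directive.value
            return
        if directive.is_global:
            self.global_settings[directive.option] = directive.value
            return
        for node in nodes:
            value = directive.value
            # "*" as a label text means "use the node's own name"
            if directive.option == "annotation" and value == "*":
                value = node.name
            self.node_settings.setdefault(node, {})[directive.option] = value


def apply_stylesheet(
    tree: Tree,
    directives: Sequence[Directive],
    base: Optional[StyleSheet] = None,
) -> StyleSheet:
    """Resolve directives onto a tree, in order, last-wins.

    ``base`` carries previously resolved properties (re-annotation); new
    directives override on collision and everything else is retained.
    """
    sheet = StyleSheet(tree)
    if base is not None:
        if base.tree is not tree:
            raise AnnotationError("stylesheet was resolved for a different tree")
        sheet.global_settings.update(base.global_settings)
        for node, over in base.node_settings.items():
            sheet.node_settings[node] = dict(over)
        for ring, over in base.ring_defaults.items():
            sheet.ring_defaults[ring] = dict(over)
        for key, over in base.ring_cells.items():
            sheet.ring_cells[key] = dict(over)
    for directive in directives:
        if directive.is_global and not directive.is_ring:
            sheet._set(directive, [])
        elif directive.is_global and directive.is_ring:
            sheet._set(directive, [])
        else:
            nodes = resolve_targets(directive, tree)
            sheet._set(directive, nodes)
    return sheet


def reannotate(
    tree: Tree, base: StyleSheet, directives: Sequence[Directive]
) -> StyleSheet:
    """Apply further directives to an already-styled tree (override on
    collision, retain otherwise).  Applying the same file twice is a
    no-op relative to applying it once."""
    return apply_stylesheet(tree, directives, base=base)


# ---------------------------------------------------------------------------
# persistence through the PhyloXML intermediate


def _value_to_text(option: str, value) -> str:
    if isinstance(value, ColorSpec):
        return value.to_hex()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def attach_to_tree(sheet: StyleSheet) -> None:
    """Write resolved overrides into ``node.props`` / ``tree.props`` so that
    :func:`phyloring.tree_io.write_phyloxml` persists them (one property per
    option per clade, ring options keyed ``option:index``)."""
    tree = sheet.tree
    tree.props = {
        opt: _value_to_text(opt, val) for opt, val in sheet.global_settings.items()
    }
    for ring, over in sheet.ring_defaults.items():
        for opt, val in over.items():
            tree.props[f"{opt}:{ring}"] = _value_to_text(opt, val)
    for node in tree.root.iter_preorder():
        props: Dict[str, str] = {}
        for opt, val in sheet.node_settings.get(node, {}).items():
            props[opt] = _value_to_text(opt, val)
        node.props = props
    for (ring, node), over in sheet.ring_cells.items():
        for opt, val in over.items():
            node.props[f"{opt}:{ring}"] = _value_to_text(opt, val)


def stylesheet_from_tree(tree: Tree) -> StyleSheet:
    """Rebuild a StyleSheet from properties embedded in a tree (the inverse
    of :func:`attach_to_tree`, used when re-reading the PhyloXML
    intermediate)."""
    sheet = StyleSheet(tree)

    def parse_prop(option_field: str, raw: str, bucket, ring_bucket):
        name, _, idx_text = option_field.partition(":")
        if idx_text and name in RING_OPTIONS and idx_text.isdigit():
            value = _parse_value(name, raw, RING_OPTIONS[name], 0)
            ring_bucket(int(idx_text), name, value)
            return
        spec = _NODE_AND_LABEL.get(option_field) or GLOBAL_OPTIONS.get(option_field)
        if spec is None:
            return  # foreign property: preserved in props, not styled
        value = _parse_value(option_field, raw, spec, 0)
        bucket(option_field, value)

    parse_prop_tree = lambda opt, val: sheet.global_settings.__setitem__(opt, val)
    for option_field, raw in tree.props.items():
        parse_prop(
            option_field,
            raw,
            parse_prop_tree,
            lambda ring, opt, val: sheet.ring_defaults.setdefault(ring, {}).__setitem__(
                opt, val
            ),
        )
    for node in tree.root.iter_preorder():
        for option_field, raw in node.props.items():
            parse_prop(
                option_field,
                raw,
                lambda opt, val, n=node: sheet.node_settings.setdefault(
                    n, {}
                ).__setitem__(opt, val),
                lambda ring, opt, val, n=node: sheet.ring_cells.setdefault(
                    (ring, n), {}
                ).__setitem__(opt, val),
            )
    return sheet
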