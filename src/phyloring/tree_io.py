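"""Tree readers and writers.

Four input formats are supported — Newick, Nexus (first tree of the TREES
block, TRANSLATE honoured), PhyloXML, and a plain-text one-lineage-per-line
format — plus format auto-detection by leading content.  PhyloXML doubles as
the annotated intermediate: per-node style properties ride along as
namespaced ``<property>`` elements, so a styled tree survives a write/parse
round trip losslessly.

All writers are deterministic: fixed element/attribute order and
shortest-round-trip decimal formatting, so equal inputs produce
byte-identical files.
"""

from __future__ import annotations

import re
from io import StringIO
from typing import Dict, List, Optional, Sequence, Tuple

from lxml import etree

from .errors import FormatError, TreeParseError
from .tree import LineagePath, Tree, TreeNode

__all__ = [
    "detect_format",
    "parse_newick",
    "write_newick",
    "parse_plain_lineages",
    "write_plain_lineages",
    "parse_phyloxml",
    "write_phyloxml",
    "parse_nexus",
    "read_tree",
]

PHYLOXML_NS = "http://www.phyloxml.org"
XSI_NS = "http://www.w3.org/2001/XMLSchema-instance"
STYLE_PREFIX = "style:"


# ---------------------------------------------------------------------------
# format detection


def detect_format(text: str) -> str:
    """Classify raw input as ``newick``, ``nexus``, ``phyloxml`` or ``plain``.

    Detection looks at leading content only, never at a filename.
    """
    stripped = text.lstrip("﻿ \t\r\n")
    if not stripped:
        raise FormatError("empty input")
    if stripped[:6].upper() == "#NEXUS":
        return "nexus"
    if stripped.startswith("<"):
        return "phyloxml"
    if "(" in text or ";" in text:
        return "newick"
    return "plain"


def read_tree(text: str, fmt: Optional[str] = None, auto_rename: bool = False) -> Tree:
    """Parse ``text`` in the given (or auto-detected) format."""
    fmt = fmt or detect_format(text)
    if fmt == "newick":
        return parse_newick(text, auto_rename=auto_rename)
    if fmt == "nexus":
        return parse_nexus(text, auto_rename=auto_rename)
    if fmt == "phyloxml":
        return parse_phyloxml(text, auto_rename=auto_rename)
    if fmt == "plain":
        return parse_plain_lineages(text.splitlines(), auto_rename=auto_rename)
    raise FormatError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Newick
#
# Hand-written tokenizer: we need exact child-order preservation, error
# offsets, and control over the quoting dialect (single-quoted labels with
# '' escapes in; canonical quoting out).  Bio.Phylo serves as an independent
# cross-check in the test suite.

_NEWICK_SPECIALS = set("()[]{}:;,'\t\n ")


def parse_newick(
    text: str, auto_rename: bool = False, underscore_to_space: bool = False
) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    ``underscore_to_space`` enables the classic dialect in which unquoted
    underscores stand for spaces; it is off by default because microbiome
    taxon names use underscores literally.
    """
    s = text.strip()
    if not s:
        raise FormatError("empty input")
    pos = 0
    n = len(s)

    def error(msg: str) -> TreeParseError:
        return TreeParseError(msg, offset=pos)

    def skip_ws():
        nonlocal pos
        while pos < n and s[pos] in " \t\r\n":
            pos += 1

    def read_label() -> str:
        nonlocal pos
        skip_ws()
        if pos < n and s[pos] == "'":
            pos += 1
            out = []
            while pos < n:
                if s[pos] == "'":
                    if pos + 1 < n and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(s[pos])
                pos += 1
            raise error("unterminated quoted label")
        out = []
        while pos < n and s[pos] not in _NEWICK_SPECIALS:
            out.append(s[pos])
            pos += 1
        label = "".join(out)
        if underscore_to_space:
            label = label.replace("_", " ")
        return label

    def read_length() -> Optional[float]:
        nonlocal pos
        skip_ws()
        if pos < n and s[pos] == ":":
            pos += 1
            skip_ws()
            m = re.match(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?", s[pos:])
            if not m:
                raise error("expected branch length after ':'")
            value = float(m.group(0))
            if value < 0:
                raise error(f"negative branch length {value}")
            pos += m.end()
            return value
        return None

    def read_subtree() -> TreeNode:
        nonlocal pos
        skip_ws()
        if pos < n and s[pos] == "(":
            pos += 1
            children = [read_subtree()]
            skip_ws()
            while pos < n and s[pos] == ",":
                pos += 1
                children.append(read_subtree())
                skip_ws()
            if pos >= n or s[pos] != ")":
                raise error("unbalanced parentheses: expected ')'")
            pos += 1
            node = TreeNode(name=read_label(), children=children)
        else:
            name = read_label()
            node = TreeNode(name=name)
        node.branch_length = read_length()
        return node

    root = read_subtree()
    skip_ws()
    if pos >= n or s[pos] != ";":
        raise error("missing ';' terminator")
    pos += 1
    skip_ws()
    if pos < n:
        raise error("trailing content after ';'")
    return Tree(root, auto_rename=auto_rename)


def _quote_label(name: str) -> str:
    if name and not any(c in _NEWICK_SPECIALS for c in name):
        return name
    if not name:
        return ""
    return "'" + name.replace("'", "''") + "'"


def _fmt_float(x: float) -> str:
    # repr() is the shortest decimal that round-trips the IEEE double
    return repr(float(x))


def write_newick(tree: Tree) -> str:
    """Canonical Newick: labels containing specials are single-quoted."""

    def fmt(node: TreeNode) -> str:
        label = _quote_label(node.name)
        bl = "" if node.branch_length is None else ":" + _fmt_float(node.branch_length)
        if node.is_leaf:
            return f"{label}{bl}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){label}{bl}"

    return fmt(tree.root) + ";\n"


# ---------------------------------------------------------------------------
# plain-text lineages (one dot-separated path per line)


def parse_plain_lineages(lines: Sequence[str], auto_rename: bool = False) -> Tree:
    """Build the prefix trie of all lineage paths under a synthetic unnamed
    root.  Duplicate lines collapse; sibling order is first appearance."""
    root = TreeNode(name="")
    seen_paths = set()
    any_line = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        any_line = True
        try:
            path = LineagePath.from_text(line)
        except TreeParseError as exc:
            raise TreeParseError(str(exc), line=lineno) from None
        if path.labels in seen_paths:
            continue
        seen_paths.add(path.labels)
        node = root
        for label in path.labels:
            for child in node.children:
                if child.name == label:
                    node = child
                    break
            else:
                child = TreeNode(name=label)
                node.children.append(child)
                node = child
    if not any_line:
        raise FormatError("empty input")
    return Tree(root, auto_rename=auto_rename)


def write_plain_lineages(tree: Tree) -> str:
    """One dot-joined root->leaf lineage per line, depth-first order."""
    out = []
    for leaf in tree.root.iter_leaves():
        out.append(str(tree.lineage_of(leaf)))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PhyloXML (the annotated intermediate)


def _q(tag: str) -> str:
    return f"{{{PHYLOXML_NS}}}{tag}"


def parse_phyloxml(document: str, auto_rename: bool = False) -> Tree:
    """Parse a PhyloXML document with exactly one ``<phylogeny>``.

    Style properties (``<property ref="style:...">``) are recovered into
    ``node.props`` / ``tree.props``; properties with other refs are
    preserved verbatim under their full ref.
    """
    try:
        xml_root = etree.fromstring(document.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise TreeParseError(f"malformed XML: {exc}") from None
    phylogenies = xml_root.findall(_q("phylogeny"))
    if len(phylogenies) != 1:
        raise TreeParseError(
            f"expected exactly one phylogeny element, found {len(phylogenies)}"
        )
    phylogeny = phylogenies[0]

    def read_props(elem) -> Dict[str, str]:
        props: Dict[str, str] = {}
        for prop in elem.findall(_q("property")):
            ref = prop.get("ref", "")
            key = ref[len(STYLE_PREFIX):] if ref.startswith(STYLE_PREFIX) else ref
            props[key] = prop.text or ""
        return props

    def read_clade(elem) -> TreeNode:
        name_el = elem.find(_q("name"))
        bl_el = elem.find(_q("branch_length"))
        bl = None
        if bl_el is not None and bl_el.text:
            bl = float(bl_el.text)
        elif elem.get("branch_length") is not None:
            bl = float(elem.get("branch_length"))
        node = TreeNode(name=name_el.text or "" if name_el is not None else "")
        node.branch_length = bl
        node.props = read_props(elem)
        for child_el in elem.findall(_q("clade")):
            node.children.append(read_clade(child_el))
        return node

    clade_el = phylogeny.find(_q("clade"))
    if clade_el is None:
        raise TreeParseError("phylogeny element has no clade")
    tree = Tree(read_clade(clade_el), auto_rename=auto_rename)
    tree.props = read_props(phylogeny)
    return tree


def write_phyloxml(tree: Tree) -> str:
    """Serialize a (possibly styled) tree as PhyloXML.

    Deterministic: fixed element order (name, branch_length, properties
    sorted by key, children in tree order) and shortest round-trip decimals.
    """
    nsmap = {None: PHYLOXML_NS, "xsi": XSI_NS}
    xml_root = etree.Element(_q("phyloxml"), nsmap=nsmap)
    xml_root.set(
        f"{{{XSI_NS}}}schemaLocation",
        "http://www.phyloxml.org http://www.phyloxml.org/1.10/phyloxml.xsd",
    )
    phylogeny = etree.SubElement(xml_root, _q("phylogeny"))
    phylogeny.set("rooted", "true")

    def write_props(elem, props: Dict[str, str], applies_to: str) -> None:
        for key in sorted(props):
            prop = etree.SubElement(elem, _q("property"))
            # keys that already carry a namespace are preserved verbatim
            prop.set("ref", key if ":" in key else STYLE_PREFIX + key)
            prop.set("applies_to", applies_to)
            prop.set("datatype", "xsd:string")
            prop.text = props[key]

    def write_clade(parent_el, node: TreeNode) -> None:
        clade = etree.SubElement(parent_el, _q("clade"))
        if node.name:
            etree.SubElement(clade, _q("name")).text = node.name
        if node.branch_length is not None:
            etree.SubElement(clade, _q("branch_length")).text = _fmt_float(
                node.branch_length
            )
        write_props(clade, node.props, "clade")
        for child in node.children:
            write_clade(clade, child)

    write_props(phylogeny, tree.props, "phylogeny")
    write_clade(phylogeny, tree.root)
    # property elements must precede clade per schema; move them first
    phylogeny[:] = sorted(
        phylogeny, key=lambda e: 0 if e.tag == _q("property") else 1
    )
    body = etree.tostring(
        xml_root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    return body.decode("utf-8")


# ---------------------------------------------------------------------------
# Nexus (via Bio.Phylo / Bio.Nexus, which honours TRANSLATE tables)


def parse_nexus(text: str, auto_rename: bool = False) -> Tree:
    """Parse the first tree of a Nexus TREES block."""
    from Bio import Phylo

    try:
        bio_trees = list(Phylo.parse(StringIO(text), "nexus"))
    except Exception as exc:
        raise TreeParseError(f"Nexus parse failed: {exc}") from None
    if not bio_trees:
        raise TreeParseError("Nexus input contains no TREES block / tree statement")

    def convert(clade) -> TreeNode:
        node = TreeNode(name=clade.name or "")
        node.branch_length = clade.branch_length
        for child in clade.clades:
            node.children.append(convert(child))
        return node

    root = convert(bio_trees[0].root)
    # Bio.Nexus reports 0.0 for absent lengths; an all-zero tree is taxonomic
    lengths = [n.branch_length for n in root.iter_preorder()]
    if all(bl in (None, 0.0) for bl in lengths):
        for n in root.iter_preorder():
            n.branch_length = None
    return Tree(root, auto_rename=auto_rename)
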