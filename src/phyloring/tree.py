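"""The rooted, ordered tree that everything else operates on.

The structural backbone is deliberately small: nodes carry a name, an
optional non-negative branch length, an ordered child list and a free-form
``props`` dict used to persist per-node style properties (the annotated
intermediate).  Child order is significant — the circular layout follows it
exactly — so no operation here ever reorders children implicitly.

Trees come in two flavours: *phylogenetic* (every non-root node has a branch
length) and *taxonomic* (no lengths at all); mixed trees are allowed on
input and simply cannot be drawn as phylograms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

from .errors import TreeParseError

__all__ = ["TreeNode", "Tree", "LineagePath", "trees_equal", "topology_hash"]


@dataclass(eq=False)
class TreeNode:
    name: str = ""
    branch_length: Optional[float] = None
    children: List["TreeNode"] = field(default_factory=list)
    #: persisted style properties (option name -> textual value)
    props: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.branch_length is not None and self.branch_length < 0:
            raise TreeParseError(
                f"negative branch length {self.branch_length!r} on {self.name!r}"
            )

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_leaves(self) -> Iterator["TreeNode"]:
        for node in self.iter_preorder():
            if node.is_leaf:
                yield node

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, {len(self.children)} children)"


class Tree:
    """A rooted tree plus derived counts and name lookup.

    Parameters
    ----------
    root:
        The root node.
    auto_rename:
        Duplicate leaf names are an error by default because annotation
        targeting requires unambiguous names; with ``auto_rename=True``
        duplicates get ``__2``, ``__3``, ... suffixes in traversal order.
    """

    def __init__(self, root: TreeNode, auto_rename: bool = False):
        self.root = root
        #: tree-level persisted properties (global annotation options)
        self.props: Dict[str, str] = {}
        self._dedupe_leaf_names(auto_rename)
        self._parents: Optional[Dict[TreeNode, Optional[TreeNode]]] = None
        self._name_index: Optional[Dict[str, List[TreeNode]]] = None
        self._lineages: Dict[TreeNode, "LineagePath"] = {}

    def invalidate_caches(self) -> None:
        """Drop derived indices after a structural edit or rename."""
        self._parents = None
        self._name_index = None
        self._lineages = {}

    # -- derived structure --------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.iter_leaves())

    @property
    def max_depth(self) -> int:
        def depth(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(depth(c) for c in node.children)

        return depth(self.root)

    def nodes(self) -> List[TreeNode]:
        return list(self.root.iter_preorder())

    def leaves(self) -> List[TreeNode]:
        return list(self.root.iter_leaves())

    @property
    def is_phylogenetic(self) -> bool:
        """True when every non-root node carries a branch length."""
        return all(
            n.branch_length is not None for n in self.root.iter_preorder() if n is not self.root
        )

    # -- naming and addressing ----------------------------------------------

    def _dedupe_leaf_names(self, auto_rename: bool) -> None:
        seen: Dict[str, int] = {}
        for leaf in self.root.iter_leaves():
            if not leaf.name:
                continue
            if leaf.name in seen:
                if not auto_rename:
                    raise TreeParseError(
                        f"duplicate leaf name {leaf.name!r}; "
                        "pass auto_rename to disambiguate"
                    )
                seen[leaf.name] += 1
                leaf.name = f"{leaf.name}__{seen[leaf.name]}"
                seen[leaf.name] = 1
            else:
                seen[leaf.name] = 1

    def parent_map(self) -> Dict[TreeNode, Optional[TreeNode]]:
        if self._parents is None:
            parents: Dict[TreeNode, Optional[TreeNode]] = {self.root: None}
            for node in self.root.iter_preorder():
                for child in node.children:
                    parents[child] = node
            self._parents = parents
        return self._parents

    def _names(self) -> Dict[str, List[TreeNode]]:
        if self._name_index is None:
            index: Dict[str, List[TreeNode]] = {}
            for node in self.root.iter_preorder():
                if node.name:
                    index.setdefault(node.name, []).append(node)
            self._name_index = index
        return self._name_index

    def lineage_of(self, node: TreeNode) -> "LineagePath":
        """Named ancestors root-most first (unnamed nodes skipped), ending
        at ``node`` itself."""
        cached = self._lineages.get(node)
        if cached is not None:
            return cached
        parents = self.parent_map()
        labels: List[str] = []
        cur: Optional[TreeNode] = node
        while cur is not None:
            if cur.name:
                labels.append(cur.name)
            cur = parents[cur]
        path = LineagePath(tuple(reversed(labels)))
        self._lineages[node] = path
        return path

    def find_by_lineage(self, path: "LineagePath") -> List[TreeNode]:
        """All nodes whose named root-path ends with ``path`` (so a full
        lineage is always a valid address and a deeper prefix can be added
        only as far as needed to disambiguate a bare name)."""
        candidates = self._names().get(path.labels[-1], [])
        k = len(path.labels)
        if k == 1:
            return list(candidates)
        return [
            n for n in candidates if self.lineage_of(n).labels[-k:] == path.labels
        ]


@dataclass(frozen=True)
class LineagePath:
    """An ordered taxonomic path, root-most first.

    Textual form joins components with ``.`` in tree/annotation files (the
    profiler tables use ``|`` instead; the exporter maps between the two).
    """

    labels: Tuple[str, ...]

    SEP = "."

    def __post_init__(self):
        for lab in self.labels:
            if not lab or self.SEP in lab or "\t" in lab:
                raise TreeParseError(f"invalid lineage component {lab!r}")

    @classmethod
    def from_text(cls, text: str, sep: str = ".") -> "LineagePath":
        parts = text.split(sep)
        if any(not p for p in parts):
            raise TreeParseError(f"lineage {text!r} has an empty component")
        return cls(tuple(parts))

    def __str__(self) -> str:
        return self.SEP.join(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


# -- structural comparison ----------------------------------------------------


def trees_equal(a: Tree, b: Tree, tol: float = 1e-9) -> bool:
    """Topology, names, child order and branch lengths (within ``tol``)."""

    def eq(x: TreeNode, y: TreeNode) -> bool:
        if x.name != y.name or len(x.children) != len(y.children):
            return False
        if (x.branch_length is None) != (y.branch_length is None):
            return False
        if x.branch_length is not None and abs(x.branch_length - y.branch_length) > tol:
            return False
        return all(eq(cx, cy) for cx, cy in zip(x.children, y.children))

    return eq(a.root, b.root)


def topology_hash(tree: Tree) -> str:
    """Digest of topology + names + child order + branch lengths.

    Used to assert that annotation never modifies tree structure.
    """

    def canon(node: TreeNode) -> str:
        bl = "" if node.branch_length is None else repr(node.branch_length)
        kids = ",".join(canon(c) for c in node.children)
        return f"({kids}){node.name}:{bl}"

    return hashlib.sha256(canon(tree.root).encode("utf-8")).hexdigest()
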