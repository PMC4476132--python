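"""Deterministic synthetic data: trees, profiles, biomarker scores.

Everything here is driven by a single integer seed through one pinned
pseudorandom generator (NumPy ``default_rng`` / PCG64), so fixture corpora
are byte-stable across runs and platforms.  The generators write the exact
external formats the parsers consume, which locks the generator/parser
contract: a generated artifact always parses cleanly.

The effect-score generator is explicitly *not* a linear discriminant
analysis: it is a simple standardized class-mean difference rescaled onto
the conventional LDA-score range [2, 6], and exists to exercise the
biomarker styling path end to end without reimplementing a biomarker
discovery tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ExportError, PhyloringError
from .export import AbundanceTable, BiomarkerRecord, LINEAGE_SEP
from .tree import Tree, TreeNode

__all__ = [
    "FixtureSpec",
    "random_tree",
    "random_profile",
    "simple_effect_scores",
    "random_directive_lines",
    "write_corpus",
]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a small two-class microbiome-like comparison: 32
    taxa, 20 samples, log-normal baseline abundances (location 0, scale 1
    on the natural-log scale).  Differential clades are listed in
    ``spiked_clades`` as (dotted lineage, log2 effect[, class label])
    triples; the effect multiplies every leaf under that clade by
    ``2**effect`` in the spiked class (default ``class_1``).
    """

    seed: int = 0
    n_leaves: int = 32
    max_depth: int = 6
    n_samples: int = 20
    n_classes: int = 2
    spiked_clades: List[tuple] = field(default_factory=list)
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    branch_lengths: bool = False

    def __post_init__(self):
        if min(self.n_leaves, self.max_depth, self.n_samples, self.n_classes) < 1:
            raise PhyloringError("all fixture counts must be >= 1")


def _rng(spec: FixtureSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def random_tree(spec: FixtureSpec) -> Tree:
    """Random rooted tree with exactly ``n_leaves`` leaves and depth at most
    ``max_depth``; unique names; identical output for identical seed."""
    rng = _rng(spec)
    counter = {"internal": 0}

    def build(leaf_ids: Sequence[int], depth: int) -> TreeNode:
        if len(leaf_ids) == 1:
            node = TreeNode(name=f"t{leaf_ids[0]:04d}")
        else:
            counter["internal"] += 1
            node = TreeNode(name=f"n{counter['internal']:04d}")
            if depth >= spec.max_depth - 1:
                groups = [[i] for i in leaf_ids]
            else:
                k = int(rng.integers(2, min(4, len(leaf_ids)) + 1))
                cuts = sorted(
                    rng.choice(
                        np.arange(1, len(leaf_ids)), size=k - 1, replace=False
                    ).tolist()
                )
                groups, prev = [], 0
                for c in cuts + [len(leaf_ids)]:
                    groups.append(list(leaf_ids[prev:c]))
                    prev = c
            for g in groups:
                node.children.append(build(g, depth + 1))
        return node

    if spec.n_leaves == 1:
        root = TreeNode(name="")
        root.children.append(TreeNode(name="t0000"))
    else:
        root = build(list(range(spec.n_leaves)), 0)
        root.name = ""  # synthetic unnamed root, as in the plain-lineage format
    if spec.branch_lengths:
        tree = Tree(root)
        for node in root.iter_preorder():
            if node is root:
                continue
            node.branch_length = float(rng.exponential(0.1))
        return tree
    return Tree(root)


def random_profile(
    tree: Tree, spec: FixtureSpec
) -> Tuple[AbundanceTable, List[str]]:
    """Log-normal per-leaf abundances, class spikes, columns renormalized
    to sum 100 over the leaves; internal lineage rows are descendant sums.

    Returns the abundance table (all named lineages, pre-order) and the
    per-sample class labels (``class_0``, ``class_1``, ... round-robin).
    """
    if spec.n_classes >= 2 and spec.n_samples < 2:
        raise PhyloringError("need n_samples >= 2 with multiple classes")
    rng = _rng(spec)
    # burn the tree-shaped draws so profile noise differs from topology noise
    rng = np.random.default_rng(rng.integers(0, 2**31 - 1) + 1)
    leaves = tree.leaves()
    labels = [f"class_{i % spec.n_classes}" for i in range(spec.n_samples)]
    values = rng.lognormal(
        mean=spec.lognormal_mu, sigma=spec.lognormal_sigma,
        size=(len(leaves), spec.n_samples),
    )

    # apply spikes
    leaf_index = {leaf: i for i, leaf in enumerate(leaves)}
    for entry in spec.spiked_clades:
        lineage, effect = entry[0], float(entry[1])
        spike_class = entry[2] if len(entry) > 2 else "class_1"
        target_name = lineage.split(".")[-1]
        matches = [
            n for n in tree.nodes() if n.name == target_name
            and str(tree.lineage_of(n)) == lineage
        ]
        if not matches:
            raise ExportError(f"spiked lineage {lineage!r} absent from tree")
        spiked_leaves = [leaf_index[l] for l in matches[0].iter_leaves()]
        cols = [j for j, lab in enumerate(labels) if lab == spike_class]
        for i in spiked_leaves:
            for j in cols:
                values[i, j] *= 2.0 ** effect

    values = values / values.sum(axis=0, keepdims=True) * 100.0

    # assemble lineage rows: every named node, pre-order; internal = sum
    rows: List[str] = []
    data: List[np.ndarray] = []

    def lineage_text(node: TreeNode) -> str:
        return LINEAGE_SEP.join(tree.lineage_of(node).labels)

    for node in tree.root.iter_preorder():
        if not node.name:
            continue
        rows.append(lineage_text(node))
        idx = [leaf_index[l] for l in node.iter_leaves()]
        data.append(values[idx].sum(axis=0))
    frame = pd.DataFrame(
        np.vstack(data), index=rows,
        columns=[f"sample_{j + 1}" for j in range(spec.n_samples)],
    )
    return AbundanceTable(frame), labels


def simple_effect_scores(
    table: AbundanceTable,
    labels: Sequence[str],
    score_floor: float = 2.5,
) -> List[BiomarkerRecord]:
    """Stand-in effect scores for the biomarker styling path (not an LDA).

    For each terminal lineage: the spread of class means of
    ``log10(1 + abundance)`` is rescaled linearly onto [2, 6]; the enriched
    class is the one with the larger mean.  Scores not strictly above
    ``score_floor`` are emitted as non-significant records (identical
    class distributions sit exactly at the floor of the range, 2.0).
    """
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ExportError("effect scores need >= 2 classes")
    logged = np.log10(1.0 + table.data.values)
    cols_by_class = {
        c: [j for j, lab in enumerate(labels) if lab == c] for c in classes
    }
    terminals = table.terminal_rows()
    row_index = {lin: i for i, lin in enumerate(table.lineages)}
    spreads: Dict[str, float] = {}
    enriched: Dict[str, str] = {}
    for lin in terminals:
        i = row_index[lin]
        means = {c: float(logged[i, cols].mean()) for c, cols in cols_by_class.items()}
        top = max(classes, key=lambda c: (means[c], c))
        spreads[lin] = max(means.values()) - min(means.values())
        enriched[lin] = top
    max_spread = max(spreads.values()) if spreads else 0.0
    records: List[BiomarkerRecord] = []
    for lin in terminals:
        score = 2.0 if max_spread <= 0 else 2.0 + 4.0 * spreads[lin] / max_spread
        if score > score_floor:
            records.append(
                BiomarkerRecord(
                    feature=lin, enriched_class=enriched[lin],
                    effect_size=round(score, 6),
                )
            )
        else:
            records.append(BiomarkerRecord(feature=lin))
    return records


def random_directive_lines(
    tree: Tree, rng: np.random.Generator, n: int = 20
) -> List[str]:
    """Random well-formed annotation lines for property testing."""
    from .annotations import GLOBAL_OPTIONS, NODE_OPTIONS, LABEL_OPTIONS

    named = [node for node in tree.nodes() if node.name]
    lines: List[str] = []
    colors = ["red", "blue", "#00ff00", "#12345680", "black"]
    for _ in range(n):
        kind = rng.integers(0, 4)
        if kind == 0:
            lines.append(
                f"total_plotted_degrees\t{float(rng.uniform(90, 360)):.3f}"
            )
        elif kind == 1:
            node = named[int(rng.integers(0, len(named)))]
            target = str(tree.lineage_of(node))
            suffix = ["", "*", "+"][int(rng.integers(0, 3))]
            lines.append(
                f"{target}{suffix}\tclade_marker_color\t"
                f"{colors[int(rng.integers(0, len(colors)))]}"
            )
        elif kind == 2:
            node = named[int(rng.integers(0, len(named)))]
            lines.append(
                f"{tree.lineage_of(node)}\tclade_marker_size\t"
                f"{float(rng.uniform(0, 12)):.3f}"
            )
        else:
            leaf = named[int(rng.integers(0, len(named)))]
            ring = int(rng.integers(1, 4))
            lines.append(
                f"{tree.lineage_of(leaf)}\tring_alpha:{ring}\t"
                f"{float(rng.uniform(0, 1)):.4f}"
            )
    return lines


def _biom_v1_document(table: AbundanceTable, sparse: bool = False) -> dict:
    lineages = table.lineages
    samples = table.samples
    doc = {
        "id": "phyloring-fixture",
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "phyloring.fixtures",
        "date": "2000-01-01T00:00:00",
        "rows": [
            {"id": lin, "metadata": {"taxonomy": lin.split(LINEAGE_SEP)}}
            for lin in lineages
        ],
        "columns": [{"id": s, "metadata": None} for s in samples],
        "matrix_type": "sparse" if sparse else "dense",
        "matrix_element_type": "float",
        "shape": [len(lineages), len(samples)],
    }
    values = table.data.values
    if sparse:
        doc["data"] = [
            [i, j, float(values[i, j])]
            for i in range(len(lineages))
            for j in range(len(samples))
            if values[i, j] != 0.0
        ]
    else:
        doc["data"] = [[float(v) for v in row] for row in values]
    return doc


def write_corpus(out_dir, spec: FixtureSpec) -> Dict[str, str]:
    """Write one full fixture corpus (every external format the parsers
    consume) into ``out_dir``; returns the path map."""
    import os

    from .export import convert
    from .tree_io import write_newick, write_plain_lineages

    os.makedirs(out_dir, exist_ok=True)
    tree = random_tree(spec)
    table, labels = random_profile(tree, spec)
    records = simple_effect_scores(table, labels)

    def lefse_text(records: Sequence[BiomarkerRecord]) -> str:
        lines = []
        for r in records:
            if r.is_biomarker:
                lines.append(
                    f"{r.feature}\t{0.0!r}\t{r.enriched_class}\t"
                    f"{r.effect_size!r}\t{0.001!r}"
                )
            else:
                lines.append(f"{r.feature}\t{0.0!r}\t-\t\t-")
        return "\n".join(lines) + "\n"

    profile_lines = ["#lineage\t" + "\t".join(table.samples)]
    for lin in table.lineages:
        cells = "\t".join(repr(round(float(v), 6)) for v in table.data.loc[lin])
        profile_lines.append(f"{lin}\t{cells}")

    rng = np.random.default_rng(spec.seed + 1)
    paths = {
        "newick": os.path.join(out_dir, "tree.nwk"),
        "plain": os.path.join(out_dir, "tree.lineages.txt"),
        "profile": os.path.join(out_dir, "profile.tsv"),
        "lefse": os.path.join(out_dir, "biomarkers.lefse.tsv"),
        "biom": os.path.join(out_dir, "table.biom.json"),
        "annotation": os.path.join(out_dir, "annotation.txt"),
    }
    contents = {
        "newick": write_newick(tree),
        "plain": write_plain_lineages(tree),
        "profile": "\n".join(profile_lines) + "\n",
        "lefse": lefse_text(records),
        "biom": json.dumps(_biom_v1_document(table), indent=1, sort_keys=True),
        "annotation": "\n".join(random_directive_lines(tree, rng)) + "\n",
    }
    for key, path in paths.items():
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(contents[key])
    return paths
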