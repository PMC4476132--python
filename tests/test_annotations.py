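"""Annotation-file parsing and stylesheet resolution."""

import warnings

import numpy as np
import pytest

from phyloring.annotations import (
    Directive,
    StyleSheet,
    UnmatchedTargetWarning,
    apply_stylesheet,
    attach_to_tree,
    parse_annotation_file,
    reannotate,
    resolve_targets,
    stylesheet_from_tree,
)
from phyloring.colors import ColorSpec
from phyloring.errors import AnnotationError
from phyloring.fixtures import random_directive_lines
from phyloring.tree import topology_hash
from phyloring.tree_io import parse_newick, parse_phyloxml, write_phyloxml

NODE_AND_LABEL_OPTIONS = [
    "clade_marker_size",
    "clade_marker_color",
    "clade_marker_shape",
    "branch_color",
    "branch_thickness",
    "annotation",
    "annotation_background_color",
    "annotation_font_size",
]


def sheets_equal(a: StyleSheet, b: StyleSheet) -> bool:
    """Resolved-value equality over every node, option and ring cell."""
    nodes = a.tree.nodes()
    if any(a.get_global(o) != b.get_global(o) for o in
           ("total_plotted_degrees", "start_rotation", "branch_color",
            "branch_thickness")):
        return False
    for node in nodes:
        for opt in NODE_AND_LABEL_OPTIONS:
            if a.get_node(node, opt) != b.get_node(node, opt):
                return False
    if a.ring_indices() != b.ring_indices():
        return False
    for ring in a.ring_indices():
        for opt in ("ring_color", "ring_height", "ring_shape", "ring_alpha"):
            if a.get_ring(ring, opt) != b.get_ring(ring, opt):
                return False
            for leaf in a.tree.leaves():
                if a.get_ring_cell(ring, leaf, opt) != b.get_ring_cell(
                    ring, leaf, opt
                ):
                    return False
    return True


class TestParse:
    def test_global_directive(self):
        (d,) = parse_annotation_file(["total_plotted_degrees\t340"])
        assert d.is_global and d.value == 340.0 and d.ring_index is None

    def test_node_directive(self):
        (d,) = parse_annotation_file(["Bacteroidetes\tclade_marker_color\t#0000ff"])
        assert d.target == "Bacteroidetes"
        assert d.value == ColorSpec(0.0, 0.0, 1.0, 1.0)

    def test_ring_directive_with_fused_index(self):
        (d,) = parse_annotation_file(["Firmicutes*\tring_color:2\tred"])
        assert d.ring_index == 2
        assert d.target == "Firmicutes*"
        assert d.value == ColorSpec(1.0, 0.0, 0.0, 1.0)

    def test_comments_and_blank_lines_skipped(self):
        ds = parse_annotation_file(["# comment", "", "start_rotation\t90"])
        assert len(ds) == 1 and ds[0].source_line == 3

    @pytest.mark.parametrize(
        "line",
        [
            "no_such_option\t1",
            "X\tno_such_option\t1",
            "one_field_only",
            "a\tb\tc\td",
            "total_plotted_degrees\tnot_a_number",
            "X\tclade_marker_shape\trhombus",
            "X\tring_color:0\tred",
            "X\tring_color:two\tred",
        ],
    )
    def test_malformed_lines_error_with_line_number(self, line):
        with pytest.raises(AnnotationError) as err:
            parse_annotation_file(["# pad", line])
        assert err.value.line == 2


class TestTargets:
    def test_exact_subtree_and_leaves(self, chain_tree):
        def names(target):
            d = Directive(target=target, option="clade_marker_size", value=1.0)
            return [n.name for n in resolve_targets(d, chain_tree)]

        assert names("A") == ["A"]
        assert names("A*") == ["A", "B", "C"]
        assert names("A+") == ["C"]

    def test_dotted_path_addressing(self, chain_tree):
        d = Directive(target="R.A.B", option="annotation", value="x")
        assert [n.name for n in resolve_targets(d, chain_tree)] == ["B"]

    def test_unmatched_target_warns_and_is_empty(self, chain_tree):
        d = Directive(target="Nope", option="annotation", value="x")
        with pytest.warns(UnmatchedTargetWarning):
            assert resolve_targets(d, chain_tree) == []

    def test_ambiguous_bare_name_lists_candidates(self):
        tree = parse_newick("((X)L,(X__2)R);", auto_rename=True)
        # rename both leaves back to the same name to force ambiguity
        tree.leaves()[0].name = "X"
        tree.leaves()[1].name = "X"
        tree.invalidate_caches()
        d = Directive(target="X", option="annotation", value="x")
        with pytest.raises(AnnotationError, match="candidates"):
            resolve_targets(d, tree)


class TestApply:
    def test_last_directive_wins(self, chain_tree):
        ds = parse_annotation_file(
            ["A\tclade_marker_color\tred", "A\tclade_marker_color\tblue"]
        )
        sheet = apply_stylesheet(chain_tree, ds)
        node = [n for n in chain_tree.nodes() if n.name == "A"][0]
        assert sheet.get_node(node, "clade_marker_color") == ColorSpec(0, 0, 1, 1)

    def test_empty_directives_all_defaults_and_structure_kept(self, chain_tree):
        before = topology_hash(chain_tree)
        sheet = apply_stylesheet(chain_tree, [])
        assert topology_hash(chain_tree) == before
        for node in chain_tree.nodes():
            for opt in NODE_AND_LABEL_OPTIONS:
                sheet.get_node(node, opt)  # defined (may be None for "unset")
            assert sheet.get_node(node, "clade_marker_shape") == "circle"
            # branch options inherit the global defaults
            assert sheet.get_node(node, "branch_thickness") == 0.75

    def test_structure_invariant_under_random_stylesheets(self, tree_corpus):
        rng = np.random.default_rng(23)
        for tree in tree_corpus(20, seed=23):
            before = topology_hash(tree)
            lines = random_directive_lines(tree, rng, n=15)
            apply_stylesheet(tree, parse_annotation_file(lines))
            assert topology_hash(tree) == before

    def test_disjoint_directives_commute(self, chain_tree):
        lines = [
            "A\tclade_marker_color\tred",
            "B\tclade_marker_size\t9",
            "C\tannotation\thello",
            "total_plotted_degrees\t270",
        ]
        forward = apply_stylesheet(chain_tree, parse_annotation_file(lines))
        backward = apply_stylesheet(
            chain_tree, parse_annotation_file(list(reversed(lines)))
        )
        assert sheets_equal(forward, backward)

    def test_wildcard_then_exact_emulates_specificity(self, chain_tree):
        lines = ["A*\tclade_marker_size\t2", "A.B\tclade_marker_size\t8"]
        sheet = apply_stylesheet(chain_tree, parse_annotation_file(lines))
        a, b = ([n for n in chain_tree.nodes() if n.name == x][0] for x in "AB")
        assert sheet.get_node(a, "clade_marker_size") == 2.0
        assert sheet.get_node(b, "clade_marker_size") == 8.0

    def test_annotation_star_means_own_name(self, chain_tree):
        sheet = apply_stylesheet(
            chain_tree, parse_annotation_file(["A\tannotation\t*"])
        )
        a = [n for n in chain_tree.nodes() if n.name == "A"][0]
        assert sheet.get_node(a, "annotation") == "A"


class TestReannotate:
    def test_idempotence(self, chain_tree):
        ds = parse_annotation_file(
            ["A*\tclade_marker_color\tred", "total_plotted_degrees\t300"]
        )
        once = apply_stylesheet(chain_tree, ds)
        twice = reannotate(chain_tree, once, ds)
        assert sheets_equal(once, twice)

    def test_retains_untouched_and_overrides_collisions(self, chain_tree):
        d1 = parse_annotation_file(
            ["A\tclade_marker_color\tred", "B\tclade_marker_size\t7"]
        )
        d2 = parse_annotation_file(["A\tclade_marker_color\tblue"])
        merged = reannotate(chain_tree, apply_stylesheet(chain_tree, d1), d2)
        single = apply_stylesheet(chain_tree, list(d1) + list(d2))
        assert sheets_equal(merged, single)
        b = [n for n in chain_tree.nodes() if n.name == "B"][0]
        assert merged.get_node(b, "clade_marker_size") == 7.0

    def test_concatenation_equivalence_on_random_suites(self, tree_corpus):
        rng = np.random.default_rng(29)
        for tree in tree_corpus(10, seed=29):
            d1 = parse_annotation_file(random_directive_lines(tree, rng, n=8))
            d2 = parse_annotation_file(random_directive_lines(tree, rng, n=8))
            staged = reannotate(tree, apply_stylesheet(tree, d1), d2)
            merged = apply_stylesheet(tree, list(d1) + list(d2))
            assert sheets_equal(staged, merged)


class TestPersistence:
    def test_stylesheet_survives_phyloxml(self, tree_corpus):
        rng = np.random.default_rng(31)
        for tree in tree_corpus(5, seed=31):
            ds = parse_annotation_file(random_directive_lines(tree, rng, n=12))
            sheet = apply_stylesheet(tree, ds)
            attach_to_tree(sheet)
            again = parse_phyloxml(write_phyloxml(tree))
            recovered = stylesheet_from_tree(again)
            # compare on the re-read tree: resolved values node by node
            for n_old, n_new in zip(tree.nodes(), again.nodes()):
                for opt in NODE_AND_LABEL_OPTIONS:
                    assert sheet.get_node(n_old, opt) == recovered.get_node(
                        n_new, opt
                    )
            assert sheet.ring_indices() == recovered.ring_indices()
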