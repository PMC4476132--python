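"""Profile/biomarker conversion: parsers, tree building, annotation
selection, file emission."""

import json
import warnings

import numpy as np
import pytest

from phyloring.annotations import apply_stylesheet, parse_annotation_file
from phyloring.colors import resolve_color
from phyloring.errors import ExportError
from phyloring.export import (
    AnnotationDecision,
    BiomarkerRecord,
    ConversionConfig,
    build_tree,
    convert,
    emit_files,
    node_size,
    parse_biom_v1,
    parse_lefse_result,
    parse_metaphlan_table,
    select_annotations,
)
from phyloring.fixtures import FixtureSpec, random_profile, random_tree
from phyloring.render import effect_size_color
from phyloring.tree_io import parse_plain_lineages


class TestMetaphlanParser:
    def test_single_row(self):
        t = parse_metaphlan_table("k__Bacteria|p__Firmicutes\t52.3")
        assert t.lineages == ["k__Bacteria|p__Firmicutes"]
        assert t.mean_abundance().iloc[0] == 52.3

    def test_mean_across_samples(self):
        t = parse_metaphlan_table("k__B\t10\t30")
        assert t.mean_abundance().iloc[0] == 20.0

    def test_header_names_samples(self):
        t = parse_metaphlan_table("#ID\ts1\ts2\nk__B\t1\t2")
        assert t.samples == ["s1", "s2"]

    def test_non_numeric_cell_names_row_and_column(self):
        with pytest.raises(ExportError, match="row 2, column 3"):
            parse_metaphlan_table("k__A\t1\t2\nk__B\t3\toops")

    def test_terminal_rows_match_trie_leaves(self, tree_corpus):
        """Independent oracle: terminal rows == leaves of a prefix trie."""
        for tree in tree_corpus(10, seed=83):
            spec = FixtureSpec(seed=5, n_samples=3)
            table, _ = random_profile(tree, spec)
            trie = {}
            for lin in table.lineages:
                d = trie
                for part in lin.split("|"):
                    d = d.setdefault(part, {})
            def trie_leaves(d, prefix):
                if not d:
                    yield "|".join(prefix)
                for k, sub in d.items():
                    yield from trie_leaves(sub, prefix + [k])
            assert set(table.terminal_rows()) == set(trie_leaves(trie, []))


class TestLefseParser:
    def test_biomarker_row(self):
        (r,) = parse_lefse_result("Bacteroidetes\t5.0\tHMP\t4.2\t0.001")
        assert r.is_biomarker
        assert (r.enriched_class, r.effect_size, r.p_value) == ("HMP", 4.2, 0.001)

    def test_non_significant_row(self):
        (r,) = parse_lefse_result("Clostridia\t4.1\t-\t\t-")
        assert not r.is_biomarker and r.effect_size is None

    def test_arity_error(self):
        with pytest.raises(ExportError):
            parse_lefse_result("a\tb\tc")

    def test_biomarker_count_equals_class_labeled_rows(self):
        rng = np.random.default_rng(89)
        lines, n_sig = [], 0
        for i in range(50):
            if rng.random() < 0.5:
                lines.append(f"f{i}\t1.0\tclassA\t{2 + rng.random():.3f}\t0.01")
                n_sig += 1
            else:
                lines.append(f"f{i}\t1.0\t-\t\t-")
        records = parse_lefse_result("\n".join(lines))
        assert sum(r.is_biomarker for r in records) == n_sig


class TestBiomParser:
    def doc(self, matrix_type, data):
        return {
            "rows": [
                {"id": "o1", "metadata": {"taxonomy": ["k__A", "p__X"]}},
                {"id": "o2", "metadata": {"taxonomy": ["k__A", "p__Y"]}},
            ],
            "columns": [{"id": "s1"}, {"id": "s2"}],
            "matrix_type": matrix_type,
            "shape": [2, 2],
            "data": data,
        }

    def test_dense_with_taxonomy(self):
        t = parse_biom_v1(self.doc("dense", [[1, 2], [3, 4]]))
        assert t.lineages == ["k__A|p__X", "k__A|p__Y"]
        assert t.data.values.tolist() == [[1.0, 2.0], [3.0, 4.0]]

    def test_sparse_triplets(self):
        t = parse_biom_v1(self.doc("sparse", [[0, 0, 5], [1, 1, 3]]))
        assert t.data.values.tolist() == [[5.0, 0.0], [0.0, 3.0]]

    def test_dense_and_sparse_encodings_agree(self):
        rng = np.random.default_rng(97)
        dense = rng.integers(0, 5, size=(2, 2)).astype(float)
        sparse = [
            [i, j, dense[i, j]] for i in range(2) for j in range(2)
            if dense[i, j]
        ]
        t1 = parse_biom_v1(self.doc("dense", dense.tolist()))
        t2 = parse_biom_v1(self.doc("sparse", sparse))
        assert t1.data.equals(t2.data)

    def test_missing_field_is_an_error(self):
        doc = self.doc("dense", [[1, 2], [3, 4]])
        del doc["shape"]
        with pytest.raises(ExportError, match="shape"):
            parse_biom_v1(doc)

    def test_missing_taxonomy_falls_back_to_id_and_collisions_sum(self):
        doc = self.doc("dense", [[1, 2], [3, 4]])
        doc["rows"] = [{"id": "obs", "metadata": None}, {"id": "obs", "metadata": None}]
        t = parse_biom_v1(doc)
        assert t.lineages == ["obs"]
        assert t.data.values.tolist() == [[4.0, 6.0]]

    def test_roundtrip_through_json_text(self):
        text = json.dumps(self.doc("dense", [[1, 2], [3, 4]]))
        assert parse_biom_v1(text).lineages == ["k__A|p__X", "k__A|p__Y"]


class TestBuildTree:
    def test_trie_structure(self):
        t = parse_metaphlan_table("A|B\t1\nA|C\t2")
        tree = build_tree(t)
        (a,) = tree.root.children
        assert a.name == "A" and [c.name for c in a.children] == ["B", "C"]

    def test_single_row_chain(self):
        t = parse_metaphlan_table("A|B|C\t1")
        tree = build_tree(t)
        assert tree.n_leaves == 1 and tree.max_depth == 3

    def test_leafset_conservation_on_random_tables(self, tree_corpus):
        for tree in tree_corpus(10, seed=101):
            table, _ = random_profile(tree, FixtureSpec(seed=7, n_samples=3))
            built = build_tree(table)
            leaf_lineages = {
                str(built.lineage_of(l)).replace(".", "|") for l in built.leaves()
            }
            assert leaf_lineages == set(table.terminal_rows())


class TestNodeSize:
    def test_zero_abundance_gives_base(self):
        assert node_size(0.0, base=3.0, scale=8.0) == 3.0

    def test_abundance_nine_gives_base_plus_scale(self):
        assert node_size(9.0, base=3.0, scale=8.0) == pytest.approx(11.0)

    def test_strictly_increasing(self):
        rng = np.random.default_rng(103)
        xs = np.sort(rng.uniform(0, 100, 50))
        sizes = [node_size(x) for x in xs]
        assert all(b > a for a, b in zip(sizes, sizes[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ExportError):
            node_size(-0.1)


class TestSelectAnnotations:
    def table(self, text="A\t10\nB\t5"):
        return parse_metaphlan_table(text)

    def labels_of(self, decisions):
        return {d.target for d in decisions if d.option == "annotation"}

    def test_top_k_by_mean(self):
        cfg = ConversionConfig(top_k=1, abundance_threshold=0.0)
        assert self.labels_of(select_annotations(self.table(), [], cfg)) == {"A"}

    def test_threshold_above_all_means_no_labels(self):
        cfg = ConversionConfig(abundance_threshold=99.0)
        assert self.labels_of(select_annotations(self.table(), [], cfg)) == set()

    def test_threshold_monotonicity(self):
        table = self.table("A\t10\nB\t5\nC\t2\nD\t0.5")
        previous = None
        for thr in (0.0, 1.0, 3.0, 7.0, 50.0):
            cfg = ConversionConfig(abundance_threshold=thr, top_k=100)
            labeled = self.labels_of(select_annotations(table, [], cfg))
            if previous is not None:
                assert labeled <= previous
            previous = labeled

    def test_max_label_depth_limits_rank(self):
        table = self.table("A\t10\nA|B\t10\nA|B|C\t10")
        cfg = ConversionConfig(abundance_threshold=0.0, top_k=10, max_label_depth=2)
        assert self.labels_of(select_annotations(table, [], cfg)) == {"A", "A.B"}

    def test_biomarker_styling_and_color_scale(self):
        cfg = ConversionConfig(class_colors={"HMP": "#00ff00"}, lda_min=2.0)
        recs = [
            BiomarkerRecord("A", "HMP", effect_size=6.0),
            BiomarkerRecord("B", "HMP", effect_size=3.0),
        ]
        decisions = select_annotations(self.table(), recs, cfg)
        marker = {
            d.target: d.value for d in decisions if d.option == "clade_marker_color"
        }
        # at the observed maximum the marker color is exactly the class color
        assert marker["A"] == "#00ff00"
        expected = effect_size_color(3.0, 2.0, 6.0, resolve_color("#00ff00"))
        assert marker["B"] == expected.to_hex()
        # every biomarker present in the table gets >= 2 directives
        for t in ("A", "B"):
            n = sum(1 for d in decisions if d.target == t and d.option in (
                "annotation_background_color", "clade_marker_color"))
            assert n == 2

    def test_absent_biomarker_feature_warns_and_is_skipped(self):
        recs = [BiomarkerRecord("Zzz", "HMP", effect_size=4.0)]
        with pytest.warns(UserWarning, match="absent"):
            decisions = select_annotations(self.table(), recs)
        assert all(d.target != "Zzz" for d in decisions)

    def test_every_row_gets_a_marker_size(self):
        decisions = select_annotations(self.table(), [])
        sized = {d.target for d in decisions if d.option == "clade_marker_size"}
        assert sized == {"A", "B"}

    def test_ring_plan_emits_heatmap_cells(self):
        table = parse_metaphlan_table("#h\ts1\ts2\nA\t4\t1\nB\t2\t1")
        cfg = ConversionConfig(ring_plan={1: "s1"})
        decisions = select_annotations(table, [], cfg)
        alphas = {
            d.target: float(d.value)
            for d in decisions
            if d.option == "ring_alpha:1"
        }
        assert alphas == {"A": 1.0, "B": 0.5}


class TestEmit:
    def test_pipe_to_dot_mapping(self):
        table = parse_metaphlan_table("k__Bacteria|p__Firmicutes\t50")
        tree_text, _ = convert(table)
        assert tree_text == "k__Bacteria.p__Firmicutes\n"

    def test_annotation_file_ordering(self):
        decisions = [
            AnnotationDecision("B", "clade_marker_size", "4"),
            AnnotationDecision("", "total_plotted_degrees", "340"),
            AnnotationDecision("A*", "clade_marker_size", "2"),
            AnnotationDecision("A", "clade_marker_size", "3"),
        ]
        table = parse_metaphlan_table("A\t1\nB\t1")
        _, annot = emit_files(build_tree(table), decisions)
        assert annot.splitlines() == [
            "total_plotted_degrees\t340",
            "A*\tclade_marker_size\t2",
            "A\tclade_marker_size\t3",
            "B\tclade_marker_size\t4",
        ]

    def test_no_biomarkers_still_emits_sizes(self):
        table = parse_metaphlan_table("A\t1")
        _, annot = convert(table)
        assert "clade_marker_size" in annot

    def test_deterministic_emission(self, tree_corpus):
        (tree,) = tree_corpus(1, seed=107)
        table, labels = random_profile(tree, FixtureSpec(seed=9, n_samples=6))
        from phyloring.fixtures import simple_effect_scores

        recs = simple_effect_scores(table, labels)
        assert convert(table, recs) == convert(table, recs)

    def test_full_roundtrip_reparses_without_warnings(self, tree_corpus):
        from phyloring.fixtures import simple_effect_scores

        for tree in tree_corpus(5, seed=109):
            table, labels = random_profile(tree, FixtureSpec(seed=11, n_samples=6))
            recs = simple_effect_scores(table, labels)
            tree_text, annot_text = convert(table, recs)
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                parsed = parse_plain_lineages(tree_text.splitlines())
                directives = parse_annotation_file(annot_text.splitlines())
                apply_stylesheet(parsed, directives)
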