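"""Profile/biomarker converters: tables in, tree + annotation files out.

Takes taxonomic or functional profiles (MetaPhlAn / HUMAnN style
pipe-separated tables, or BIOM v1 documents) and optionally a
biomarker-discovery result (LEfSe-style table with per-feature LDA effect
sizes), and emits a plain-lineage tree file plus an annotation file in the
grammar of :mod:`phyloring.annotations`:

* the most abundant clades are labeled (top-k above an abundance floor,
  down to a maximum rank depth);
* every biomarker clade gets a shaded background in its class color and a
  node color scaled from black (low LDA score) to the full class color
  (high LDA score);
* every clade's marker size grows logarithmically with its mean relative
  abundance.

Emission is deterministic: identical inputs and config give byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .colors import ColorSpec, resolve_color
from .errors import ExportError
from .render import effect_size_color
from .tree import Tree, TreeNode

__all__ = [
    "AbundanceTable",
    "BiomarkerRecord",
    "ConversionConfig",
    "parse_metaphlan_table",
    "parse_lefse_result",
    "parse_biom_v1",
    "build_tree",
    "select_annotations",
    "node_size",
    "emit_files",
    "convert",
]

LINEAGE_SEP = "|"

#: deterministic class -> color assignment (matplotlib tab10, hex)
_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]


@dataclass
class AbundanceTable:
    """Lineage-by-sample relative abundances (percent scale).

    Rows are keyed by pipe-separated lineage text; *terminal* rows are the
    rows that are no other row's prefix (the leaves of the implied
    taxonomy).
    """

    data: pd.DataFrame  # index: lineage text; columns: sample ids

    def __post_init__(self):
        if (self.data.values < 0).any():
            raise ExportError("abundance values must be >= 0")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ExportError(f"duplicate lineage key {dup!r}")

    @property
    def lineages(self) -> List[str]:
        return list(self.data.index)

    @property
    def samples(self) -> List[str]:
        return list(self.data.columns)

    def mean_abundance(self, summary: str = "mean") -> pd.Series:
        if summary == "median":
            return self.data.median(axis=1)
        return self.data.mean(axis=1)

    def terminal_rows(self) -> List[str]:
        keys = set(self.lineages)
        prefixes = set()
        for lin in keys:
            parts = lin.split(LINEAGE_SEP)
            for i in range(1, len(parts)):
                prefixes.add(LINEAGE_SEP.join(parts[:i]))
        return [lin for lin in self.lineages if lin not in prefixes]


@dataclass(frozen=True)
class BiomarkerRecord:
    """One feature from a biomarker-discovery run.

    ``effect_size`` (a log10-scale LDA score) is present exactly when the
    feature was called significant.
    """

    feature: str
    enriched_class: Optional[str] = None
    effect_size: Optional[float] = None
    p_value: Optional[float] = None

    @property
    def is_biomarker(self) -> bool:
        return self.effect_size is not None


@dataclass
class ConversionConfig:
    """User-controllable knobs of the conversion.

    Defaults label the ten most abundant clades with mean abundance of at
    least 1% down to rank depth 5; node sizes grow as
    ``base + scale * log10(1 + abundance)``; biomarker node colors span
    LDA scores from ``lda_min`` (conventional significance cutoff 2.0) to
    the maximum observed score.
    """

    abundance_threshold: float = 1.0
    top_k: int = 10
    max_label_depth: int = 5
    class_colors: Dict[str, str] = field(default_factory=dict)
    size_base: float = 3.0
    size_scale: float = 8.0
    #: ring index -> sample id plotted as a heatmap ring
    ring_plan: Dict[int, str] = field(default_factory=dict)
    lda_min: float = 2.0
    lda_max: Optional[float] = None  # None -> max observed
    summary: str = "mean"

    def __post_init__(self):
        if self.top_k < 0 or self.abundance_threshold < 0:
            raise ExportError("top_k and abundance_threshold must be >= 0")

    def color_for(self, cls: str, all_classes: Sequence[str]) -> ColorSpec:
        if cls in self.class_colors:
            return resolve_color(self.class_colors[cls])
        ordered = sorted(set(all_classes))
        return resolve_color(_PALETTE[ordered.index(cls) % len(_PALETTE)])


# ---------------------------------------------------------------------------
# input parsers


def parse_metaphlan_table(text: str) -> AbundanceTable:
    """Parse a MetaPhlAn/HUMAnN-style tab-separated profile.

    First column: pipe-separated lineage; remaining columns: numeric
    relative abundances per sample.  A leading ``#``-prefixed header row
    names the samples.
    """
    rows: List[Tuple[str, List[float]]] = []
    header: Optional[List[str]] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line.lstrip("#").split("\t")
            if len(fields) > 1:
                header = fields[1:]
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ExportError(f"row {lineno}: expected lineage + abundances")
        lineage = fields[0].strip()
        values = []
        for col, cell in enumerate(fields[1:], start=2):
            try:
                values.append(float(cell))
            except ValueError:
                raise ExportError(
                    f"row {lineno}, column {col}: non-numeric abundance {cell!r}"
                ) from None
        rows.append((lineage, values))
    if not rows:
        raise ExportError("empty profile table")
    n_cols = len(rows[0][1])
    if any(len(v) != n_cols for _, v in rows):
        raise ExportError("ragged profile table: rows differ in column count")
    columns = header if header and len(header) == n_cols else [
        f"sample_{i + 1}" for i in range(n_cols)
    ]
    frame = pd.DataFrame(
        [v for _, v in rows], index=[l for l, _ in rows], columns=columns,
        dtype=float,
    )
    return AbundanceTable(frame)


def parse_lefse_result(text: str) -> List[BiomarkerRecord]:
    """Parse a LEfSe-style result table.

    Columns: feature, log of the highest class mean, enriched class, LDA
    score, p-value.  A dash or empty class marks a non-significant feature
    (record without an effect size).
    """
    records: List[BiomarkerRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ExportError(
                f"row {lineno}: expected 5 tab-separated fields, got {len(fields)}"
            )
        feature, _log_max, cls, lda, pval = (f.strip() for f in fields)
        if cls in ("", "-"):
            records.append(BiomarkerRecord(feature=feature))
            continue
        try:
            effect = float(lda)
        except ValueError:
            raise ExportError(f"row {lineno}: bad LDA score {lda!r}") from None
        p = None
        if pval not in ("", "-"):
            try:
                p = float(pval)
            except ValueError:
                raise ExportError(f"row {lineno}: bad p-value {pval!r}") from None
        records.append(
            BiomarkerRecord(
                feature=feature, enriched_class=cls, effect_size=effect, p_value=p
            )
        )
    return records


def parse_biom_v1(document) -> AbundanceTable:
    """Parse a BIOM 1.0 (JSON) table, dense or sparse.

    Lineage keys come from the observation ``taxonomy`` metadata (rank list
    joined with ``|``), falling back to the observation id; values for
    observations mapping to the same lineage are summed.
    """
    if isinstance(document, str):
        try:
            doc = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ExportError(f"invalid BIOM JSON: {exc}") from None
    else:
        doc = document
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise ExportError(f"BIOM document missing required field {key!r}")
    n_obs, n_samples = doc["shape"]
    if len(doc["rows"]) != n_obs or len(doc["columns"]) != n_samples:
        raise ExportError("BIOM shape disagrees with rows/columns")
    sample_ids = [c["id"] for c in doc["columns"]]

    def lineage_for(row) -> str:
        md = row.get("metadata") or {}
        taxonomy = md.get("taxonomy")
        if taxonomy:
            parts = [t.strip() for t in taxonomy if t and t.strip()]
            if parts:
                return LINEAGE_SEP.join(parts)
        return row["id"]

    dense = [[0.0] * n_samples for _ in range(n_obs)]
    if doc["matrix_type"] == "dense":
        for i, row in enumerate(doc["data"]):
            dense[i] = [float(v) for v in row]
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            dense[i][j] = float(v)
    else:
        raise ExportError(f"unknown matrix_type {doc['matrix_type']!r}")

    frame = pd.DataFrame(dense, columns=sample_ids, dtype=float)
    frame.insert(0, "__lineage", [lineage_for(r) for r in doc["rows"]])
    collapsed = frame.groupby("__lineage", sort=False).sum()
    collapsed.index.name = None
    return AbundanceTable(collapsed)


# ---------------------------------------------------------------------------
# conversion proper


def build_tree(table: AbundanceTable, auto_rename: bool = False) -> Tree:
    """Prefix trie of the table's lineages (``|`` -> ``.`` components);
    leaves are exactly the terminal rows."""
    if not table.lineages:
        raise ExportError("empty table")
    root = TreeNode(name="")
    for lineage in table.lineages:
        node = root
        for label in lineage.split(LINEAGE_SEP):
            for child in node.children:
                if child.name == label:
                    node = child
                    break
            else:
                child = TreeNode(name=label)
                node.children.append(child)
                node = child
    return Tree(root, auto_rename=auto_rename)


def node_size(mean_abundance: float, base: float = 3.0, scale: float = 8.0) -> float:
    """Marker size growing logarithmically with percent abundance:
    ``base + scale * log10(1 + abundance)``."""
    import math

    if mean_abundance < 0:
        raise ExportError(f"negative abundance {mean_abundance}")
    return base + scale * math.log10(1.0 + mean_abundance)


@dataclass(frozen=True)
class AnnotationDecision:
    target: str  # dotted path (may carry a wildcard suffix)
    option: str  # possibly "option:ring"
    value: str


def _dotted(lineage: str) -> str:
    return lineage.replace(LINEAGE_SEP, ".")


def _fmt(x: float) -> str:
    return repr(round(float(x), 6))


def select_annotations(
    table: AbundanceTable,
    biomarkers: Sequence[BiomarkerRecord],
    config: Optional[ConversionConfig] = None,
) -> List[AnnotationDecision]:
    """Decide labels, biomarker styling and node sizes.

    * labels: the ``top_k`` clades by mean abundance among those at or
      above ``abundance_threshold`` and within ``max_label_depth`` ranks,
      ties broken lexicographically by lineage;
    * biomarkers: background + label in the class color, node marker color
      from the black -> class-color effect-size scale;
    * every clade: marker size from :func:`node_size`.
    """
    config = config or ConversionConfig()
    means = table.mean_abundance(config.summary)
    decisions: List[AnnotationDecision] = []
    known = set(table.lineages)

    # (c) node sizes for every row
    for lineage in table.lineages:
        decisions.append(
            AnnotationDecision(
                _dotted(lineage),
                "clade_marker_size",
                _fmt(node_size(means[lineage], config.size_base, config.size_scale)),
            )
        )

    # (a) most abundant clades get labels
    eligible = [
        lin
        for lin in table.lineages
        if means[lin] >= config.abundance_threshold
        and len(lin.split(LINEAGE_SEP)) <= config.max_label_depth
    ]
    eligible.sort(key=lambda lin: (-means[lin], lin))
    for lineage in eligible[: config.top_k]:
        decisions.append(AnnotationDecision(_dotted(lineage), "annotation", "*"))

    # (b) biomarker styling
    significant = [b for b in biomarkers if b.is_biomarker]
    classes = [b.enriched_class for b in significant]
    observed = [b.effect_size for b in significant]
    lda_max = config.lda_max
    if lda_max is None:
        lda_max = max(observed) if observed else config.lda_min + 1.0
    if lda_max <= config.lda_min:
        lda_max = config.lda_min + 1.0
    import warnings

    for rec in significant:
        if rec.feature not in known:
            warnings.warn(
                f"biomarker feature {rec.feature!r} absent from the profile table"
            )
            continue
        cls_color = config.color_for(rec.enriched_class, classes)
        marker = effect_size_color(
            rec.effect_size, config.lda_min, lda_max, cls_color
        )
        target = _dotted(rec.feature)
        decisions.append(
            AnnotationDecision(
                target, "annotation_background_color",
                cls_color.with_alpha(0.25).to_hex(),
            )
        )
        decisions.append(AnnotationDecision(target, "annotation", "*"))
        decisions.append(
            AnnotationDecision(target, "clade_marker_color", marker.to_hex())
        )

    # heatmap rings for selected samples
    terminals = table.terminal_rows()
    for ring_idx in sorted(config.ring_plan):
        sample = config.ring_plan[ring_idx]
        if sample not in table.data.columns:
            raise ExportError(f"ring {ring_idx}: unknown sample {sample!r}")
        col = table.data[sample]
        peak = max((col[lin] for lin in terminals), default=0.0)
        decisions.append(
            AnnotationDecision("", f"ring_height:{ring_idx}", _fmt(0.15))
        )
        for lin in terminals:
            value = 0.0 if peak <= 0 else col[lin] / peak
            decisions.append(
                AnnotationDecision(
                    _dotted(lin), f"ring_alpha:{ring_idx}", _fmt(value)
                )
            )
    return decisions


def emit_files(
    tree: Tree, decisions: Sequence[AnnotationDecision]
) -> Tuple[str, str]:
    """Serialize the tree (plain-lineage format, depth-first) and the
    annotation file (globals, then wildcard targets, then exact targets,
    each block lexicographically sorted)."""
    from .tree_io import write_plain_lineages

    tree_text = write_plain_lineages(tree)

    def line(d: AnnotationDecision) -> str:
        if d.target == "":
            return f"{d.option}\t{d.value}"
        return f"{d.target}\t{d.option}\t{d.value}"

    globals_ = sorted(
        {line(d) for d in decisions if d.target == ""}
    )
    wildcards = sorted(
        {line(d) for d in decisions if d.target and d.target[-1] in "*+"}
    )
    exact = sorted(
        {line(d) for d in decisions if d.target and d.target[-1] not in "*+"}
    )
    annot_text = "\n".join(globals_ + wildcards + exact) + "\n"
    return tree_text, annot_text


def convert(
    table: AbundanceTable,
    biomarkers: Sequence[BiomarkerRecord] = (),
    config: Optional[ConversionConfig] = None,
) -> Tuple[str, str]:
    """Full conversion: profile (+ optional biomarkers) -> (tree text,
    annotation text), both re-parseable by the tree and annotation
    readers."""
    tree = build_tree(table)
    decisions = select_annotations(table, biomarkers, config)
    return emit_files(tree, decisions)
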