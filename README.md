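# phyloring

Compact, publication-quality **circular phylogeny and taxonomy plots** with
rich per-clade styling and stacked external data rings — built for microbial
genomics and microbiome studies, where trees with hundreds to thousands of
taxa must be shown together with abundances, biomarker effect sizes, and
genomic properties.

The tool is batch/command-driven and split into two deterministic stages:

1. **annotate** — a tab-delimited *annotation file* is resolved onto a tree
   (Newick, Nexus, PhyloXML, or plain one-lineage-per-line text) without
   ever modifying the tree's structure; the result is written as PhyloXML
   with the style carried in per-clade `<property>` elements, so annotation
   can be applied repeatedly and incrementally.
2. **plot** — the styled tree is laid out on a circle and serialized as
   byte-deterministic SVG: branch elbows (radial segment + arc), per-node
   markers, shaded background wedges with labels (long labels move to a
   lettered legend), and external rings showing per-leaf data as glyphs,
   blank-to-full-color heatmap sectors, or radial bars.

A converter (**export**) turns the outputs of standard metagenomic pipelines
into tree + annotation file pairs: MetaPhlAn/HUMAnN-style pipe-separated
profiles, LEfSe-style biomarker tables, and BIOM 1.0 tables. It labels the
most abundant clades, shades biomarker clades in their class color, scales
node color from **black (low LDA score) to the full class color (high LDA
score)**, and sizes every node as `base + scale·log10(1 + abundance)`.

## The geometry in brief

For a tree with *n* leaves plotted over `total_plotted_degrees` *T* starting
at rotation *R*, leaf *i* (depth-first, input child order) is placed at

```
theta_i = R + (i + 0.5) · T / n
```

and owns the angular slot of width *T*/*n* centred on it; internal nodes sit
at the midpoint of their leaf span. Radius is normalized to the unit circle:
`depth / max_depth` for taxonomic trees (cladogram), cumulative root-path
branch length over its maximum for phylogenetic trees (phylogram, invariant
under uniform branch-length rescaling). Clade wedges span
`[first leaf slot start, last leaf slot end] × [node radius, 1]`; external
rings stack outside `r = 1`.

## Worked example

```
$ cat tree.nwk
((Bacteroides_fragilis,Bacteroides_ovatus)Bacteroides,(Faecalibacterium_prausnitzii)Faecalibacterium);

$ cat annot.txt
total_plotted_degrees	340
Bacteroides	annotation	*
Bacteroides	annotation_background_color	#1f77b4
Bacteroides*	clade_marker_color	#1f77b4
Faecalibacterium_prausnitzii	clade_marker_size	12
Bacteroides_fragilis	ring_alpha:1	0.9
Bacteroides_ovatus	ring_alpha:1	0.3
ring_color:1	#d62728

$ phyloring annotate tree.nwk --annot annot.txt --out styled.xml
$ phyloring plot styled.xml --out plot.svg
```

The resulting `plot.svg` (2,652 bytes) contains 6 `class="marker"` node
markers (one per node, all with positive size), 1 `class="wedge"` background
sector covering the *Bacteroides* clade with its label, and 2
`class="ring-cell"` heatmap sectors in ring 1 — red at 90% and 30% intensity
for the two *Bacteroides* leaves. Re-running either command reproduces both
files byte for byte; annotating `styled.xml` again with the same file is a
no-op.

The full pipeline from synthetic data:

```
phyloring fixtures --seed 7 --n-leaves 40 --out-dir corpus/
phyloring export --profile corpus/profile.tsv --lefse corpus/biomarkers.lefse.tsv \
    --out-tree tree.txt --out-annot annot.txt
phyloring annotate tree.txt --annot annot.txt --out styled.xml
phyloring plot styled.xml --out plot.svg
```

Annotation grammar: two tab-separated fields for a global option
(`total_plotted_degrees	340`), three for a targeted one
(`Firmicutes*	ring_color:2	red`). Targets address nodes by name or dotted
lineage; `path*` selects a clade with all its descendants, `path+` its
terminal taxa only; ring options fuse the 1-based ring index into the option
name. Later directives win on collision.

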