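# Methods

This note records the model of the visualization, the parameter surface,
the numerical conventions, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The two-stage model

The tool treats a plot as a pure function of three immutable inputs: a
rooted ordered tree, a resolved stylesheet, and a polar layout. Annotation
and drawing are deliberately separate stages. The annotation stage resolves
a directive list onto the tree and never changes its structure — this is an
asserted invariant (topology hash before/after), not a convention. The
drawing stage first builds a renderer-neutral *scene graph* (ordered
primitives: wedge fills, ring cells, branch paths, markers, texts, legend
entries) and only then serializes SVG. The scene graph is the determinism
boundary: equal inputs give equal scenes, and serialization prints every
coordinate at six decimals, so output files are byte-identical across runs
and platforms.

Trees come in two flavours with different radial models:

* **cladogram** (taxonomic trees, no branch lengths): `r = depth /
  max_depth`. Leaves shallower than the maximum depth sit at `r < 1`, which
  matches rank-labeled taxonomies; rings always begin outside `r = 1`
  regardless.
* **phylogram** (phylogenetic trees): `r` is the cumulative root-path
  length normalized by its maximum, hence invariant under uniform
  rescaling of branch lengths. Zero-length branches are allowed and place
  the child at its parent's radius, weakening radial monotonicity from
  strict to non-decreasing.

Angles are equal-per-leaf: leaf *i* of *n* (depth-first in input child
order, no ladderizing unless requested) is centred in the *i*-th of *n*
equal slots spanning `total_plotted_degrees` from `start_rotation`.
Allocating equally per leaf rather than per subtree was an open choice;
equal-per-leaf keeps every taxon readable at the rim, which is what the
external rings need. Angles are stored in degrees end to end; radians
appear only inside the single polar→cartesian conversion.

## The annotation language

Options form a closed vocabulary with typed values and defaults: global
(`total_plotted_degrees` 360, `start_rotation` 0, `branch_color` black,
`branch_thickness` 0.75), per-node (`clade_marker_size` 4, shape `circle`,
color dark grey; branch options unset = inherit global), label
(`annotation`, `annotation_background_color`, `annotation_font_size`) and
ring options carrying a 1-based index (`ring_color`, `ring_height` 0.1,
`ring_shape`, `ring_alpha`). Resolution is strictly positional — the last
directive touching a node+option wins, with no specificity ranking.
Generated files exploit this by emitting wildcards before exact targets.
Unmatched targets warn instead of failing so one annotation file can serve
several trees.

Wildcards: `path*` = the clade including all descendants; `path+` = its
terminal taxa only. Targets are bare names or dotted paths matched against
the tail of a node's named root-path; an ambiguous bare name is an error
that lists the candidate lineages. The label value `*` means "use the
node's own name".

Ring cells need three visual kinds (glyph, heatmap, bar) but the vocabulary
stays closed by overloading within it: the default cell is a heatmap
*sector* whose intensity is `ring_alpha` ∈ [0, 1] (0 = exactly blank, 1 =
exactly the full ring color — asserted endpoint exactness); `ring_shape`
switches a cell to a glyph (`circle`, `triangle-up`, `triangle-down` — the
triangles encode a directional sign) or to a radial `bar`, in which case
the per-cell `ring_height` is the bar value, normalized per ring by its
maximum, while the per-ring global `ring_height` remains the band width.

The annotated intermediate is PhyloXML. The style is embedded as one
namespaced `<property ref="style:option">` element per option per clade
(ring options keyed `option:index`, globals attached to the phylogeny
element); foreign properties are preserved verbatim. The PhyloXML schema
does not prescribe a style encoding, so this convention is the package's
own. Serialization fixes element order and uses shortest-round-trip decimal
formatting (`repr`), which is what makes re-annotation idempotent at the
byte level.

## Biomarker and abundance styling

The converter maps an LDA-style effect size `s` onto node color by linear
per-channel interpolation between black at `s_min` and the enriched class's
full color at `s_max` (scores clamped; endpoints exact). `s_min` defaults
to 2.0 — the conventional significance cutoff on the log10 LDA scale — and
`s_max` to the maximum observed score. Node size is
`base + scale·log10(1 + abundance)` with defaults base 3, scale 8 (so 0%
→ 3 and 9% → 11), strictly increasing in abundance. Clade labels go to the
`top_k` = 10 clades with mean abundance ≥ 1% within the first 5 ranks, ties
broken lexicographically; label font sizes decay geometrically toward the
root (base 11 pt, factor 0.85 per labeled level, floor 5 pt), so nested
biomarker labels shrink with rank depth. These converter defaults are this
package's own parameter surface.

## Input dialects

* **Newick**: hand-parsed for exact child-order preservation, error
  offsets, and quoting control (single quotes with `''` escapes; writes
  quote any label containing specials). The classic underscore-as-space
  dialect is supported behind an opt-in flag and is off by default because
  microbiome taxon names (`k__Bacteria`) use underscores literally.
* **Nexus**: first tree of the TREES block via Bio.Phylo, TRANSLATE tables
  honoured. Bio.Nexus reports absent branch lengths as 0.0, so an all-zero
  tree is normalized to a taxonomic (lengthless) tree.
* **Plain lineages**: prefix trie under a synthetic unnamed root; sibling
  order is first appearance; duplicate lines collapse.
* **Profiles**: pipe-separated hierarchical tables (taxonomic or
  functional — the dialect is identical, so no pathway-specific logic).
  The per-row summary across samples is the mean (median available).
* **BIOM**: version 1 (JSON), dense or sparse, lineages from the
  `taxonomy` observation metadata with fallback to the observation id and
  summing on collision. Version 2 (HDF5) is out of scope for the core.
* Duplicate leaf names are an error by default (annotation targeting needs
  unambiguous names); `auto_rename` appends `__2`, `__3`, … in traversal
  order.

## Synthetic data: what it emulates and what it does not

The fixtures module generates the study conditions used throughout the
tests: random trees (exact leaf counts, bounded depth, optional exponential
branch lengths), two-class profiles with log-normal baseline abundances
(location 0, scale 1 on the natural-log scale, 20 samples by default),
spiked clades multiplied by `2^effect` in the spiked class, and columns
renormalized to sum to 100 over the terminal taxa with internal rows as
descendant sums — the structure of a real profiler table. One seed drives
one pinned generator (NumPy PCG64); corpora are byte-stable.

The effect-score generator is *not* a linear discriminant analysis. It
rescales the spread of class means of `log10(1 + abundance)` onto the
conventional score range [2, 6] and marks records below a floor of 2.5 as
non-significant; the floor is chosen so that only clades carrying a
substantial fraction of the maximum spread are called, which is what a real
biomarker-discovery run looks like. Identical class distributions sit
exactly at 2.0 and are never significant. Consequently, passing tests show
that the conversion and styling pipeline is faithful to its inputs — they
say nothing about the statistical behaviour of any real biomarker method,
and the profiles carry no compositional covariance or phylogenetic signal
in their noise.

Because columns are renormalized, a +3 log2 spike on a clade is attenuated
in relative abundance (the spiked column's total grows); at 64 leaves with
a single spiked leaf the observed class-mean log2 ratio lands around 2.6–
2.9 rather than 3.0. The recovery checks therefore assert rank and class,
and bound the ratio from below, rather than demanding the unattenuated
effect.

## Problem sizes and numerics

The test suite and the acceptance script use 100–200-tree corpora of up to
64 leaves for round-trip and geometry checks, 100 random profiles for
converter fidelity, 200-sample profiles for effect recovery, and one
4,000-leaf tree through the full fixtures → export → annotate → plot chain
— a size representative of tree-of-life-scale figures; the whole chain
runs in seconds because target resolution caches the parent map, name
index and lineages per tree. Angular bookkeeping is checked to 1e−9
degrees; branch lengths round-trip within 1e−9; color channels are exact
at scale endpoints (no tolerance). Degenerate inputs have defined
behaviour: empty trees and non-positive ring heights or angular spans are
errors, zero-size markers are suppressed, zero-height bars draw nothing,
and a heatmap value outside [0, 1] is an error rather than a clamp.

## Known limitations

SVG is the only first-class output; raster export is delegated to external
converters with no determinism claim. There is no label collision
avoidance beyond the lettered legend, no unrooted or rectangular layouts,
no NHX or multi-tree Nexus handling, and the converter does not reimplement
any profiler or biomarker-discovery method — it only consumes their output
formats.
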