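# Methods

This note documents the models, heuristics, defaults and numerical choices
behind `goldenpath`, and what the synthetic test bed does and does not show
about real data.

## Problem setting and assumptions

The input is a set of linear contigs (no assembly-graph awareness), a table of
mapped Hi-C read-pair positions produced by an external mapper, and a guide
map: markers with a chromosome and a position (bp for reference-derived
markers, cM for genetic-map markers) aligned to the contigs. The package
assumes an inbred/homozygous genome — one haplotype per chromosome — and does
not attempt haplotype separation or polyploid phasing.

The guide map supplies two things only: chromosome membership of contigs and
the global orientation of each chromosome. Local contig order is inferred
from Hi-C alone, which deliberately allows structural rearrangements relative
to the guide (a reference-derived guide map is a *related* genome, not the
genome being assembled).

Coordinates are 0-based half-open everywhere inside the package; AGP output
is 1-based inclusive per the AGP v2.1 standard, and PAF input is read as
0-based half-open. Contig identifiers are opaque strings and are never
normalized or "repaired"; curation tables that fail validation raise errors
naming the offending line instead of being silently fixed, because
spreadsheet autocorrection is a real corruption channel for sequence
identifiers.

## Digestion and link statistics

In-silico digestion places fragment boundaries at every occurrence of the
recognition site (MboI/GATC by default; cut offset 0, so boundaries sit at
site starts). Fragment counts per contig serve as the default normalizer for
link densities: they track mappable restriction-site density rather than raw
length, which is what determines how many Hi-C reads a contig can capture.
Length normalization (`--normalize length`) is available for protocols where
fragment density is uninformative.

Pair ingestion keeps pairs with `min(mapq1, mapq2) >= 10`: Q10 retains reads
mapped with some degree of uniqueness while discarding the large multi-mapping
fraction typical of repeat-rich genomes. Exact-duplicate removal is offered
as a flag but is off by default, since upstream mapping pipelines differ in
whether they deduplicate.

Physical coverage of a window is the number of intra-contig pairs whose
spanned interval overlaps it. Defaults: 1-kb windows, 1-Mb span cap. The
span cap keeps the statistic local — without it, abundant long-range pairs
flatten the troughs that mark chimera junctions. The 1-kb window makes "one
window" a meaningful localization guarantee on multi-megabase contigs.

Contact matrices bin pair ends lifted through the map layout (offset and
orientation) into fixed windows (1 Mb default). Each pair is counted once;
the symmetric storage is a convention, so the upper triangle plus diagonal
sums to the number of contributing pairs. Raw counts are plotted — no
matrix balancing (ICE/KR), which is diagnostic overkill for spotting
misplaced contigs.

## Guide-map construction and assignment

Reference-derived markers are maximal runs of positions whose covering
31-mers (canonical, i.e. strand-symmetric) each occur exactly once
genome-wide, kept when ≥ 100 bp. k-mer multiplicity was chosen over
self-alignment because it is deterministic, dependency-free and desk-testable;
k = 31 is the usual single-copy k-mer size for plant-scale genomes — long
enough that random 31-mers essentially never collide, short enough to keep
sensitivity. Genetic-map markers get 101-bp tags (50 bp up- and downstream of
the marker site, truncated at sequence ends, dropped below 20 bp); a
`tag_style="end100"` variant emits exact 100-bp tags ending at the marker
position, matching the convention of some published SNP-array maps.

Marker alignments (PAF) are filtered to the single best hit per marker by
(matches, alignment length), requiring identity ≥ 0.9 and ≥ 0.8 of the tag
aligned, and discarding markers whose second-best hit reaches 0.9× the best
match count — ambiguous placements hurt more than missing markers. These
four thresholds are package defaults chosen as conventional values for
near-identical alignments; they are all configurable.

Chromosome assignment is an unweighted vote: the winning chromosome is the
mode of a contig's marker chromosomes, requiring ≥ 2 supporting markers and
≥ 0.75 purity. Unweighted voting (rather than weighting by alignment length)
keeps a handful of long repetitive markers from outvoting many short unique
ones. Contigs spanning more than one chromosome with purity < 0.95 are
flagged as chimera candidates. The consensus guide position is the median of
the winning chromosome's marker positions (robust to stray markers).

## Ordering and orientation

Within a chromosome, the graph on assigned contigs has edge weights
`w = n_links / (f_i f_j)` and edge costs `-log w`; a minimum spanning tree of
this graph maximizes the product of weights over the tree. The backbone is
the tree's maximum-cardinality path (ties broken by total path weight, then
lexicographically). Off-backbone contigs are inserted in breadth-first order
from the backbone, each immediately before or after its (already placed) tree
neighbor, on the side with the larger summed weight to the would-be adjacent
contigs. Contigs with no usable links are inserted where their guide
position fits the current order. Finally the order is reversed if contig
ranks anticorrelate with guide positions (Spearman), anchoring the
pseudomolecule to the guide map's chromosomal orientation. All tie-breaks
are lexicographic on contig id, so output is deterministic for fixed input.

Orientation: contigs with ≥ 2 markers take the sign of the Spearman
correlation between marker positions on the contig and on the guide;
tied/degenerate cases and markerless contigs use the Hi-C rule — a contig
points forward when its pair ends linking to predecessor contigs lie on
average before those linking to successors; a contig with neighbors on one
side only compares against its midpoint; isolated contigs default to `+`.

On simulated instances of up to 7 contigs the heuristic's adjacency objective
(sum of adjacent-pair weights) matched the exhaustive-search optimum in all
50 random trials of the test suite; this is an empirical property of the test
conditions, not a guarantee — MST diameter + greedy insertion is a heuristic.

## Chimera detection and breaking

Coverage-trough detection flags windows at least 8-fold below the contig-wide
mean whose centers lie ≥ 100 kb from both contig ends; sub-threshold windows
within 3 windows of each other merge into one run, and each run yields one
candidate at its minimum-coverage window center. Junctions closer than
~2% of a chromosome length to their true neighborhood produce shallow troughs
that this heuristic can miss; marker discordance is the fallback signal. The
discordance rule requires at least two blocks of ≥ 3 consecutive
same-chromosome markers from different chromosomes, so isolated mis-mapped
markers never flag a contig.

Detection only proposes candidates. Breaking requires an explicit breakpoint
list: position `p` splits `[0, p)` / `[p, length)`, parts are named
`<contig>.1 ... <contig>.n+1`, every pair and marker position is remapped into
its part, and restriction fragments are re-cut at the break position rather
than re-digested (no sequence access needed at break time; the two fragments
flanking a cut are the only ones affected, and their boundary is synthetic
either way). Pair count, marker count and total bp are conserved exactly.

## Curation metric

"Off-diagonal mass" — the per-chromosome sum of contact counts weighted by
`|bin1 - bin2|` — is this package's scalar summary of what a curator assesses
visually: misplaced or flipped contigs push signal away from the diagonal,
and a corrective edit must strictly reduce the mass. It is a relative
quantity for before/after comparison on the same binning, not an absolute
quality score.

## Pseudomolecule compilation

Gaps between consecutive contigs are 100 bp of `N`, typed `U` (unknown size)
with evidence `proximity_ligation` — the NCBI convention for scaffold gaps of
unknown size. Unplaced contigs are written as individual FASTA records,
never concatenated into a `chrUn`, since INSDC archives refuse concatenated
pseudo-sequences. N50/N90 are defined as the smallest contig length such
that contigs at least that long cover ≥ 50%/90% of the total.

## Synthetic data generator

The generator emulates the study conditions end to end:

- **Genome**: i.i.d. uniform A/C/G/T chromosomes. Random sequence makes
  essentially every position single-copy, which is what the guide-map
  machinery assumes after masking; it does *not* model repeats.
- **Contigs**: uniform breakpoints (contig counts per chromosome drawn
  multinomially by length). Injected inter-chromosomal chimeras join two
  runs of adjacent intervals ≥ 2 Mb each from different chromosomes;
  inversions reverse-complement a contig in place. Contig names are assigned
  in random order so identifiers carry no positional hint.
- **Hi-C pairs**: with probability `1 - trans_frac` (default 0.95) a cis pair
  — first end uniform on a length-weighted chromosome, separation `d` drawn
  from a truncated power law `d^-alpha` on `[1 kb, chromosome length)`,
  direction random, separations that fit on neither side of the first end are
  resampled (never clamped to termini, which would fabricate long-range
  signal at chromosome ends). With probability `trans_frac` (default 0.05,
  a typical usable-trans fraction) both ends are uniform on independent
  chromosomes. `alpha = 1` approximates observed Hi-C contact decay.
  Positions are projected through the ground truth onto contig coordinates,
  honoring injected chimeras/inversions, with mapping quality 60; a 2% noise
  fraction emulates mis-mapped reads (one end moved to a random position,
  mapping quality < 10), which the Q10 ingestion filter removes.
- **Guide map**: markers every `spacing` bp (default 100 kb) with ±25%
  jitter; alignments are computed exactly from the truth, so guide-map noise
  enters only through the optional `noise_markers` mislabeling, not through
  alignment error.
- **Reference conditions**: 2 chromosomes × 20 Mb, 60 contigs, 5×10⁵ pairs,
  decay 1.0, trans 0.05, markers every 100 kb. At this depth (≈12.5 pairs/kb)
  the scaffolder recovers the true map essentially perfectly, which is the
  point: the acceptance checks measure the machinery, not the biology.
  Problem sizes throughout the tests (20-Mb chromosomes rather than
  gigabases, tens of contigs rather than hundreds) are chosen so the whole
  suite runs on a laptop in minutes while still spanning multiple 1-Mb
  contact bins, dozens of markers per contig, and multi-megabase chimera
  arms.

What passing tests therefore do **not** show: behavior on repeat-rich
sequence (mapping ambiguity, collapsed repeats), real restriction-site
density variation, heterozygosity, reference–target structural divergence
beyond what marker mislabeling emulates, or chimeras whose junctions fall
within 100 kb of contig ends.

## Numerical and degenerate-input choices

- Pearson correlations between maps use contig midpoints (orientation-stable,
  unlike starts/ends); chromosomes sharing fewer than two contigs report NaN
  rather than raising; contigs placed on different chromosomes in the two
  maps are excluded from `r` and counted separately. Both `r` and `r²` are
  emitted.
- Downsampling retains each row independently with probability `fraction`
  (seeded), so retained counts are binomial, matching how sequencing depth
  actually thins.
- Empty inputs: digesting an empty sequence yields no fragments (not an
  error); an empty pair file is an empty table; `assembly_stats` of an empty
  list raises (no meaningful N50).
- Spearman/orientation ties: a zero or undefined correlation falls through to
  the Hi-C rule, then to `+1`.
- Sub-seeds for multi-stage simulations are spawned from the master seed via
  `numpy.random.SeedSequence`, keeping stages independently reproducible.

## Known limitations

- The ordering refinement is a heuristic; pathological weight structures
  (e.g. very small contigs whose normalized background weights rival genuine
  adjacency weights under shallow contact decay) can misplace contigs, which
  is precisely what the curation cycle exists to catch.
- No automatic breakpoint refinement: breaks happen where the user (or the
  coverage scan) says, to the resolution of one coverage window.
- The interactive matrix inspector of the original workflow is replaced by
  static heatmaps plus a `map locate CHR POS` lookup; there is no browser UI.
- Hi-C-only chromosome clustering is out of scope by design: without a guide
  map this package cannot assign contigs to chromosomes.
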