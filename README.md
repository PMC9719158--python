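# goldenpath

Chromosome-scale scaffolding of long-read contigs with Hi-C proximity-ligation
data and a **guide map**.

Modern long-read assemblers produce highly contiguous contigs, but contigs
rarely span whole chromosomes. Hi-C read pairs provide the long-range linkage
needed to order and orient contigs into pseudomolecules — in-silico
representations of entire chromosomes. Unlike Hi-C-only scaffolders,
`goldenpath` does not cluster contigs into chromosomes from Hi-C signal alone:
a guide map — an ordered set of sequence-tag markers with chromosome and
position coordinates, derived either from a related reference genome
(single-copy regions ≥ 100 bp) or from a genetic map (marker flank tags
positioned in cM) — assigns contigs to chromosomes and fixes each
chromosome's global orientation, while the *local* contig order within a
chromosome comes from Hi-C alone. This targets genome and pangenome projects
in species where a reference genome or a dense genetic map exists: plant
genomes are the motivating case.

## Method

For contigs $i, j$ assigned to the same chromosome, Hi-C links are aggregated
and normalized by restriction-fragment content,

$$w_{ij} = \frac{n_{ij}}{f_i\, f_j},$$

where $n_{ij}$ is the number of Q10+ read pairs connecting the contigs and
$f_i$ the number of in-silico restriction fragments (MboI by default) of
contig $i$. On the graph with edge costs $-\log w_{ij}$ a minimum spanning
tree is computed; the tree's maximum-cardinality (diameter) path becomes the
ordering backbone, remaining contigs are greedily inserted next to their tree
attachment point on the side that maximizes adjacent link weight, and the
whole order is reversed if contig ranks anticorrelate (Spearman) with guide
positions. Orientation per contig is the sign of the Spearman correlation
between marker positions on the contig and on the guide; markerless contigs
fall back to a Hi-C rule comparing mean link positions toward predecessors
vs. successors.

Around that core the package provides:

- **Chimera handling** — candidate mis-joins are flagged by troughs in
  physical Hi-C coverage (windows ≥ 8-fold below the contig mean, ≥ 100 kb
  from contig ends) and by guide-marker blocks from more than one chromosome;
  breaking at user-specified coordinates remaps every pair, marker and
  fragment.
- **Spreadsheet curation** — the map exports as a TSV of ordered, oriented
  contigs; after editing (flip an orientation, swap two ranks, move a contig
  to `unplaced`) it re-imports under strict validation, and contact matrices
  before/after an edit are compared, including a per-chromosome
  *off-diagonal mass* score that corrective edits should reduce.
- **Compilation** — AGP v2.1 plus pseudomolecule FASTA (100-bp `N` gaps,
  minus-oriented contigs reverse-complemented) and a multi-FASTA of unplaced
  contigs, one record each.
- **Evaluation** — downsampling of Hi-C links or guide markers with
  Pearson-correlation comparison of contig positions between maps, plus
  collinearity dot-plot data and contact-matrix heatmaps.
- **Simulation** — a generator of synthetic genomes, contigs (with optional
  injected chimeras and inversions), Hi-C pairs with power-law contact decay,
  and guide maps, with full ground truth; it underpins the test suite.

## Worked example

The whole pipeline on a bundled synthetic dataset (2 × 5 Mb genome, 16
contigs, 100 k Hi-C pairs, markers every 100 kb):

```sh
goldenpath simulate --out sim --seed 1 --chrom-length 5000000 \
    --n-contigs 16 --n-pairs 100000 --marker-spacing 100000
goldenpath init --fasta sim/contigs.fasta --pairs sim/pairs.tsv \
    --alignments sim/alignments.tsv --out asm
goldenpath scaffold build --assembly asm --out-map map.tsv --report report.json
goldenpath compile --assembly asm --map map.tsv --out-prefix demo
goldenpath stats --fasta demo.fasta
```

which prints

```
wrote synthetic dataset to sim
assembly directory -> asm
Hi-C map (13 placed, 3 unplaced) -> map.tsv
demo.agp, demo.fasta, demo.unplaced.fasta
count   2
total   9729267
N50     4879888
N90     4849379
mean    4864633.5
max     4879888
min     4849379
```

13 of the 16 contigs were placed (the 3 unplaced ones are too short to carry
the two guide markers required for assignment), producing two pseudomolecules
of ~4.85 and ~4.88 Mb whose N50 equals the longer pseudomolecule. The map
table is the curation spreadsheet:

```
chromosome  rank  contig_id  orientation  length_bp  n_markers  guide_pos
chr1        1     tig00012   +            1101135    11         571645.0
chr1        2     tig00008   +            776730     8          1603444.0
...
```

ranks follow the true contig order along each chromosome and `guide_pos`
(median marker position) increases with rank. The AGP records the golden
path, alternating contig (`W`) and 100-bp gap (`U`) rows:

```
##agp-version   2.1
chr1  1        1101135  1  W  tig00012  1  1101135  +
chr1  1101136  1101235  2  U  100  scaffold  yes  proximity_ligation
chr1  1101236  1877965  3  W  tig00008  1  776730   +
```

For real data, `sim/` is replaced by your contig FASTA, a mapped Hi-C pair
table (any mapper; 6 columns `contig1 pos1 mapq1 contig2 pos2 mapq2`), and
marker alignments from `goldenpath guidemap from-reference` /
`from-genetic-map` + minimap2 + `guidemap ingest-paf`. `goldenpath chimera
detect` / `break` and `goldenpath map export/import/diff/plot/locate` support
the correct-map-inspect curation cycle, and `goldenpath evaluate downsample`
measures how much Hi-C depth or marker density the map actually needs.

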