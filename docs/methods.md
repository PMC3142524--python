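# Methods

## Coordinates and projection

All internal coordinates are 0-based, half-open, on the forward strand;
conversion happens only at the I/O boundary (GFF3 is 1-based inclusive; MAF
reverse-strand rows carry offsets from the start of the reverse complement,
converted on read to forward leftmost offsets, `fwd_start = srcSize − start
− size`). The `src` field of a MAF row is split on the first `.` into
genome and contig identifiers; a `src` without a dot is an error. Blocks
with more than one row for a genome are skipped with a warning rather than
failing the run: positional orthology is undefined for duplicated segments,
and aligners can emit them.

Alignment blocks and gene intervals are indexed in interval trees keyed by
`(genome, contig)`; each block row additionally carries precomputed numpy
maps between forward positions and alignment columns, so position↔column
projection is O(1) after an O(width) build. Projecting a gap column yields
the forward position of the nearest non-gap character to its left in the
row (−1 when the gap run reaches the block edge). Left-anchoring is a
deterministic convention needed when extracting sequence across indels;
nothing downstream depends on the choice of side beyond determinism.

A gene spanning several blocks is anchored, for all column comparisons, in
the block containing its stop (3′) codon base; ties fall to the block with
the most covered bases, then the lowest block id. Groups whose members
anchor in different blocks are never guessed equal: they classify as
`combination` with a block-split note in the report.

## Ortholog grouping

Genes are processed in order of decreasing length (ties broken by
`(genome_id, gene_id)` for reproducibility). The longest unassigned gene
seeds a group as its query; candidates are genes of *other* genomes whose
intervals intersect the query's projected span. Overlap is measured in
shared alignment columns — columns holding a base of both genes — which
makes the measure indel-insensitive. A candidate joins when the shared
columns cover at least `cov_match` (default 0.5) of its own length; the
query-side cutoff `cov_query` (default 0.5) is evaluated once per query as
the aligned fraction of the query's length over all blocks, and a query
failing it still seeds a singleton group, so the output is always an exact
partition of the input gene set. Several genes of one non-query genome may
join the same group; that is how fragmented genes surface. Genes of the
query's own genome never join — same-genome co-membership exists only via
fragments in non-query genomes.

## Consistency classification

For every non-singleton group the alignment columns of each member's
biological 5′ and 3′ terminal bases are compared exactly (same block, same
column). The decision table: all starts and stops equal with at most one
gene per genome → `consistent`; stops equal, starts differ →
`inconsistent_starts`; starts equal, stops differ → `inconsistent_stops`;
both differ (including members on different strands) → `combination`. A
genome contributing two or more members makes `fragmentation` the primary
class, with the start/stop pattern retained as a secondary class — this
keeps the class mutually exclusive with `consistent` and the per-class
counts unambiguous. Singletons are excluded from all anomaly denominators;
they have nothing to be inconsistent with.

A group's *sole outlier* is the genome whose removal — and no other single
genome's — leaves the remaining members consistent. Two-member inconsistent
groups attribute to neither genome (either removal trivially succeeds), and
groups where two or more genomes disagree with the rest attribute to
nobody. The per-genome table aggregates these attributions.

Missing annotations are reported per group for genomes whose row covers the
query's region but which contribute no member, provided no annotated gene
of any kind overlaps the projected interval. Only blocks containing at
least `min_block_genome_frac` (default 0.9) of all genomes are considered,
so sparsely aligned accessory regions do not flood the report. The
contig-boundary flag fires when any member is marked partial or has a
terminus within `boundary_window` (default 10) bp of a contig end —
the draft-assembly artifact behind many apparent inconsistencies.

## Alternative structures and frameshift repair

Candidate structures are the Cartesian product of the distinct annotated
start and stop columns observed in a group, restricted to pairs on one
strand, in one block, with the start 5′ of the stop. Each pair is evaluated
in each genome by projecting both columns, extracting the spanned sequence
on the gene strand, and testing: initiator first codon, terminator last
codon, no internal in-frame stop, length divisible by three. Codon sets
default to ATG/GTG/TTG and TAA/TAG/TGA (the bacterial code's common
initiators; the full table-11 initiator set can be configured).

When the plain test fails and the spanned region shows an indel signature —
a gap in this genome's row, or a column where another row is gapped while
this row has a base — a frameshift repair is attempted: skipping one or two
bases at a junction within one codon of the indel site, i.e. allowing the
reading frame to change once at the indel. The minimal number of shifts
(default cap 1, configurable to 2) that validates is kept together with the
indel column. Restricting junctions to ±1 codon of an observed indel keeps
the search linear and grounded in the alignment; an unrestricted search
would accept biologically unmotivated repairs. For a 1-bp deletion the
skip-two repair at the codon boundary nearest the deletion reproduces the
ancestral codon sequence minus one codon exactly, which is why planted
splits are recovered at the planted column.

Candidates shorter than `min_len_frac` (default 0.5) of a genome's
annotated length, in any genome that has an annotated member, are dropped.
Survivors are ranked by number of genomes with a valid ORF, then by length
(the sort is configurable to length-first), with deterministic column-order
tie-breaks, flagged when they would overlap an annotated gene outside the
group, and labelled with the direction (upstream/downstream) of the
proposed TIS relative to the query's annotation. For each missing-annotation
record the group's rank-1 pair is evaluated in the unannotated genome and
suggested only when it forms a valid ORF there.

## Synthetic pan-genome generator

The generator is the package's study system, and its defaults are the
conditions the test-suite properties are stated under: 5 isolates, a 1 Mb
single-contig ancestor, 800 non-overlapping genes of 300–900 bp (uniform,
multiples of 3, both strands, random sense codons between a start and a
stop), per-base substitution rate 0.005, intergenic indel rate 1e-4 with
lengths 1–3. One seeded RNG drives everything in a fixed order (ancestor,
then isolates, then anomaly planting), so outputs are byte-reproducible.

Substitutions are rejection-sampled against the annotation: never in a
start or stop codon, never creating an in-frame stop (evaluated in the
partially mutated sequence, so co-occurring substitutions in one codon
cannot combine into a stop); indels are rejected inside or within 5 bp of
genes. This stop-avoiding neutrality is what makes planted-anomaly counts
exact: every anomaly the pipeline finds was planted, and the acceptance
checks can demand equality rather than tolerances. Disabling it
(`avoid_stops=False`) yields genuinely noisy data.

The truth alignment is a star alignment to the ancestor: isolate rows are
written directly from the mutation history (insertions become gap columns
in all other rows; deletions become gaps in the carrier), so every column
is correct by construction and the MAF and FASTA outputs cannot disagree.
Annotation coordinates are lifted through the same history.

Planting: TIS shifts move one isolate's annotated start in frame to the
first internal start codon at codon index ≥ 2 within the first third of the
gene; if none exists, an ATG + AAA pair is written 6 bp upstream in that
isolate only (as logged substitutions, so the alignment stays exact). Gene
splits delete one mid-gene base and re-annotate the gene as two fragments
meeting at the stop codon induced by the shifted frame (both fragments must
be ≥ 30 bp or another gene is drawn). Deleted annotations drop the record
and keep the sequence. Contig breaks split the contig mid-gene — and the
alignment block at the same column for every genome — marking both
fragments partial; the `partial_gene` variant keeps only the longer
fragment's annotation, emulating a truncated prediction at a draft edge.

What the generator does **not** emulate: rearrangement, recombination, gene
gain/loss, segmental duplication, non-uniform substitution models, or
alignment error (the truth MAF is exact, whereas a real aligner's output
near indels and repeats is not). Passing tests therefore demonstrate the
correctness of the grouping/classification/repair logic given a correct
alignment, not robustness to alignment artifacts.

## Problem sizes and numerical choices

The acceptance-style properties run at the generator's default scale
(5 × 1 Mb × 800 genes, ≈ 4000 genes; a few seconds per run), with 50
smaller randomized instances (≤ 105 genes) for the oracle-equivalence
check of the grouping against a naive O(n²) per-base reimplementation.
Column maps use int64 numpy arrays; interval queries deduplicate and sort
block ids so every traversal order is deterministic. Degenerate inputs are
defined: an empty MAF yields an empty index and all-singleton groups; a
gene aligned in no block is queryable but marked unaligned and never
classified; a gap column with no non-gap character to its left projects to
position −1 and any candidate touching it is marked unprojectable rather
than guessed.

## Known limitations

* Spliced CDS structures are rejected (GFF3 multi-row CDS, GenBank compound
  locations): the method targets unspliced prokaryotic genes.
* Duplicated aligned segments (two rows of one genome in a block) are
  skipped, so duplication-aware orthology is out of scope.
* Column equality is exact; genes anchored in different blocks are reported
  as `combination`/block-split rather than reconciled across blocks.
* The tool scores consistency, not correctness: a uniformly wrong but
  consistent annotation produces no anomaly, and resolving flagged groups
  correctly needs evidence beyond the alignment (RBS, homology, proteomics).
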