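# panannot

Annotation consistency checking and repair suggestions for bacterial
pan-genomes, driven by whole-genome multiple alignment.

## The problem

When many closely related isolates of one species are sequenced, each genome
is usually annotated independently — by different pipelines, at different
times, with different amounts of manual curation. The result is that
orthologous genes, often identical in sequence, end up annotated with
different translation-initiation sites (TIS), different stop sites, or as
several fragments, and sometimes not at all. These inconsistencies are
bioinformatic artifacts, not biology, and they corrupt downstream
comparative analyses (core-genome definition, dN/dS, regulatory-region
comparison).

`panannot` consumes per-genome FASTA sequences, CDS annotations (GFF3, or
GenBank), and a reference-independent whole-genome multiple alignment in MAF
format (one aligned segment per genome per block, as produced by
whole-genome aligners such as Mugsy or progressiveMauve), and:

1. **builds positional ortholog groups** — genes whose intervals occupy the
   same alignment columns are clustered greedily from the longest gene down,
   with configurable coverage cutoffs (50% by default on both the query and
   each candidate). Because grouping is positional, paralogs stay apart and
   a gene fragmented across one genome is captured as multiple members of
   one group;
2. **classifies each group's annotation consistency** by comparing the
   alignment columns of every member's start and stop codons:
   `consistent`, `inconsistent_starts`, `inconsistent_stops`, `combination`
   (both differ, or mixed frames/strands), `fragmentation` (a genome
   contributes ≥ 2 members), plus missing-annotation records and
   contig-boundary flags for draft-assembly artifacts; and
3. **ranks alternative gene structures**: every annotated start/stop column
   pair observed in a group is checked in every genome as an ORF under the
   bacterial genetic code (NCBI table 11; initiators ATG/GTG/TTG by
   default). Where an alignment indel breaks the reading frame, a single
   frameshift repair at the indel is attempted, which rejoins
   pseudogene-like fragments into one spanning ORF. Candidates are ranked
   by the number of genomes with a valid ORF, then by length, and flagged
   when they would overlap an adjacent gene.

A fully ground-truthed synthetic pan-genome generator (ancestor with valid
ORFs, isolates with stop-avoiding substitutions and intergenic indels, an
exact star-alignment truth MAF, and planted anomalies of every class) makes
the whole pipeline testable without any external data.

## Worked example

```sh
panannot simulate --outdir data --seed 1 --n-genomes 3 --genome-len 20000 \
    --n-genes 12 --tis-shift 2 --gene-split-indel 1 --deleted-annotation 1
panannot annotate --maf data/alignment.maf --outdir out \
    --fasta data/s1.fasta --gff3 data/s1.gff3 \
    --fasta data/s2.fasta --gff3 data/s2.gff3 \
    --fasta data/s3.fasta --gff3 data/s3.gff3
```

prints

```
genes                 36
ortholog groups       12
  singletons          0
  consistent          9
  fragmentation       1
  inconsistent_starts 2
fraction consistent   0.750
missing annotations   1
suggested edits       1
```

12 ancestral genes give 12 ortholog groups; the two planted TIS shifts
surface as `inconsistent_starts` (the per-genome table in
`out/inconsistency.tsv` attributes each to the one isolate that disagrees),
the frameshift-split gene as `fragmentation`, and the deleted annotation as
a missing-annotation record with a suggested gene structure.
`out/alternatives.tsv` holds the ranked candidate structures — for the
fragmentation group, rank 1 is the ancestral start/stop pair, valid in all
three genomes via one frameshift placed at the planted indel column.
Plain-text alignment views of each anomalous group are written under
`out/alignments/`. The same workflow is available as a library API; see
`examples/` for one short script per capability.

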