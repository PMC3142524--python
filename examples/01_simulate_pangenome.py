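"""Generate a small ground-truthed pan-genome and write its input files.

Builds 3 isolates of a 20 kb ancestor carrying 12 genes, with two
mis-annotated start sites, one frameshift-split gene and one missing
annotation planted, then writes FASTA + GFF3 per isolate, the exact truth
alignment (MAF) and a truth table.
"""

from panannot import SimConfig, emit_truth_maf, simulate

config = SimConfig(
    n_genomes=3,
    genome_len=20_000,
    n_genes=12,
    seed=1,
    tis_shift=2,
    gene_split_indel=1,
    deleted_annotation=1,
)
result = simulate(config)
paths = emit_truth_maf(result, "example_data")

print(f"isolates : {[iso.genome_id for iso in result.isolates]}")
print(f"genes    : {sum(len(iso.annotations) for iso in result.isolates)} annotated CDS")
print(f"alignment: {len(result.blocks)} block(s), width {result.blocks[0].width} columns")
print("planted  :")
for a in result.truth.anomalies:
    print(f"  {a.kind:<20} gene {a.ancestor_gene} in {a.genome_id}")
print(f"files in example_data/: {sorted(set(p.split('/')[-1] for p in paths.values()))}")
# Each planted anomaly is one deliberate annotation error; everything else
# in the dataset is consistent by construction, so a perfect checker should
# find exactly these and nothing more.
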