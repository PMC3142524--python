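"""Rank alternative gene structures that restore cross-genome consistency.

Every annotated start/stop column pair in an inconsistent group is checked
as an ORF (bacterial code, table 11) in every genome; where an alignment
indel breaks the frame, a single frameshift repair is attempted.
"""

from panannot import (
    SimConfig, build_index, classify_group, group_orthologs,
    rank_alternatives, simulate,
)

result = simulate(SimConfig(n_genomes=3, genome_len=20_000, n_genes=12, seed=1,
                            tis_shift=1, gene_split_indel=1))
genomes = {iso.genome_id: iso.genome for iso in result.isolates}
annotations = [a for iso in result.isolates for a in iso.annotations]
index = build_index(result.blocks, annotations)
groups = group_orthologs(annotations, index)

for grp in groups:
    rep = classify_group(grp, index)
    if rep.klass in ("consistent", "singleton"):
        continue
    alts = rank_alternatives(grp, index, genomes)
    top = alts[0]
    print(f"{grp.group_id} ({rep.klass}): {len(alts)} candidate structure(s)")
    print(f"  rank 1: columns {top.start_locus.column}-{top.stop_locus.column} "
          f"({top.length} bp), valid ORF in {top.n_valid_orfs}/3 genomes, "
          f"direction vs annotation: {top.tis_direction}")
    for genome_id, ev in sorted(top.evaluations.items()):
        note = f"{ev.n_frameshifts} frameshift(s) at columns {list(ev.frameshift_columns)}" \
            if ev.n_frameshifts else "clean"
        print(f"    {genome_id}: {ev.contig_id}:{ev.start}-{ev.end}({ev.strand}) "
              f"valid={ev.orf_valid} [{note}]")
# The rank-1 candidate is the structure valid in the most genomes (longest
# on ties). For the split gene it joins the two fragments through one
# frameshift placed exactly at the alignment indel — the pseudogene /
# sequencing-error signature a curator would want to review.
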