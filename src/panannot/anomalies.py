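"""Consistency classification of ortholog groups.

Each non-singleton group is compared in alignment-column space: the columns
holding every member's annotated start (5') and stop (3') codon bases.  The
decision table is:

* all start columns equal, all stop columns equal, at most one gene per
  genome  -> ``consistent``
* stops equal, starts differ              -> ``inconsistent_starts``
* starts equal, stops differ              -> ``inconsistent_stops``
* both differ (including members on different strands or anchored in
  different blocks)                       -> ``combination``
* any genome contributing two or more members -> ``fragmentation``
  (primary; the start/stop pattern is kept as a secondary class)

Column equality is exact — same block, same column.  Members anchored in
different blocks are never guessed equal: the group becomes ``combination``
with a block-split note.  When removing exactly one genome's member(s)
would leave the rest consistent, that genome is recorded as the group's
sole outlier (the per-genome attribution the summary tables aggregate).

Missing annotations are detected per group: a genome whose row covers the
group's region but contributes no member, and whose projected interval
overlaps no annotation at all, is reported — provided the alignment block
contains a sufficient fraction of all genomes, so accessory regions do not
flood the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .index import AlignmentIndex
from .model import (
    AnomalyReport,
    ColumnLocus,
    GeneAnnotation,
    GeneTermini,
    GenomeSequence,
    OrthologGroup,
)

logger = logging.getLogger(__name__)


def locate_gene_termini(index: AlignmentIndex, gene: GeneAnnotation) -> GeneTermini:
    """Columns of the biological 5' and 3' terminal bases of a gene.

    For a forward gene the start locus is the leftmost base of the start
    codon; for a reverse gene it is the rightmost base (the biological 5'
    end).  A terminus outside every block is reported as None with a reason;
    a fully unaligned gene is an error.
    """
    if index.is_unaligned(gene.gene_id) or not index.gene_column_span(gene):
        raise ValueError(f"gene {gene.gene_id!r} is not aligned in any block")
    start_locus = index.project_to_column(
        gene.genome_id, gene.contig_id, gene.five_prime_pos()
    )
    stop_locus = index.project_to_column(
        gene.genome_id, gene.contig_id, gene.three_prime_pos()
    )
    return GeneTermini(
        gene_id=gene.gene_id,
        start_locus=start_locus,
        stop_locus=stop_locus,
        start_reason=None if start_locus else "start terminus unaligned",
        stop_reason=None if stop_locus else "stop terminus unaligned",
    )


def _all_equal(loci: list[Optional[ColumnLocus]]) -> bool:
    """True when all loci are present and identical (same block, same column)."""
    if any(l is None for l in loci):
        return False
    return len(set(loci)) == 1


def _members_consistent(
    termini: list[GeneTermini], strands: list[str], genome_ids: list[str]
) -> bool:
    """Would this member subset be classified consistent on its own?"""
    if len(genome_ids) != len(set(genome_ids)):
        return False
    if len(set(strands)) > 1:
        return False
    return _all_equal([t.start_locus for t in termini]) and _all_equal(
        [t.stop_locus for t in termini]
    )


def classify_group(group: OrthologGroup, index: AlignmentIndex) -> AnomalyReport:
    """Classify one ortholog group's annotation consistency."""
    anns = [index.annotations[gid] for gid in group.members]
    if group.is_singleton:
        return AnomalyReport(group_id=group.group_id, klass="singleton", n_genomes=1)

    termini = {a.gene_id: locate_gene_termini(index, a) for a in anns}
    strands = [a.strand for a in anns]
    genome_ids = [a.genome_id for a in anns]
    genomes = set(genome_ids)

    starts_equal = _all_equal([termini[a.gene_id].start_locus for a in anns])
    stops_equal = _all_equal([termini[a.gene_id].stop_locus for a in anns])
    fragmented = len(genome_ids) != len(genomes)
    mixed_strand = len(set(strands)) > 1

    anchor_blocks = {
        b
        for t in termini.values()
        for b in (
            t.start_locus.block_id if t.start_locus else None,
            t.stop_locus.block_id if t.stop_locus else None,
        )
        if b is not None
    }
    block_split = len(anchor_blocks) > 1

    if starts_equal and stops_equal and not fragmented:
        klass = "consistent"
    elif stops_equal and not starts_equal:
        klass = "inconsistent_starts"
    elif starts_equal and not stops_equal:
        klass = "inconsistent_stops"
    else:
        klass = "combination"
    secondary: set[str] = set()
    if fragmented:
        if klass not in ("consistent",):
            secondary.add(klass)
        klass = "fragmentation"
    if mixed_strand:
        secondary.add("mixed_strand")

    sole_outlier = None
    if klass != "consistent":
        culprits = []
        for g in sorted(genomes):
            rest = [a for a in anns if a.genome_id != g]
            if len(rest) >= 1 and _members_consistent(
                [termini[a.gene_id] for a in rest],
                [a.strand for a in rest],
                [a.genome_id for a in rest],
            ):
                culprits.append(g)
        if len(culprits) == 1:
            sole_outlier = culprits[0]

    return AnomalyReport(
        group_id=group.group_id,
        klass=klass,
        secondary_classes=secondary,
        termini=termini,
        sole_outlier_genome=sole_outlier,
        block_split=block_split,
        n_genomes=len(genomes),
    )


def flag_contig_boundary(
    report: AnomalyReport,
    group: OrthologGroup,
    index: AlignmentIndex,
    genomes: dict[str, GenomeSequence],
    window: int = 10,
) -> AnomalyReport:
    """Flag groups whose members abut contig boundaries.

    Set when any member is marked partial, or any member terminus lies
    within ``window`` bp of its contig end — the draft-assembly artifacts
    that account for many apparent start/stop inconsistencies.
    """
    for gid in group.members:
        gene = index.annotations[gid]
        if gene.partial5 or gene.partial3:
            report.contig_boundary = True
            return report
        clen = genomes[gene.genome_id].contig_len(gene.contig_id)
        if gene.start < window or gene.end > clen - window:
            report.contig_boundary = True
            return report
    return report


@dataclass(frozen=True)
class MissingAnnotation:
    """A projected gene interval with no annotation in one genome."""

    group_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int


def find_missing_annotations(
    groups: list[OrthologGroup],
    index: AlignmentIndex,
    min_block_genome_frac: float = 0.9,
) -> list[MissingAnnotation]:
    """Genomes aligned across a group's region but lacking any annotation.

    For each group, every genome with a row in the query's anchor block but
    no member gene is checked: the query gene's interval is projected into
    that genome and reported iff no annotated gene of any kind overlaps it.
    Only blocks containing at least ``min_block_genome_frac`` of all genomes
    are considered, so sparsely aligned accessory regions are skipped.
    """
    out: list[MissingAnnotation] = []
    n_genomes = len(index.genomes) or 1
    for grp in groups:
        query = index.annotations[grp.query_gene]
        member_genomes = grp.genomes_present(index.annotations)
        spans = index.gene_column_span(query)
        if not spans:
            continue
        candidates: dict[str, MissingAnnotation] = {}
        for block_id, _cs, _ce, _cov in spans:
            block = index.blocks[block_id]
            if len(block.rows) < min_block_genome_frac * n_genomes:
                continue
            qcols = index.gene_columns(query, block_id)
            for genome_id, row in block.rows.items():
                if genome_id in member_genomes or genome_id in candidates:
                    continue
                rmap = index.row_map(block_id, genome_id)
                pos = rmap.pos_of_col[qcols]
                pos = pos[pos >= 0]
                if pos.size == 0:
                    continue
                lo, hi = int(pos.min()), int(pos.max()) + 1
                if index.genes_at(genome_id, row.contig_id, lo, hi):
                    continue  # an unrelated prediction already covers it
                candidates[genome_id] = MissingAnnotation(
                    group_id=grp.group_id,
                    genome_id=genome_id,
                    contig_id=row.contig_id,
                    start=lo,
                    end=hi,
                )
        out.extend(candidates[g] for g in sorted(candidates))
    return out
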