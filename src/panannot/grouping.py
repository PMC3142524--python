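"""Positional ortholog grouping.

Genes are clustered greedily by descending length: the longest unassigned
gene seeds a group (the query), and genes from *other* genomes whose bases
share alignment columns with the query join it.  Coverage cutoffs (default
50% on both sides) follow common practice for positional orthology: the
candidate must have at least ``cov_match`` of its own length aligned into
the query's column span, and the alignment must cover at least ``cov_query``
of the query.  A query whose own aligned coverage fails the cutoff still
seeds a singleton group, so the result is always a partition of the input
gene set.  Several genes of one (non-query) genome may join the same group —
that is how fragmented genes (draft-assembly breaks, pseudogenes) surface.

Overlap is measured in shared alignment columns (non-gap on both rows),
which makes it insensitive to indels between the genomes.
"""

from __future__ import annotations

import logging

import numpy as np

from .index import AlignmentIndex
from .model import GeneAnnotation, OrthologGroup

logger = logging.getLogger(__name__)


def sort_key(gene: GeneAnnotation):
    """Descending length, then (genome_id, gene_id) for reproducibility."""
    return (-gene.length, gene.genome_id, gene.gene_id)


def group_orthologs(
    genes: list[GeneAnnotation],
    index: AlignmentIndex,
    cov_query: float = 0.5,
    cov_match: float = 0.5,
) -> list[OrthologGroup]:
    """Greedy, length-sorted clustering of genes by shared alignment columns.

    Returns groups forming an exact partition of ``genes``; group ids are
    assigned in seeding order (``group00001``...).
    """
    order = sorted(genes, key=sort_key)
    assigned: set[str] = set()
    groups: list[OrthologGroup] = []

    for query in order:
        if query.gene_id in assigned:
            continue
        assigned.add(query.gene_id)
        members = [query.gene_id]

        spans = index.gene_column_span(query)
        aligned_bases = sum(cov for _b, _cs, _ce, cov in spans)
        if aligned_bases >= cov_query * query.length:
            for block_id, _cs, _ce, _cov in spans:
                qcols = index.gene_columns(query, block_id)
                block = index.blocks[block_id]
                for genome_id, row in block.rows.items():
                    if genome_id == query.genome_id:
                        continue
                    rmap = index.row_map(block_id, genome_id)
                    # forward interval the query's columns touch in this genome
                    pos = rmap.pos_of_col[qcols]
                    pos = pos[pos >= 0]
                    if pos.size == 0:
                        continue
                    lo, hi = int(pos.min()), int(pos.max()) + 1
                    for cand_id in index.genes_at(genome_id, row.contig_id, lo, hi):
                        if cand_id in assigned or cand_id in members:
                            continue
                        cand = index.annotations[cand_id]
                        overlap = _column_overlap(index, query, cand)
                        if overlap >= cov_match * cand.length:
                            members.append(cand_id)
        for m in members:
            assigned.add(m)
        # canonical member order: the query, then descending length
        members = [query.gene_id] + sorted(
            (m for m in members[1:]), key=lambda m: sort_key(index.annotations[m])
        )
        groups.append(
            OrthologGroup(
                group_id=f"group{len(groups) + 1:05d}",
                query_gene=query.gene_id,
                members=members,
            )
        )
    return groups


def _column_overlap(index: AlignmentIndex, query: GeneAnnotation, cand: GeneAnnotation) -> int:
    """Number of alignment columns holding a base of both genes."""
    total = 0
    q_spans = {b for b, *_ in index.gene_column_span(query)}
    c_spans = {b for b, *_ in index.gene_column_span(cand)}
    for block_id in q_spans & c_spans:
        qcols = index.gene_columns(query, block_id)
        ccols = index.gene_columns(cand, block_id)
        total += np.intersect1d(qcols, ccols, assume_unique=True).size
    return total


def per_genome_inconsistency_counts(
    groups: list[OrthologGroup], anomalies: list
) -> dict[str, int]:
    """Per genome, the number of groups where it is the sole mismatch.

    A group contributes to a genome's count when removing that genome's
    member(s) — and no other single genome's — would leave the remaining
    annotated boundaries consistent.  Groups where two or more genomes
    disagree with the rest count for nobody.
    """
    counts: dict[str, int] = {}
    by_group = {rep.group_id: rep for rep in anomalies}
    for grp in groups:
        rep = by_group.get(grp.group_id)
        if rep is None:
            continue
        if rep.sole_outlier_genome is not None:
            counts[rep.sole_outlier_genome] = counts.get(rep.sole_outlier_genome, 0) + 1
    return counts
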