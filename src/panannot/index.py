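"""Interval-tree index over alignment blocks and gene annotations.

The index answers two kinds of question fast:

* which alignment block(s) and which gene(s) cover a genomic interval
  (interval trees keyed by ``(genome_id, contig_id)``), and
* bidirectional projection between a genomic position and an alignment
  column (pre-computed numpy column maps per block row).

Conventions
-----------
Positions are 0-based forward-strand offsets.  For a reverse-strand row the
stored text is the reverse complement of the forward slice, so text index
``i`` (counting non-gap characters) corresponds to forward position
``start + ungapped_len - 1 - i``; the column maps absorb this so callers
never see strand.  Projecting a gap column yields the forward position of
the nearest non-gap character to the LEFT in that row (column order), or -1
when there is none — a deterministic anchor for extracting sequence across
indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from intervaltree import IntervalTree

from .model import AlignmentBlock, ColumnLocus, GeneAnnotation

_GAP = ord("-")


@dataclass
class _RowMap:
    """Pre-computed projection arrays for one block row."""

    pos_of_col: np.ndarray  # width; forward pos at non-gap cols, -1 at gaps
    col_of_off: np.ndarray  # ungapped_len; column of forward offset start+j
    left_anchor: np.ndarray  # width; forward pos of nearest non-gap col to the left (-1)
    is_gap: np.ndarray  # width; bool

    @property
    def gap_columns(self) -> np.ndarray:
        return np.flatnonzero(self.is_gap)


def _build_row_map(row) -> _RowMap:
    text = np.frombuffer(row.text.encode("ascii"), dtype=np.uint8)
    is_gap = text == _GAP
    nongap_cols = np.flatnonzero(~is_gap)
    n = nongap_cols.size
    pos_of_col = np.full(text.size, -1, dtype=np.int64)
    col_of_off = np.empty(n, dtype=np.int64)
    if n:
        if row.strand == "+":
            # i-th non-gap char is forward position start + i
            offs = np.arange(n, dtype=np.int64)
        else:
            # text is the reverse complement: i-th non-gap char is the
            # (n-1-i)-th forward base of the segment
            offs = np.arange(n - 1, -1, -1, dtype=np.int64)
        pos_of_col[nongap_cols] = row.start + offs
        col_of_off[offs] = nongap_cols
    # nearest non-gap column to the left of each column (itself if non-gap)
    idx = np.where(~is_gap, np.arange(text.size), -1)
    idx = np.maximum.accumulate(idx)
    left_anchor = np.where(idx >= 0, pos_of_col[np.clip(idx, 0, None)], -1)
    return _RowMap(pos_of_col=pos_of_col, col_of_off=col_of_off,
                   left_anchor=left_anchor, is_gap=is_gap)


@dataclass
class ProjectedPosition:
    contig_id: str
    pos: int  # -1 when a gap column has no non-gap character to its left
    is_gap: bool


@dataclass
class AlignmentIndex:
    """Queryable index over blocks and genes; built by :func:`build_index`."""

    blocks: dict[str, AlignmentBlock] = field(default_factory=dict)
    annotations: dict[str, GeneAnnotation] = field(default_factory=dict)
    _block_trees: dict[tuple[str, str], IntervalTree] = field(default_factory=dict)
    _gene_trees: dict[tuple[str, str], IntervalTree] = field(default_factory=dict)
    _row_maps: dict[tuple[str, str], _RowMap] = field(default_factory=dict)
    genomes: set[str] = field(default_factory=set)
    unaligned_genes: set[str] = field(default_factory=set)

    # -- construction ------------------------------------------------------

    def _add_block(self, block: AlignmentBlock) -> None:
        self.blocks[block.block_id] = block
        for genome_id, row in block.rows.items():
            self.genomes.add(genome_id)
            key = (genome_id, row.contig_id)
            tree = self._block_trees.setdefault(key, IntervalTree())
            if row.ungapped_len > 0:
                tree.addi(row.start, row.end, block.block_id)
            self._row_maps[(block.block_id, genome_id)] = _build_row_map(row)

    def _add_gene(self, gene: GeneAnnotation) -> None:
        self.annotations[gene.gene_id] = gene
        self.genomes.add(gene.genome_id)
        key = (gene.genome_id, gene.contig_id)
        self._gene_trees.setdefault(key, IntervalTree()).addi(
            gene.start, gene.end, gene.gene_id
        )
        btree = self._block_trees.get(key)
        if btree is None or not btree.overlap(gene.start, gene.end):
            self.unaligned_genes.add(gene.gene_id)

    def row_map(self, block_id: str, genome_id: str) -> Optional[_RowMap]:
        return self._row_maps.get((block_id, genome_id))

    # -- queries -----------------------------------------------------------

    def blocks_at(self, genome_id: str, contig_id: str, start: int, end: int) -> list[str]:
        """Block ids overlapping a genomic interval, sorted by block_id."""
        tree = self._block_trees.get((genome_id, contig_id))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})

    def genes_at(self, genome_id: str, contig_id: str, start: int, end: int) -> list[str]:
        """Gene ids overlapping a genomic interval."""
        tree = self._gene_trees.get((genome_id, contig_id))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})

    def is_unaligned(self, gene_id: str) -> bool:
        return gene_id in self.unaligned_genes

    def project_to_column(
        self, genome_id: str, contig_id: str, pos: int
    ) -> Optional[ColumnLocus]:
        """Alignment column holding the base at forward offset ``pos``.

        Returns None when the position lies in no block.  Unknown genome or
        contig is an error (a typo, not an unaligned region).
        """
        known = any(g == genome_id and c == contig_id for g, c in self._block_trees) or any(
            g == genome_id and c == contig_id for g, c in self._gene_trees
        )
        if not known:
            raise KeyError(f"unknown genome/contig {genome_id}/{contig_id}")
        tree = self._block_trees.get((genome_id, contig_id))
        if tree is None:
            return None
        hits = sorted(tree[pos], key=lambda iv: iv.data)
        if not hits:
            return None
        block_id = hits[0].data
        row = self.blocks[block_id].rows[genome_id]
        rmap = self._row_maps[(block_id, genome_id)]
        return ColumnLocus(block_id, int(rmap.col_of_off[pos - row.start]))

    def project_from_column(
        self, block_id: str, column: int, genome_id: str
    ) -> Optional[ProjectedPosition]:
        """Forward position of ``column`` in ``genome_id``'s row.

        On a gap column, ``pos`` is the nearest non-gap position to the left
        in the row (-1 when the gap run reaches the block edge).  Returns
        None when the genome has no row in the block.
        """
        block = self.blocks[block_id]
        row = block.rows.get(genome_id)
        if row is None:
            return None
        if not 0 <= column < block.width:
            raise IndexError(f"column {column} outside block {block_id} width {block.width}")
        rmap = self._row_maps[(block_id, genome_id)]
        if rmap.is_gap[column]:
            return ProjectedPosition(row.contig_id, int(rmap.left_anchor[column]), True)
        return ProjectedPosition(row.contig_id, int(rmap.pos_of_col[column]), False)

    def gene_column_span(
        self, gene: GeneAnnotation
    ) -> list[tuple[str, int, int, int]]:
        """Smallest column interval per block covering the gene's aligned bases.

        Returns ``(block_id, col_start, col_end, covered_bases)`` tuples,
        half-open in columns, sorted by block_id; empty for unaligned genes.
        """
        out = []
        for block_id in self.blocks_at(gene.genome_id, gene.contig_id, gene.start, gene.end):
            row = self.blocks[block_id].rows[gene.genome_id]
            lo = max(gene.start, row.start)
            hi = min(gene.end, row.end)
            if lo >= hi:
                continue
            rmap = self._row_maps[(block_id, gene.genome_id)]
            cols = rmap.col_of_off[lo - row.start : hi - row.start]
            out.append((block_id, int(cols.min()), int(cols.max()) + 1, hi - lo))
        return out

    def gene_columns(self, gene: GeneAnnotation, block_id: str) -> np.ndarray:
        """Sorted array of columns holding the gene's bases in one block."""
        row = self.blocks[block_id].rows.get(gene.genome_id)
        if row is None:
            return np.empty(0, dtype=np.int64)
        lo = max(gene.start, row.start)
        hi = min(gene.end, row.end)
        if lo >= hi:
            return np.empty(0, dtype=np.int64)
        rmap = self._row_maps[(block_id, gene.genome_id)]
        return np.sort(rmap.col_of_off[lo - row.start : hi - row.start])

    def anchor_block(self, gene: GeneAnnotation) -> Optional[str]:
        """The block anchoring a gene for column comparisons.

        The block containing the gene's stop (3') codon base; when the stop
        is unaligned, ties fall to the block with the most covered bases,
        then the lowest block_id.  None for unaligned genes.
        """
        spans = self.gene_column_span(gene)
        if not spans:
            return None
        stop_pos = gene.three_prime_pos()
        for block_id, _cs, _ce, _cov in spans:
            row = self.blocks[block_id].rows[gene.genome_id]
            if row.start <= stop_pos < row.end:
                return block_id
        return sorted(spans, key=lambda s: (-s[3], s[0]))[0][0]


def build_index(
    blocks: list[AlignmentBlock], annotations: list[GeneAnnotation]
) -> AlignmentIndex:
    """Index alignment blocks and gene intervals for fast lookup.

    Empty inputs yield an empty (but queryable) index; genes overlapping no
    block are retained and marked unaligned.
    """
    index = AlignmentIndex()
    for block in blocks:
        index._add_block(block)
    for gene in annotations:
        index._add_gene(gene)
    return index


# Thin functional aliases mirroring the library's public operation names.

def project_to_column(index: AlignmentIndex, genome_id: str, contig_id: str, pos: int):
    return index.project_to_column(genome_id, contig_id, pos)


def project_from_column(index: AlignmentIndex, block_id: str, column: int, genome_id: str):
    return index.project_from_column(block_id, column, genome_id)


def gene_column_span(index: AlignmentIndex, gene: GeneAnnotation):
    return index.gene_column_span(gene)
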