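"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — per-base scans, O(n^2) loops,
Biopython translation — and shares no code with the package's indexed
implementations.
"""

from __future__ import annotations

from Bio.Seq import Seq

from panannot.model import AlignmentBlock, GeneAnnotation, revcomp


def projection_table(block: AlignmentBlock) -> dict[str, dict[int, int]]:
    """Per genome: forward position -> column, by scanning the row text.

    For a '+' row the i-th non-gap character is forward position start+i;
    for a '-' row the text is the reverse complement of the forward slice,
    so the i-th non-gap character is forward position start+size-1-i.
    """
    tables: dict[str, dict[int, int]] = {}
    for genome_id, row in block.rows.items():
        table: dict[int, int] = {}
        i = 0
        for col, ch in enumerate(row.text):
            if ch == "-":
                continue
            if row.strand == "+":
                pos = row.start + i
            else:
                pos = row.start + row.ungapped_len - 1 - i
            table[pos] = col
            i += 1
        tables[genome_id] = table
    return tables


def gene_columns(
    blocks: list[AlignmentBlock], gene: GeneAnnotation
) -> dict[str, set[int]]:
    """Per block: the set of columns holding the gene's bases (naive scan)."""
    out: dict[str, set[int]] = {}
    for block in blocks:
        row = block.rows.get(gene.genome_id)
        if row is None or row.contig_id != gene.contig_id:
            continue
        table = projection_table(block)[gene.genome_id]
        cols = {table[p] for p in range(gene.start, gene.end) if p in table}
        if cols:
            out[block.block_id] = cols
    return out


def greedy_groups(
    genes: list[GeneAnnotation],
    blocks: list[AlignmentBlock],
    cov_query: float = 0.5,
    cov_match: float = 0.5,
) -> list[list[str]]:
    """Naive O(n^2) greedy length-sorted clustering (no interval trees).

    Returns member lists in seeding order; the first member is the query.
    """
    order = sorted(genes, key=lambda g: (-(g.end - g.start), g.genome_id, g.gene_id))
    cols = {g.gene_id: gene_columns(blocks, g) for g in genes}
    assigned: set[str] = set()
    groups: list[list[str]] = []
    for query in order:
        if query.gene_id in assigned:
            continue
        assigned.add(query.gene_id)
        members = [query.gene_id]
        qcols = cols[query.gene_id]
        aligned = sum(len(c) for c in qcols.values())
        if aligned >= cov_query * query.length:
            for cand in order:
                if cand.gene_id in assigned or cand.genome_id == query.genome_id:
                    continue
                overlap = sum(
                    len(qcols.get(b, set()) & c) for b, c in cols[cand.gene_id].items()
                )
                if overlap >= cov_match * cand.length:
                    members.append(cand.gene_id)
                    assigned.add(cand.gene_id)
        groups.append(members)
    return groups


def is_clean_orf(seq: str) -> bool:
    """Strict bacterial ORF check through Biopython's table 11.

    Start codon, terminal stop, and no internal stop in the conceptual
    translation; no frameshift allowance.
    """
    if len(seq) < 6 or len(seq) % 3:
        return False
    if seq[:3] not in ("ATG", "GTG", "TTG"):
        return False
    protein = str(Seq(seq).translate(table=11))
    return protein.endswith("*") and "*" not in protein[:-1]


def repairable_orf(seq: str, n_shifts: int) -> bool:
    """Can removing 1 or 2 bases at any single point make ``seq`` a clean ORF?

    Brute force over every cut position; used to vet frameshift-repaired
    candidates independently of where the implementation placed the shift.
    """
    if n_shifts == 0:
        return is_clean_orf(seq)
    if n_shifts != 1:
        raise NotImplementedError
    for o in range(3, len(seq) - 3):
        for d in (1, 2):
            if is_clean_orf(seq[:o] + seq[o + d :]):
                return True
    return False


def extract(seq: str, start: int, end: int, strand: str) -> str:
    s = seq[start:end]
    return s if strand == "+" else revcomp(s)
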