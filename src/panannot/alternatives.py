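"""Ranked alternative gene structures for ortholog groups.

Every distinct annotated start locus in a group is paired with every
distinct stop locus (same strand, start 5' of stop), and each pair is
checked in every aligned genome: project both columns into the genome,
extract the spanned sequence on the gene strand, and test whether it is a
valid ORF under the configured genetic code — initiator first codon,
terminator last codon, no internal in-frame stop, length divisible by 3.

When a genome fails the plain check and the spanned alignment region shows
an indel signature (gap columns in its own row, or columns where it alone
holds extra bases), a single-frameshift repair is attempted: the reading
frame is allowed to change once near the indel, implemented by skipping one
or two bases at a junction within one codon of the indel.  The minimal
number of shifts that validates is kept, together with the indel column —
this is how a gene split into fragments by a sequencing error or pseudogene
mutation is recognised as one spanning ORF.

Candidates are filtered against the annotated lengths (a candidate shorter
than ``min_len_frac`` of a genome's existing annotation is discarded),
flagged when they would overlap an adjacent gene outside the group, and
ranked by the number of genomes with a valid ORF, then by length.
"""

from __future__ import annotations

import itertools
import logging
from typing import Optional, Sequence

import numpy as np

from .anomalies import MissingAnnotation, locate_gene_termini
from .index import AlignmentIndex
from .model import (
    AlternativeAnnotation,
    CodonConfig,
    ColumnLocus,
    GeneAnnotation,
    GenomeSequence,
    OrfEvaluation,
    OrthologGroup,
    revcomp,
)

logger = logging.getLogger(__name__)

#: candidate frameshift junctions are searched within one codon of the indel
_JUNCTION_WINDOW = 3
#: cap on distinct indel sites tried per evaluation (keeps the search linear)
_MAX_SHIFT_SITES = 8


# ---------------------------------------------------------------------------
# codon-pair enumeration
# ---------------------------------------------------------------------------

def enumerate_codon_pairs(
    group: OrthologGroup, index: AlignmentIndex
) -> list[tuple[ColumnLocus, ColumnLocus, str]]:
    """Distinct (start_locus, stop_locus, strand) pairs observed in a group.

    The Cartesian product of the members' annotated start and stop columns,
    restricted to pairs on the same strand, in the same block, with the
    start 5' of the stop; deduplicated, deterministic order.
    """
    starts: set[tuple[ColumnLocus, str]] = set()
    stops: set[tuple[ColumnLocus, str]] = set()
    for gid in group.members:
        gene = index.annotations[gid]
        try:
            t = locate_gene_termini(index, gene)
        except ValueError:
            continue
        if t.start_locus is not None:
            starts.add((t.start_locus, gene.strand))
        if t.stop_locus is not None:
            stops.add((t.stop_locus, gene.strand))
    pairs = []
    for (s, s_strand), (e, e_strand) in itertools.product(sorted(starts), sorted(stops)):
        if s_strand != e_strand or s.block_id != e.block_id:
            continue
        if (s_strand == "+" and s.column >= e.column) or (
            s_strand == "-" and s.column <= e.column
        ):
            continue  # start must be 5' of stop
        pairs.append((s, e, s_strand))
    return pairs


# ---------------------------------------------------------------------------
# ORF validity
# ---------------------------------------------------------------------------

def _orf_ok(seq: str, cfg: CodonConfig) -> bool:
    n = len(seq)
    if n < 6 or n % 3:
        return False
    if seq[:3] not in cfg.start_codons or seq[-3:] not in cfg.stop_codons:
        return False
    for i in range(3, n - 3, 3):
        if seq[i : i + 3] in cfg.stop_codons:
            return False
    return True


def _shift_sites(index: AlignmentIndex, block_id: str, genome_id: str,
                 col_lo: int, col_hi: int) -> list[tuple[int, int]]:
    """Indel sites in ``[col_lo, col_hi)`` as (first_column, anchored_pos).

    A site is a run of columns where this genome's gap state differs from
    some other row's — either a gap in this row (a deletion here) or a
    column where another row is gapped while this row has a base (an
    insertion here).  Runs of adjacent columns collapse to one site.
    """
    block = index.blocks[block_id]
    rmap = index.row_map(block_id, genome_id)
    own_gaps = rmap.is_gap[col_lo:col_hi]
    other_gaps = np.zeros(col_hi - col_lo, dtype=bool)
    for other_id in block.rows:
        if other_id == genome_id:
            continue
        other_gaps |= index.row_map(block_id, other_id).is_gap[col_lo:col_hi]
    marked = np.flatnonzero(own_gaps | (other_gaps & ~own_gaps))
    sites: list[tuple[int, int]] = []
    prev = None
    for c in marked:
        col = col_lo + int(c)
        if prev is not None and col == prev + 1:
            prev = col
            continue
        anchor = index.project_from_column(block_id, col, genome_id)
        sites.append((col, anchor.pos))
        prev = col
    return sites[:_MAX_SHIFT_SITES]


def _try_frameshifts(
    seq: str,
    offsets: Sequence[tuple[int, int]],  # (column, offset of site within seq)
    cfg: CodonConfig,
) -> Optional[tuple[str, tuple[int, ...]]]:
    """Search for up to ``max_frameshifts`` repairs that validate ``seq``.

    A repair at a site skips 1 or 2 bases at a junction within one codon of
    the site, emulating a +1/-1 reading-frame change at the indel.  Returns
    (repaired_sequence, shift_columns) for the first (fewest-shift,
    deterministic-order) success, else None.
    """
    n = len(seq)

    def junctions(off: int):
        for o in range(max(3, off - _JUNCTION_WINDOW), min(n - 3, off + _JUNCTION_WINDOW + 1)):
            for d in (1, 2):
                yield o, d

    for n_shifts in range(1, cfg.max_frameshifts + 1):
        for combo in itertools.combinations(offsets, n_shifts):
            for choice in itertools.product(*(junctions(off) for _col, off in combo)):
                cuts = sorted(zip((c for c, _o in combo), choice), key=lambda x: x[1][0])
                repaired = []
                pos = 0
                ok = True
                for _col, (o, d) in cuts:
                    if o < pos:
                        ok = False
                        break
                    repaired.append(seq[pos:o])
                    pos = o + d
                if not ok or pos > n:
                    continue
                repaired.append(seq[pos:])
                cand = "".join(repaired)
                if _orf_ok(cand, cfg):
                    return cand, tuple(c for c, _ in cuts)
    return None


def evaluate_orf(
    pair: tuple[ColumnLocus, ColumnLocus, str],
    genome_id: str,
    index: AlignmentIndex,
    genome: GenomeSequence,
    cfg: CodonConfig,
) -> OrfEvaluation:
    """Check one candidate start/stop column pair in one genome."""
    start_locus, stop_locus, strand = pair
    block_id = start_locus.block_id
    block = index.blocks[block_id]
    if genome_id not in block.rows:
        return OrfEvaluation(genome_id=genome_id, present=False, reason="absent")
    row = block.rows[genome_id]
    p5 = index.project_from_column(block_id, start_locus.column, genome_id)
    p3 = index.project_from_column(block_id, stop_locus.column, genome_id)
    if p5.pos < 0 or p3.pos < 0:
        return OrfEvaluation(
            genome_id=genome_id, present=True, contig_id=row.contig_id,
            strand=strand, reason="unprojectable",
        )
    lo, hi = (p5.pos, p3.pos + 1) if strand == "+" else (p3.pos, p5.pos + 1)
    contig_seq = genome.contigs[row.contig_id]
    if lo < 0 or hi > len(contig_seq) or hi - lo < 6:
        return OrfEvaluation(
            genome_id=genome_id, present=True, contig_id=row.contig_id,
            start=max(lo, 0), end=min(hi, len(contig_seq)), strand=strand,
            reason="unprojectable",
        )
    seq = contig_seq[lo:hi]
    if strand == "-":
        seq = revcomp(seq)
    ev = OrfEvaluation(
        genome_id=genome_id, present=True, contig_id=row.contig_id,
        start=lo, end=hi, strand=strand,
    )
    if _orf_ok(seq, cfg):
        ev.orf_valid = True
        return ev
    if cfg.max_frameshifts > 0:
        col_lo = min(start_locus.column, stop_locus.column)
        col_hi = max(start_locus.column, stop_locus.column) + 1
        sites = _shift_sites(index, block_id, genome_id, col_lo, col_hi)
        offsets = []
        for col, anchor_pos in sites:
            if anchor_pos < lo or anchor_pos >= hi:
                continue
            off = (anchor_pos - lo) if strand == "+" else (hi - 1 - anchor_pos)
            offsets.append((col, off))
        if offsets:
            repaired = _try_frameshifts(seq, offsets, cfg)
            if repaired is not None:
                _, shift_cols = repaired
                ev.orf_valid = True
                ev.n_frameshifts = len(shift_cols)
                ev.frameshift_columns = shift_cols
                return ev
    ev.reason = "invalid_orf"
    return ev


# ---------------------------------------------------------------------------
# overlap flag, ranking, missing-gene suggestions
# ---------------------------------------------------------------------------

def flag_overlaps(
    candidate: AlternativeAnnotation,
    index: AlignmentIndex,
    group: OrthologGroup,
) -> bool:
    """True when the candidate would overlap an annotated gene outside the group."""
    members = set(group.members)
    for ev in candidate.evaluations.values():
        if not ev.present or ev.start is None or ev.end is None:
            continue
        for gid in index.genes_at(ev.genome_id, ev.contig_id, ev.start, ev.end):
            if gid not in members:
                return True
    return False


def _tis_direction(
    candidate: AlternativeAnnotation, group: OrthologGroup, index: AlignmentIndex
) -> Optional[str]:
    """Is the candidate TIS upstream or downstream of the query's annotation?"""
    query = index.annotations[group.query_gene]
    ev = candidate.evaluations.get(query.genome_id)
    if ev is None or ev.start is None:
        return None
    cand_5p = ev.start if candidate.strand == "+" else ev.end - 1
    ann_5p = query.five_prime_pos()
    if cand_5p == ann_5p:
        return "same"
    upstream = cand_5p < ann_5p if candidate.strand == "+" else cand_5p > ann_5p
    return "upstream" if upstream else "downstream"


def rank_alternatives(
    group: OrthologGroup,
    index: AlignmentIndex,
    genomes: dict[str, GenomeSequence],
    cfg: CodonConfig = CodonConfig(),
    min_len_frac: float = 0.5,
    sort_order: str = "valid_orfs,length",
) -> list[AlternativeAnnotation]:
    """Enumerate, evaluate, filter and rank a group's candidate structures.

    Candidates shorter than ``min_len_frac`` of a genome's annotated length
    (in any genome that has an annotated member) are dropped.  The sort is
    (n_valid_orfs desc, length desc) by default, or length-first with
    ``sort_order="length,valid_orfs"``; ties break on ascending
    (start_locus, stop_locus).
    """
    member_len: dict[str, int] = {}
    for gid in group.members:
        a = index.annotations[gid]
        member_len[a.genome_id] = max(member_len.get(a.genome_id, 0), a.length)
    query_genome = index.annotations[group.query_gene].genome_id

    candidates: list[AlternativeAnnotation] = []
    for pair in enumerate_codon_pairs(group, index):
        start_locus, stop_locus, strand = pair
        block = index.blocks[start_locus.block_id]
        evals = {
            genome_id: evaluate_orf(pair, genome_id, index, genomes[genome_id], cfg)
            for genome_id in sorted(block.rows)
            if genome_id in genomes
        }
        qev = evals.get(query_genome)
        length = qev.length if qev is not None and qev.length is not None else 0
        too_short = False
        for genome_id, ann_len in member_len.items():
            ev = evals.get(genome_id)
            if ev is None or ev.length is None:
                continue
            if ev.length < min_len_frac * ann_len:
                too_short = True
                break
        if too_short:
            continue
        cand = AlternativeAnnotation(
            group_id=group.group_id,
            start_locus=start_locus,
            stop_locus=stop_locus,
            strand=strand,
            evaluations=evals,
            n_valid_orfs=sum(1 for ev in evals.values() if ev.orf_valid),
            length=length,
        )
        cand.overlap_flag = flag_overlaps(cand, index, group)
        cand.tis_direction = _tis_direction(cand, group, index)
        candidates.append(cand)

    if sort_order == "length,valid_orfs":
        key = lambda c: (-c.length, -c.n_valid_orfs, c.start_locus, c.stop_locus)
    else:
        key = lambda c: (-c.n_valid_orfs, -c.length, c.start_locus, c.stop_locus)
    candidates.sort(key=key)
    for i, cand in enumerate(candidates, 1):
        cand.rank = i
    return candidates


def suggest_missing_genes(
    missing: list[MissingAnnotation],
    ranked: dict[str, list[AlternativeAnnotation]],
    index: AlignmentIndex,
    genomes: dict[str, GenomeSequence],
    cfg: CodonConfig = CodonConfig(),
) -> list[AlternativeAnnotation]:
    """Propose gene structures in genomes lacking any annotation for a group.

    For each missing-annotation record, the group's best-ranked codon pair
    is evaluated in the unannotated genome; a suggestion is emitted only
    when it forms a valid ORF there.
    """
    out: list[AlternativeAnnotation] = []
    for rec in missing:
        alts = ranked.get(rec.group_id)
        if not alts:
            continue
        best = alts[0]
        pair = (best.start_locus, best.stop_locus, best.strand)
        ev = evaluate_orf(pair, rec.genome_id, index, genomes[rec.genome_id], cfg)
        if not ev.orf_valid:
            continue
        out.append(
            AlternativeAnnotation(
                group_id=rec.group_id,
                start_locus=best.start_locus,
                stop_locus=best.stop_locus,
                strand=best.strand,
                evaluations={rec.genome_id: ev},
                n_valid_orfs=1,
                length=ev.length or 0,
                rank=1,
            )
        )
    return out
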