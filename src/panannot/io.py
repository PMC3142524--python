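"""Readers and writers for the external formats.

FASTA and GenBank go through Biopython; MAF is read with ``Bio.AlignIO`` and
written directly (the format is line-oriented and the writer must preserve
reverse-strand offsets exactly).  GFF3 CDS rows are parsed with a small
dedicated reader: only seqid/type/start/end/strand and the ID/Parent/partial
attributes are consumed, so a full GFF toolkit is not required.

MAF dialect: the ``src`` field of every ``s`` line is ``genomeId.contigId``,
split on the FIRST dot.  Reverse-strand rows carry offsets counted from the
start of the reverse complement, as per the MAF definition; they are
converted here to forward-strand leftmost offsets
(``fwd_start = srcSize - start - size``) so that everything downstream is
strand-free.  Blocks with more than one row for a genome are skipped with a
warning: positional orthology is only defined for one segment per genome.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

from .model import (
    AlignmentBlock,
    AlignmentRow,
    AlternativeAnnotation,
    AnomalyReport,
    GeneAnnotation,
    GenomeSequence,
    OrthologGroup,
)

logger = logging.getLogger(__name__)

MISSING_CELL = "."


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str, genome_id: Optional[str] = None) -> GenomeSequence:
    """Read a genome FASTA.

    The first whitespace-delimited token of each header is the contig id.
    Sequences are uppercased.  Duplicate contig ids and empty records are
    hard errors.  ``genome_id`` defaults to the file's basename stem.
    """
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(path))[0]
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        cid = rec.id
        if cid in contigs:
            raise ValueError(f"{path}: duplicate contig id {cid!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty record {cid!r}")
        contigs[cid] = seq
    if not contigs:
        raise ValueError(f"{path}: no FASTA records")
    return GenomeSequence(genome_id=genome_id, contigs=contigs)


def write_fasta(genome: GenomeSequence, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col9.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str, genome_id: str) -> list[GeneAnnotation]:
    """Read CDS features from a GFF3 file.

    GFF3 1-based inclusive coordinates become 0-based half-open.  Only rows
    of type ``CDS`` are kept; each needs an ``ID`` (or ``Parent``) attribute.
    A ``partial=5``, ``partial=3`` or ``partial=5,3`` attribute marks genes
    truncated by a contig boundary.  Two CDS rows sharing an ID would denote
    a spliced structure, which is not supported and rejected.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, col9 = fields
            if ftype != "CDS":
                continue
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: CDS end {end1} < start {start1}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_gff_attributes(col9)
            gene_id = attrs.get("ID") or attrs.get("Parent")
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: CDS without ID or Parent attribute")
            if gene_id in seen:
                raise ValueError(
                    f"{path}:{lineno}: multiple CDS rows for {gene_id!r} "
                    "(spliced gene structures are not supported)"
                )
            seen.add(gene_id)
            partial = attrs.get("partial", "")
            parts = set(partial.split(",")) if partial else set()
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=seqid,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    partial5="5" in parts,
                    partial3="3" in parts,
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneAnnotation], path: str) -> None:
    """Write CDS annotations (internal 0-based half-open -> GFF3 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            parts = []
            if g.partial5:
                parts.append("5")
            if g.partial3:
                parts.append("3")
            attrs = f"ID={g.gene_id}"
            if parts:
                attrs += f";partial={','.join(parts)}"
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "panannot",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GenBank (optional convenience)
# ---------------------------------------------------------------------------

def read_genbank(path: str, genome_id: str) -> tuple[GenomeSequence, list[GeneAnnotation]]:
    """Read sequence and CDS features from a GenBank flat file.

    Spliced (multi-interval) CDS features are rejected: the method only
    handles unspliced prokaryotic gene structures.
    """
    contigs: dict[str, str] = {}
    genes: list[GeneAnnotation] = []
    n = 0
    for rec in SeqIO.parse(path, "genbank"):
        if rec.id in contigs:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if len(feat.location.parts) != 1:
                raise ValueError(
                    f"{path}: spliced CDS in {rec.id} not supported"
                )
            n += 1
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("protein_id", [None])[0]
                or f"{rec.id}_cds{n}"
            )
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand >= 0 else "-",
                )
            )
    return GenomeSequence(genome_id=genome_id, contigs=contigs), genes


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def _split_src(src: str) -> tuple[str, str]:
    if "." not in src:
        raise ValueError(f"MAF src {src!r} lacks a '.' separating genome and contig")
    genome_id, contig_id = src.split(".", 1)
    return genome_id, contig_id


def read_maf(path: str) -> list[AlignmentBlock]:
    """Read MAF alignment blocks.

    Reverse-strand row starts are converted to forward-strand leftmost
    offsets; row text is stored as read.  A block with two rows for one
    genome is skipped with a warning rather than failing the run.
    """
    blocks: list[AlignmentBlock] = []
    for i, aln in enumerate(AlignIO.parse(path, "maf")):
        block_id = f"block{i}"
        rows: dict[str, AlignmentRow] = {}
        duplicated = False
        for rec in aln:
            genome_id, contig_id = _split_src(rec.id)
            ann = rec.annotations
            start, size = int(ann["start"]), int(ann["size"])
            strand = "+" if int(ann["strand"]) >= 0 else "-"
            src_size = int(ann["srcSize"])
            text = str(rec.seq).upper()
            nongap = len(text) - text.count("-")
            if nongap != size:
                raise ValueError(
                    f"{path}: block {block_id} row {rec.id}: size={size} but "
                    f"{nongap} non-gap characters"
                )
            fwd_start = start if strand == "+" else src_size - start - size
            if genome_id in rows:
                duplicated = True
                logger.warning(
                    "MAF block %s has multiple rows for genome %s; block skipped",
                    block_id,
                    genome_id,
                )
                break
            rows[genome_id] = AlignmentRow(
                contig_id=contig_id,
                start=fwd_start,
                ungapped_len=size,
                strand=strand,
                contig_len=src_size,
                text=text,
            )
        if duplicated:
            continue
        blocks.append(AlignmentBlock(block_id=block_id, rows=rows))
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], path: str) -> None:
    """Write blocks in MAF, restoring reverse-strand offset convention."""
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for block in blocks:
            fh.write("\na score=0\n")
            for genome_id, row in block.rows.items():
                maf_start = (
                    row.start
                    if row.strand == "+"
                    else row.contig_len - row.start - row.ungapped_len
                )
                fh.write(
                    f"s {genome_id}.{row.contig_id} {maf_start} "
                    f"{row.ungapped_len} {row.strand} {row.contig_len} {row.text}\n"
                )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None or value == "" or value == set() or value == ():
        return MISSING_CELL
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, (set, frozenset, list, tuple)):
        return ",".join(str(v) for v in sorted(value)) if value else MISSING_CELL
    return str(value)


def write_reports(
    groups: Sequence[OrthologGroup],
    anomalies: Sequence[AnomalyReport],
    alternatives: Sequence[AlternativeAnnotation],
    outdir: str,
    *,
    annotations: Optional[dict[str, GeneAnnotation]] = None,
    missing: Optional[Sequence] = None,
    inconsistency_counts: Optional[dict[str, int]] = None,
    index=None,
    alignment_dumps: bool = True,
) -> None:
    """Write the TSV reports (and per-group alignment dumps) to ``outdir``.

    Always writes groups.tsv, anomalies.tsv and alternatives.tsv (header-only
    when empty); missing.tsv and inconsistency.tsv are written when the
    corresponding inputs are given.  Empty cells are '.'.
    """
    os.makedirs(outdir, exist_ok=True)
    annotations = annotations or {}

    group_rows = []
    for grp in groups:
        for gid in grp.members:
            genome = annotations[gid].genome_id if gid in annotations else None
            group_rows.append(
                {
                    "group_id": grp.group_id,
                    "gene_id": gid,
                    "genome_id": _fmt(genome),
                    "is_query": _fmt(gid == grp.query_gene),
                }
            )
    pd.DataFrame(group_rows, columns=["group_id", "gene_id", "genome_id", "is_query"]).to_csv(
        os.path.join(outdir, "groups.tsv"), sep="\t", index=False
    )

    anomaly_rows = []
    for rep in anomalies:
        anomaly_rows.append(
            {
                "group_id": rep.group_id,
                "class": rep.klass,
                "secondary_classes": _fmt(rep.secondary_classes),
                "n_genomes": rep.n_genomes,
                "inconsistent_genomes": _fmt(
                    {rep.sole_outlier_genome} if rep.sole_outlier_genome else set()
                ),
                "contig_boundary_flag": _fmt(rep.contig_boundary),
                "block_split": _fmt(rep.block_split),
            }
        )
    pd.DataFrame(
        anomaly_rows,
        columns=[
            "group_id",
            "class",
            "secondary_classes",
            "n_genomes",
            "inconsistent_genomes",
            "contig_boundary_flag",
            "block_split",
        ],
    ).to_csv(os.path.join(outdir, "anomalies.tsv"), sep="\t", index=False)

    alt_rows = []
    for alt in alternatives:
        coords = []
        for genome_id in sorted(alt.evaluations):
            ev = alt.evaluations[genome_id]
            if ev.present and ev.start is not None:
                coords.append(
                    f"{genome_id}:{ev.contig_id}:{ev.start}-{ev.end}({ev.strand})"
                    f"{'*' if ev.orf_valid else ''}"
                )
        alt_rows.append(
            {
                "group_id": alt.group_id,
                "rank": alt.rank,
                "start_col": f"{alt.start_locus.block_id}:{alt.start_locus.column}",
                "stop_col": f"{alt.stop_locus.block_id}:{alt.stop_locus.column}",
                "n_valid_orfs": alt.n_valid_orfs,
                "length": alt.length,
                "per_genome_coords": _fmt(";".join(coords)),
                "overlap_flag": _fmt(alt.overlap_flag),
                "n_frameshifts": sum(
                    ev.n_frameshifts for ev in alt.evaluations.values() if ev.orf_valid
                ),
                "tis_direction": _fmt(alt.tis_direction),
            }
        )
    pd.DataFrame(
        alt_rows,
        columns=[
            "group_id",
            "rank",
            "start_col",
            "stop_col",
            "n_valid_orfs",
            "length",
            "per_genome_coords",
            "overlap_flag",
            "n_frameshifts",
            "tis_direction",
        ],
    ).to_csv(os.path.join(outdir, "alternatives.tsv"), sep="\t", index=False)

    if missing is not None:
        miss_rows = [
            {
                "group_id": m.group_id,
                "genome_id": m.genome_id,
                "contig_id": m.contig_id,
                "start": m.start,
                "end": m.end,
            }
            for m in missing
        ]
        pd.DataFrame(
            miss_rows, columns=["group_id", "genome_id", "contig_id", "start", "end"]
        ).to_csv(os.path.join(outdir, "missing.tsv"), sep="\t", index=False)

    if inconsistency_counts is not None:
        pd.DataFrame(
            [{"genome_id": g, "n_sole_outlier_groups": c} for g, c in sorted(inconsistency_counts.items())],
            columns=["genome_id", "n_sole_outlier_groups"],
        ).to_csv(os.path.join(outdir, "inconsistency.tsv"), sep="\t", index=False)

    if alignment_dumps and index is not None:
        _write_alignment_dumps(groups, anomalies, annotations, index, outdir)


def _write_alignment_dumps(groups, anomalies, annotations, index, outdir, pad: int = 9):
    """Plain-text gapped alignment views for the anomalous groups.

    One file per inconsistent group, showing the group's column span with
    annotated start (``[``) and stop (``]``) columns marked above each row.
    """
    dump_dir = os.path.join(outdir, "alignments")
    os.makedirs(dump_dir, exist_ok=True)
    by_id = {rep.group_id: rep for rep in anomalies}
    for grp in groups:
        rep = by_id.get(grp.group_id)
        if rep is None or rep.klass in ("consistent", "singleton"):
            continue
        spans = []
        for gid in grp.members:
            for bid, cs, ce, _cov in index.gene_column_span(annotations[gid]):
                spans.append((bid, cs, ce))
        if not spans:
            continue
        # dump the span in the block that holds the most member termini
        block_id = max({s[0] for s in spans}, key=lambda b: sum(1 for s in spans if s[0] == b))
        cs = max(0, min(s[1] for s in spans if s[0] == block_id) - pad)
        block = index.blocks[block_id]
        ce = min(block.width, max(s[2] for s in spans if s[0] == block_id) + pad)
        with open(os.path.join(dump_dir, f"{grp.group_id}.txt"), "w") as fh:
            fh.write(f"# group {grp.group_id} class {rep.klass} ")
            fh.write(f"block {block_id} columns [{cs},{ce})\n")
            for genome_id in sorted(block.rows):
                row = block.rows[genome_id]
                marks = [" "] * (ce - cs)
                for gid in grp.members:
                    if annotations[gid].genome_id != genome_id:
                        continue
                    t = rep.termini.get(gid)
                    if t is None:
                        continue
                    for locus, ch in ((t.start_locus, "["), (t.stop_locus, "]")):
                        if locus and locus.block_id == block_id and cs <= locus.column < ce:
                            marks[locus.column - cs] = ch
                fh.write(" " * 12 + "".join(marks) + "\n")
                fh.write(f"{genome_id:<11} {row.text[cs:ce]}\n")
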