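"""End-to-end annotation comparison run.

Reads genomes, annotations and the whole-genome multiple alignment,
cross-validates the alignment against the sequences, builds the index,
groups orthologs, classifies anomalies, finds missing annotations, ranks
alternative structures, and writes the reports.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import io as pio
from .alternatives import rank_alternatives, suggest_missing_genes
from .anomalies import (
    classify_group,
    find_missing_annotations,
    flag_contig_boundary,
)
from .grouping import group_orthologs, per_genome_inconsistency_counts
from .index import build_index
from .model import (
    AlignmentBlock,
    CodonConfig,
    GeneAnnotation,
    GenomeSequence,
    revcomp,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and thresholds for one annotation-comparison run."""

    fasta_paths: list[str]
    gff3_paths: list[str]
    maf_path: str
    outdir: str
    cov_query: float = 0.5
    cov_match: float = 0.5
    min_len_frac: float = 0.5
    codon_config: CodonConfig = field(default_factory=CodonConfig)
    boundary_window: int = 10
    min_block_genome_frac: float = 0.9
    sort_order: str = "valid_orfs,length"
    alignment_dumps: bool = True

    def __post_init__(self) -> None:
        for frac in (self.cov_query, self.cov_match, self.min_len_frac,
                     self.min_block_genome_frac):
            if not 0 <= frac <= 1:
                raise ValueError(f"threshold {frac} outside [0, 1]")


@dataclass
class RunSummary:
    """Stage counts reported by :func:`run_annotate`."""

    n_genes: int = 0
    n_groups: int = 0
    n_singletons: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)
    fraction_consistent: float = 0.0  # over non-singleton groups
    n_missing: int = 0
    n_suggestions: int = 0
    inconsistency_counts: dict[str, int] = field(default_factory=dict)

    def format(self) -> str:
        lines = [
            f"genes                 {self.n_genes}",
            f"ortholog groups       {self.n_groups}",
            f"  singletons          {self.n_singletons}",
        ]
        for klass in sorted(self.class_counts):
            lines.append(f"  {klass:<19} {self.class_counts[klass]}")
        lines.append(f"fraction consistent   {self.fraction_consistent:.3f}")
        lines.append(f"missing annotations   {self.n_missing}")
        lines.append(f"suggested edits       {self.n_suggestions}")
        return "\n".join(lines)


def validate_alignment(
    blocks: list[AlignmentBlock], genomes: dict[str, GenomeSequence]
) -> None:
    """Every non-gap block character must equal the FASTA base.

    Reverse-strand rows are compared after strand normalisation.  Any
    mismatch is fatal: every downstream codon decision reads the FASTA
    through alignment coordinates.
    """
    for block in blocks:
        for genome_id, row in block.rows.items():
            genome = genomes.get(genome_id)
            if genome is None:
                continue
            contig = genome.contigs.get(row.contig_id)
            if contig is None:
                raise ValueError(
                    f"block {block.block_id}: contig {row.contig_id!r} of "
                    f"{genome_id} not in FASTA"
                )
            if row.contig_len != len(contig):
                raise ValueError(
                    f"block {block.block_id} row {genome_id}.{row.contig_id}: "
                    f"srcSize {row.contig_len} != contig length {len(contig)}"
                )
            expect = contig[row.start : row.end]
            got = row.forward_text()
            if expect != got:
                offset = next(
                    i for i, (a, b) in enumerate(zip(expect, got)) if a != b
                )
                raise ValueError(
                    f"MAF/FASTA mismatch in block {block.block_id}, row "
                    f"{genome_id}.{row.contig_id}, forward offset "
                    f"{row.start + offset}"
                )


def run_annotate(config: RunConfig) -> RunSummary:
    """Execute the full comparison and write reports to ``config.outdir``.

    Raises on hard errors (unreadable inputs, MAF/FASTA disagreement,
    missing annotation file for an aligned genome); genomes annotated but
    absent from the alignment are dropped with a warning.
    """
    genomes: dict[str, GenomeSequence] = {}
    for path in config.fasta_paths:
        g = pio.read_fasta(path)
        genomes[g.genome_id] = g
    annotations: list[GeneAnnotation] = []
    gff_genomes = set()
    for path in config.gff3_paths:
        genome_id = os.path.splitext(os.path.basename(path))[0]
        gff_genomes.add(genome_id)
        annotations.extend(pio.read_gff3(path, genome_id))

    blocks = pio.read_maf(config.maf_path)
    maf_genomes = {g for b in blocks for g in b.rows}
    for genome_id in sorted(maf_genomes):
        if genome_id not in genomes:
            raise ValueError(f"genome {genome_id!r} in MAF but no FASTA given")
        if genome_id not in gff_genomes:
            raise ValueError(f"genome {genome_id!r} in MAF but no GFF3 given")
    dropped = {a.genome_id for a in annotations} - maf_genomes
    if dropped and blocks:
        logger.warning(
            "genomes %s annotated but absent from the alignment; excluded",
            ",".join(sorted(dropped)),
        )
        annotations = [a for a in annotations if a.genome_id in maf_genomes]

    validate_alignment(blocks, genomes)

    index = build_index(blocks, annotations)
    logger.info("indexed %d blocks, %d genes", len(blocks), len(annotations))

    groups = group_orthologs(
        annotations, index, cov_query=config.cov_query, cov_match=config.cov_match
    )
    logger.info("built %d ortholog groups", len(groups))

    reports = []
    for grp in groups:
        rep = classify_group(grp, index)
        flag_contig_boundary(rep, grp, index, genomes, window=config.boundary_window)
        reports.append(rep)

    missing = find_missing_annotations(
        groups, index, min_block_genome_frac=config.min_block_genome_frac
    )
    for rec in missing:
        for rep in reports:
            if rep.group_id == rec.group_id:
                rep.missing_in.add(rec.genome_id)

    alternatives = []
    ranked_by_group = {}
    for grp in groups:
        if grp.is_singleton:
            continue
        alts = rank_alternatives(
            grp,
            index,
            genomes,
            cfg=config.codon_config,
            min_len_frac=config.min_len_frac,
            sort_order=config.sort_order,
        )
        ranked_by_group[grp.group_id] = alts
        alternatives.extend(alts)
    suggestions = suggest_missing_genes(
        missing, ranked_by_group, index, genomes, cfg=config.codon_config
    )

    counts = per_genome_inconsistency_counts(groups, reports)
    for genome_id in sorted(maf_genomes):
        counts.setdefault(genome_id, 0)

    pio.write_reports(
        groups,
        reports,
        alternatives,
        config.outdir,
        annotations=index.annotations,
        missing=missing,
        inconsistency_counts=counts,
        index=index,
        alignment_dumps=config.alignment_dumps,
    )

    class_counts: dict[str, int] = {}
    for rep in reports:
        class_counts[rep.klass] = class_counts.get(rep.klass, 0) + 1
    n_singletons = class_counts.pop("singleton", 0)
    n_nonsingleton = len(groups) - n_singletons
    summary = RunSummary(
        n_genes=len(annotations),
        n_groups=len(groups),
        n_singletons=n_singletons,
        class_counts=class_counts,
        fraction_consistent=(
            class_counts.get("consistent", 0) / n_nonsingleton if n_nonsingleton else 0.0
        ),
        n_missing=len(missing),
        n_suggestions=len(suggestions),
        inconsistency_counts=counts,
    )
    with open(os.path.join(config.outdir, "summary.txt"), "w") as fh:
        fh.write(summary.format() + "\n")
    logger.info("summary:\n%s", summary.format())
    return summary
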