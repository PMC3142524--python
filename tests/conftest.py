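import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from panannot.model import AlignmentBlock, AlignmentRow, GeneAnnotation, GenomeSequence, revcomp


@pytest.fixture
def toy_block():
    """One block, one '+' row 'AC-GT' over positions [10, 14) of a 100 bp contig."""
    return AlignmentBlock(
        block_id="b0",
        rows={
            "g1": AlignmentRow(
                contig_id="c1", start=10, ungapped_len=4, strand="+",
                contig_len=100, text="AC-GT",
            )
        },
    )


def make_block(block_id, rows):
    """rows: list of (genome_id, contig_id, start, strand, contig_len, text)."""
    return AlignmentBlock(
        block_id=block_id,
        rows={
            g: AlignmentRow(
                contig_id=c, start=s,
                ungapped_len=len(t) - t.count("-"),
                strand=st, contig_len=L, text=t,
            )
            for g, c, s, st, L, t in rows
        },
    )


def random_block(rng: np.random.Generator, n_genomes=3, width=60, gap_frac=0.15,
                 minus=False, block_id="b0"):
    """A consistent random block with genomes carrying matching contigs."""
    rows = {}
    for i in range(n_genomes):
        gid = f"g{i + 1}"
        gaps = rng.random(width) < gap_frac
        size = int(width - gaps.sum())
        if size == 0:
            gaps[0] = False
            size = 1
        bases = rng.choice(list("ACGT"), size=size)
        text = []
        it = iter(bases)
        for g in gaps:
            text.append("-" if g else str(next(it)))
        text = "".join(text)
        strand = "-" if (minus and i % 2) else "+"
        contig_len = size + 20
        start = 7
        rows[gid] = AlignmentRow(
            contig_id="c1", start=start, ungapped_len=size, strand=strand,
            contig_len=contig_len, text=text,
        )
    return AlignmentBlock(block_id=block_id, rows=rows)


def genomes_for_block(block, seed=0):
    """GenomeSequence objects whose contigs agree with the block's rows."""
    rng = np.random.default_rng(seed)
    out = {}
    for genome_id, row in block.rows.items():
        forward = row.forward_text()
        left = "".join(rng.choice(list("ACGT"), size=row.start))
        right = "".join(
            rng.choice(list("ACGT"), size=row.contig_len - row.start - row.ungapped_len)
        )
        out[genome_id] = GenomeSequence(genome_id, {row.contig_id: left + forward + right})
    return out


@pytest.fixture
def small_sim():
    """A 3-genome, 12-gene pan-genome with one planted anomaly of each kind."""
    from panannot.simulate import SimConfig, simulate

    cfg = SimConfig(
        n_genomes=3, genome_len=20000, n_genes=12, seed=1,
        tis_shift=2, gene_split_indel=1, deleted_annotation=1,
    )
    return simulate(cfg)


def sim_inputs(result):
    """(genomes, annotations, blocks) for direct in-memory analysis."""
    genomes = {iso.genome_id: iso.genome for iso in result.isolates}
    annotations = [a for iso in result.isolates for a in iso.annotations]
    return genomes, annotations, result.blocks
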