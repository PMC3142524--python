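"""Core domain types.

All genomic coordinates are 0-based, half-open, on the forward strand.
Conversion to and from external conventions (1-based GFF3, reverse-strand
MAF offsets) happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A genome: an ordered collection of contigs with uppercase DNA."""

    genome_id: str
    contigs: dict[str, str]  # contig_id -> sequence, insertion-ordered

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"empty contig {cid!r} in genome {self.genome_id!r}")

    def contig_len(self, contig_id: str) -> int:
        return len(self.contigs[contig_id])


@dataclass(frozen=True)
class GeneAnnotation:
    """A CDS interval.

    ``partial5``/``partial3`` mark genes whose start/stop codon falls outside
    a contig boundary (draft assemblies); they may only be set when the
    corresponding gene boundary abuts a contig end.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    partial5: bool = False
    partial3: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime_pos(self) -> int:
        """Forward-strand offset of the biological 5' (first) base."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime_pos(self) -> int:
        """Forward-strand offset of the biological 3' (last) base."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class AlignmentRow:
    """One genome's segment in an alignment block.

    ``start`` is always the forward-strand offset of the leftmost aligned
    base, regardless of strand (reverse-strand MAF offsets are normalised at
    read time).  ``text`` is stored exactly as read: for a '-' row it is the
    reverse complement of the forward-strand slice.
    """

    contig_id: str
    start: int
    ungapped_len: int
    strand: str
    contig_len: int
    text: str

    def __post_init__(self) -> None:
        nongap = len(self.text) - self.text.count("-")
        if nongap != self.ungapped_len:
            raise ValueError(
                f"row {self.contig_id}: {nongap} non-gap characters but "
                f"ungapped_len={self.ungapped_len}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + self.ungapped_len

    def forward_text(self) -> str:
        """The row text in forward-strand orientation (gaps removed)."""
        s = self.text.replace("-", "")
        return s if self.strand == "+" else revcomp(s)


@dataclass
class AlignmentBlock:
    """One alignment block: equal-width gapped rows, at most one per genome."""

    block_id: str
    rows: dict[str, AlignmentRow]  # genome_id -> row

    def __post_init__(self) -> None:
        widths = {len(r.text) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValueError(f"block {self.block_id}: unequal row widths {widths}")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())).text) if self.rows else 0


class ColumnLocus(NamedTuple):
    """An alignment column: the coordinate system for 'same location' tests."""

    block_id: str
    column: int


@dataclass
class OrthologGroup:
    """Genes joined by aligned genomic position.

    The query gene seeded the group and is at least as long as every member;
    a genome may contribute several members (gene fragments).
    """

    group_id: str
    query_gene: str
    members: list[str]  # gene_ids, query included

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    def genome_counts(self, annotations: dict[str, GeneAnnotation]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for gid in self.members:
            g = annotations[gid].genome_id
            counts[g] = counts.get(g, 0) + 1
        return counts

    def genomes_present(self, annotations: dict[str, GeneAnnotation]) -> set[str]:
        return {annotations[gid].genome_id for gid in self.members}


#: Primary consistency classes a non-singleton group may receive.
ANOMALY_CLASSES = (
    "consistent",
    "inconsistent_starts",
    "inconsistent_stops",
    "combination",
    "fragmentation",
)


@dataclass
class GeneTermini:
    """Alignment columns of a gene's start (5') and stop (3') codon bases."""

    gene_id: str
    start_locus: Optional[ColumnLocus]
    stop_locus: Optional[ColumnLocus]
    start_reason: Optional[str] = None  # why start_locus is None
    stop_reason: Optional[str] = None


@dataclass
class AnomalyReport:
    """Consistency classification of one ortholog group."""

    group_id: str
    klass: str  # one of ANOMALY_CLASSES, or "singleton"
    secondary_classes: set[str] = field(default_factory=set)
    termini: dict[str, GeneTermini] = field(default_factory=dict)  # gene_id -> termini
    sole_outlier_genome: Optional[str] = None
    contig_boundary: bool = False
    block_split: bool = False
    missing_in: set[str] = field(default_factory=set)
    n_genomes: int = 0


@dataclass
class CodonConfig:
    """Genetic-code symbols used for ORF validation.

    Defaults follow the bacterial/archaeal code (NCBI table 11) with the
    initiator set restricted to the codons prokaryotic annotation pipelines
    actually emit; the full table additionally admits rare initiators
    (CTG, ATT, ATC, ATA), which can be enabled here.
    """

    start_codons: frozenset[str] = frozenset({"ATG", "GTG", "TTG"})
    stop_codons: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})
    max_frameshifts: int = 1

    def __post_init__(self) -> None:
        for c in self.start_codons | self.stop_codons:
            if len(c) != 3 or set(c) - set("ACGT"):
                raise ValueError(f"invalid codon {c!r}")
        if self.start_codons & self.stop_codons:
            raise ValueError("start and stop codon sets must be disjoint")
        if not 0 <= self.max_frameshifts <= 2:
            raise ValueError("max_frameshifts must be 0, 1 or 2")


@dataclass
class OrfEvaluation:
    """Outcome of checking one candidate start/stop pair in one genome."""

    genome_id: str
    present: bool  # genome has a row in the pair's block
    contig_id: Optional[str] = None
    start: Optional[int] = None  # forward-strand half-open interval
    end: Optional[int] = None
    strand: Optional[str] = None
    orf_valid: bool = False
    n_frameshifts: int = 0
    frameshift_columns: tuple[int, ...] = ()
    reason: Optional[str] = None  # why invalid

    @property
    def length(self) -> Optional[int]:
        if self.start is None or self.end is None:
            return None
        return self.end - self.start


@dataclass
class AlternativeAnnotation:
    """A ranked candidate gene structure for an ortholog group."""

    group_id: str
    start_locus: ColumnLocus
    stop_locus: ColumnLocus
    strand: str
    evaluations: dict[str, OrfEvaluation]
    n_valid_orfs: int
    length: int  # ungapped span in the query genome
    overlap_flag: bool = False
    rank: int = 0
    tis_direction: Optional[str] = None  # upstream/downstream/same vs annotation
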