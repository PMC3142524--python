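"""Ground-truthed synthetic bacterial pan-genomes.

The generator emulates the setting the annotation checker is built for: a
set of closely related isolates descended from one ancestor, each carrying
its own annotation, some of it deliberately wrong.  An ancestral genome is
packed with non-overlapping valid ORFs on both strands; isolates accumulate
substitutions and small intergenic indels; annotation coordinates are lifted
through the mutation history; and a truth MAF is emitted directly from that
history (a star alignment to the ancestor, so every column is exact by
construction rather than estimated by an aligner).

By default, mutations that would change any gene's ORF validity are
rejection-sampled away: substitutions never touch a start or stop codon or
create an in-frame stop, and indels land only between genes.  Annotation
anomalies therefore exist only where they are planted:

* ``tis_shift``     — one isolate's annotated start moves in frame to
  another start codon (downstream when one exists inside the gene, else a
  start codon is created a few codons upstream in that isolate only),
* ``gene_split_indel`` — one base is deleted mid-gene in the sequence and
  the gene is re-annotated as two fragments meeting at the induced stop,
* ``deleted_annotation`` — the annotation record is dropped, sequence kept,
* ``contig_break``  — the contig is split inside a gene, both fragments
  annotated as partial,
* ``partial_gene``  — as contig_break, but only the longer fragment keeps
  an annotation (a truncated prediction at a draft-assembly edge).

Everything is driven by one seeded RNG, consumed in a documented order
(ancestor, then isolates in index order, then anomalies), so outputs are
bit-reproducible.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import io as pio
from .model import (
    AlignmentBlock,
    AlignmentRow,
    CodonConfig,
    GeneAnnotation,
    GenomeSequence,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
]
_CONTIG = "chr"
_MIN_FRAG = 30  # bp; smallest gene fragment a split may produce


@dataclass
class SimConfig:
    """Study conditions for the synthetic pan-genome."""

    n_genomes: int = 5
    genome_len: int = 1_000_000
    n_genes: int = 800
    gene_len: tuple[int, int] = (300, 900)  # bp, multiples of 3 enforced
    snp_rate: float = 0.005  # per-base substitution probability per isolate
    indel_rate: float = 1e-4  # per-base probability of an indel event start
    indel_len: tuple[int, int] = (1, 3)
    seed: int = 0
    # planted anomaly counts
    tis_shift: int = 0
    gene_split_indel: int = 0
    deleted_annotation: int = 0
    contig_break: int = 0
    partial_gene: int = 0
    avoid_stops: bool = True  # rejection-sample mutations that break ORFs

    def __post_init__(self) -> None:
        for r in (self.snp_rate, self.indel_rate):
            if not 0 <= r <= 1:
                raise ValueError("mutation rates must be in [0, 1]")
        n_planted = (
            self.tis_shift
            + self.gene_split_indel
            + self.deleted_annotation
            + self.contig_break
            + self.partial_gene
        )
        if n_planted > self.n_genes:
            raise ValueError("planted anomalies exceed available genes")


@dataclass
class MutationLog:
    """Per-isolate events in ancestor coordinates."""

    subs: dict[int, str] = field(default_factory=dict)  # pos -> alt base
    ins: dict[int, str] = field(default_factory=dict)  # anchor -> inserted seq
    dels: set[int] = field(default_factory=set)  # deleted positions
    breaks: list[int] = field(default_factory=list)  # isolate-coordinate breaks


@dataclass
class Isolate:
    genome_id: str
    genome: GenomeSequence
    annotations: list[GeneAnnotation]
    log: MutationLog
    row_text: str = ""  # gapped row of the star alignment (pre-break)

    def lift(self, pos: int) -> int:
        """Ancestor position -> isolate position (pre-break coordinates)."""
        shift = sum(len(s) for a, s in self.log.ins.items() if a <= pos)
        shift -= sum(1 for d in self.log.dels if d < pos)
        return pos + shift


@dataclass
class PlantedAnomaly:
    kind: str
    ancestor_gene: str
    genome_id: str
    shift_bp: int = 0
    direction: str = ""
    ancestor_pos: int = -1
    indel_column: int = -1


@dataclass
class TruthSet:
    """What the pipeline should recover, recorded while planting."""

    gene_to_ancestor: dict[str, str]
    groups: dict[str, dict[str, list[str]]]  # anc gene -> genome -> gene ids
    anomalies: list[PlantedAnomaly]
    true_tis_column: dict[str, int]  # anc gene -> column of the ancestral 5' base

    def anomalies_of(self, kind: str) -> list[PlantedAnomaly]:
        return [a for a in self.anomalies if a.kind == kind]


@dataclass
class SimResult:
    config: SimConfig
    ancestor: GenomeSequence
    ancestor_genes: list[GeneAnnotation]
    isolates: list[Isolate]
    blocks: list[AlignmentBlock]
    truth: TruthSet


# ---------------------------------------------------------------------------
# ancestor
# ---------------------------------------------------------------------------

def generate_ancestor(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[GenomeSequence, list[GeneAnnotation]]:
    """Random genome with non-overlapping valid ORFs on both strands."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo = max(9, 3 * (config.gene_len[0] // 3))
    hi = max(lo, 3 * (config.gene_len[1] // 3))
    lengths = rng.integers(lo // 3, hi // 3 + 1, size=config.n_genes) * 3
    margin, min_gap = 50, 20
    slack = config.genome_len - 2 * margin - int(lengths.sum()) - min_gap * max(config.n_genes - 1, 0)
    if config.n_genes and slack < 0:
        raise ValueError(
            f"cannot pack {config.n_genes} genes totalling {int(lengths.sum())} bp "
            f"into {config.genome_len} bp"
        )

    seq = rng.choice(_BASES, size=config.genome_len).astype(np.uint8)
    genes: list[GeneAnnotation] = []
    if config.n_genes:
        weights = rng.random(config.n_genes)
        extras = np.floor(weights / weights.sum() * slack).astype(int)
        pos = margin
        starts = []
        for i, length in enumerate(lengths):
            starts.append(pos)
            pos += int(length) + min_gap + int(extras[i])
        for i, (s, length) in enumerate(zip(starts, lengths)):
            n_codons = int(length) // 3
            codons = ["ATG"]
            codons += list(rng.choice(_SENSE_CODONS, size=n_codons - 2))
            codons.append(str(rng.choice(_STOPS)))
            orf = "".join(codons)
            strand = "+" if rng.random() < 0.5 else "-"
            insert = orf if strand == "+" else revcomp(orf)
            seq[s : s + length] = np.frombuffer(insert.encode(), dtype=np.uint8)
            genes.append(
                GeneAnnotation(
                    gene_id=f"g{i + 1:05d}",
                    genome_id="ancestor",
                    contig_id=_CONTIG,
                    start=int(s),
                    end=int(s + length),
                    strand=strand,
                )
            )
    genome = GenomeSequence(genome_id="ancestor", contigs={_CONTIG: seq.tobytes().decode()})
    return genome, genes


# ---------------------------------------------------------------------------
# isolates
# ---------------------------------------------------------------------------

def _oriented_codon(seq: bytearray, gene: GeneAnnotation, pos: int, alt: str) -> tuple[int, str]:
    """(codon_index, codon string) of ``pos`` in ``gene`` after applying ``alt``."""
    if gene.strand == "+":
        off = pos - gene.start
        cstart = gene.start + 3 * (off // 3)
        codon = seq[cstart : cstart + 3].decode()
        codon = codon[: pos - cstart] + alt + codon[pos - cstart + 1 :]
        return off // 3, codon
    off = gene.end - 1 - pos
    cstart_fwd = gene.end - 3 * (off // 3) - 3
    codon_fwd = seq[cstart_fwd : cstart_fwd + 3].decode()
    i = pos - cstart_fwd
    codon_fwd = codon_fwd[:i] + alt + codon_fwd[i + 1 :]
    return off // 3, revcomp(codon_fwd)


def _sample_snps(
    seq_bytes: bytes,
    genes: list[GeneAnnotation],
    gene_of_pos: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[int, str]:
    """Substitutions, rejecting any that would break an annotated ORF."""
    L = len(seq_bytes)
    n = rng.binomial(L, config.snp_rate)
    positions = np.sort(rng.choice(L, size=n, replace=False))
    work = bytearray(seq_bytes)
    subs: dict[int, str] = {}
    for pos in positions:
        pos = int(pos)
        ref = chr(work[pos])
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        gi = int(gene_of_pos[pos])
        if config.avoid_stops and gi >= 0:
            gene = genes[gi]
            codon_idx, codon = _oriented_codon(work, gene, pos, alt)
            n_codons = gene.length // 3
            if codon_idx == 0 or codon_idx == n_codons - 1:
                continue  # never touch start or stop codons
            if codon in _STOPS:
                continue  # would create an in-frame stop
        work[pos] = ord(alt)
        subs[pos] = alt
    return subs


def _sample_indels(
    gene_of_pos: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[int, str], set[int]]:
    """Intergenic insertions and deletions (never inside or adjacent to genes)."""
    L = gene_of_pos.size
    margin = 5
    blocked = gene_of_pos >= 0
    n_events = rng.poisson(config.indel_rate * L)
    ins: dict[int, str] = {}
    dels: set[int] = set()
    used: set[int] = set()
    for _ in range(n_events):
        pos = int(rng.integers(margin + 10, L - margin - 10))
        length = int(rng.integers(config.indel_len[0], config.indel_len[1] + 1))
        span = range(pos - margin, pos + length + margin)
        if any(blocked[p] for p in span) or any(p in used for p in span):
            continue  # rejection keeps indels strictly intergenic
        used.update(span)
        if rng.random() < 0.5:
            ins[pos] = "".join(str(b) for b in rng.choice(list("ACGT"), size=length))
        else:
            dels.update(range(pos, pos + length))
    return ins, dels


def _gene_of_pos(genes: list[GeneAnnotation], L: int) -> np.ndarray:
    arr = np.full(L, -1, dtype=np.int64)
    for i, g in enumerate(genes):
        arr[g.start : g.end] = i
    return arr


def evolve_isolates(
    ancestor: GenomeSequence,
    ancestor_genes: list[GeneAnnotation],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[Isolate]:
    """Derive isolates from the ancestor and materialise their sequences."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    seq_bytes = ancestor.contigs[_CONTIG].encode()
    gene_of_pos = _gene_of_pos(ancestor_genes, len(seq_bytes))
    isolates = []
    for i in range(config.n_genomes):
        genome_id = f"s{i + 1}"
        subs = _sample_snps(seq_bytes, ancestor_genes, gene_of_pos, config, rng)
        ins, dels = _sample_indels(gene_of_pos, config, rng)
        isolates.append(
            Isolate(
                genome_id=genome_id,
                genome=GenomeSequence(genome_id, {_CONTIG: "N"}),  # placeholder
                annotations=[],
                log=MutationLog(subs=subs, ins=ins, dels=dels),
            )
        )
    _materialize(ancestor, ancestor_genes, isolates)
    return isolates


def _materialize(
    ancestor: GenomeSequence,
    ancestor_genes: list[GeneAnnotation],
    isolates: list[Isolate],
) -> np.ndarray:
    """Rebuild isolate sequences, lifted annotations and alignment rows.

    Returns ``col_of_anc``: alignment column of every ancestor position.
    Sequences and rows come from the same per-position arrays, so the MAF
    and the FASTA can never disagree.
    """
    anc = np.frombuffer(ancestor.contigs[_CONTIG].encode(), dtype=np.uint8)
    L = anc.size

    anchors = sorted({a for iso in isolates for a in iso.log.ins})
    anchor_arr = np.array(anchors, dtype=np.int64)
    widths = np.array(
        [sum(len(iso.log.ins.get(a, "")) for iso in isolates) for a in anchors],
        dtype=np.int64,
    )
    cum = np.concatenate([[0], np.cumsum(widths)])
    # column of ancestor position p: insertions at anchors <= p come first
    col_of_anc = np.arange(L, dtype=np.int64) + cum[
        np.searchsorted(anchor_arr, np.arange(L), side="right")
    ]

    per_iso_base: list[np.ndarray] = []
    for iso in isolates:
        arr = anc.copy()
        if iso.log.subs:
            pos = np.fromiter(iso.log.subs.keys(), dtype=np.int64)
            alt = np.frombuffer("".join(iso.log.subs.values()).encode(), dtype=np.uint8)
            arr[pos] = alt
        if iso.log.dels:
            arr[np.fromiter(iso.log.dels, dtype=np.int64)] = ord("-")
        per_iso_base.append(arr)

    for k, iso in enumerate(isolates):
        segments: list[str] = []
        prev = 0
        base = per_iso_base[k]
        for a in anchors:
            segments.append(base[prev:a].tobytes().decode())
            for j, other in enumerate(isolates):
                insert = other.log.ins.get(a, "")
                if not insert:
                    continue
                segments.append(insert if j == k else "-" * len(insert))
            prev = a
        segments.append(base[prev:].tobytes().decode())
        text = "".join(segments)
        iso.row_text = text
        seq = text.replace("-", "")
        genome = GenomeSequence(iso.genome_id, {_CONTIG: seq})
        anns = []
        for g in ancestor_genes:
            anns.append(
                GeneAnnotation(
                    gene_id=f"{iso.genome_id}_{g.gene_id}",
                    genome_id=iso.genome_id,
                    contig_id=_CONTIG,
                    start=iso.lift(g.start),
                    end=iso.lift(g.end),
                    strand=g.strand,
                )
            )
        iso.genome = genome
        iso.annotations = anns
    return col_of_anc


# ---------------------------------------------------------------------------
# anomaly planting
# ---------------------------------------------------------------------------

def _gene_seq(iso: Isolate, ann: GeneAnnotation) -> str:
    s = iso.genome.contigs[ann.contig_id][ann.start : ann.end]
    return s if ann.strand == "+" else revcomp(s)


def _find_internal_start(seq: str, cfg: CodonConfig) -> Optional[int]:
    """Codon index of an in-frame start codon in the first third (j >= 2)."""
    for j in range(2, max(3, len(seq) // 9)):
        if seq[3 * j : 3 * j + 3] in cfg.start_codons:
            return j
    return None


def _induced_stop(seq: str) -> Optional[int]:
    """First in-frame stop codon index in a (frameshifted) gene sequence."""
    for c in range(1, len(seq) // 3 - 1):
        if seq[3 * c : 3 * c + 3] in _STOPS:
            if _MIN_FRAG <= 3 * c + 3 <= len(seq) - _MIN_FRAG:
                return c
            return None
    return None


def plant_anomalies(
    ancestor: GenomeSequence,
    ancestor_genes: list[GeneAnnotation],
    isolates: list[Isolate],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    codon_config: CodonConfig = CodonConfig(),
) -> TruthSet:
    """Plant the configured anomalies; isolates are modified in place."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    pool = list(rng.permutation(len(ancestor_genes)))
    plan = (
        [("tis_shift", None)] * config.tis_shift
        + [("gene_split_indel", None)] * config.gene_split_indel
        + [("deleted_annotation", None)] * config.deleted_annotation
        + [("contig_break", None)] * config.contig_break
        + [("partial_gene", None)] * config.partial_gene
    )
    placements: list[tuple[str, int, int]] = []  # (kind, gene index, isolate index)
    anomalies: list[PlantedAnomaly] = []

    # phase A: choose targets and append sequence-level events
    for kind, _ in plan:
        placed = False
        while pool and not placed:
            gi = pool.pop()
            gene = ancestor_genes[gi]
            iso_idx = int(rng.integers(len(isolates)))
            iso = isolates[iso_idx]
            ann = iso.annotations[gi]
            if kind == "tis_shift":
                seq = _gene_seq(iso, ann)
                j = _find_internal_start(seq, codon_config)
                if j is not None:
                    placements.append((kind, gi, iso_idx))
                    anomalies.append(
                        PlantedAnomaly(
                            kind, gene.gene_id, iso.genome_id,
                            shift_bp=3 * j, direction="downstream",
                        )
                    )
                    placed = True
                else:
                    placed = _plant_upstream_start(
                        gene, iso, codon_config, anomalies, placements, gi, iso_idx
                    )
            elif kind == "gene_split_indel":
                anc_pos = _choose_split_deletion(gene, iso)
                if anc_pos is not None:
                    iso.log.subs.pop(anc_pos, None)
                    iso.log.dels.add(anc_pos)
                    placements.append((kind, gi, iso_idx))
                    anomalies.append(
                        PlantedAnomaly(
                            kind, gene.gene_id, iso.genome_id, ancestor_pos=anc_pos
                        )
                    )
                    placed = True
            else:
                placements.append((kind, gi, iso_idx))
                anomalies.append(PlantedAnomaly(kind, gene.gene_id, iso.genome_id))
                placed = True
        if not placed:
            raise ValueError(f"could not place planted anomaly {kind!r}")

    # phase B: rebuild sequences, rows and lifted annotations
    col_of_anc = _materialize(ancestor, ancestor_genes, isolates)

    # phase C: annotation edits in rebuilt coordinates
    for (kind, gi, iso_idx), anomaly in zip(placements, anomalies):
        gene = ancestor_genes[gi]
        iso = isolates[iso_idx]
        ann = iso.annotations[gi]
        if kind == "tis_shift":
            shifted = _apply_tis_shift(ann, anomaly)
            iso.annotations[gi] = shifted
        elif kind == "gene_split_indel":
            anomaly.indel_column = int(col_of_anc[anomaly.ancestor_pos])
            frag1, frag2 = _split_fragments(iso, ann)
            iso.annotations[gi] = frag1
            iso.annotations.append(frag2)
        elif kind == "deleted_annotation":
            iso.annotations[gi] = None  # type: ignore[assignment]
        elif kind in ("contig_break", "partial_gene"):
            b = (ann.start + ann.end) // 2
            iso.log.breaks.append(b)
            anomaly.ancestor_pos = b  # isolate coordinate of the break

    for iso in isolates:
        iso.annotations = [a for a in iso.annotations if a is not None]
        if iso.log.breaks:
            _apply_breaks(iso, keep_short_fragments={
                a.ancestor_pos for a in anomalies
                if a.kind == "contig_break" and a.genome_id == iso.genome_id
            })

    # phase D: truth bookkeeping
    gene_to_anc: dict[str, str] = {}
    groups: dict[str, dict[str, list[str]]] = {g.gene_id: {} for g in ancestor_genes}
    for iso in isolates:
        for a in iso.annotations:
            anc_id = a.gene_id.split("_", 1)[1].split("_f")[0].split("_p")[0]
            gene_to_anc[a.gene_id] = anc_id
            groups[anc_id].setdefault(iso.genome_id, []).append(a.gene_id)
    true_tis = {
        g.gene_id: int(col_of_anc[g.five_prime_pos()]) for g in ancestor_genes
    }
    return TruthSet(
        gene_to_ancestor=gene_to_anc,
        groups=groups,
        anomalies=anomalies,
        true_tis_column=true_tis,
    )


def _plant_upstream_start(
    gene: GeneAnnotation,
    iso: Isolate,
    cfg: CodonConfig,
    anomalies: list[PlantedAnomaly],
    placements: list,
    gi: int,
    iso_idx: int,
) -> bool:
    """Create a start codon two codons upstream of the gene, in one isolate.

    Rewrites six upstream bases (in ancestor coordinates) so the isolate
    gains an in-frame ATG with no intervening stop; both codons lie in
    intergenic sequence, so no other gene is affected.
    """
    s, e = gene.start, gene.end
    if gene.strand == "+":
        if s < 16:
            return False
        edit_start, new_codons = s - 6, "ATGAAA"
    else:
        if e + 16 > len(iso.genome.contigs[gene.contig_id]):
            return False
        edit_start, new_codons = e, revcomp("ATGAAA")
    window = range(edit_start - 1, edit_start + 8)
    if any(p in iso.log.dels or p in iso.log.ins for p in window):
        return False  # an indel nearby would corrupt the created codons
    for k, base in enumerate(new_codons):
        pos = edit_start + k
        iso.log.subs.pop(pos, None)
        iso.log.subs[pos] = base
    placements.append(("tis_shift", gi, iso_idx))
    anomalies.append(
        PlantedAnomaly(
            "tis_shift", gene.gene_id, iso.genome_id, shift_bp=6, direction="upstream"
        )
    )
    return True


def _choose_split_deletion(gene: GeneAnnotation, iso: Isolate) -> Optional[int]:
    """Ancestor position whose deletion splits the gene at a findable stop."""
    ann = iso.annotations[int(gene.gene_id[1:]) - 1]
    seq = _gene_seq(iso, ann)
    mid = 3 * (len(seq) // 6) + 1
    for off in (mid, mid + 30, mid - 30, mid + 60, mid - 60):
        if not _MIN_FRAG < off < len(seq) - _MIN_FRAG:
            continue
        mutated = seq[:off] + seq[off + 1 :]
        if _induced_stop(mutated) is None:
            continue
        # oriented offset -> ancestor coordinate (genes contain no indels)
        return gene.start + off if gene.strand == "+" else gene.end - 1 - off
    return None


def _apply_tis_shift(ann: GeneAnnotation, anomaly: PlantedAnomaly) -> GeneAnnotation:
    d = anomaly.shift_bp
    if anomaly.direction == "downstream":
        if ann.strand == "+":
            return replace(ann, start=ann.start + d)
        return replace(ann, end=ann.end - d)
    if ann.strand == "+":
        return replace(ann, start=ann.start - d)
    return replace(ann, end=ann.end + d)


def _split_fragments(iso: Isolate, ann: GeneAnnotation) -> tuple[GeneAnnotation, GeneAnnotation]:
    """Re-annotate a frameshifted gene as two fragments at the induced stop."""
    seq = _gene_seq(iso, ann)
    c = _induced_stop(seq)
    if c is None:
        raise RuntimeError(f"no induced stop in split gene {ann.gene_id}")
    cut = 3 * c + 3  # oriented offset of the base after the induced stop
    if ann.strand == "+":
        i1 = (ann.start, ann.start + cut)
        i2 = (ann.start + cut, ann.end)
    else:
        i1 = (ann.end - cut, ann.end)
        i2 = (ann.start, ann.end - cut)
    f1 = replace(ann, gene_id=f"{ann.gene_id}_f1", start=i1[0], end=i1[1])
    f2 = replace(ann, gene_id=f"{ann.gene_id}_f2", start=i2[0], end=i2[1])
    return f1, f2


def _apply_breaks(iso: Isolate, keep_short_fragments: set[int]) -> None:
    """Split the isolate's contig at the recorded break positions.

    Annotations are re-coordinated onto the new contigs; a gene spanning a
    break becomes two partial fragments (``partial_gene`` breaks keep only
    the longer fragment).
    """
    seq = iso.genome.contigs[_CONTIG]
    breaks = sorted(set(iso.log.breaks))
    bounds = [0] + breaks + [len(seq)]
    names = [f"{_CONTIG}_{i + 1}" for i in range(len(bounds) - 1)]
    iso.genome = GenomeSequence(
        iso.genome_id,
        {n: seq[bounds[i] : bounds[i + 1]] for i, n in enumerate(names)},
    )
    new_anns: list[GeneAnnotation] = []
    for ann in iso.annotations:
        pieces = []
        for i, name in enumerate(names):
            lo, hi = bounds[i], bounds[i + 1]
            s, e = max(ann.start, lo), min(ann.end, hi)
            if s >= e:
                continue
            cut5 = s > ann.start if ann.strand == "+" else e < ann.end
            cut3 = e < ann.end if ann.strand == "+" else s > ann.start
            pieces.append(
                replace(
                    ann,
                    gene_id=ann.gene_id if len(pieces) == 0 and s == ann.start and e == ann.end
                    else f"{ann.gene_id}_p{len(pieces) + 1}",
                    contig_id=name,
                    start=s - lo,
                    end=e - lo,
                    partial5=ann.partial5 or cut5,
                    partial3=ann.partial3 or cut3,
                )
            )
        if len(pieces) > 1:
            broken_at = {b for b in breaks if ann.start < b < ann.end}
            if broken_at and not (broken_at & keep_short_fragments):
                pieces = [max(pieces, key=lambda p: p.length)]  # partial_gene
        new_anns.extend(pieces)
    iso.annotations = new_anns


# ---------------------------------------------------------------------------
# truth alignment and file output
# ---------------------------------------------------------------------------

def build_truth_blocks(isolates: list[Isolate]) -> list[AlignmentBlock]:
    """Alignment blocks from the isolates' star-alignment rows.

    One block per stretch between contig breaks; every isolate contributes
    one forward-strand row per block.
    """
    # break columns: isolate break positions mapped through that row's gaps
    break_cols: set[int] = set()
    for iso in isolates:
        if not iso.log.breaks:
            continue
        nongap = np.flatnonzero(
            np.frombuffer(iso.row_text.encode(), dtype=np.uint8) != ord("-")
        )
        for b in iso.log.breaks:
            break_cols.add(int(nongap[b]))
    width = len(isolates[0].row_text)
    bounds = [0] + sorted(break_cols) + [width]

    blocks = []
    for bi in range(len(bounds) - 1):
        lo, hi = bounds[bi], bounds[bi + 1]
        rows: dict[str, AlignmentRow] = {}
        for iso in isolates:
            text = iso.row_text[lo:hi]
            size = len(text) - text.count("-")
            if size == 0:
                continue
            global_start = len(iso.row_text[:lo]) - iso.row_text[:lo].count("-")
            contig_id, local_start, contig_len = _local_coords(iso, global_start)
            rows[iso.genome_id] = AlignmentRow(
                contig_id=contig_id,
                start=local_start,
                ungapped_len=size,
                strand="+",
                contig_len=contig_len,
                text=text,
            )
        blocks.append(AlignmentBlock(block_id=f"block{bi}", rows=rows))
    return blocks


def _local_coords(iso: Isolate, pos: int) -> tuple[str, int, int]:
    """Pre-break isolate coordinate -> (contig_id, local pos, contig length)."""
    offset = 0
    for cid, seq in iso.genome.contigs.items():
        if pos < offset + len(seq):
            return cid, pos - offset, len(seq)
        offset += len(seq)
    cid, seq = list(iso.genome.contigs.items())[-1]
    return cid, len(seq), len(seq)


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: ancestor, isolates, anomalies, truth MAF."""
    rng = np.random.default_rng(config.seed)
    ancestor, genes = generate_ancestor(config, rng)
    isolates = evolve_isolates(ancestor, genes, config, rng)
    truth = plant_anomalies(ancestor, genes, isolates, config, rng)
    blocks = build_truth_blocks(isolates)
    return SimResult(
        config=config,
        ancestor=ancestor,
        ancestor_genes=genes,
        isolates=isolates,
        blocks=blocks,
        truth=truth,
    )


def emit_truth_maf(result: SimResult, outdir: str) -> dict[str, str]:
    """Write FASTA + GFF3 per isolate, the truth MAF, and truth.tsv."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    for iso in result.isolates:
        fa = os.path.join(outdir, f"{iso.genome_id}.fasta")
        gff = os.path.join(outdir, f"{iso.genome_id}.gff3")
        pio.write_fasta(iso.genome, fa)
        pio.write_gff3(iso.annotations, gff)
        paths[f"fasta:{iso.genome_id}"] = fa
        paths[f"gff3:{iso.genome_id}"] = gff
    maf = os.path.join(outdir, "alignment.maf")
    pio.write_maf(result.blocks, maf)
    paths["maf"] = maf
    truth_path = os.path.join(outdir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("kind\tancestor_gene\tgenome_id\tshift_bp\tdirection\tancestor_pos\tindel_column\n")
        for a in result.truth.anomalies:
            fh.write(
                f"{a.kind}\t{a.ancestor_gene}\t{a.genome_id}\t{a.shift_bp}\t"
                f"{a.direction or '.'}\t{a.ancestor_pos}\t{a.indel_column}\n"
            )
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# dataset transforms (used for strand-invariance checks)
# ---------------------------------------------------------------------------

def revcomp_dataset(
    genomes: dict[str, GenomeSequence],
    annotations: list[GeneAnnotation],
    blocks: list[AlignmentBlock],
) -> tuple[dict[str, GenomeSequence], list[GeneAnnotation], list[AlignmentBlock]]:
    """Reverse-complement every genome and rewrite annotations and blocks.

    Gene intervals flip within their contig and change strand.  A block
    row's text is unchanged — it reads the same physical strand as before,
    which is now the reverse strand — so only the strand label and the
    forward-start change, and alignment columns stay identical.
    """
    new_genomes = {
        gid: GenomeSequence(gid, {cid: revcomp(s) for cid, s in g.contigs.items()})
        for gid, g in genomes.items()
    }
    new_annotations = []
    for a in annotations:
        clen = genomes[a.genome_id].contig_len(a.contig_id)
        new_annotations.append(
            replace(
                a,
                start=clen - a.end,
                end=clen - a.start,
                strand="-" if a.strand == "+" else "+",
                partial5=a.partial5,
                partial3=a.partial3,
            )
        )
    new_blocks = []
    for block in blocks:
        rows = {}
        for genome_id, row in block.rows.items():
            rows[genome_id] = AlignmentRow(
                contig_id=row.contig_id,
                start=row.contig_len - row.end,
                ungapped_len=row.ungapped_len,
                strand="-" if row.strand == "+" else "+",
                contig_len=row.contig_len,
                text=row.text,
            )
        new_blocks.append(AlignmentBlock(block_id=block.block_id, rows=rows))
    return new_genomes, new_annotations, new_blocks
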