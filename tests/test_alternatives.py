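"""Codon-pair enumeration, ORF evaluation, frameshift repair and ranking."""

import numpy as np
import pytest

import oracles
from panannot.alternatives import (
    enumerate_codon_pairs,
    evaluate_orf,
    flag_overlaps,
    rank_alternatives,
    suggest_missing_genes,
)
from panannot.anomalies import MissingAnnotation
from panannot.grouping import group_orthologs
from panannot.index import build_index
from panannot.model import (
    AlternativeAnnotation,
    CodonConfig,
    ColumnLocus,
    GeneAnnotation,
    GenomeSequence,
    OrfEvaluation,
    OrthologGroup,
)

from conftest import genomes_for_block, make_block, sim_inputs

CFG = CodonConfig()


def _codons(rng, n):
    out = []
    while len(out) < n:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in ("TAA", "TAG", "TGA"):
            out.append(c)
    return out


def make_orf(length, rng, internal_start_at=None):
    """A clean ORF of ``length`` bp; optionally an in-frame ATG at an offset."""
    n = length // 3
    codons = ["ATG"] + _codons(rng, n - 2) + ["TAA"]
    if internal_start_at is not None:
        codons[internal_start_at // 3] = "ATG"
    return "".join(codons)


# -- enumeration ------------------------------------------------------------

def _pairs_for(genes, block):
    idx = build_index([block], genes)
    grp = OrthologGroup("G", genes[0].gene_id, [g.gene_id for g in genes])
    return enumerate_codon_pairs(grp, idx)


def test_two_starts_one_stop_give_two_pairs():
    rng = np.random.default_rng(0)
    text = make_orf(60, rng, internal_start_at=12)
    block = make_block("b0", [(g, "c1", 0, "+", 80, text) for g in ("g1", "g2")])
    genes = [
        GeneAnnotation("a", "g1", "c1", 0, 60, "+"),
        GeneAnnotation("b", "g2", "c1", 12, 60, "+"),
    ]
    assert len(_pairs_for(genes, block)) == 2


def test_consistent_group_yields_its_own_single_pair():
    rng = np.random.default_rng(1)
    text = make_orf(60, rng)
    block = make_block("b0", [(g, "c1", 0, "+", 80, text) for g in ("g1", "g2")])
    genes = [GeneAnnotation(g, f"g{i}", "c1", 0, 60, "+") for i, g in enumerate(["a", "b"], 1)]
    pairs = _pairs_for(genes, block)
    assert pairs == [(ColumnLocus("b0", 0), ColumnLocus("b0", 59), "+")]


def test_inverted_orientation_pairs_filtered():
    """3 starts x 2 stops with one start 3' of one stop -> 5 pairs."""
    rng = np.random.default_rng(2)
    text = "".join(rng.choice(list("ACGT"), size=60))
    block = make_block("b0", [(g, "c1", 0, "+", 80, text) for g in ("g1", "g2", "g3")])
    genes = [
        GeneAnnotation("a", "g1", "c1", 0, 28, "+"),   # start 0, stop 27
        GeneAnnotation("b", "g2", "c1", 6, 46, "+"),   # start 6, stop 45
        GeneAnnotation("c", "g3", "c1", 30, 46, "+"),  # start 30 is 3' of stop 27
    ]
    pairs = _pairs_for(genes, block)
    assert len(pairs) == 5
    assert (ColumnLocus("b0", 30), ColumnLocus("b0", 27), "+") not in pairs


# -- ORF evaluation ---------------------------------------------------------

def _single_genome_eval(seq_text, gene_interval, strand="+"):
    block = make_block("b0", [("g1", "c1", 10, strand if strand == "+" else "+", 10 + len(seq_text) + 10, seq_text)])
    genomes = genomes_for_block(block)
    idx = build_index([block], [])
    s, e = gene_interval
    if strand == "+":
        pair = (ColumnLocus("b0", s), ColumnLocus("b0", e - 1), "+")
    else:
        pair = (ColumnLocus("b0", e - 1), ColumnLocus("b0", s), "-")
    return evaluate_orf(pair, "g1", idx, genomes["g1"], CFG)


def test_canonical_orf_is_valid_with_zero_shifts():
    ev = _single_genome_eval("ATGAAATAA", (0, 9))
    assert ev.orf_valid and ev.n_frameshifts == 0


def test_internal_in_frame_stop_invalidates():
    ev = _single_genome_eval("ATGAAATAAAAATAA", (0, 15))
    assert not ev.orf_valid and ev.reason == "invalid_orf"


def test_non_start_first_codon_invalidates():
    ev = _single_genome_eval("CCCAAATAA", (0, 9))
    assert not ev.orf_valid


def test_minus_strand_orf_evaluation():
    from panannot.model import revcomp

    ev = _single_genome_eval(revcomp("ATGAAATAA"), (0, 9), strand="-")
    assert ev.orf_valid and ev.strand == "-"


def test_frameshift_repair_at_planted_deletion():
    """One base deleted mid-ORF in g2: repairable with one shift at the gap.

    Oracle: hand-removal of one or two bases around the gap restores a
    clean translation (checked through Biopython), and no repair exists for
    the unshifted reading.
    """
    rng = np.random.default_rng(3)
    orf = make_orf(30, rng)
    del_at = 16  # inside codon 5
    g1_text = orf
    g2_text = orf[:del_at] + "-" + orf[del_at + 1 :]
    block = make_block(
        "b0",
        [("g1", "c1", 0, "+", 50, g1_text), ("g2", "c1", 0, "+", 49, g2_text)],
    )
    genomes = genomes_for_block(block)
    idx = build_index([block], [])
    pair = (ColumnLocus("b0", 0), ColumnLocus("b0", 29), "+")

    ev1 = evaluate_orf(pair, "g1", idx, genomes["g1"], CFG)
    assert ev1.orf_valid and ev1.n_frameshifts == 0

    ev2 = evaluate_orf(pair, "g2", idx, genomes["g2"], CFG)
    assert ev2.orf_valid and ev2.n_frameshifts == 1
    assert ev2.frameshift_columns == (del_at,)
    seq2 = oracles.extract(genomes["g2"].contigs["c1"], ev2.start, ev2.end, "+")
    assert not oracles.is_clean_orf(seq2)  # broken without the repair
    assert oracles.repairable_orf(seq2, 1)


def test_no_repair_attempted_without_indel_signature():
    """A gapless invalid region must stay invalid (no frameshift licence)."""
    ev = _single_genome_eval("ATGAAATAAAAATAA", (0, 15))
    assert not ev.orf_valid and ev.n_frameshifts == 0


def test_repair_disabled_when_max_frameshifts_zero():
    rng = np.random.default_rng(4)
    orf = make_orf(30, rng)
    g2_text = orf[:16] + "-" + orf[17:]
    block = make_block(
        "b0", [("g1", "c1", 0, "+", 50, orf), ("g2", "c1", 0, "+", 49, g2_text)]
    )
    genomes = genomes_for_block(block)
    idx = build_index([block], [])
    pair = (ColumnLocus("b0", 0), ColumnLocus("b0", 29), "+")
    cfg0 = CodonConfig(max_frameshifts=0)
    assert not evaluate_orf(pair, "g2", idx, genomes["g2"], cfg0).orf_valid


# -- ranking ----------------------------------------------------------------

def _ranking_fixture(g3_start_base=None):
    """Three genomes sharing a 300 bp ORF with an internal ATG at 180.

    ``g3_start_base`` replaces g3's base at the outer start codon so the
    long candidate becomes invalid in g3.
    """
    rng = np.random.default_rng(5)
    orf = make_orf(300, rng, internal_start_at=180)
    texts = {"g1": orf, "g2": orf, "g3": orf}
    if g3_start_base:
        texts["g3"] = g3_start_base + orf[1:]
    block = make_block("b0", [(g, "c1", 0, "+", 320, t) for g, t in texts.items()])
    genomes = genomes_for_block(block)
    genes = [
        GeneAnnotation("a", "g1", "c1", 0, 300, "+"),
        GeneAnnotation("b", "g2", "c1", 0, 300, "+"),
        GeneAnnotation("c", "g3", "c1", 180, 300, "+"),
    ]
    idx = build_index([block], genes)
    grp = OrthologGroup("G", "a", ["a", "b", "c"])
    return grp, idx, genomes


def test_short_candidate_dropped_by_length_filter():
    grp, idx, genomes = _ranking_fixture()
    alts = rank_alternatives(grp, idx, genomes, min_len_frac=0.5)
    # the 120 bp candidate is 40% of the 300 bp annotations in g1/g2
    assert [a.length for a in alts] == [300]


def test_equal_validity_ranks_longer_first():
    grp, idx, genomes = _ranking_fixture()
    alts = rank_alternatives(grp, idx, genomes, min_len_frac=0.3)
    assert [a.length for a in alts] == [300, 120]
    assert [a.rank for a in alts] == [1, 2]
    assert all(a.n_valid_orfs == 3 for a in alts)


def test_more_valid_orfs_ranks_first():
    grp, idx, genomes = _ranking_fixture(g3_start_base="C")
    alts = rank_alternatives(grp, idx, genomes, min_len_frac=0.3)
    assert [(a.n_valid_orfs, a.length) for a in alts] == [(3, 120), (2, 300)]


def test_configurable_sort_order_length_first():
    grp, idx, genomes = _ranking_fixture(g3_start_base="C")
    alts = rank_alternatives(grp, idx, genomes, min_len_frac=0.3,
                             sort_order="length,valid_orfs")
    assert [(a.n_valid_orfs, a.length) for a in alts] == [(2, 300), (3, 120)]


def test_tis_direction_reported():
    grp, idx, genomes = _ranking_fixture()
    alts = rank_alternatives(grp, idx, genomes, min_len_frac=0.3)
    # query (g1) is annotated at the outer start: the short one is downstream
    assert [a.tis_direction for a in alts] == ["same", "downstream"]


def test_adding_valid_genome_never_decreases_validity():
    """Monotonicity of n_valid_orfs in the genome set."""
    grp, idx, genomes = _ranking_fixture()
    two = {g: genomes[g] for g in ("g1", "g2")}
    alts2 = {
        (a.start_locus, a.stop_locus): a.n_valid_orfs
        for a in rank_alternatives(grp, idx, two, min_len_frac=0.3)
    }
    alts3 = {
        (a.start_locus, a.stop_locus): a.n_valid_orfs
        for a in rank_alternatives(grp, idx, genomes, min_len_frac=0.3)
    }
    for key, n2 in alts2.items():
        assert alts3[key] >= n2


# -- overlap flag -----------------------------------------------------------

def _overlap_fixture(neighbor_interval):
    genes = [
        GeneAnnotation("a", "g1", "c1", 60, 120, "+"),
        GeneAnnotation("n", "g1", "c1", *neighbor_interval, "+"),
    ]
    block = make_block("b0", [("g1", "c1", 0, "+", 220, "A" * 200)])
    idx = build_index([block], genes)
    grp = OrthologGroup("G", "a", ["a"])
    cand = AlternativeAnnotation(
        group_id="G",
        start_locus=ColumnLocus("b0", 30),
        stop_locus=ColumnLocus("b0", 119),
        strand="+",
        evaluations={
            "g1": OrfEvaluation("g1", True, "c1", 30, 120, "+", orf_valid=True)
        },
        n_valid_orfs=1,
        length=90,
    )
    return cand, idx, grp


def test_extension_into_adjacent_gene_flagged():
    cand, idx, grp = _overlap_fixture((0, 40))  # candidate reaches into [0,40)
    assert flag_overlaps(cand, idx, grp)


def test_candidate_interior_to_span_not_flagged():
    cand, idx, grp = _overlap_fixture((150, 200))
    assert not flag_overlaps(cand, idx, grp)


def test_overlap_with_group_member_not_flagged():
    cand, idx, grp = _overlap_fixture((150, 200))
    # overlap with the gene being replaced (a member) does not count
    assert not flag_overlaps(cand, idx, grp)


# -- missing-gene suggestions -----------------------------------------------

def _missing_fixture(third_text):
    rng = np.random.default_rng(6)
    orf = make_orf(60, rng)
    block = make_block(
        "b0",
        [("g1", "c1", 0, "+", 80, orf), ("g2", "c1", 0, "+", 80, orf),
         ("g3", "c1", 0, "+", 80, third_text or orf)],
    )
    genomes = genomes_for_block(block)
    genes = [
        GeneAnnotation("a", "g1", "c1", 0, 60, "+"),
        GeneAnnotation("b", "g2", "c1", 0, 60, "+"),
    ]
    idx = build_index([block], genes)
    grp = OrthologGroup("G", "a", ["a", "b"])
    ranked = {"G": rank_alternatives(grp, idx, genomes)}
    missing = [MissingAnnotation("G", "g3", "c1", 0, 60)]
    return suggest_missing_genes(missing, ranked, idx, genomes)


def test_intact_projected_orf_suggested():
    out = _missing_fixture(None)
    assert len(out) == 1 and out[0].evaluations["g3"].orf_valid


def test_unrepairable_internal_stop_suppresses_suggestion():
    rng = np.random.default_rng(7)
    bad = make_orf(60, rng)
    bad = bad[:30] + "TAA" + bad[33:]  # gapless internal stop: no licence to shift
    assert _missing_fixture(bad) == []


# -- soundness over a full synthetic run ------------------------------------

def test_all_valid_candidates_pass_independent_retranslation(small_sim):
    """Re-extract every orf_valid candidate from raw FASTA and re-check it."""
    genomes, anns, blocks = sim_inputs(small_sim)
    idx = build_index(blocks, anns)
    groups = group_orthologs(anns, idx)
    n_checked = 0
    for grp in groups:
        if grp.is_singleton:
            continue
        for alt in rank_alternatives(grp, idx, genomes):
            for ev in alt.evaluations.values():
                if not ev.orf_valid:
                    continue
                seq = oracles.extract(
                    genomes[ev.genome_id].contigs[ev.contig_id], ev.start, ev.end, ev.strand
                )
                if ev.n_frameshifts == 0:
                    assert oracles.is_clean_orf(seq)
                else:
                    assert oracles.repairable_orf(seq, ev.n_frameshifts)
                n_checked += 1
    assert n_checked > 20
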