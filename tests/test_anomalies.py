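"""Anomaly classification, missing annotations, contig-boundary flags."""

import itertools

import numpy as np
import pytest

import oracles
from panannot.anomalies import (
    classify_group,
    find_missing_annotations,
    flag_contig_boundary,
    locate_gene_termini,
)
from panannot.grouping import group_orthologs
from panannot.index import build_index
from panannot.model import GeneAnnotation, GenomeSequence, OrthologGroup
from panannot.simulate import SimConfig, revcomp_dataset, simulate

from conftest import make_block, sim_inputs


def gapless_block(n=3, width=600, seed=0):
    text = "".join(np.random.default_rng(seed).choice(list("ACGT"), size=width))
    return make_block(
        "b0", [(f"g{i}", "c1", 10, "+", width + 20, text) for i in range(1, n + 1)]
    )


# -- termini ----------------------------------------------------------------

def test_termini_plus_strand():
    block = make_block("b0", [("g1", "c1", 10, "+", 100, "ACGTAC")])
    gene = GeneAnnotation("g", "g1", "c1", 10, 16, "+")
    idx = build_index([block], [gene])
    t = locate_gene_termini(idx, gene)
    assert (t.start_locus.column, t.stop_locus.column) == (0, 5)


def test_termini_minus_strand_reflection():
    block = make_block("b0", [("g1", "c1", 10, "+", 100, "ACGTAC")])
    gene = GeneAnnotation("g", "g1", "c1", 10, 16, "-")
    idx = build_index([block], [gene])
    t = locate_gene_termini(idx, gene)
    assert (t.start_locus.column, t.stop_locus.column) == (5, 0)


def test_termini_skip_gap_columns():
    """First gene base sits right of a gap column; oracle: per-base table."""
    block = make_block("b0", [("g1", "c1", 10, "+", 100, "AC--GTAC")])
    gene = GeneAnnotation("g", "g1", "c1", 12, 16, "+")
    idx = build_index([block], [gene])
    table = oracles.projection_table(block)["g1"]
    t = locate_gene_termini(idx, gene)
    assert t.start_locus.column == table[12] == 4
    assert t.stop_locus.column == table[15] == 7


def test_unaligned_gene_is_error():
    block = make_block("b0", [("g1", "c1", 10, "+", 100, "ACGTAC")])
    gene = GeneAnnotation("lost", "g1", "c9", 0, 6, "+")
    idx = build_index([block], [gene])
    with pytest.raises(ValueError, match="lost"):
        locate_gene_termini(idx, gene)


# -- classification ---------------------------------------------------------

def _classify(genes):
    idx = build_index([gapless_block()], genes)
    grp = OrthologGroup("G", genes[0].gene_id, [g.gene_id for g in genes])
    return classify_group(grp, idx)


def mk(gene_id, genome, start, end, strand="+"):
    return GeneAnnotation(gene_id, genome, "c1", start, end, strand)


def test_identical_columns_are_consistent():
    rep = _classify([mk("a", "g1", 100, 400), mk("b", "g2", 100, 400), mk("c", "g3", 100, 400)])
    assert rep.klass == "consistent" and rep.sole_outlier_genome is None


def test_single_shifted_start_is_inconsistent_starts_with_outlier():
    rep = _classify([mk("a", "g1", 100, 400), mk("b", "g2", 100, 400), mk("c", "g3", 106, 400)])
    assert rep.klass == "inconsistent_starts"
    assert rep.sole_outlier_genome == "g3"


def test_single_shifted_stop_is_inconsistent_stops():
    rep = _classify([mk("a", "g1", 100, 400), mk("b", "g2", 100, 400), mk("c", "g3", 100, 394)])
    assert rep.klass == "inconsistent_stops" and rep.sole_outlier_genome == "g3"


def test_both_ends_differ_is_combination():
    rep = _classify([mk("a", "g1", 100, 400), mk("b", "g2", 103, 397), mk("c", "g3", 100, 400)])
    assert rep.klass == "combination"


def test_opposite_strands_are_combination():
    rep = _classify([mk("a", "g1", 100, 400), mk("b", "g2", 100, 400, "-")])
    assert rep.klass == "combination"
    assert "mixed_strand" in rep.secondary_classes


def test_two_fragments_in_one_genome_is_fragmentation():
    rep = _classify(
        [mk("a", "g1", 100, 400), mk("b1", "g2", 100, 250), mk("b2", "g2", 250, 400)]
    )
    assert rep.klass == "fragmentation"
    assert rep.sole_outlier_genome == "g2"


def test_singleton_excluded_from_anomaly_classes():
    genes = [mk("a", "g1", 100, 400)]
    idx = build_index([gapless_block()], genes)
    rep = classify_group(OrthologGroup("G", "a", ["a"]), idx)
    assert rep.klass == "singleton"


def test_every_configuration_gets_exactly_one_primary_class():
    """Exhaustive small enumeration: start shift x stop shift x fragment."""
    for ds1, ds2, de1, de2, frag in itertools.product(
        [0, 3], [0, 6], [0, 3], [0, 6], [False, True]
    ):
        genes = [
            mk("a", "g1", 120, 420),
            mk("b", "g2", 120 + ds1, 420 - de1),
            mk("c", "g3", 120 + ds2, 420 - de2),
        ]
        if frag:
            genes.append(mk("c2", "g3", 423, 480))
        rep = _classify(genes)
        assert rep.klass in (
            "consistent", "inconsistent_starts", "inconsistent_stops",
            "combination", "fragmentation",
        )
        assert (rep.klass == "fragmentation") == frag
        if not frag:
            starts_differ = len({ds1, ds2, 0}) > 1
            stops_differ = len({de1, de2, 0}) > 1
            expect = {
                (False, False): "consistent",
                (True, False): "inconsistent_starts",
                (False, True): "inconsistent_stops",
                (True, True): "combination",
            }[(starts_differ, stops_differ)]
            assert rep.klass == expect


def test_genes_anchored_in_different_blocks_are_combination():
    b1 = make_block("b1", [("g1", "c1", 0, "+", 100, "ACGTAC"), ("g2", "c1", 0, "+", 100, "ACGTAC")])
    b2 = make_block("b2", [("g1", "c1", 6, "+", 100, "GTACGT"), ("g2", "c1", 6, "+", 100, "GTACGT")])
    genes = [mk("a", "g1", 0, 6), GeneAnnotation("b", "g2", "c1", 6, 12, "+")]
    idx = build_index([b1, b2], genes)
    rep = classify_group(OrthologGroup("G", "a", ["a", "b"]), idx)
    assert rep.klass == "combination" and rep.block_split


@pytest.mark.parametrize("shift_codons", [1, 2, 5])
def test_planted_in_frame_tis_shift_recovered(shift_codons):
    """A TIS moved by +3k bp in one isolate yields inconsistent_starts there."""
    res = simulate(SimConfig(n_genomes=4, genome_len=15000, n_genes=8, seed=21))
    genomes, anns, blocks = sim_inputs(res)
    target = res.ancestor_genes[2]
    shifted = []
    for a in anns:
        if a.gene_id == f"s2_{target.gene_id}":
            d = 3 * shift_codons
            a = (
                GeneAnnotation(a.gene_id, a.genome_id, a.contig_id, a.start + d, a.end, "+")
                if a.strand == "+"
                else GeneAnnotation(a.gene_id, a.genome_id, a.contig_id, a.start, a.end - d, "-")
            )
        shifted.append(a)
    idx = build_index(blocks, shifted)
    groups = group_orthologs(shifted, idx)
    reports = [classify_group(g, idx) for g in groups]
    bad = [r for r in reports if r.klass != "consistent"]
    assert len(bad) == 1
    assert bad[0].klass == "inconsistent_starts" and bad[0].sole_outlier_genome == "s2"


def test_strand_invariance_of_classification(small_sim):
    """Reverse-complementing every genome leaves class assignments unchanged."""
    genomes, anns, blocks = sim_inputs(small_sim)

    def classes(gs, ans, bls):
        idx = build_index(bls, ans)
        out = {}
        for grp in group_orthologs(ans, idx):
            rep = classify_group(grp, idx)
            out[frozenset(grp.members)] = rep.klass
        return out

    fwd = classes(genomes, anns, blocks)
    rgenomes, ranns, rblocks = revcomp_dataset(genomes, anns, blocks)
    rev = classes(rgenomes, ranns, rblocks)
    assert fwd == rev


# -- contig boundary flag ---------------------------------------------------

def _boundary_fixture(start, end, partial3=False):
    genes = [
        GeneAnnotation("a", "g1", "c1", 100, 400, "+"),
        GeneAnnotation("b", "g2", "c1", start, end, "+", partial3=partial3),
    ]
    idx = build_index([gapless_block()], genes)
    grp = OrthologGroup("G", "a", ["a", "b"])
    rep = classify_group(grp, idx)
    genomes = {
        f"g{i}": GenomeSequence(f"g{i}", {"c1": "A" * 620}) for i in (1, 2, 3)
    }
    return flag_contig_boundary(rep, grp, idx, genomes)


def test_partial_gene_flags_boundary():
    assert _boundary_fixture(100, 400, partial3=True).contig_boundary


def test_interior_genes_not_flagged():
    assert not _boundary_fixture(100, 400).contig_boundary


def test_terminus_within_window_of_contig_end_flags():
    # contig is 620 bp; a gene ending at 615 is 5 bp from the end (W=10)
    assert _boundary_fixture(300, 615).contig_boundary


# -- missing annotations ----------------------------------------------------

def _missing_setup(third_gene=None):
    genes = [mk("a", "g1", 100, 400), mk("b", "g2", 100, 400)]
    if third_gene is not None:
        genes.append(third_gene)
    all_genes = list(genes)
    idx = build_index([gapless_block()], all_genes)
    groups = group_orthologs([g for g in all_genes if g.genome_id != "g3"], idx)
    return find_missing_annotations(groups, idx, min_block_genome_frac=0.9)


def test_unannotated_aligned_genome_reported():
    recs = _missing_setup()
    assert len(recs) == 1
    rec = recs[0]
    assert (rec.genome_id, rec.start, rec.end) == ("g3", 100, 400)


def test_overlapping_unrelated_gene_suppresses_record():
    recs = _missing_setup(third_gene=mk("x", "g3", 380, 500))
    assert recs == []


def test_genome_absent_from_block_not_reported():
    genes = [mk("a", "g1", 100, 400), mk("b", "g2", 100, 400)]
    idx = build_index([gapless_block(n=2)], genes)
    groups = group_orthologs(genes, idx)
    # only g1/g2 are in the alignment: nothing to report for anyone else
    assert find_missing_annotations(groups, idx, min_block_genome_frac=0.9) == []


def test_sparse_blocks_skipped_by_genome_fraction():
    # block holds 3 genomes but a fourth exists only in the annotations
    genes = [mk("a", "g1", 100, 400), mk("b", "g2", 100, 400),
             GeneAnnotation("z", "g4", "c9", 0, 300, "+")]
    idx = build_index([gapless_block()], genes)
    groups = group_orthologs(genes, idx)
    # 3 of 4 genomes in the block = 0.75 < 0.9 -> suppressed
    assert find_missing_annotations(groups, idx, min_block_genome_frac=0.9) == []
    # lowering the threshold reports g3
    recs = find_missing_annotations(groups, idx, min_block_genome_frac=0.7)
    assert [r.genome_id for r in recs] == ["g3"]
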