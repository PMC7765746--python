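"""Gene-map arithmetic: lengths on a circle, junctions, validation, order."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitochar.core import (
    CoordinateError,
    GeneFeature,
    GeneTable,
    NucleotideSequence,
    feature_length,
    feature_sequence,
    gene_order_string,
    junction_gaps,
    reverse_complement,
    validate_table,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


@given(dna)
def test_reverse_complement_is_an_involution(s):
    assert reverse_complement(reverse_complement(s)) == s


@pytest.mark.parametrize(
    "start,stop,L,expected",
    [
        (4052, 5096, 16598, 1045),   # ND2
        (15664, 16598, 16598, 935),  # D-loop
        (16590, 10, 16598, 19),      # wraps the origin: 9 + 10
        (1, 1, 16598, 1),
    ],
)
def test_feature_length(start, stop, L, expected):
    f = GeneFeature("X", "PCG", "H", start, stop)
    assert feature_length(f, L) == expected


def test_feature_length_rejects_out_of_range_coordinates():
    f = GeneFeature("ND9", "PCG", "H", 5, 20000)
    with pytest.raises(CoordinateError, match="ND9"):
        feature_length(f, 16598)


def test_feature_sequence_handles_wrap_and_strand():
    seq = NucleotideSequence("AACCGGTTAA", "circular", "s")
    wrap = GeneFeature("w", "control", "H", 9, 2)  # AA + AA
    assert feature_sequence(seq, wrap) == "AAAA"
    minus = GeneFeature("m", "tRNA", "L", 3, 6)  # CCGG -> CCGG
    assert feature_sequence(seq, minus) == reverse_complement("CCGG")


@pytest.mark.parametrize(
    "up_stop,down_start,expected",
    [
        (5313, 5349, 35),   # tRNA-Asn -> tRNA-Cys spacer
        (8129, 8123, -7),   # ATP8 -> ATP6 overlap
        (100, 101, 0),      # contiguous genes
    ],
)
def test_junction_gap_formula(up_stop, down_start, expected):
    t = GeneTable(
        [
            GeneFeature("up", "tRNA", "H", 50, up_stop),
            GeneFeature("down", "tRNA", "H", down_start, down_start + 60),
        ],
        genome_length=20000,
    )
    assert junction_gaps(t).junctions[0].gap == expected


def test_junction_gaps_requires_sorted_table():
    t = GeneTable(
        [GeneFeature("b", "tRNA", "H", 100, 160), GeneFeature("a", "tRNA", "H", 5, 70)],
        genome_length=200,
    )
    with pytest.raises(ValueError, match="order"):
        junction_gaps(t)


def test_reference_junction_totals(ref_table):
    """22 bp of overlap across exactly 6 junctions; extremes as published."""
    rep = junction_gaps(ref_table)
    assert rep.overlap_bp == 22
    assert rep.overlap_junction_count == 6
    assert (rep.largest_overlap.upstream, rep.largest_overlap.downstream) == ("ATP8", "ATP6")
    assert rep.largest_overlap.gap == -7
    seven_bp = {(j.upstream, j.downstream) for j in rep.junctions if j.gap == -7}
    assert seven_bp == {("ATP8", "ATP6"), ("ND4L", "ND4")}
    assert (rep.largest_spacer.upstream, rep.largest_spacer.downstream) == ("tRNA-Asn", "tRNA-Cys")
    assert rep.largest_spacer.gap == 35


def test_origin_junction_included_on_request(ref_table):
    rep = junction_gaps(ref_table, include_origin_junction=True)
    assert len(rep.junctions) == len(ref_table.features)
    last = rep.junctions[-1]
    assert (last.upstream, last.downstream) == ("D-loop", "tRNA-Phe")
    assert last.gap == 0  # D-loop ends at the origin, tRNA-Phe starts at 1


def _shift_table(table, offset):
    L = table.genome_length
    feats = [
        GeneFeature(f.locus, f.category, f.strand,
                    (f.start - 1 + offset) % L + 1, (f.stop - 1 + offset) % L + 1)
        for f in table.features
    ]
    feats.sort(key=lambda f: f.start)
    return GeneTable(feats, L, circular=True)


def test_overlap_and_spacer_totals_invariant_under_origin_rotation(ref_table):
    """Rotating the circular origin through a spacer leaves totals unchanged."""
    base = junction_gaps(ref_table, include_origin_junction=True)
    # offset chosen inside the tRNA-Asn/tRNA-Cys spacer: splits no feature
    rotated = _shift_table(ref_table, 16598 - 5320)
    rep = junction_gaps(rotated, include_origin_junction=True)
    assert rep.overlap_bp == base.overlap_bp
    assert rep.spacer_bp == base.spacer_bp


def test_validator_flags_published_intergenic_discrepancy(ref_table):
    """The printed ND1 -> tRNA-Ile intergenic value (4) disagrees with the
    coordinates (3840 - 3834 - 1 = 5)."""
    findings = validate_table(ref_table)
    inter = [f for f in findings if f.kind == "intergenic"]
    assert len(inter) == 1 and inter[0].locus == "tRNA-Ile"
    assert "4" in inter[0].message and "5" in inter[0].message


def test_validator_flags_stop_label_incompatible_with_frame(ref_table):
    """The published COIII stop label (TAA) is impossible at 785 bp (mod 3 == 2)."""
    findings = validate_table(ref_table)
    frame = [f for f in findings if f.kind == "stop_frame"]
    assert [f.locus for f in frame] == ["COIII"]


def test_validator_silent_on_consistent_sizes(ref_table):
    assert not [f for f in validate_table(ref_table) if f.kind == "size"]


def test_validator_reports_missing_canonical_genes():
    t = GeneTable([GeneFeature("ND1", "PCG", "H", 1, 99),
                   GeneFeature("tRNA-Phe", "tRNA", "H", 120, 190)], 1000)
    kinds = {(f.kind, f.locus) for f in validate_table(t)}
    assert ("complement", "PCG") in kinds
    assert ("complement", "rRNA") in kinds


def test_gene_order_string_prefix_and_strand_signs(ref_table):
    s = gene_order_string(ref_table)
    assert s.startswith(
        "tRNA-Phe,12S-rRNA,tRNA-Val,16S-rRNA,tRNA-Leu,ND1,tRNA-Ile,-tRNA-Gln,"
    )
    assert s.count(",") == 37


def test_gene_order_string_single_token_edit_on_strand_flip(ref_table):
    flipped = GeneTable(
        [GeneFeature(f.locus, f.category, "H" if f.locus == "ND6" else f.strand,
                     f.start, f.stop) for f in ref_table.features],
        ref_table.genome_length,
    )
    a = gene_order_string(ref_table).split(",")
    b = gene_order_string(flipped).split(",")
    assert sum(x != y for x, y in zip(a, b)) == 1
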