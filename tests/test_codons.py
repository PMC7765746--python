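"""Codon extraction, start/stop classification, RSCU and CDpT."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitochar.codons import (
    VERTEBRATE_MITO,
    MalformedCDSError,
    cdpt,
    classify_start,
    extract_codons,
    extract_codons_from_cds,
    pcg_codon_report,
    rscu,
    stop_label_of,
)
from mitochar.core import feature_length


def test_vertebrate_mito_code_departures():
    code = VERTEBRATE_MITO
    assert code.forward["TGA"] == "W"  # Trp, not stop
    assert code.forward["ATA"] == "M"
    assert {"AGA", "AGG"} <= set(code.stop_codons)
    assert len(code.forward) + len(code.stop_codons) == 64


def test_extract_codons_trivial_cds():
    ext = extract_codons_from_cds("toy", "ATGAAATAA")
    assert ext.start_label == "ATG"
    assert len(ext.complete_codons) == 3
    assert ext.incomplete_tail == ""
    assert stop_label_of(ext) == "TAA"


def test_extract_codons_short_cds_rejected():
    with pytest.raises(MalformedCDSError):
        extract_codons_from_cds("toy", "ATGA")


def test_extract_codons_internal_stop_is_a_warning():
    with pytest.warns(UserWarning, match="internal stop"):
        ext = extract_codons_from_cds("toy", "ATGTAAAAATAA")
    assert ext.internal_stop_positions == [1]


def test_incomplete_stop_labels_on_synthetic_genes(synth_record):
    """ND2 (1045 nt) ends on a single planted T; ATP6 (683 nt) on TA."""
    nd2 = extract_codons(synth_record, "ND2")
    assert nd2.incomplete_tail == "T" and stop_label_of(nd2) == "T-"
    atp6 = extract_codons(synth_record, "ATP6")
    assert atp6.incomplete_tail == "TA" and stop_label_of(atp6) == "TA-"
    assert atp6.start_label == "GTG"


def test_codon_count_conservation(synth_record):
    """3 * complete codons + tail length equals the annotated gene length."""
    L = synth_record.table.genome_length
    for f in synth_record.table.of_category("PCG"):
        ext = extract_codons(synth_record, f.locus)
        assert 3 * len(ext.complete_codons) + len(ext.incomplete_tail) == \
            feature_length(f, L)


@pytest.mark.parametrize(
    "codon,expected",
    [("ATG", "canonical"), ("GTG", "alternative"), ("ATA", "alternative"),
     ("CCC", "invalid")],
)
def test_classify_start(codon, expected):
    ext = extract_codons_from_cds("toy", codon + "AAACCCTAA")
    assert classify_start(ext) == expected


def test_rscu_uniform_and_biased_families():
    vals = rscu({"GCA": 2, "GCC": 2, "GCG": 2, "GCT": 2})
    assert all(vals[c] == 1.0 for c in ("GCA", "GCC", "GCG", "GCT"))
    vals = rscu({"AAA": 3, "AAG": 1})
    assert vals["AAA"] == 1.5 and vals["AAG"] == 0.5


def test_rscu_zero_family_and_stop_exclusion():
    vals = rscu({"TAA": 50})  # a stop codon: not in any family
    assert "TAA" not in vals
    assert vals["GGA"] == 0.0  # untouched Gly family reports zero


family_counts = st.dictionaries(
    st.sampled_from(sorted(VERTEBRATE_MITO.forward)),
    st.integers(0, 500), min_size=1, max_size=40,
)


@given(family_counts)
def test_rscu_family_mean_is_one_for_used_families(counts):
    vals = rscu(counts)
    for members in VERTEBRATE_MITO.families().values():
        if sum(counts.get(c, 0) for c in members) > 0:
            mean = sum(vals[c] for c in members) / len(members)
            assert abs(mean - 1.0) < 1e-9


@given(family_counts)
def test_cdpt_sums_to_one_thousand(counts):
    if sum(counts.values()) == 0:
        return
    vals = cdpt(counts)
    assert abs(sum(vals.values()) - 1000.0) < 0.5


def test_cdpt_examples_and_ser_split():
    assert cdpt({"TGA": 7})["Trp"] == 1000.0
    vals = cdpt({"TGG": 10, "GGA": 90})
    assert vals["Trp"] == 100.0
    vals = cdpt({"TCA": 3, "AGC": 1})
    assert vals["Ser"] == 750.0 and vals["Ser2"] == 250.0


def test_pcg_codon_report_totals_and_labels(synth_record):
    usage, extractions = pcg_codon_report(synth_record)
    assert usage.total_codons == 3803  # 11409 / 3
    # planted labels reproduced for every gene
    declared = {
        f.locus: (f.declared_start_codon, f.declared_stop_codon)
        for f in synth_record.table.of_category("PCG")
    }
    observed = {e.gene: (e.start_label, stop_label_of(e)) for e in extractions}
    assert observed == declared
    # stop triplets and tails are excluded from the usage tally
    complete_stops = sum(
        1 for e in extractions
        if not e.incomplete_tail and e.complete_codons[-1] in VERTEBRATE_MITO.stop_codons
    )
    total_complete = sum(len(e.complete_codons) for e in extractions)
    assert usage.counted_codons == total_complete - complete_stops
    fams = {r["amino_acid_family"] for r in usage.rows()}
    assert "Ser2" in fams and "Trp" in fams


def test_initiator_counted_literally_by_default(synth_record):
    literal, _ = pcg_codon_report(synth_record)
    as_met, _ = pcg_codon_report(synth_record, initiator_as_met=True)
    # COI and ATP6 start with GTG: re-assigning initiators moves 2 counts
    assert as_met.counts.get("ATG", 0) - literal.counts.get("ATG", 0) == 2
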