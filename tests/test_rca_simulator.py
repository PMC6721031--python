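"""Fixture generation, rolling-circle reads, RNase R filter, in-silico PCR."""

import pytest
from scipy import stats

from circrca import (
    Molecule,
    MoleculePool,
    design_full_length_primers,
    extract_mature_sequence,
    linear_counterpart,
    make_fixture_loci,
    pcr_amplify,
    rnase_r_filter,
    simulate_rolling_circle,
)
from circrca.core_io import CircRcaError
from circrca.rca_simulator import TandemRead, find_approx

EXPECTED_STRUCTURES = {
    # gene -> (circBase exon lengths, variant mature lengths)
    "ASPH": ((150, 45, 69), [219]),
    "CNOT2": ((143, 224, 123), [266, 324]),
    "KDM1A": ((166, 60, 134, 79, 93, 107, 82, 95), [756]),
    "PALLD": ((136, 99, 51, 222, 150, 95, 133), [835]),
    "AP3S2": ((92, 112, 119, 72), [276]),
    "MAPK9": ((169, 130, 59, 139), [738]),
}


def test_fixture_panel_matches_catalogue_structures(fixture_set):
    assert len(fixture_set.loci) == 6
    for fx in fixture_set.loci:
        exon_lens, variant_lens = EXPECTED_STRUCTURES[fx.gene]
        got = tuple(e - s for s, e in fx.locus.exons)
        assert got == exon_lens
        assert fx.circbase_variant.mature_length == sum(exon_lens)
        assert [v.mature_length for v in fx.splice_variants] == variant_lens


def test_fixture_cnot2_and_mapk9_special_segments(cnot2, mapk9):
    v324 = cnot2.variants[2]
    kinds = [s.kind for s in v324.segments]
    assert kinds == ["exon", "partial_exon", "exon"]
    assert v324.segments[1].length == 58
    v738 = mapk9.variants[1]
    novel = [s for s in v738.segments if s.kind == "novel_exon"]
    assert len(novel) == 1 and novel[0].length == 241
    # the novel segment lies strictly inside an intron of the locus
    s, e = novel[0].genomic_interval
    introns = mapk9.locus.introns_in_span(mapk9.junction)
    assert any(i_s < s and e < i_e for i_s, i_e in introns)
    exonic = any(not (e <= es or s >= ee) for es, ee in mapk9.locus.exons)
    assert not exonic


def test_fixture_determinism_same_seed_same_genome():
    a = make_fixture_loci(7)
    b = make_fixture_loci(7)
    assert a.genome == b.genome
    assert a.loci == b.loci
    c = make_fixture_loci(8)
    assert c.genome != a.genome


def test_rolling_circle_error_free_periodicity():
    from circrca import MatureCircSequence

    circ = MatureCircSequence(seq="ACGTTGCAGT")  # L = 10
    read = simulate_rolling_circle(circ, copies=3.0)
    assert read.seq == circ.seq * 3
    read = simulate_rolling_circle(circ, copies=2.5, start_phase=4)
    assert len(read.seq) == 25
    assert read.seq[:10] == circ.rotate(4)


def test_rolling_circle_rejects_bad_parameters():
    from circrca import MatureCircSequence

    circ = MatureCircSequence(seq="ACGTACGTAC")
    with pytest.raises(CircRcaError):
        simulate_rolling_circle(circ, copies=0)
    with pytest.raises(CircRcaError):
        simulate_rolling_circle(circ, copies=2, error_rate=0.6)
    with pytest.raises(CircRcaError):
        simulate_rolling_circle(circ, copies=2, start_phase=10)


def test_rolling_circle_error_count_in_binomial_band(fixture_set, cnot2):
    """Mismatches vs truth at 2% error over n=1200 fall in the 99% band."""
    circ = extract_mature_sequence(fixture_set.genome, cnot2.locus,
                                   cnot2.variants[2])  # L = 324
    L, copies, p = 300, 4.0, 0.02
    from circrca import MatureCircSequence

    circ300 = MatureCircSequence(seq=circ.seq[:L])
    read = simulate_rolling_circle(circ300, copies=copies, error_rate=p, seed=11)
    truth = (circ300.seq * 5)[: len(read.seq)]
    mism = sum(a != b for a, b in zip(read.seq, truth))
    n = int(copies * L)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
    assert lo <= mism <= hi
    assert mism == len(read.provenance.error_positions)


def test_rnase_r_filter_extremes_and_binomial_band():
    circles = [Molecule(id=f"c{i}", seq="ACGT", topology="circular") for i in range(5)]
    linears = [Molecule(id=f"l{i}", seq="ACGT", topology="linear") for i in range(1000)]
    pool = MoleculePool(molecules=tuple(circles + linears))

    complete = rnase_r_filter(pool, efficiency=1.0, seed=3)
    assert all(m.topology == "circular" for m in complete.molecules)
    assert len(complete) == 5

    untouched = rnase_r_filter(pool, efficiency=0.0, seed=3)
    assert untouched.molecules == pool.molecules

    partial = rnase_r_filter(pool, efficiency=0.9, seed=3)
    survivors = sum(1 for m in partial.molecules if m.topology == "linear")
    lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.1)
    assert lo <= survivors <= hi
    assert sum(1 for m in partial.molecules if m.topology == "circular") == 5


def _occurrence_oracle(text, pattern):
    """Brute-force exact occurrence enumeration via str.find."""
    out, i = [], text.find(pattern)
    while i >= 0:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def test_pcr_ladder_monomer_and_doublet(fixture_set, cnot2):
    """3.2-copy error-free read of the 266-nt circle yields the 266/532 ladder."""
    circ = extract_mature_sequence(fixture_set.genome, cnot2.locus, cnot2.variants[1])
    pair = design_full_length_primers(circ)
    read = simulate_rolling_circle(circ, copies=3.2, start_phase=0)
    amp = pcr_amplify(read, pair, max_rounds=2)
    assert amp.lengths() == {266, 532}
    # brute-force oracle agrees on primer occurrence positions
    from circrca.core_io import revcomp

    assert find_approx(read.seq, pair.forward_seq) == \
        _occurrence_oracle(read.seq, pair.forward_seq)
    assert find_approx(read.seq, revcomp(pair.reverse_seq)) == \
        _occurrence_oracle(read.seq, revcomp(pair.reverse_seq))


def test_pcr_ladder_multiples_of_circle_length(fixture_set):
    """Ladder law: every amplicon length is an exact multiple of L."""
    for fx in fixture_set.loci:
        for v in fx.variants:
            circ = extract_mature_sequence(fixture_set.genome, fx.locus, v)
            pair = design_full_length_primers(circ)
            read = simulate_rolling_circle(circ, copies=3.0,
                                           start_phase=circ.length - 10)
            amp = pcr_amplify(read, pair)
            assert amp.lengths() and all(
                length % circ.length == 0 for length in amp.lengths())
            assert {a.rounds * circ.length for a in amp.amplicons} == amp.lengths()


def test_pcr_single_copy_gives_at_most_monomer(fixture_set, cnot2):
    circ = extract_mature_sequence(fixture_set.genome, cnot2.locus, cnot2.variants[1])
    pair = design_full_length_primers(circ)
    read = simulate_rolling_circle(circ, copies=1.0, start_phase=0)
    amp = pcr_amplify(read, pair)
    assert all(a.rounds == 1 for a in amp.amplicons)
    assert len(amp) <= 1


def test_junction_primer_silent_on_linear_transcript(fixture_set):
    """The junction-spanning forward primer never binds the spliced linear
    mRNA of the same locus."""
    for fx in fixture_set.loci:
        circ = extract_mature_sequence(fixture_set.genome, fx.locus,
                                       fx.circbase_variant)
        pair = design_full_length_primers(circ)
        linear = linear_counterpart(fixture_set.genome, fx.locus)
        read = TandemRead(seq=linear, read_id=f"{fx.gene}_mRNA")
        assert pair.forward_seq not in linear
        assert len(pcr_amplify(read, pair)) == 0


def test_read_and_amplicon_determinism(fixture_set, cnot2):
    circ = extract_mature_sequence(fixture_set.genome, cnot2.locus, cnot2.variants[1])
    r1 = simulate_rolling_circle(circ, copies=3.3, error_rate=0.05, seed=42)
    r2 = simulate_rolling_circle(circ, copies=3.3, error_rate=0.05, seed=42)
    assert r1.seq == r2.seq and r1.provenance == r2.provenance
    r3 = simulate_rolling_circle(circ, copies=3.3, error_rate=0.05, seed=43)
    assert r3.seq != r1.seq


def test_indel_mode_changes_length():
    from circrca import MatureCircSequence

    circ = MatureCircSequence(seq="ACGTTGCAGTATTGCCAGGT" * 5)
    read = simulate_rolling_circle(circ, copies=3.0, ins_rate=0.02,
                                   del_rate=0.02, seed=9)
    assert abs(len(read.seq) - 300) < 40
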