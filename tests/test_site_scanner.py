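"""Seed-site and motif scanning on circular topology."""

import numpy as np
import pytest

from circrca import (
    IupacMotif,
    MatureCircSequence,
    PwmMotif,
    diff_sites,
    extract_mature_sequence,
    revcomp,
    scan_mirna_seeds,
    scan_rbp_motifs,
)
from circrca.core_io import CircRcaError
from circrca.site_scanner import SEED_TYPES

MIRNA = ("mir-test", "UAGCUUAUCAGACUGAUGUUGA")  # 22 nt


def _plant(site: str, L: int = 60, at: int = 20) -> MatureCircSequence:
    """Embed a site in an otherwise site-free A/C background."""
    backbone = ("AC" * L)[:L]
    seq = backbone[:at] + site + backbone[at + len(site):]
    return MatureCircSequence(seq=seq[:L], circ_id="planted")


def test_planted_8mer_classified_once():
    m = MIRNA[1].replace("U", "T")
    site = revcomp(m[1:8]) + "A"  # m2-m8 complement + A opposite m1
    circ = _plant(site)
    hits = scan_mirna_seeds(circ, [MIRNA])
    assert len(hits) == 1
    h = hits[0]
    assert (h.site_type, h.position, h.length, h.spans_junction) == ("8mer", 20, 8, False)


def test_seed_type_hierarchy_on_constructed_sites():
    m = MIRNA[1].replace("U", "T")
    core = revcomp(m[1:7])
    m8 = revcomp(m[7])
    cases = {
        "8mer": m8 + core + "A",
        "7mer-m8": m8 + core + "G",
        "7mer-A1": "T" + core + "A" if m8 != "T" else "G" + core + "A",
        "6mer": ("T" if m8 != "T" else "G") + core + "G",
    }
    for expected, site in cases.items():
        hits = scan_mirna_seeds(_plant(site), [MIRNA])
        assert [h.site_type for h in hits] == [expected], expected


def test_junction_spanning_site_found_only_in_circular_mode():
    m = MIRNA[1].replace("U", "T")
    site = revcomp(m[1:7])  # 6mer core, split 4 + 2 across the junction
    L = 60
    backbone = ("AC" * L)[:L]
    seq = site[4:] + backbone[2: L - 4] + site[:4]
    circ = MatureCircSequence(seq=seq, circ_id="wrap")
    circular = scan_mirna_seeds(circ, [MIRNA], types={"6mer"})
    assert len(circular) == 1
    assert circular[0].position == L - 4 and circular[0].spans_junction
    linear = scan_mirna_seeds(circ, [MIRNA], types={"6mer"}, topology="linear")
    assert linear == []


def test_short_mirna_skipped_with_warning():
    circ = _plant("ACGTACGT")
    with pytest.warns(UserWarning, match="shorter than 8"):
        assert scan_mirna_seeds(circ, [("tiny", "ACGUACG")]) == []


def _rotation_union_oracle_seeds(circ, mirnas):
    """Best seed class per (miRNA, core position) over all L linear rotations."""
    L = circ.length
    rank = {t: i for i, t in enumerate(SEED_TYPES)}  # lower = more specific
    best = {}
    for r in range(L):
        rot = MatureCircSequence(seq=circ.rotate(r), circ_id=circ.circ_id)
        for h in scan_mirna_seeds(rot, mirnas, topology="linear"):
            core_pos = (h.position + r + (1 if h.site_type in ("8mer", "7mer-m8") else 0)) % L
            key = (h.motif_id, core_pos)
            if key not in best or rank[h.site_type] < rank[best[key].site_type]:
                best[key] = h
    return {(k[0], k[1], v.site_type) for k, v in best.items()}


def test_circular_seed_scan_equals_rotation_oracle():
    rng = np.random.default_rng(77)
    for _ in range(5):
        L = int(rng.integers(60, 160))
        circ = MatureCircSequence(
            seq="".join(rng.choice(list("ACGT"), size=L)), circ_id="r")
        mir = ("m", "".join(rng.choice(list("ACGU"), size=22)))
        got = {
            (h.motif_id,
             (h.position + (1 if h.site_type in ("8mer", "7mer-m8") else 0)) % L,
             h.site_type)
            for h in scan_mirna_seeds(circ, [mir])
        }
        assert got == _rotation_union_oracle_seeds(circ, [mir])


def test_iupac_motif_scan_trivial_and_degenerate():
    circ = MatureCircSequence(seq="ACGTAAAA")
    hits = scan_rbp_motifs(circ, [IupacMotif(name="m", pattern="ACGT")])
    assert [(h.position, h.spans_junction) for h in hits] == [(0, False)]

    circ2 = MatureCircSequence(seq="AAGA")
    hits2 = scan_rbp_motifs(circ2, [IupacMotif(name="ra", pattern="RA")])
    # enumeration: positions where A/G precedes A on the circularized text
    expected = [p for p in range(4) if circ2.seq[p] in "AG"
                and circ2.seq[(p + 1) % 4] == "A"]
    assert [h.position for h in hits2] == expected


def test_iupac_rejects_invalid_letter():
    with pytest.raises(CircRcaError, match="IUPAC"):
        IupacMotif(name="bad", pattern="ACQT")


def test_pwm_at_max_threshold_equals_consensus_scan():
    rng = np.random.default_rng(5)
    circ = MatureCircSequence(
        seq="".join(rng.choice(list("ACGT"), size=200)), circ_id="r")
    consensus = "GATC"
    mat = np.full((4, 4), 0.0)
    for i, b in enumerate(consensus):
        mat["ACGT".index(b), i] = 1.0
    pwm = PwmMotif(name="p", matrix=mat, threshold=8.0)  # max score = 4*log2(4)
    assert pwm.max_score == pytest.approx(8.0)
    got = {h.position for h in scan_rbp_motifs(circ, [pwm])}
    want = {h.position for h in
            scan_rbp_motifs(circ, [IupacMotif(name="c", pattern=consensus)])}
    assert got == want


def test_pwm_rejects_non_finite_matrix():
    with pytest.raises(CircRcaError):
        PwmMotif(name="bad", matrix=np.full((4, 3), np.nan), threshold=0.0)


def test_diff_sites_skipped_exon_site(fixture_set, cnot2):
    """A site planted inside the skipped middle exon is counted only for the
    composition retaining that exon; a site in a shared exon appears in all."""
    variants = {f"v{v.mature_length}": v for v in cnot2.variants}
    circles = {
        name: extract_mature_sequence(fixture_set.genome, cnot2.locus, v)
        for name, v in variants.items()
    }
    # motifs matching unique 10-mers of the middle exon and the shared first exon
    cb = circles["v490"].seq
    mid_exon_motif = IupacMotif(name="in_skipped", pattern=cb[143 + 80: 143 + 90])
    shared_motif = IupacMotif(name="in_shared", pattern=cb[40:50])
    hits = {
        name: scan_rbp_motifs(circ, [mid_exon_motif, shared_motif])
        for name, circ in circles.items()
    }
    res = diff_sites(hits, variants)
    assert res.classification["in_shared"] == "shared-by-all"
    assert res.classification["in_skipped"] == "subset-specific"
    assert res.table.loc["in_skipped", "v490"] >= 1
    assert res.table.loc["in_skipped", "v266"] == 0
    assert res.table.loc["in_skipped", "v324"] == 0
    assert (res.table.loc["in_shared"] >= 1).all()
    seg = res.annotated.query("motif_id == 'in_skipped'")["segment"]
    assert set(seg) == {"E2"}


def test_diff_sites_skipping_creates_junction_site(fixture_set, cnot2):
    """A site spanning the exon1/exon3 joint exists only in the skipping
    variant, where that joint exists."""
    variants = {f"v{v.mature_length}": v for v in cnot2.variants}
    circles = {
        name: extract_mature_sequence(fixture_set.genome, cnot2.locus, v)
        for name, v in variants.items()
    }
    skip_joint = circles["v266"].seq[143 - 5: 143 + 5]
    motif = IupacMotif(name="joint", pattern=skip_joint)
    hits = {name: scan_rbp_motifs(c, [motif]) for name, c in circles.items()}
    res = diff_sites(hits, variants)
    assert res.table.loc["joint", "v266"] == 1
    assert res.table.loc["joint", "v490"] == 0
    assert res.table.loc["joint", "v324"] == 0


def test_diff_sites_rejects_mismatched_junctions(fixture_set, cnot2, mapk9):
    va = cnot2.variants[1]
    vb = mapk9.variants[1]
    with pytest.raises(CircRcaError, match="junction"):
        diff_sites({"a": [], "b": []}, {"a": va, "b": vb})
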