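"""Synthetic-data engine for the circRNA rolling-circle workflow.

This module emulates, in silico, the molecular steps of circRNA-RCA:

1. **Fixture loci** — six synthetic gene loci whose exon-length structures
   match the HeLa circRNA panel this package is built around (ASPH, CNOT2,
   KDM1A, PALLD, AP3S2, MAPK9 backsplice circles), each with its
   catalogue-reported exon composition and the experimentally observed
   splice variants: a skipped internal exon, a 58-nt partial exon, and a
   241-nt novel exon placed inside an intron.  Exon/intron *sequences* are
   random (seeded); exon *lengths* are the real ones.
2. **RNase R enrichment** — a filter that keeps circular molecules and
   degrades linear ones with a configurable efficiency.
3. **Rolling-circle reverse transcription** — an RNase H-minus RT that
   traverses the circle repeatedly, producing a tandem-repeat read of
   ``floor(copies * L)`` nt with i.i.d. substitution errors (optional
   indels).
4. **PCR** — primer-site enumeration on the tandem read, producing the
   characteristic amplicon ladder (monomer, doublet, ...) of exact
   circle-length multiples for the full-length junction pair.

Reads are emitted in the sense orientation of the circle: the physical
first-strand cDNA is the reverse complement, but after PCR both strands
exist, so sense normalisation loses nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import (
    BackspliceJunction,
    CircRcaError,
    CircVariant,
    GeneLocus,
    MatureCircSequence,
    Segment,
    revcomp,
)
from .primer_design import PrimerPair

__all__ = [
    "Provenance",
    "TandemRead",
    "Molecule",
    "MoleculePool",
    "Amplicon",
    "AmpliconSet",
    "LocusFixture",
    "FixtureSet",
    "FIXTURE_PANEL_SPECS",
    "make_fixture_loci",
    "linear_counterpart",
    "simulate_rolling_circle",
    "rnase_r_filter",
    "pcr_amplify",
    "find_approx",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Provenance:
    circle_id: str
    start_phase: int
    copies: float
    seed: int
    error_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class TandemRead:
    """A linear read holding >= 1 tandem copies of a circle (sense strand)."""

    seq: str
    read_id: str = ""
    provenance: Provenance | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Molecule:
    id: str
    seq: str
    topology: str  # circular | linear

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise CircRcaError(f"bad topology {self.topology!r}")


@dataclass(frozen=True)
class MoleculePool:
    molecules: tuple[Molecule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "molecules", tuple(self.molecules))

    def __len__(self) -> int:
        return len(self.molecules)


@dataclass(frozen=True)
class Amplicon:
    length: int
    rounds: int
    seq: str
    start: int  # position of the forward primer's 5' end in the read


@dataclass(frozen=True)
class AmpliconSet:
    amplicons: tuple[Amplicon, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplicons", tuple(self.amplicons))

    def lengths(self) -> set[int]:
        return {a.length for a in self.amplicons}

    def __len__(self) -> int:
        return len(self.amplicons)


# ---------------------------------------------------------------------------
# fixture loci
# ---------------------------------------------------------------------------

# (gene, circBase id, catalogue junction id, strand, circBase exon lengths,
#  splice-variant segment specs).  Segment specs: ("exon", i),
# ("partial", i, length, "prefix"|"suffix"), ("novel", intron_index, length);
# indices are transcript-order ordinals within the junction span.
FIXTURE_PANEL_SPECS: tuple = (
    ("ASPH", "hsa_circ_0084615", "hsa_chr8_62593526_62596747_R", "-",
     (150, 45, 69),
     ((("exon", 0), ("exon", 2)),)),
    ("CNOT2", "hsa_circ_0007127", "hsa_chr12_70671911_70704797_F", "+",
     (143, 224, 123),
     ((("exon", 0), ("exon", 2)),
      (("exon", 0), ("partial", 1, 58, "suffix"), ("exon", 2)))),
    ("KDM1A", "hsa_circ_0007822", "hsa_chr1_23356961_23385660_F", "+",
     (166, 60, 134, 79, 93, 107, 82, 95),
     ((("exon", 0), ("exon", 2), ("exon", 3), ("exon", 4), ("exon", 5),
       ("exon", 6), ("exon", 7)),)),
    ("PALLD", "hsa_circ_0071410", "hsa_chr4_169812072_169837178_F", "+",
     (136, 99, 51, 222, 150, 95, 133),
     ((("exon", 0), ("exon", 1), ("exon", 3), ("exon", 4), ("exon", 5),
       ("exon", 6)),)),
    ("AP3S2", "hsa_circ_0009156", "hsa_chr15_90414706_90432372_R", "-",
     (92, 112, 119, 72),
     ((("exon", 0), ("exon", 1), ("exon", 3)),)),
    ("MAPK9", "hsa_circ_0001566", "hsa_chr5_179688683_179707608_R", "-",
     (169, 130, 59, 139),
     ((("exon", 0), ("novel", 0, 241), ("exon", 1), ("exon", 2),
       ("exon", 3)),)),
)


@dataclass(frozen=True)
class LocusFixture:
    gene: str
    circbase_id: str
    catalog_junction_id: str
    locus: GeneLocus
    junction: BackspliceJunction
    variants: tuple[CircVariant, ...]  # variants[0] = circBase composition

    @property
    def circbase_variant(self) -> CircVariant:
        return self.variants[0]

    @property
    def splice_variants(self) -> tuple[CircVariant, ...]:
        return self.variants[1:]


@dataclass(frozen=True)
class FixtureSet:
    genome: dict[str, str]
    loci: tuple[LocusFixture, ...]

    def __getitem__(self, gene: str) -> LocusFixture:
        for fx in self.loci:
            if fx.gene == gene or fx.circbase_id == gene:
                return fx
        raise KeyError(gene)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def make_fixture_loci(
    seed: int, intron_len: int = 100, flank: int = 60, novel_margin: int = 40
) -> FixtureSet:
    """Generate the six fixture loci on one synthetic chromosome each.

    Exon lengths follow the catalogue structures exactly; sequences are
    random but deterministic for a fixed seed.  Introns default to
    ``intron_len`` nt; an intron that must host a novel exon is widened to
    ``novel_len + 2*novel_margin`` so the novel segment lies strictly
    inside it.
    """
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    loci: list[LocusFixture] = []
    for gene, circ_id, catalog_id, strand, exon_lens, var_specs in FIXTURE_PANEL_SPECS:
        k = len(exon_lens)
        novel_by_intron = {
            spec[1]: spec[2]
            for segs in var_specs for spec in segs if spec[0] == "novel"
        }
        intron_lens = [
            max(intron_len, novel_by_intron[t] + 2 * novel_margin)
            if t in novel_by_intron else intron_len
            for t in range(k - 1)
        ]
        # genomic layout left-to-right; '-' strand loci are laid out with
        # transcript order running right-to-left
        t_order = list(range(k)) if strand == "+" else list(range(k))[::-1]
        pos = flank
        g_interval: dict[int, tuple[int, int]] = {}
        for j, t in enumerate(t_order):
            g_interval[t] = (pos, pos + exon_lens[t])
            pos += exon_lens[t]
            if j < k - 1:
                t_next = t_order[j + 1]
                intron_t = min(t, t_next)  # transcript intron index
                pos += intron_lens[intron_t]
        total = pos + flank
        chrom = f"chr{gene}"
        genome[chrom] = _random_seq(rng, total)

        start = flank
        end = pos
        jid = f"syn_{chrom}_{start}_{end}_{'F' if strand == '+' else 'R'}"
        junction = BackspliceJunction(id=jid, chrom=chrom, start=start,
                                      end=end, strand=strand)
        exons = tuple(g_interval[t] for t in range(k))
        locus = GeneLocus(gene=gene, chrom=chrom, strand=strand, exons=exons)
        introns = locus.introns_in_span(junction)

        def build_segment(spec) -> Segment:
            if spec[0] == "exon":
                t = spec[1]
                s, e = g_interval[t]
                return Segment(kind="exon", length=e - s, exon_index=t,
                               genomic_interval=(s, e))
            if spec[0] == "partial":
                _, t, length, which = spec
                s, e = g_interval[t]
                if (which == "suffix") == (strand == "+"):
                    gi = (e - length, e)   # transcript 3' end on '+' / 5' on '-'
                else:
                    gi = (s, s + length)
                return Segment(kind="partial_exon", length=length, exon_index=t,
                               genomic_interval=gi, partial_end=which)
            if spec[0] == "novel":
                _, intron_t, length = spec
                isv, iev = introns[intron_t]
                off = (iev - isv - length) // 2
                return Segment(kind="novel_exon", length=length,
                               genomic_interval=(isv + off, isv + off + length))
            raise CircRcaError(f"unknown segment spec {spec!r}")

        variants = [
            CircVariant(
                junction=junction,
                segments=tuple(
                    Segment(kind="exon", length=e - s, exon_index=t,
                            genomic_interval=(s, e))
                    for t, (s, e) in enumerate(exons)
                ),
            )
        ]
        for segs in var_specs:
            variants.append(
                CircVariant(junction=junction,
                            segments=tuple(build_segment(sp) for sp in segs))
            )
        variants = [
            # name carries the circBase id and the mature length
            CircVariant(junction=v.junction, segments=v.segments,
                        name=f"{circ_id}_{v.mature_length}")
            for v in variants
        ]
        loci.append(LocusFixture(
            gene=gene, circbase_id=circ_id, catalog_junction_id=catalog_id,
            locus=locus, junction=junction, variants=tuple(variants),
        ))
    return FixtureSet(genome=genome, loci=tuple(loci))


def linear_counterpart(genome: dict[str, str], locus: GeneLocus) -> str:
    """Spliced linear mRNA of the locus: all annotated exons in transcript
    order (the molecule RNase R degrades and junction primers cannot
    amplify)."""
    parts = []
    for s, e in locus.exons:
        piece = genome[locus.chrom][s:e]
        if locus.strand == "-":
            piece = revcomp(piece)
        parts.append(piece)
    return "".join(parts)


# ---------------------------------------------------------------------------
# rolling-circle reverse transcription
# ---------------------------------------------------------------------------

def simulate_rolling_circle(
    circ: MatureCircSequence,
    copies: float,
    start_phase: int = 0,
    error_rate: float = 0.0,
    seed: int = 0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    read_id: str = "",
) -> TandemRead:
    """Simulate an RNase H-minus RT traversing the circle ``copies`` times.

    The error-free read is ``floor(copies * L)`` nt of the infinite periodic
    extension of the circle starting at ``start_phase``.  Substitutions are
    drawn i.i.d. per base at ``error_rate`` (uniform over the three
    alternative bases); optional ``ins_rate``/``del_rate`` add per-base
    indels for stress-testing the consensus stage.
    """
    L = circ.length
    if copies <= 0:
        raise CircRcaError(f"copies must be > 0, got {copies}")
    if not (0 <= error_rate < 0.5):
        raise CircRcaError(f"error_rate must be in [0, 0.5), got {error_rate}")
    if not (0 <= start_phase < L):
        raise CircRcaError(f"start_phase must be in [0, {L}), got {start_phase}")
    n = math.floor(copies * L)
    reps = math.ceil((start_phase + n) / L) + 1
    arr = np.frombuffer((circ.seq * reps).encode(), dtype=np.uint8)[
        start_phase: start_phase + n
    ].copy()

    rng = np.random.default_rng(seed)
    err_pos: tuple[int, ...] = ()
    if error_rate > 0:
        hits = np.nonzero(rng.random(n) < error_rate)[0]
        # substitute with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(idx + shift) % 4]
        err_pos = tuple(int(i) for i in hits)
    seq = arr.tobytes().decode()
    if ins_rate > 0 or del_rate > 0:
        out = []
        for ch in seq:
            if del_rate > 0 and rng.random() < del_rate:
                continue
            out.append(ch)
            if ins_rate > 0 and rng.random() < ins_rate:
                out.append("ACGT"[rng.integers(0, 4)])
        seq = "".join(out)
    return TandemRead(
        seq=seq,
        read_id=read_id or f"{circ.circ_id}_read",
        provenance=Provenance(circle_id=circ.circ_id, start_phase=start_phase,
                              copies=copies, seed=seed, error_positions=err_pos),
    )


# ---------------------------------------------------------------------------
# RNase R enrichment
# ---------------------------------------------------------------------------

def rnase_r_filter(
    pool: MoleculePool, efficiency: float = 1.0, seed: int = 0
) -> MoleculePool:
    """Digest linear molecules; circles always survive.

    Each linear molecule is retained with probability ``1 - efficiency``
    (efficiency 1.0 = complete digestion, 0.0 = no digestion).
    """
    rng = np.random.default_rng(seed)
    kept = [
        m for m in pool.molecules
        if m.topology == "circular" or rng.random() >= efficiency
    ]
    return MoleculePool(molecules=tuple(kept))


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def find_approx(text: str, pattern: str, max_mismatch: int = 0) -> list[int]:
    """Start positions of Hamming-distance <= max_mismatch occurrences."""
    n, m = len(text), len(pattern)
    if m == 0 or m > n:
        return []
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = (windows != p).sum(axis=1)
    return [int(i) for i in np.nonzero(mism <= max_mismatch)[0]]


def pcr_amplify(
    read: TandemRead,
    pair: PrimerPair,
    max_rounds: int = 3,
    max_mismatch: int = 0,
) -> AmpliconSet:
    """Enumerate amplicons of ``pair`` on a tandem-repeat read.

    Forward-primer occurrences are searched on the sense read; reverse-primer
    binding sites are sense stretches whose reverse complement matches the
    reverse primer.  Each (forward occurrence, k-th downstream reverse
    occurrence) pair with k <= max_rounds yields one amplicon; for the
    full-length junction pair on an error-free read, amplicon lengths are
    exact multiples of the circle length (the monomer/doublet ladder seen on
    a gel).  No binding site for either primer yields an empty set.
    """
    if len(pair.forward_seq) >= len(read.seq) or len(pair.reverse_seq) >= len(read.seq):
        raise CircRcaError("primers must be shorter than the read")
    fwd_occ = find_approx(read.seq, pair.forward_seq, max_mismatch)
    rev_site = revcomp(pair.reverse_seq)
    rev_occ = find_approx(read.seq, rev_site, max_mismatch)
    m_rev = len(rev_site)
    amplicons: list[Amplicon] = []
    for f in fwd_occ:
        downstream = [r for r in rev_occ if r >= f + len(pair.forward_seq)]
        for k, r in enumerate(downstream[:max_rounds], start=1):
            end = r + m_rev
            amplicons.append(
                Amplicon(length=end - f, rounds=k, seq=read.seq[f:end], start=f)
            )
    return AmpliconSet(amplicons=tuple(amplicons))
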