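"""Domain types and I/O for circRNA backsplice junctions and mature sequences.

A circRNA is identified by its backsplice junction — the covalent joint
between a downstream exon's 3' end (the donor) and an upstream exon's 5'
start (the acceptor).  Catalogue-style junction identifiers such as
``hsa_chr12_70671911_70704797_F`` encode species, chromosome, the genomic
span between the two backsplice coordinates, and the strand (F/R).  The
mature spliced sequence of the circle is the concatenation of the exonic
(and occasionally unannotated) segments actually retained between those
coordinates, which alternative splicing can vary while the junction stays
fixed.

Coordinates are handled internally in the BED convention: 0-based start,
exclusive end.  Junction identifiers are assumed to use the same convention
(the circBase one); a ``one_based`` flag on the parser accommodates tables
that print 1-based starts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircRcaError",
    "ParseError",
    "BackspliceJunction",
    "GeneLocus",
    "Segment",
    "CircVariant",
    "MatureCircSequence",
    "parse_junction_id",
    "extract_mature_sequence",
    "revcomp",
    "read_genome_fasta",
    "read_fasta",
    "write_fasta",
    "read_exons_bed12",
    "read_exons_gtf",
    "read_exons",
    "write_tsv",
    "junction_table",
]


class CircRcaError(Exception):
    """Base class for all data/validation errors raised by this package."""


class ParseError(CircRcaError):
    """Malformed identifier or annotation record."""


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters tolerated)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackspliceJunction:
    """Genomic coordinates and strand of a circRNA's backsplice junction.

    ``start``/``end`` are 0-based half-open; the span ``end - start`` is the
    genomic footprint between the backsplice acceptor and donor coordinates,
    not the mature circle length.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParseError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ParseError(
                f"junction {self.id!r}: need 0 <= start < end, "
                f"got start={self.start}, end={self.end}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneLocus:
    """Ordered exon intervals of a parent pre-mRNA.

    ``exons`` are 0-based half-open genomic intervals in transcript (5'→3')
    order: ascending genomic order on '+', descending on '-'.
    """

    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParseError(f"locus {self.gene}: bad strand {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if not (0 <= s < e):
                raise ParseError(f"locus {self.gene}: bad exon interval ({s}, {e})")
        genomic = sorted(exons)
        expected = tuple(genomic) if self.strand == "+" else tuple(genomic[::-1])
        if exons != expected:
            raise ParseError(
                f"locus {self.gene}: exons not in transcript order for strand "
                f"{self.strand}"
            )
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ParseError(
                    f"locus {self.gene}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )

    def exons_in_span(self, junction: BackspliceJunction) -> tuple[tuple[int, int], ...]:
        """Exons fully contained in the junction span, transcript order."""
        return tuple(
            (s, e) for s, e in self.exons
            if s >= junction.start and e <= junction.end
        )

    def introns_in_span(self, junction: BackspliceJunction) -> tuple[tuple[int, int], ...]:
        """Intronic gaps between consecutive in-span exons, transcript order."""
        exons = self.exons_in_span(junction)
        out = []
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return tuple(out)


@dataclass(frozen=True)
class Segment:
    """One building block of a mature circRNA: a full annotated exon, a
    truncated (partial) exon, an unannotated (novel) exon, or an unmapped
    stretch."""

    kind: str  # exon | partial_exon | novel_exon | unmapped
    length: int
    exon_index: int | None = None          # ordinal within the junction span
    genomic_interval: tuple[int, int] | None = None
    partial_end: str | None = None         # 'prefix' | 'suffix' for partial_exon

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "partial_exon", "novel_exon", "unmapped"):
            raise CircRcaError(f"unknown segment kind {self.kind!r}")
        if self.length < 1:
            raise CircRcaError(f"segment length must be >= 1, got {self.length}")
        if self.genomic_interval is not None:
            s, e = self.genomic_interval
            if e - s != self.length:
                raise CircRcaError(
                    f"segment interval ({s},{e}) inconsistent with length {self.length}"
                )


@dataclass(frozen=True)
class CircVariant:
    """An ordered list of segments defining one mature splice variant of a
    backsplice junction."""

    junction: BackspliceJunction
    segments: tuple[Segment, ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise CircRcaError("variant needs at least one segment")

    @property
    def mature_length(self) -> int:
        return sum(s.length for s in self.segments)

    def composition(self) -> str:
        """Compact composition string, e.g. ``E1+E2p58+E3`` or ``E1+N241+E2``.

        Exon ordinals are 1-based within the junction span.
        """
        parts = []
        for s in self.segments:
            if s.kind == "exon":
                parts.append(f"E{s.exon_index + 1}")
            elif s.kind == "partial_exon":
                parts.append(f"E{s.exon_index + 1}p{s.length}")
            elif s.kind == "novel_exon":
                parts.append(f"N{s.length}")
            else:
                parts.append(f"U{s.length}")
        return "+".join(parts)


@dataclass(frozen=True)
class MatureCircSequence:
    """A mature circRNA sequence in its canonical rotation.

    Position 0 is the first base of the backsplice acceptor exon (the
    5'-most exon in transcript orientation), so two circles are equal iff
    their anchored strings are equal.
    """

    seq: str
    circ_id: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise CircRcaError("empty mature sequence")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)

    def rotate(self, offset: int) -> str:
        """Linear string starting at circle coordinate ``offset``."""
        k = offset % self.length
        return self.seq[k:] + self.seq[:k]

    def is_rotation_of(self, other: "MatureCircSequence") -> bool:
        return len(self.seq) == len(other.seq) and self.seq in other.seq + other.seq

    def junction_kmer(self, span: int = 10) -> str:
        """2*span-mer centred on the backsplice junction (donor side then
        acceptor side)."""
        if self.length < 2 * span:
            raise CircRcaError(
                f"circle of {self.length} nt too short for a {2 * span}-nt junction k-mer"
            )
        return self.seq[-span:] + self.seq[:span]


# ---------------------------------------------------------------------------
# junction identifier parsing
# ---------------------------------------------------------------------------

_JUNCTION_RE = re.compile(
    r"^(?P<species>[^_]+)_(?P<chrom>.+)_(?P<start>\d+)_(?P<end>\d+)_(?P<fr>[FR])$"
)


def parse_junction_id(junction_id: str, one_based: bool = False) -> BackspliceJunction:
    """Parse a junction identifier like ``hsa_chr12_70671911_70704797_F``.

    ``F``/``R`` map to genomic strand '+'/'-'.  Coordinates are taken as
    0-based half-open by default (circBase/BED convention); pass
    ``one_based=True`` for tables with 1-based inclusive starts.
    """
    m = _JUNCTION_RE.match(junction_id.strip())
    if m is None:
        raise ParseError(
            f"junction id {junction_id!r} does not match "
            "species_chrom_start_end_{F|R}"
        )
    start = int(m.group("start"))
    end = int(m.group("end"))
    if one_based:
        start -= 1
    if start >= end:
        raise ParseError(
            f"junction id {junction_id!r}: empty or inverted span "
            f"(start={start}, end={end})"
        )
    strand = "+" if m.group("fr") == "F" else "-"
    return BackspliceJunction(
        id=junction_id.strip(), chrom=m.group("chrom"),
        start=start, end=end, strand=strand,
    )


# ---------------------------------------------------------------------------
# mature sequence extraction
# ---------------------------------------------------------------------------

def _clean_bases(seq: str, context: str) -> str:
    if re.fullmatch(r"[ACGT]*", seq) is None:
        warnings.warn(
            f"{context}: non-ACGT characters replaced with N", stacklevel=3
        )
        seq = re.sub(r"[^ACGT]", "N", seq)
    return seq


def extract_mature_sequence(
    genome: Mapping[str, str],
    locus: GeneLocus,
    variant: CircVariant,
) -> MatureCircSequence:
    """Build the mature circle sequence for ``variant`` from the genome.

    Segments are concatenated in transcript order; on the '-' strand each
    segment is reverse-complemented (transcript order being descending
    genomic order).  The result is anchored at the backsplice acceptor, so
    its length equals the variant's mature length.
    """
    if locus.chrom not in genome:
        raise CircRcaError(f"chromosome {locus.chrom!r} not in genome store")
    chrom_seq = genome[locus.chrom]
    junction = variant.junction
    parts: list[str] = []
    for seg in variant.segments:
        if seg.genomic_interval is None:
            raise CircRcaError(
                f"segment of kind {seg.kind!r} has no genomic interval; "
                "cannot extract sequence"
            )
        s, e = seg.genomic_interval
        if s < junction.start or e > junction.end:
            raise CircRcaError(
                f"segment ({s},{e}) outside junction span "
                f"[{junction.start},{junction.end})"
            )
        piece = chrom_seq[s:e].upper()
        if locus.strand == "-":
            piece = revcomp(piece)
        parts.append(piece)
    seq = _clean_bases("".join(parts), f"variant {variant.name or junction.id}")
    return MatureCircSequence(seq=seq, circ_id=variant.name or junction.id)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a plain chrom -> uppercase-sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA records as (id, description, sequence) tuples."""
    return [
        (rec.id, rec.description, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str] | tuple[str, str, str]]) -> None:
    """Write (id, seq) or (id, description, seq) tuples as FASTA."""
    out = []
    for rec in records:
        if len(rec) == 2:
            rid, seq = rec
            desc = ""
        else:
            rid, desc, seq = rec
        out.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# exon annotation (BED12 / GTF)
# ---------------------------------------------------------------------------

def read_exons_bed12(path: str | Path) -> list[GeneLocus]:
    """Read one locus per BED12 line; blocks become exons (0-based half-open)."""
    loci = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
        chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
        block_count = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != block_count or len(starts) != block_count:
            raise ParseError(
                f"{path}:{lineno}: blockCount={block_count} but "
                f"{len(sizes)} blockSizes / {len(starts)} blockStarts"
            )
        exons = [(chrom_start + st, chrom_start + st + sz)
                 for st, sz in zip(starts, sizes)]
        if exons != sorted(exons):
            raise ParseError(f"{path}:{lineno}: BED12 blocks not sorted")
        if strand == "-":
            exons = exons[::-1]
        loci.append(GeneLocus(gene=name, chrom=chrom, strand=strand,
                              exons=tuple(exons)))
    return loci


def read_exons_gtf(path: str | Path) -> list[GeneLocus]:
    """Read exon features from a GTF file, one locus per gene.

    GTF coordinates are 1-based inclusive and converted to 0-based half-open
    on read.  Gene identity is taken from the ``gene_name`` attribute,
    falling back to ``gene_id``.
    """
    by_gene: dict[str, dict] = {}
    attr_re = re.compile(r'(\w+) "([^"]*)"')
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ParseError(f"{path}:{lineno}: GTF needs 9 columns")
        if f[2] != "exon":
            continue
        chrom, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
        attrs = dict(attr_re.findall(f[8]))
        gene = attrs.get("gene_name") or attrs.get("gene_id")
        if gene is None:
            raise ParseError(f"{path}:{lineno}: exon without gene_name/gene_id")
        rec = by_gene.setdefault(gene, {"chrom": chrom, "strand": strand, "exons": []})
        if rec["chrom"] != chrom:
            raise ParseError(
                f"{path}:{lineno}: gene {gene} spans chromosomes "
                f"{rec['chrom']} and {chrom} (mixed chromosome naming?)"
            )
        rec["exons"].append((start, end))
    loci = []
    for gene, rec in by_gene.items():
        exons = sorted(rec["exons"])
        if rec["strand"] == "-":
            exons = exons[::-1]
        loci.append(GeneLocus(gene=gene, chrom=rec["chrom"],
                              strand=rec["strand"], exons=tuple(exons)))
    return loci


def read_exons(path: str | Path) -> list[GeneLocus]:
    """Dispatch on extension: .bed -> BED12, .gtf/.gff -> GTF."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_exons_bed12(path)
    if suffix in (".gtf", ".gff"):
        return read_exons_gtf(path)
    raise ParseError(f"unrecognised annotation extension {suffix!r}")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def junction_table(junctions: Sequence[BackspliceJunction]) -> pd.DataFrame:
    """Tabulate junctions with columns id, chrom, start, end, strand."""
    return pd.DataFrame(
        [
            {"id": j.id, "chrom": j.chrom, "start": j.start,
             "end": j.end, "strand": j.strand}
            for j in junctions
        ],
        columns=["id", "chrom", "start", "end", "strand"],
    )
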