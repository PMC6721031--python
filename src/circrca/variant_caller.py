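"""Exon-composition calling for circular consensus sequences.

Given a parent locus annotation and a junction-anchored consensus circle,
this module resolves which annotated exons the circle contains, whether any
of them is truncated (alternative 5'/3' splice site -> partial exon), and
whether the circle carries unannotated sequence found inside an intron of
the locus (novel exon).  It also enumerates the combinatorial space of
exon-skipping variants compatible with a backsplice junction (first and
last in-span exons fixed, internal exons free) and matches observed
amplicon lengths against them, flagging doublet (two-rotation) products.

Matching is exact by default — a circular consensus is expected to be
error-free — with an optional per-segment mismatch fraction for calling
directly on raw reads.  Chaining is greedy left-to-right in transcript
order; since segments are exact exon substrings this is sufficient, and a
full spliced-alignment DP is deliberately avoided.
"""

from __future__ import annotations

import itertools
import warnings
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

__all__ = [
    "LengthMatches",
    "enumerate_variants",
    "assign_exons",
    "match_length_to_variants",
]

# shortest stretch accepted as a partial-exon or novel-exon match; guards
# against chance matches of a few bases in random/repetitive sequence
MIN_PARTIAL = 12
MIN_NOVEL = 20


@dataclass(frozen=True)
class LengthMatches:
    """Candidates compatible with an observed amplicon length: direct
    (monomer) matches and doublet interpretations (observed ~ 2x mature)."""

    matches: tuple[CircVariant, ...]
    doublets: tuple[CircVariant, ...]


def enumerate_variants(
    locus: GeneLocus, junction: BackspliceJunction
) -> list[CircVariant]:
    """All exon-skipping compositions for a junction, sorted by length.

    The first and last in-span exons are fixed (they form the backsplice);
    each of the k-2 internal exons is independently kept or skipped, giving
    2^(k-2) ordered compositions (one when k <= 2).
    """
    exons = locus.exons_in_span(junction)
    k = len(exons)
    if k == 0:
        raise CircRcaError(
            f"no annotated exon of {locus.gene} lies inside junction "
            f"[{junction.start},{junction.end})"
        )
    internal = list(range(1, k - 1))
    variants = []
    for keep in itertools.product((True, False), repeat=len(internal)):
        idxs = [0] + [j for j, kp in zip(internal, keep) if kp] + ([k - 1] if k > 1 else [])
        segments = tuple(
            Segment(kind="exon", length=exons[j][1] - exons[j][0],
                    exon_index=j, genomic_interval=exons[j])
            for j in idxs
        )
        variants.append(CircVariant(junction=junction, segments=segments))
    variants.sort(key=lambda v: (v.mature_length, v.composition()))
    return variants


# ---------------------------------------------------------------------------
# exon assignment
# ---------------------------------------------------------------------------

def _transcript_seq(genome: dict[str, str], chrom: str, strand: str,
                    interval: tuple[int, int]) -> str:
    s, e = interval
    piece = genome[chrom][s:e].upper()
    return revcomp(piece) if strand == "-" else piece


def _ham_ok(a: str, b: str, max_frac: float) -> bool:
    if len(a) != len(b):
        return False
    if max_frac <= 0:
        return a == b
    allowed = int(max_frac * len(a))
    mism = np.count_nonzero(
        np.frombuffer(a.encode(), np.uint8) != np.frombuffer(b.encode(), np.uint8)
    )
    return mism <= allowed


def _partial_interval(exon: tuple[int, int], strand: str, which: str,
                      t: int) -> tuple[int, int]:
    """Genomic interval of a t-nt transcript prefix/suffix of an exon."""
    s, e = exon
    if (which == "prefix") == (strand == "+"):
        return (s, s + t)
    return (e - t, e)


def assign_exons(
    consensus: MatureCircSequence,
    genome: dict[str, str],
    locus: GeneLocus,
    junction: BackspliceJunction,
    max_mismatch_frac: float = 0.0,
) -> CircVariant:
    """Greedy left-to-right decomposition of a consensus into segments.

    The consensus must be anchored at the backsplice acceptor (position 0 =
    first base of the 5'-most in-span exon); otherwise a rotation-mismatch
    error is raised.  At each position the caller tries, in order: a full
    annotated exon (earliest transcript position on ties, with a warning),
    the longest transcript prefix/suffix of an exon (partial exon), the
    longest exact substring of an in-span intron (novel exon, with genomic
    coordinates), and finally an unmapped stretch up to the next full-exon
    resync.  Exon order in the call is strictly increasing, and segment
    lengths always sum to the consensus length.
    """
    exons = locus.exons_in_span(junction)
    k = len(exons)
    if k == 0:
        raise CircRcaError("no annotated exon in junction span")
    exon_seqs = [_transcript_seq(genome, locus.chrom, locus.strand, ex)
                 for ex in exons]
    introns = locus.introns_in_span(junction)
    intron_seqs = [_transcript_seq(genome, locus.chrom, locus.strand, iv)
                   for iv in introns]
    text = consensus.seq
    Lc = len(text)

    probe = min(10, len(exon_seqs[0]), Lc)
    if not _ham_ok(text[:probe], exon_seqs[0][:probe], max_mismatch_frac):
        raise CircRcaError(
            "rotation mismatch: consensus does not start at the backsplice "
            f"acceptor exon of {locus.gene}"
        )

    def full_exon_at(i: int, j_min: int) -> int | None:
        hits = [
            j for j in range(j_min, k)
            if len(exon_seqs[j]) <= Lc - i
            and _ham_ok(text[i:i + len(exon_seqs[j])], exon_seqs[j],
                        max_mismatch_frac)
        ]
        if len(hits) > 1:
            warnings.warn(
                f"{locus.gene}: position {i} matches exons {hits}; "
                "keeping the earliest", stacklevel=3
            )
        return hits[0] if hits else None

    segments: list[Segment] = []
    i, j_min = 0, 0
    while i < Lc:
        remaining = Lc - i
        j = full_exon_at(i, j_min)
        if j is not None:
            segments.append(Segment(kind="exon", length=len(exon_seqs[j]),
                                    exon_index=j, genomic_interval=exons[j]))
            i += len(exon_seqs[j])
            j_min = j + 1
            continue

        # partial exon: longest transcript prefix or suffix of an exon
        best = None  # (t, j, which)
        for j2 in range(j_min, k):
            es = exon_seqs[j2]
            for t in range(min(len(es) - 1, remaining), MIN_PARTIAL - 1, -1):
                if best is not None and t <= best[0]:
                    break
                if _ham_ok(text[i:i + t], es[:t], max_mismatch_frac):
                    best = (t, j2, "prefix")
                    break
                if _ham_ok(text[i:i + t], es[-t:], max_mismatch_frac):
                    best = (t, j2, "suffix")
                    break
        if best is not None:
            t, j2, which = best
            segments.append(Segment(
                kind="partial_exon", length=t, exon_index=j2,
                genomic_interval=_partial_interval(exons[j2], locus.strand,
                                                   which, t),
                partial_end=which,
            ))
            i += t
            j_min = j2 + 1
            continue

        # novel exon: longest exact substring of an in-span intron
        best_nov = None  # (m, intron_idx, offset_in_intron_transcript)
        for ti in range(max(j_min - 1, 0), k - 1):
            iseq = intron_seqs[ti]
            lo, hi = MIN_NOVEL, min(len(iseq), remaining)
            if lo > hi:
                continue
            # containment is monotone in m: binary-search the longest match
            m_best, pos_best = None, None
            while lo <= hi:
                mid = (lo + hi) // 2
                pos = iseq.find(text[i:i + mid])
                if pos >= 0:
                    m_best, pos_best = mid, pos
                    lo = mid + 1
                else:
                    hi = mid - 1
            if m_best is not None and (best_nov is None or m_best > best_nov[0]):
                best_nov = (m_best, ti, pos_best)
        if best_nov is not None:
            m, ti, pos = best_nov

            def exon_resumes(pos2: int) -> bool:
                if pos2 == Lc:
                    return True
                return any(
                    len(exon_seqs[j2]) <= Lc - pos2
                    and _ham_ok(text[pos2:pos2 + len(exon_seqs[j2])],
                                exon_seqs[j2], max_mismatch_frac)
                    for j2 in range(j_min, k)
                )

            # the longest intron match can overshoot by a few coincidental
            # bases; trim until an annotated exon resumes right after it
            m_try = m
            while m_try > MIN_NOVEL and not exon_resumes(i + m_try):
                m_try -= 1
            if exon_resumes(i + m_try):
                m = m_try
                pos = intron_seqs[ti].find(text[i:i + m])
            iv_s, iv_e = introns[ti]
            if locus.strand == "+":
                gi = (iv_s + pos, iv_s + pos + m)
            else:
                gi = (iv_e - pos - m, iv_e - pos)
            segments.append(Segment(kind="novel_exon", length=m,
                                    genomic_interval=gi))
            i += m
            j_min = max(j_min, ti + 1)
            continue

        # unmapped: advance to the next position where a full exon resyncs
        start = i
        i += 1
        while i < Lc and full_exon_at(i, j_min) is None:
            i += 1
        segments.append(Segment(kind="unmapped", length=i - start))

    return CircVariant(junction=junction, segments=tuple(segments),
                       name=consensus.circ_id)


def match_length_to_variants(
    observed_len: int,
    candidates: list[CircVariant],
    tol_frac: float = 0.05,
) -> LengthMatches:
    """Candidates whose mature length explains an observed amplicon length.

    Direct matches satisfy ``|mature - observed| <= tol_frac * observed``;
    doublets satisfy the same with ``2 * mature`` (two full rotations of the
    circle amplified as one product).  An empty result is a valid outcome.
    """
    if not candidates:
        raise CircRcaError("candidate list is empty")
    tol = tol_frac * observed_len
    matches = tuple(v for v in candidates
                    if abs(v.mature_length - observed_len) <= tol)
    doublets = tuple(v for v in candidates
                     if abs(2 * v.mature_length - observed_len) <= tol)
    return LengthMatches(matches=matches, doublets=doublets)
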