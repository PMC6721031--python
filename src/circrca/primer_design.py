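"""Primer design for circRNA amplification.

Two geometries are supported, both defined on the mature circle in its
canonical (acceptor-anchored) rotation:

* **full-length** — the rolling-circle pair: a forward primer straddling the
  backsplice junction (``span`` nt on each side of it) and a reverse primer
  placed exactly upstream so that its footprint abuts the forward footprint.
  On a tandem-repeat cDNA this pair yields an amplicon ladder whose lengths
  are exact multiples of the circle length (monomer, doublet, ...).

* **divergent** — a conventional junction-detection pair: both primers lie
  inside the mature sequence and point away from each other on the linear
  exonic sequence, so only a circular (junction-containing) template yields
  a product, which necessarily spans the junction.

Primer sequences are reported on the sense strand of the mature circle
(forward) and its reverse complement (reverse).  No thermodynamic
optimisation is attempted beyond simple GC/Tm summaries: the point of these
designs is geometric correctness, not oligo QC.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core_io import CircRcaError, MatureCircSequence, revcomp

__all__ = [
    "PrimerPair",
    "design_full_length_primers",
    "design_divergent_primers",
    "predicted_amplicon",
    "primer_stats",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class PrimerPair:
    """A designed primer pair with footprints in circle coordinates.

    Footprints are tuples of half-open intervals; a junction-spanning
    footprint is split into its pre-wrap and post-wrap pieces, e.g.
    ``((256, 266), (0, 10))`` on a 266-nt circle.
    """

    kind: str  # full_length | divergent
    forward_seq: str
    reverse_seq: str
    forward_footprint: tuple[Interval, ...]
    reverse_footprint: tuple[Interval, ...]
    junction_offset: int        # nt of forward primer 5' of the junction
    product_len: int            # monomer product length on the circle
    circ_id: str = ""


def _check_window(seq: str, what: str) -> None:
    bad = [i for i, b in enumerate(seq) if b not in "ACGT"]
    if bad:
        raise CircRcaError(f"non-ACGT bases in {what} window at positions {bad}")


def design_full_length_primers(
    circ: MatureCircSequence, span: int = 10, rev_len: int = 20
) -> PrimerPair:
    """Design the rolling-circle full-length pair.

    The forward primer is the sense 2*span-mer across the backsplice
    junction (``span`` nt of the donor exon's 3' end followed by ``span`` nt
    of the acceptor exon's 5' start); the reverse primer is the reverse
    complement of the ``rev_len`` nt immediately upstream, so its footprint
    ends exactly where the forward footprint begins.  One full PCR round of
    this pair copies one complete rotation of the circle, hence the monomer
    product length equals the circle length.
    """
    L = circ.length
    if L < 2 * span + rev_len:
        raise CircRcaError(
            f"circle of {L} nt too short for span={span}, rev_len={rev_len} "
            f"(needs >= {2 * span + rev_len})"
        )
    forward = circ.seq[L - span:] + circ.seq[:span]
    rev_window = circ.seq[L - span - rev_len: L - span]
    _check_window(forward, "forward primer")
    _check_window(rev_window, "reverse primer")
    return PrimerPair(
        kind="full_length",
        forward_seq=forward,
        reverse_seq=revcomp(rev_window),
        forward_footprint=((L - span, L), (0, span)),
        reverse_footprint=((L - span - rev_len, L - span),),
        junction_offset=span,
        product_len=L,
        circ_id=circ.circ_id,
    )


def design_divergent_primers(
    circ: MatureCircSequence,
    product_len_range: tuple[int, int] = (60, 120),
    primer_len: int = 20,
) -> PrimerPair:
    """Design a divergent pair whose circular amplicon spans the junction.

    The amplicon runs from the forward primer's 5' end, through the
    backsplice junction (circle position 0), to the reverse footprint's end.
    Placement takes the largest feasible product length in
    ``product_len_range`` and splits it symmetrically around the junction,
    maximising both primers' distance from the junction.
    """
    L = circ.length
    lo, hi = product_len_range
    feas_lo, feas_hi = 2 * primer_len, L - 1
    if lo > hi or hi >= L or lo < 2 * primer_len:
        raise CircRcaError(
            f"infeasible product length range ({lo}, {hi}) for a {L}-nt "
            f"circle with {primer_len}-nt primers; tightest feasible range "
            f"is ({feas_lo}, {feas_hi})"
        )
    product = min(hi, feas_hi)
    upstream = (product + 1) // 2          # amplicon nt 5' of the junction
    downstream = product - upstream        # amplicon nt 3' of the junction
    f_start = L - upstream
    r_end = downstream
    r_start = r_end - primer_len
    forward = circ.seq[f_start: f_start + primer_len]
    rev_window = circ.seq[r_start: r_end]
    _check_window(forward, "forward primer")
    _check_window(rev_window, "reverse primer")
    return PrimerPair(
        kind="divergent",
        forward_seq=forward,
        reverse_seq=revcomp(rev_window),
        forward_footprint=((f_start, f_start + primer_len),),
        reverse_footprint=((r_start, r_end),),
        junction_offset=upstream,
        product_len=product,
        circ_id=circ.circ_id,
    )


def predicted_amplicon(circ: MatureCircSequence, pair: PrimerPair) -> str:
    """Sense sequence of the monomer amplicon predicted for ``pair``.

    For a full-length pair this is one full rotation of the circle starting
    at the forward primer; for a divergent pair it is the junction-spanning
    stretch from the forward primer start to the reverse footprint end.
    """
    f_start = pair.forward_footprint[0][0]
    return circ.rotate(f_start)[: pair.product_len]


def primer_stats(primer: str) -> tuple[float, float]:
    """GC fraction and melting temperature of a primer.

    Tm uses the Wallace rule ``2(A+T) + 4(G+C)`` up to 13 nt and the
    length-corrected formula ``64.9 + 41*(G+C-16.4)/len`` above that.
    """
    if not primer or re.fullmatch(r"[ACGT]+", primer) is None:
        raise CircRcaError(f"primer must be non-empty ACGT, got {primer!r}")
    n = len(primer)
    gc = sum(primer.count(b) for b in "GC")
    at = n - gc
    if n <= 13:
        tm = 2.0 * at + 4.0 * gc
    else:
        tm = 64.9 + 41.0 * (gc - 16.4) / n
    return gc / n, tm
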