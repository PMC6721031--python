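"""Circular consensus from tandem-repeat reads.

A rolling-circle read is (noise aside) a periodic string whose fundamental
period is the mature circle length.  Deconvolution runs in two steps:

* **period estimation** — with a known junction k-mer, the period is the
  modal distance between successive k-mer occurrences; without one, it is
  found by self-comparison: the smallest shift ``s`` at which the read
  agrees with itself (match fraction of ``read[:-s]`` vs ``read[s:]``) at
  least as well as any other qualifying shift.  The 0.8 match-fraction
  floor tolerates ~2% per-base error on both arms of the comparison with
  margin; the default 50-nt lower bound excludes implausibly short units.

* **consensus voting** — bases at positions congruent modulo the period are
  stacked and majority-voted per column (partial terminal copies vote only
  where they cover).  Ties go to the earliest copy and flag the column
  ambiguous.  In indel mode the whole read is first aligned (exact edit
  alignment) to a tandem repetition of its first copy, and votes are cast
  per reference column instead of per residue index.

When a junction k-mer is supplied the consensus is rotated so that position
0 is the first base on the acceptor side of the backsplice junction, making
consensus circles directly comparable to anchored mature sequences.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import edlib
import numpy as np

from .core_io import CircRcaError, MatureCircSequence
from .rca_simulator import TandemRead, find_approx

__all__ = [
    "PeriodEstimate",
    "ConsensusResult",
    "estimate_period",
    "build_consensus",
    "reconstruct",
    "FLAG_NO_PERIOD",
    "FLAG_INSUFFICIENT",
]

FLAG_NO_PERIOD = "no-period"
FLAG_INSUFFICIENT = "insufficient"
FLAG_JUNCTION_NOT_FOUND = "junction-not-found"
FLAG_AMBIGUOUS = "ambiguous-columns"
FLAG_LOW_COVERAGE = "low-coverage-columns"


@dataclass(frozen=True)
class PeriodEstimate:
    period: int | None
    flag: str  # 'ok' | 'no-period' | 'insufficient'
    match_fraction: float = float("nan")

    @property
    def ok(self) -> bool:
        return self.flag == "ok"


@dataclass(frozen=True)
class ConsensusResult:
    consensus: MatureCircSequence | None
    period: int | None
    n_full_copies: int
    per_column_agreement: np.ndarray | None
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return self.consensus is not None

    @property
    def mean_agreement(self) -> float:
        if self.per_column_agreement is None:
            return float("nan")
        return float(np.mean(self.per_column_agreement))


# ---------------------------------------------------------------------------
# period estimation
# ---------------------------------------------------------------------------

def _modal_gap(positions: list[int]) -> int:
    gaps: dict[int, int] = {}
    for a, b in zip(positions, positions[1:]):
        gaps[b - a] = gaps.get(b - a, 0) + 1
    # modal gap; ties broken toward the smallest gap
    return min(gaps, key=lambda g: (-gaps[g], g))


def estimate_period(
    read: TandemRead,
    junction_kmer: str | None = None,
    min_period: int = 50,
    min_fraction: float = 0.8,
    kmer_mismatch: int = 1,
) -> PeriodEstimate:
    """Estimate the tandem-repeat period of a read.

    With ``junction_kmer`` (the 2*span junction-spanning k-mer), the period
    is the modal spacing of its occurrences (allowing ``kmer_mismatch``
    mismatches per occurrence).  Otherwise the read is compared against
    itself at every shift in ``[min_period, len/2]``; among shifts whose
    match fraction reaches ``min_fraction``, the smallest shift within 0.02
    of the best fraction is returned, which prefers the fundamental period
    over its multiples.  Failure modes are reported as flags, not raised.
    """
    n = len(read.seq)
    if junction_kmer is not None:
        if n < 2 * len(junction_kmer):
            return PeriodEstimate(None, FLAG_INSUFFICIENT)
        occ = find_approx(read.seq, junction_kmer.upper(), kmer_mismatch)
        if len(occ) < 2:
            return PeriodEstimate(None, FLAG_NO_PERIOD)
        return PeriodEstimate(_modal_gap(occ), "ok", 1.0)

    if n < 2 * min_period:
        return PeriodEstimate(None, FLAG_INSUFFICIENT)
    arr = np.frombuffer(read.seq.encode(), dtype=np.uint8)
    best_s, best_frac = None, -1.0
    fracs: list[tuple[int, float]] = []
    for s in range(min_period, n // 2 + 1):
        frac = float(np.mean(arr[:-s] == arr[s:]))
        fracs.append((s, frac))
        if frac > best_frac:
            best_s, best_frac = s, frac
    if best_frac < min_fraction:
        return PeriodEstimate(None, FLAG_NO_PERIOD, best_frac)
    for s, frac in fracs:  # smallest shift within tolerance of the best
        if frac >= best_frac - 0.02:
            return PeriodEstimate(s, "ok", frac)
    return PeriodEstimate(best_s, "ok", best_frac)


# ---------------------------------------------------------------------------
# consensus voting
# ---------------------------------------------------------------------------

def _vote(columns: list[list[tuple[int, str]]]) -> tuple[str, np.ndarray, bool, bool]:
    """Majority-vote per column; votes are (copy_index, base) pairs."""
    out = []
    agreement = np.ones(len(columns))
    any_tie = False
    any_empty = False
    for i, votes in enumerate(columns):
        if not votes:
            out.append("N")
            agreement[i] = 0.0
            any_empty = True
            continue
        counts: dict[str, int] = {}
        first_seen: dict[str, int] = {}
        for k, b in votes:
            counts[b] = counts.get(b, 0) + 1
            first_seen.setdefault(b, k)
        top = max(counts.values())
        winners = [b for b, c in counts.items() if c == top]
        if len(winners) > 1:
            any_tie = True
            winners.sort(key=lambda b: first_seen[b])  # earliest copy wins
        out.append(winners[0])
        agreement[i] = top / len(votes)
    return "".join(out), agreement, any_tie, any_empty


def _indel_consensus(seq: str, period: int) -> tuple[str, list[float], bool, bool]:
    """Gap-aware consensus for indel-bearing copies.

    The read is aligned end-to-end against a tandem repetition of its first
    copy (exact semi-global edit alignment), pooling the alignment columns
    modulo the period.  Each copy then votes per reference column with a
    base or a gap; a gap majority deletes the column (an insertion error in
    the reference copy), and an insertion between columns supported by a
    strict majority of covering copies is spliced in (a deletion error in
    the reference copy).  This keeps the consensus in the circle's true
    frame even when the reference copy itself has indels.
    """
    reps = math.ceil(len(seq) / period) + 1
    aln = edlib.align(seq, seq[:period] * reps, mode="SHW", task="path")
    columns: list[list[tuple[int, str]]] = [[] for _ in range(period)]
    gaps: list[list[int]] = [[] for _ in range(period)]
    inserts: dict[int, list[tuple[int, str]]] = {}
    q = t = 0
    for num, op in re.findall(r"(\d+)([=XIDM])", aln["cigar"]):
        num = int(num)
        if op in "=XM":
            for _ in range(num):
                columns[t % period].append((t // period, seq[q]))
                q += 1
                t += 1
        elif op == "I":  # read bases absent from the reference frame
            inserts.setdefault(t % period, []).append((t // period, seq[q:q + num]))
            q += num
        else:            # 'D': reference column with no read base
            for _ in range(num):
                gaps[t % period].append(t // period)
                t += 1

    out: list[str] = []
    agreement: list[float] = []
    any_tie = False
    any_empty = False
    for col in range(period):
        covering = len(columns[col]) + len(gaps[col])
        # majority-supported insertion before this column
        if col in inserts and covering:
            strings: dict[str, int] = {}
            for _, s in inserts[col]:
                strings[s] = strings.get(s, 0) + 1
            best = max(strings, key=lambda s: (strings[s], -len(s)))
            if strings[best] * 2 > covering:
                out.extend(best)
                agreement.extend([strings[best] / covering] * len(best))
        if not columns[col]:
            any_empty = True
            continue
        if len(gaps[col]) > len(columns[col]):
            continue  # gap majority: reference-copy insertion, drop column
        counts: dict[str, int] = {}
        first_seen: dict[str, int] = {}
        for k, b in columns[col]:
            counts[b] = counts.get(b, 0) + 1
            first_seen.setdefault(b, k)
        top = max(counts.values())
        winners = sorted((b for b, c in counts.items() if c == top),
                         key=lambda b: first_seen[b])
        if len(winners) > 1:
            any_tie = True
        out.append(winners[0])
        agreement.append(top / covering)
    return "".join(out), agreement, any_tie, any_empty


def _anchor_rotation(consensus: str, junction_kmer: str, kmer_mismatch: int = 1) -> int | None:
    """Circle offset of the acceptor-side base following the junction, or
    None if the k-mer is not found on the circularized consensus."""
    L = len(consensus)
    km = junction_kmer.upper()
    ext = consensus + consensus[: len(km) - 1]
    occ = [p for p in find_approx(ext, km, kmer_mismatch) if p < L]
    if not occ:
        return None
    return (occ[0] + len(km) // 2) % L


def build_consensus(
    read: TandemRead,
    period: int,
    junction_kmer: str | None = None,
    mode: str = "sub",
) -> ConsensusResult:
    """Stack the read's copies at ``period`` and majority-vote a circle.

    ``mode='sub'`` assumes copies are column-aligned (substitution-only
    errors); ``mode='indel'`` aligns the read to a tandem repetition of its
    first copy before voting, tolerating insertions/deletions.
    """
    if period <= 0:
        raise CircRcaError(f"period must be positive, got {period}")
    if mode not in ("sub", "indel"):
        raise CircRcaError(f"mode must be 'sub' or 'indel', got {mode!r}")
    n = len(read.seq)
    flags: list[str] = []

    if mode == "sub":
        columns: list[list[tuple[int, str]]] = [[] for _ in range(period)]
        for i, b in enumerate(read.seq):
            columns[i % period].append((i // period, b))
        consensus, agreement, any_tie, any_empty = _vote(columns)
        agreement = list(agreement)
    else:
        consensus, agreement, any_tie, any_empty = _indel_consensus(
            read.seq, period
        )
    agreement = np.asarray(agreement)
    if any_tie:
        flags.append(FLAG_AMBIGUOUS)
    if any_empty:
        flags.append(FLAG_LOW_COVERAGE)

    if junction_kmer is not None:
        offset = _anchor_rotation(consensus, junction_kmer)
        if offset is None:
            flags.append(FLAG_JUNCTION_NOT_FOUND)
        else:
            consensus = consensus[offset:] + consensus[:offset]
            agreement = np.concatenate([agreement[offset:], agreement[:offset]])

    return ConsensusResult(
        consensus=MatureCircSequence(seq=consensus, circ_id=read.read_id),
        period=period,
        n_full_copies=n // period,
        per_column_agreement=agreement,
        flags=tuple(flags),
    )


def reconstruct(
    read: TandemRead,
    junction_kmer: str | None = None,
    mode: str = "sub",
    min_period: int = 50,
    min_fraction: float = 0.8,
) -> ConsensusResult:
    """Estimate the period, then build the (anchored) circular consensus.

    Estimation failures propagate as flags on a consensus-less result
    rather than exceptions, so batch processing can continue.
    """
    est = estimate_period(read, junction_kmer=junction_kmer,
                          min_period=min_period, min_fraction=min_fraction)
    if not est.ok:
        return ConsensusResult(consensus=None, period=None, n_full_copies=0,
                               per_column_agreement=None, flags=(est.flag,))
    return build_consensus(read, est.period, junction_kmer=junction_kmer,
                           mode=mode)
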