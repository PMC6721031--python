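"""miRNA seed-site and RBP-motif scanning on circular sequences.

Because a circRNA has no ends, a binding site may straddle the backsplice
junction; scanning the circularized text (the sequence extended by its own
first ``width - 1`` bases) captures every such site exactly once, with
positions reported modulo the circle length.  The scanner implements only
canonical, fully specified rules:

* **miRNA seeds** — Watson–Crick matches to the miRNA seed region, classed
  as 6mer (pairs miRNA positions 2–7), 7mer-m8 (2–8), 7mer-A1 (2–7 plus an
  adenosine opposite position 1), and 8mer (2–8 plus the A1).  Each
  occurrence is reported once, under its most specific class.
* **RBP motifs** — IUPAC degenerate consensus strings, or position
  probability matrices scored as log-odds against a uniform background
  with a user threshold.

Scans are pure functions of their inputs.  Proprietary target-prediction
scores (miRDB, RBPmap and kin) are deliberately not imitated; the point is
that different splice variants of one junction present different site
sets, which these first-principles rules already expose.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core_io import CircRcaError, CircVariant, MatureCircSequence, revcomp

__all__ = [
    "SiteHit",
    "IupacMotif",
    "PwmMotif",
    "DiffResult",
    "SEED_TYPES",
    "scan_mirna_seeds",
    "scan_rbp_motifs",
    "diff_sites",
    "parse_motifs_tsv",
]

SEED_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class SiteHit:
    circ_id: str
    motif_id: str
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer | motif
    position: int   # circle coordinate of the site's first base
    length: int
    spans_junction: bool


@dataclass(frozen=True)
class IupacMotif:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        bad = [c for c in self.pattern.upper() if c not in _IUPAC]
        if bad or not self.pattern:
            raise CircRcaError(
                f"motif {self.name!r}: invalid IUPAC letters {bad!r}"
            )
        object.__setattr__(self, "pattern", self.pattern.upper().replace("U", "T"))

    @property
    def width(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class PwmMotif:
    """Position probability matrix (rows A, C, G, T; one column per
    position), scored as sum of log2(p / background) >= threshold."""

    name: str
    matrix: np.ndarray
    threshold: float
    background: float = 0.25

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != 4 or mat.shape[1] < 1:
            raise CircRcaError(f"motif {self.name!r}: matrix must be 4 x W")
        if not np.isfinite(mat).all() or (mat < 0).any():
            raise CircRcaError(
                f"motif {self.name!r}: matrix entries must be finite and >= 0"
            )
        object.__setattr__(self, "matrix", mat)

    @property
    def width(self) -> int:
        return int(self.matrix.shape[1])

    def score(self, window: str) -> float:
        total = 0.0
        for i, b in enumerate(window):
            j = "ACGT".find(b)
            if j < 0:
                return float("-inf")
            p = self.matrix[j, i]
            total += math.log2(p / self.background) if p > 0 else float("-inf")
        return total

    @property
    def max_score(self) -> float:
        with np.errstate(divide="ignore"):
            logs = np.log2(self.matrix / self.background)
        return float(np.max(logs, axis=0).sum())


# ---------------------------------------------------------------------------
# miRNA seeds
# ---------------------------------------------------------------------------

def scan_mirna_seeds(
    circ: MatureCircSequence,
    mirnas: Iterable[tuple[str, str]],
    types: Iterable[str] = SEED_TYPES,
    topology: str = "circular",
) -> list[SiteHit]:
    """Scan for canonical miRNA seed sites; one hit per occurrence, classed
    as the most specific requested type it satisfies.

    ``mirnas`` are (name, sequence) pairs in RNA or DNA alphabet, 5'->3'.
    miRNAs shorter than 8 nt are skipped with a warning.  In linear
    topology sites may not wrap past the junction.
    """
    types = set(types)
    unknown = types - set(SEED_TYPES)
    if unknown:
        raise CircRcaError(f"unknown seed site types {sorted(unknown)}")
    L = circ.length
    seq = circ.seq
    circular = topology == "circular"

    def base(i: int) -> str | None:
        if circular:
            return seq[i % L]
        return seq[i] if 0 <= i < L else None

    hits: list[SiteHit] = []
    for name, mseq in mirnas:
        m = mseq.upper().replace("U", "T")
        if len(m) < 8:
            warnings.warn(f"miRNA {name} shorter than 8 nt; skipped", stacklevel=2)
            continue
        core = revcomp(m[1:7])     # target match to miRNA positions 2-7
        m8c = revcomp(m[7])        # target base opposite position 8 (5' of core)
        for q in range(L):
            if any(base(q + i) != core[i] for i in range(6)):
                continue
            has_m8 = base(q - 1) == m8c
            has_a1 = base(q + 6) == "A"
            for st in SEED_TYPES:
                if st not in types:
                    continue
                if st == "8mer" and has_m8 and has_a1:
                    start, width = q - 1, 8
                elif st == "7mer-m8" and has_m8:
                    start, width = q - 1, 7
                elif st == "7mer-A1" and has_a1:
                    start, width = q, 7
                elif st == "6mer":
                    start, width = q, 6
                else:
                    continue
                if not circular and (start < 0 or start + width > L):
                    continue
                pos = start % L
                hits.append(SiteHit(
                    circ_id=circ.circ_id, motif_id=name, site_type=st,
                    position=pos, length=width,
                    spans_junction=pos + width > L,
                ))
                break
    return hits


# ---------------------------------------------------------------------------
# RBP motifs
# ---------------------------------------------------------------------------

def scan_rbp_motifs(
    circ: MatureCircSequence,
    motifs: Iterable[IupacMotif | PwmMotif],
    topology: str = "circular",
) -> list[SiteHit]:
    """Scan IUPAC consensus / PWM motifs on the (circularized) sequence."""
    L = circ.length
    seq = circ.seq
    circular = topology == "circular"
    hits: list[SiteHit] = []
    for motif in motifs:
        w = motif.width
        if w > L:
            raise CircRcaError(
                f"motif {motif.name!r} wider ({w}) than circle ({L})"
            )
        text = seq + seq[: w - 1] if circular else seq
        last = L if circular else L - w + 1
        for p in range(last):
            window = text[p: p + w]
            if isinstance(motif, IupacMotif):
                if any(window[i] not in _IUPAC[motif.pattern[i]] for i in range(w)):
                    continue
            else:
                if motif.score(window) < motif.threshold:
                    continue
            hits.append(SiteHit(
                circ_id=circ.circ_id, motif_id=motif.name, site_type="motif",
                position=p, length=w, spans_junction=p + w > L,
            ))
    return hits


def parse_motifs_tsv(path) -> list[IupacMotif | PwmMotif]:
    """Read motifs from a simple text format.

    IUPAC motifs are ``name<TAB>pattern`` lines.  A PWM block is a
    ``name<TAB>pwm<TAB>threshold`` line followed by four tab-separated rows
    of probabilities in A/C/G/T order.
    """
    from pathlib import Path

    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    motifs: list[IupacMotif | PwmMotif] = []
    i = 0
    while i < len(lines):
        fields = lines[i].split("\t")
        if len(fields) >= 3 and fields[1] == "pwm":
            rows = [
                [float(x) for x in lines[i + 1 + r].split("\t")]
                for r in range(4)
            ]
            motifs.append(PwmMotif(name=fields[0], matrix=np.array(rows),
                                   threshold=float(fields[2])))
            i += 5
        elif len(fields) == 2:
            motifs.append(IupacMotif(name=fields[0], pattern=fields[1]))
            i += 1
        else:
            raise CircRcaError(f"unrecognised motif line: {lines[i]!r}")
    return motifs


# ---------------------------------------------------------------------------
# differential site sets across splice variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffResult:
    """Per-motif site counts across the splice variants of one junction."""

    table: pd.DataFrame           # motif_id x variant site counts
    classification: dict          # motif_id -> 'shared-by-all' | 'subset-specific'
    annotated: pd.DataFrame       # one row per hit, with its host segment


def _segment_label(variant: CircVariant, position: int) -> str:
    off = 0
    for seg in variant.segments:
        if off <= position < off + seg.length:
            if seg.kind == "exon":
                return f"E{seg.exon_index + 1}"
            if seg.kind == "partial_exon":
                return f"E{seg.exon_index + 1}p{seg.length}"
            if seg.kind == "novel_exon":
                return f"N{seg.length}"
            return f"U{seg.length}"
        off += seg.length
    raise CircRcaError(f"position {position} outside variant of length {off}")


def diff_sites(
    hits_by_variant: Mapping[str, list[SiteHit]],
    variants: Mapping[str, CircVariant],
) -> DiffResult:
    """Compare site sets across splice variants sharing one junction.

    Produces a motif x variant count table, classifies each motif as
    present in all variants or only a subset, and annotates every hit with
    the variant segment its start position falls in.
    """
    if set(hits_by_variant) != set(variants):
        raise CircRcaError("hits_by_variant and variants must share keys")
    junctions = {v.junction.id for v in variants.values()}
    if len(junctions) > 1:
        raise CircRcaError(
            f"variants do not share one backsplice junction: {sorted(junctions)}"
        )
    names = list(variants)
    motif_ids = sorted({h.motif_id for hs in hits_by_variant.values() for h in hs})
    table = pd.DataFrame(0, index=motif_ids, columns=names, dtype=int)
    rows = []
    for vname in names:
        variant = variants[vname]
        for h in hits_by_variant[vname]:
            table.loc[h.motif_id, vname] += 1
            rows.append({
                "variant": vname, "motif_id": h.motif_id,
                "site_type": h.site_type, "position": h.position,
                "spans_junction": h.spans_junction,
                "segment": _segment_label(variant, h.position),
            })
    classification = {
        mid: "shared-by-all" if (table.loc[mid] > 0).all() else "subset-specific"
        for mid in motif_ids
    }
    annotated = pd.DataFrame(
        rows, columns=["variant", "motif_id", "site_type", "position",
                       "spans_junction", "segment"],
    )
    return DiffResult(table=table, classification=classification,
                      annotated=annotated)
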