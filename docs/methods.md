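# Methods

## Scope and model

`circrca` models the rolling-circle route to full-length circRNA sequences
as a chain of well-defined transformations on strings and intervals:

1. a **mature circle** is the concatenation, in transcript order, of the
   segments (full/partial/novel exons) retained between a backsplice
   junction's coordinates, reverse-complemented per segment on `−`-strand
   loci, and anchored so position 0 is the first base of the acceptor exon;
2. **RNase R enrichment** is a Bernoulli filter on molecule topology:
   circles always survive, each linear molecule survives with probability
   `1 − efficiency`;
3. **rolling-circle RT** emits `⌊copies·L⌋` nt of the circle's periodic
   extension from a start phase, with i.i.d. per-base substitutions
   (uniform over the three alternative bases) and optional per-base
   insertions/deletions;
4. **PCR** enumerates primer binding sites on the tandem read (Hamming
   matching up to `max_mismatch`) and emits one amplicon per forward
   occurrence × k-th downstream reverse occurrence, `k ≤ max_rounds`;
5. **circular consensus** estimates the repeat period and majority-votes
   the stacked copies;
6. **composition calling** decodes the consensus against the locus
   annotation.

## Coordinate and strand conventions

All intervals are 0-based half-open (BED convention). Junction identifiers
(`species_chrom_start_end_{F|R}`) are read in the same convention — the
catalogues that use these identifiers never state the base explicitly, so
the parser exposes a `one_based` flag for tables with 1-based starts. `F`
and `R` map to genomic `+`/`−`; on `−`-strand loci transcript order is
descending genomic order and every extracted segment is
reverse-complemented. Bases outside `ACGT` are preserved as `N` (with a
warning) rather than rejected, so real genome FASTA files pass through.

The canonical rotation anchor — position 0 = acceptor-exon start — makes
consensus circles, extracted variants, and composition calls directly
comparable; the junction 20-mer (`s[L−10:] + s[:10]`) is both the forward
primer and the anchoring key.

## Primer geometry

The full-length pair follows the assay's construction exactly: the forward
primer spans `span` nt (default 10) on each side of the junction, and the
reverse primer is the reverse complement of the `rev_len` nt immediately
upstream, so the reverse footprint ends where the forward footprint begins
and one PCR round copies one full rotation. `rev_len` defaults to 20 nt,
matching the forward primer's total length; the assay itself does not fix
a reverse length. Divergent pairs take the largest feasible product length
in the requested range and split it symmetrically around the junction,
maximising both primers' distance from it. Primer QC is limited to GC
fraction and the Wallace / length-corrected Tm formulas; the pairs are
validated geometrically (footprints, ladder law, junction specificity),
not thermodynamically.

## The synthetic fixture panel

`make_fixture_loci(seed)` builds one synthetic chromosome per locus of the
six-circRNA HeLa panel. Exon *lengths* are the published structures; exon
and intron *sequences* are uniform random bases from a seeded generator, so
all sequence-level behaviour (primer uniqueness, exact exon matching) holds
with overwhelming probability but is not guaranteed by construction —
conclusions transfer to real loci only to the extent that real exons are
similarly non-repetitive. Introns default to 100 nt; an intron that must
strictly contain a novel exon (the 241-nt MAPK9 segment) is widened to
`novel_len + 80` nt and the segment centred in it, since its true position
inside the intron is not published. The 58-nt partial exon of the 324-nt
CNOT2 circle is taken from the transcript 3' end (suffix) of the middle
exon — which end contributes is not recoverable from the published
description, and the caller accepts either.

Three loci run on the `−` strand (ASPH, AP3S2, MAPK9), so strand handling
is exercised by default, not as an edge case.

What the simulator deliberately does not model: RT template switching,
chimeras, amplification-efficiency bias, non-specific PCR products, and
mixed-variant reads (one read = one molecule). Reads are emitted in the
circle's sense orientation; after PCR both strands exist, so this loses
nothing. Copy numbers in examples (2.2–4) are fixture choices: the assay
itself does not report how many rotations the RT achieves.

## Period estimation and consensus

With a junction k-mer, the period is the modal spacing between k-mer
occurrences (≤1 mismatch per occurrence — at 2% base error a 20-mer
occurrence is occasionally lost, which can double the modal gap; the
consensus length distribution over seeds shows this as rare `2L` outcomes).
Without a k-mer, the period is found by self-comparison over shifts in
`[min_period, |read|/2]`: among shifts reaching a 0.8 match fraction, the
smallest shift within 0.02 of the best fraction is returned, preferring
the fundamental period over its multiples. `min_period` defaults to 50 nt,
the shortest plausible circle unit in this assay; 0.8 tolerates ~2% error
on both arms of the comparison with margin. Failures are flags
(`insufficient`, `no-period`), not exceptions, so batch runs continue.

Substitution-mode consensus stacks bases at positions congruent mod the
period and takes per-column majorities; partial terminal copies vote only
where they cover; ties go to the earliest copy and flag the column. With 4
copies at 2% error, a column is miscalled roughly when two copies take the
same substitution and the tie-break picks wrongly (~4·10⁻⁴ per column), so
exact recovery of a 324-nt circle happens in ~87% of runs — the modal
consensus is still exact essentially always, and error positions are
visible in `per_column_agreement`.

Indel mode aligns the whole read once (exact semi-global edit alignment,
via edlib) against a tandem repetition of its first copy and votes
gap-aware per reference column: a gap majority deletes the column (an
insertion error in the reference copy), and an insertion supported by a
strict majority of covering copies is spliced in (a reference deletion).
This keeps the consensus in the circle's true frame even when the
reference copy itself has indels, at the cost of one alignment.

## Composition calling

`enumerate_variants` fixes the first and last in-span exons (they form the
backsplice) and toggles the `k−2` internal exons, giving `2^(k−2)` ordered
candidates. `assign_exons` chains greedily left-to-right: full exon first
(earliest transcript position on ties, warned), then the longest
prefix/suffix of an annotated exon (partial exon; internal deletions are
reported as unmapped rather than guessed), then the longest exact
substring of an in-span intron (novel exon, with genomic coordinates),
else an unmapped stretch up to the next full-exon resync. Because the
longest intron match can overshoot by coincidental bases, the novel match
is trimmed until an annotated exon resumes immediately after it. Minimum
partial/novel match lengths (12/20 nt) guard against chance matches; a
genuinely shorter partial or novel segment would be folded into an
unmapped stretch — a documented blind spot. Matching is exact by default
(a consensus is expected error-free); a mismatch fraction is exposed for
calling on raw reads. Length matching against candidates uses a 5%
tolerance and reports `observed ≈ 2·mature` separately as a doublet
interpretation.

## Site scanning

Seeds use the canonical classes — 6mer (pairs miRNA positions 2–7),
7mer-m8 (2–8), 7mer-A1 (2–7 + A opposite position 1), 8mer — each
occurrence reported once under its most specific requested class. The
circularized text is the sequence extended by its first `width − 1` bases,
the minimal wrap that captures each junction-spanning site exactly once;
positions are reported mod `L`. RBP motifs are IUPAC consensus strings or
position probability matrices scored as `Σ log2(p/0.25) ≥ threshold`
(background configurable). Proprietary target predictors are intentionally
not imitated: their scores are not reproducible from first principles, so
per-variant comparisons here rest only on fully specified rules.
`diff_sites` tabulates counts per motif × variant, classifies motifs as
shared-by-all vs subset-specific, and annotates each hit with the variant
segment it falls in — skipping an exon removes that exon's sites and can
*create* junction sites at the new exon joint, so monotone containment
across variants is not assumed.

## Determinism and sizes

All randomness flows through explicit integer seeds; the pipeline derives
per-stage seeds from one global seed as `(seed·1000003 + stage) mod 2³¹`.
Property suites run at deliberately small sizes — circles of 50–400 nt,
2–4 copies, 50–200 instances per suite — chosen so the whole test suite
and the demo complete in seconds while still exercising every code path;
the fixture panel itself is full-size (circles up to 886 nt).

## Known limitations

- One molecule per read: mixed-variant traces are out of scope.
- Novel-exon search is intron-only and on the gene strand; exonic repeats
  elsewhere in the genome are not considered.
- Intron-retention circRNA classes are represented only through the
  novel-exon mechanism.
- The period estimator requires ≥2 copies; single-pass reads are flagged
  unrecoverable by design.
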