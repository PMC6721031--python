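# circrca

In-silico circRNA rolling-circle amplification: primer design, tandem-repeat
read simulation, circular consensus, and splice-variant calling.

## The problem

Circular RNAs (circRNAs) are covalently closed transcripts produced by
backsplicing: a downstream exon's 3' end (donor) is joined to an upstream
exon's 5' start (acceptor). Catalogues identify a circRNA by its backsplice
junction coordinates, e.g. `hsa_chr12_70671911_70704797_F`, and *predict*
its mature sequence as the exons spanned by those coordinates. But
alternative splicing can produce several circles — splice variants — that
share one junction while differing in internal content: a skipped exon, a
truncated (partial) exon, or an unannotated (novel) exon retained from an
intron. Junction-based assays cannot tell these apart, and the variants can
carry different miRNA and RNA-binding-protein (RBP) sites, hence different
functions.

The rolling-circle strategy resolves this. RNase R digestion removes linear
RNA (circles, lacking free ends, survive). A reverse transcriptase without
RNase H activity then traverses the circle repeatedly, producing a cDNA of
tandem repeats of the full mature sequence. PCR with a **full-length primer
pair** — a forward primer spanning 10 nt on either side of the junction and
a reverse primer placed exactly upstream of it — amplifies complete
rotations of the circle: for a circle of length `L` the products form an
exact ladder `L, 2L, 3L, …` (monomer, doublet, …). Sequencing a product and
collapsing its tandem copies gives the true mature sequence, whose exon
composition can then be read off against the parent-gene annotation.

This package implements every step of that workflow in silico:

| module | role |
|---|---|
| `core_io` | junction-ID parsing, FASTA/BED12/GTF I/O, mature-sequence extraction |
| `primer_design` | full-length (junction-spanning) and divergent primer pairs |
| `rca_simulator` | synthetic loci, RNase R filter, rolling-circle reads, in-silico PCR |
| `circular_consensus` | repeat-period estimation and junction-anchored consensus |
| `variant_caller` | exon-skipping enumeration and full/partial/novel exon calling |
| `site_scanner` | miRNA seed sites and RBP motifs on circular topology, per-variant comparison |
| `pipeline` / `cli` | seeding, logging, the `circrca` command |

The built-in fixture panel mirrors six human circRNAs characterised in HeLa
cells (from the genes *ASPH*, *CNOT2*, *KDM1A*, *PALLD*, *AP3S2*, *MAPK9*),
with the real exon-length structures — including a 58-nt partial exon in
the 324-nt *CNOT2* circle and a 241-nt novel exon in the 738-nt *MAPK9*
circle — over random, seeded sequences.

## The core quantities

For a mature circle `s` of length `L`, anchored so position 0 is the first
base of the backsplice acceptor exon:

- forward full-length primer: `s[L−10 .. L) + s[0 .. 10)` (the junction
  20-mer); reverse primer: reverse complement of `s[L−30 .. L−10)`, so the
  reverse footprint abuts the forward footprint and one PCR round copies one
  full rotation (`product = n·L`).
- a rolling-circle read of `c` copies has length `⌊c·L⌋`; the consensus is
  the per-column majority over bases at positions congruent mod the
  estimated period, rotated to the junction anchor.
- exon composition is called greedily in transcript order: full exon →
  longest exon prefix/suffix (partial) → longest intron substring (novel) →
  unmapped; segment lengths always sum to `L`.
- miRNA sites follow the canonical seed classes (6mer = pairs miRNA
  positions 2–7, 7mer-m8, 7mer-A1, 8mer), scanned on the circularized text
  so junction-spanning sites are found.

## Worked example

```bash
circrca demo --seed 1 --outdir demo_out
```

prints (abridged):

```
 gene          circ_id              variant  true_length  consensus_length       composition amplicon_lengths
CNOT2 hsa_circ_0007127 hsa_circ_0007127_490          490               490          E1+E2+E3     490,980,1470
CNOT2 hsa_circ_0007127 hsa_circ_0007127_266          266               266             E1+E3      266,532,798
CNOT2 hsa_circ_0007127 hsa_circ_0007127_324          324               324       E1+E2p58+E3      324,648,972
MAPK9 hsa_circ_0001566 hsa_circ_0001566_497          497               497       E1+E2+E3+E4     497,994,1491
MAPK9 hsa_circ_0001566 hsa_circ_0001566_738          738               738  E1+N241+E2+E3+E4    738,1476,2214
```

Reading the *CNOT2* rows: the catalogue composition uses all three exons
(490 nt); the two splice variants skip exon 2 entirely (266 nt, `E1+E3`) or
retain a 58-nt portion of it (324 nt, `E1+E2p58+E3`). Each read's PCR
ladder is an exact multiple of its circle length (monomer, doublet,
triplet), and every consensus length equals the true mature length. The
*MAPK9* variant row shows the 241-nt novel exon (`N241`) recovered from the
intron with its genomic coordinates.

Individual stages are available as subcommands (`parse-junctions`,
`design`, `simulate`, `consensus`, `call`, `scan`) or as library functions:

```python
import circrca as c

fx = c.make_fixture_loci(seed=1)
cnot2 = fx["CNOT2"]
circ = c.extract_mature_sequence(fx.genome, cnot2.locus, cnot2.variants[1])
read = c.simulate_rolling_circle(circ, copies=3.2, error_rate=0.01, seed=5)
result = c.reconstruct(read, junction_kmer=circ.junction_kmer(10))
call = c.assign_exons(result.consensus, fx.genome, cnot2.locus, cnot2.junction)
print(result.consensus.length, call.composition())   # 266 E1+E3
```

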