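# gblscreen

Design and in-silico evaluation of degenerate PCR screens for
γ-butyrolactone-like (GBL) autoregulatory systems in *Streptomyces*.

## The problem

γ-butyrolactones, butenolides and methylenomycin-furan-type molecules are
diffusible autoregulators that gate secondary-metabolite production in
*Streptomyces*. The biosynthesis gene (an AfsA-family synthase, e.g. ScbA)
and the cognate TetR-family receptor gene (e.g. ScbR) are very often
collocated and **divergently** oriented — transcribed away from each other
with their 5′ ends flanking a short shared intergenic region that carries
the palindromic operator (the autoregulatory response element, ARE). A
degenerate primer pair anchored on conserved protein motifs — one primer in
each gene, pointing into the intergenic region — can detect such systems in
a strain collection by plain PCR, without whole-genome sequencing.

`gblscreen` implements that workflow end to end, for people designing or
evaluating such screens:

1. **pair_finder** — find homologues of the two query proteins in annotated
   genomes (Smith–Waterman local alignment, BLOSUM62, Karlin–Altschul
   expectation, E < 0.02 by default), pair hits on the same contig within a
   maximum intergenic distance (600 bp default) and classify orientation
   (divergent / convergent / tandem).
2. **conservation** — star-align the homologue sets, compute per-column
   information content (IC(col) = log₂20 − H(col), occupancy-scaled), and
   rank candidate 4–6-residue anchor windows; positions whose modal residue
   falls below 50 % are wildcarded (`ETxRQ`).
3. **primer_design** — back-translate the anchor context with a bundled
   high-GC *Streptomyces*-style codon usage table under per-position
   degeneracy rules, and reverse-complement so the motif's first codon is
   the primer's 3′ end. The bundled policy reproduces the screen primers
   scb_F `CCGCTCCTTGCTSGGRAARTGRAARTA` (degeneracy 32, anchors YFHF in the
   receptor's DNA-binding domain) and scb_R `GCCGCTCTGGCGVABSGTYTC`
   (degeneracy 36, anchors ETxRQ in the synthase).
4. **insilico_pcr** — match degenerate primers against genomic DNA with
   IUPAC set-intersection semantics and a strict 3′-exactness rule, predict
   product sizes (outer primer edge to outer primer edge), and call
   qualitative priming classes for motif variants (will prime / will likely
   prime / might not prime / will not prime).
5. **are_discovery** — find the shared ARE in the amplified intergenic
   regions with a ZOOPS EM motif finder (widths 15–30, both strands),
   score palindromicity, and estimate significance from a
   dinucleotide-shuffle null.
6. **synth_fixtures** — generate synthetic GC-rich loci with planted pairs,
   motif variants and AREs, plus sidecar ground truth; this is the test
   bed for everything above.

## Worked example

Generate a synthetic divergent locus and run the primers against it:

```bash
$ gblscreen make-fixtures --preset demo --seed 3 -o fixtures
demo locus -> fixtures

$ gblscreen design-primers -o primers.tsv
scb_F   CCGCTCCTTGCTSGGRAARTGRAARTA     degeneracy=32
scb_R   GCCGCTCTGGCGVABSGTYTC   degeneracy=36

$ gblscreen insilico-pcr --fwd CCGCTCCTTGCTSGGRAARTGRAARTA \
    --rev GCCGCTCTGGCGVABSGTYTC --genome fixtures/demo.gbk
contig  start   end     length_bp
demo    666     1344    678
```

The demo locus has a 180 bp intergenic gap; the predicted 678 bp product
spans from the outer edge of the scb_F site (inside the receptor gene)
to the outer edge of the scb_R site (inside the synthase gene), the way a
band size would be read off a gel.

The full screen on a cohort of 20 synthetic genomes (75 % identity
homologues, mixed orientations and motif variants):

```bash
$ gblscreen screen --receptor-query receptor.fasta --synthase-query synthase.fasta \
    --genome genomes/*.gbk --max-mismatch 2 --seed 1 -o screen_out
[orientation census]
  divergent     14
  convergent    5
  tandem        1
[anchor patterns]
  receptor      YFHF
  synthase      ETxRQ
[amplifiability]
  n_pairs       14
  n_amplifiable 9
  percent       64.3
[in-silico PCR]
  n_amplicons   4
  lengths       [841, 878, 889, 893]
```

The screen recovers the two anchor motifs from the cohort alignments, and
the motif co-occurrence estimate (64.3 % of divergent pairs carry both
anchors) mirrors the corpus-scale expectation that a single degenerate pair
amplifies roughly two thirds of divergent synthase/receptor systems.
Intermediate files (`pairs.tsv`, `intergenic.fasta`, `profile_*.tsv`,
`primers.tsv`, `amplicons.tsv`, `prime_classes.tsv`, `are_motif.txt`) are
persisted next to the report.

Public genomes can be fetched with `python scripts/fetch_genomes.py`
(network required) and fed to `gblscreen insilico-pcr` to predict expected
band sizes for real strains.

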