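# Methods

This note documents the models, algorithms and parameter choices behind
`gblscreen`, what the synthetic fixtures do and do not emulate, and the
known limitations.

## Homology search and pairing (`pair_finder`)

Each query protein is aligned locally against every annotated CDS
translation with `Bio.Align.PairwiseAligner` (BLOSUM62, gap open −11, gap
extend −1). Significance uses the Karlin–Altschul form E = K·m·n·e^(−λS)
with the standard ungapped BLOSUM62 parameters λ = 0.318, K = 0.13 on an
effective search space of query length × summed proteome length. Applying
ungapped parameters to gapped scores is a deliberate approximation: it is
conservative for strong homologies and we make no claim of threshold parity
with BLAST-family tools. The fixture-based tests keep score margins of many
hundreds of bits so the approximation cannot flip any outcome; the default
cutoff E < 0.02 matches the screening protocol the package implements.

Two hits form a pair when they lie on the same contig and the gap between
their nearest CDS boundaries (strand-agnostic; 0 for overlapping CDS) is at
most `max_intergenic` = 600 bp. Orientation is classified from the strands
of the left/right feature: (−,+) divergent (back-to-back, 5′ ends flanking
the gap), (+,−) convergent, same strand tandem. Pairs overlapping by more
than 30 bp are flagged ambiguous and excluded from the census proper.
Overlapping hits of one query at a locus are deduplicated by best score so
a locus is never counted twice. The intergenic regulatory sequence — where
the receptor's operator sits — is defined only for divergent pairs and
returned on the plus strand of the contig.

Orientation classification is invariant under reverse-complementing the
whole contig; this is asserted property-style in the tests.

## Conservation profiling (`conservation`)

Homologue sets are star-aligned: every sequence is globally aligned to the
reference (BLOSUM62, open −10, extend −0.5) and merged on reference
coordinates, insertions opening gap columns. A star alignment is sufficient
here because the downstream consumer is per-column residue statistics at
anchor windows, not alignment fidelity; full progressive alignment would
change nothing the pipeline measures.

Per-column information content is IC = (log₂20 − H) × occupancy, with a
pseudocount of 1/20 per residue type and no background-composition or
small-sample correction (at the cohort sizes the pipeline handles, the
small-sample bias is well below the contrast between conserved and variable
columns). Gap-only columns score 0.

Anchor windows of 4–6 residues are ranked by mean IC over
reference-anchored columns (occupancy ≥ 0.5), ties toward the smaller
column index. Within a window, positions whose modal residue frequency
(occupancy-weighted) is below `wildcard_threshold` = 0.5 are written as the
wildcard `x`; 0.5 is the natural majority rule and reproduces `ETxRQ` for
an I/L/V-mixed third position. Note that for very small or near-identical
cohorts many windows tie at maximal IC and the index tie-break decides;
anchor recovery is meaningful only when the homologue set actually diverges
outside the conserved motifs.

Motif-variant counting reads residues from the alignment columns of the
chosen window (not by re-scanning sequences), so insertions elsewhere
cannot shift the counted window. Wildcards in a pattern match anything,
which gives the subsumption property count(specific) ≤ count(generalised),
asserted in tests. The amplifiability estimate is the fraction of
index-paired receptor/synthase variant lists where both anchor patterns
match, reported as a percentage rounded to one decimal.

## Degenerate primer design (`primer_design`)

A primer is built from a 5–10-residue protein context whose N-terminal
positions are the conserved motif. Back-translation applies one rule per
position:

- `full` — positionwise IUPAC closure of all synonymous codons (motif
  positions; maximal degeneracy where annealing matters most);
- `top2` — closure of the two most frequent codons (wobble positions);
- `single` — one codon, explicit or the most frequent (5′ clamp);
- `residue_set` — closure of the codons (frequency ≥ 0.05) of a tolerated
  residue set, e.g. {I,L,V} → VTB.

The coding-sense string is reverse-complemented, so the primer anneals
antisense to the coding strand with the motif's first codon at its 3′
end — mismatches at the extending end are the ones that abolish priming,
so the motif belongs there. Degeneracy is the product of per-position IUPAC
cardinalities, capped at 512 by default (commercial oligo practicality).

The positionwise closure is minimal per position but can admit extra
codons as a set product: VTB covers the nine high-GC codons of I/L/V and
also ATG (Met). This over-coverage is intentional and documented — it
costs pool fraction, not specificity at the 3′ end.

The bundled policy file encodes the per-position rules that generate the
two screen primers exactly (verified by string equality in the acceptance
tests): scb_F from context YFHFPSKER (motif YFHF full, P top2, S/K/E/R
single AGC/AAG/GAG/CGG) and scb_R from context ET{ILV}RQSG (E full, T
top2, {ILV} residue_set, R/Q/S/G single CGC/CAG/AGC/GGC). The context
residues flanking each motif are recovered from the primer sequences
themselves and shipped as the package's ground-truth policy. The bundled
codon usage table is a versioned high-GC *Streptomyces coelicolor*-style
table (fractions per amino acid summing to 1).

No thermodynamic model is implemented beyond reported GC% and
Wallace-rule Tm ranges per expansion; dimer/hairpin screening and
primer3-style optimisation are out of scope.

## In-silico PCR (`insilico_pcr`)

Primer–template compatibility is IUPAC set intersection per position,
except that `N` in the template never matches (unknown sequence is not
assumed to anneal). A site is accepted with at most `max_mismatch`
incompatible positions (default 0) and none within the 3′-terminal
`three_prime_exact` = 3 bases. Both template strands are scanned with a
vectorised bit-mask encoding; at `max_mismatch` 0 the matcher is exactly
equivalent to exact-searching every concrete expansion of the primer, which
the tests assert against a brute-force oracle. Match counts are monotone in
`max_mismatch`.

Products are every inward-facing pair of sites on opposite strands with
length — 5′-most base of one footprint to 5′-most base of the other, both
footprints included — inside [`min_size`, `max_size`] = [100, 3000]. The
window is deliberately wider than the 500–700 bp the screen targets so
that unexpected products are surfaced rather than hidden; prediction of
nonspecific annealing products is out of scope.

Priming classes for a motif variant are scored at nucleotide level against
the primer's 3′-proximal codons (codon 1 = the 3′-terminal codon). For a
definite residue, the score is the fewest incompatible bases over its
synonymous codons; a wildcard position is uncertainty, weighted by how
broadly the primer codon covers residues:

- will_not_prime — any definite mismatch in codon 1, ≥ 2 mismatching bases
  in codon 2, or ≥ 3 overall: the extending end cannot pair;
- might_not_prime — any other definite mismatch before the last motif
  codon, or a wildcard where the primer codon encodes ≤ 2 residues: a
  3′-region mismatch is possible but not certain;
- will_likely_prime — deviations confined to the last motif codon (it sits
  farthest from the 3′ end), or wildcards only at broadly degenerate
  primer codons (≥ 3 residues covered, e.g. VTB);
- will_prime — no deviation anywhere.

The class boundaries (exact 3′ window of 3 bases, the 2-base / 3-base
thresholds, the ≥ 3-residue breadth criterion) are conventional PCR
practice rather than measured constants; they reproduce the qualitative
outcome for every motif variant the package's validation panel covers,
including conservative substitutions whose first/second codon bases agree
silently (ETIRQ, ETVRQ → will prime) and 3′-anchor substitutions that
block amplification (YHHF, HHHF, ESVRQ, EAIRQ).

## ARE discovery (`are_discovery`)

A single ungapped motif of width 15–30 is fitted with a ZOOPS
(zero-or-one-occurrence-per-sequence) two-component mixture: each sequence
contains a site with prior 0.8, uniform over positions and strands, or no
site; background is the order-0 composition of the input. EM alternates
responsibilities over all windows on both strands with PWM re-estimation
under a Dirichlet pseudocount of 0.1 per base. The recorded objective (log
likelihood plus the Dirichlet log-prior) is non-decreasing every iteration
— asserted in tests — and iteration stops at Δ < 1e-6 or 200 iterations.

Seeding enumerates the (strided) w-mers of the input, screens them with a
vectorised best-match identity score, and runs full EM from the top seeds
(3 by default), keeping the best final likelihood with ties toward the
smaller (sequence, offset). Screening before refining is what makes
every-w-mer seeding affordable; running every seed to convergence would
change the selected optimum only on pathological inputs.

Width selection and significance both use an empirical dinucleotide-shuffle
null (Altschul–Erickson Eulerian-path shuffling, preserving exact
dinucleotide counts and terminal bases — implemented here because no
installed package provides it). Width is chosen by the z-score of the
observed LLR against a small per-width null (8 shuffles by default);
significance is p = (1 + #{null LLR ≥ observed}) / (1 + n_shuffles), floor
1/(n+1). No analytic E-value is computed: an analytic MEME-style E-value
depends on that tool's internals, and the package's contract is motif and
site recovery, not bit-parity. A strongly planted motif reaches the null
floor; a fit on i.i.d. noise stays insignificant (> 0.05).

Palindromicity is 1 minus the mean per-column total-variation distance
between the PWM and its reverse complement: a perfect inverted repeat
scores 1, a poly-A consensus 0. Note the score is width-sensitive — if the
fitted window is offset or wider than the underlying palindrome, the
misalignment lowers the score even when the palindrome is recovered.

Primer-derived ends of amplicon sequences are not trimmed before motif
discovery by default; callers can trim upstream if their reads include
primer sequence.

## Synthetic fixtures (`synth_fixtures`)

Fixtures emulate a *Streptomyces*-like locus: order-0 background at 70 %
GC, a receptor gene (left) and synthase gene (right) separated by a
controlled gap, strands set by the requested orientation, coding sequences
back-translated by codon-usage sampling from the bundled table. At the
primer anchor window the most frequent primer-compatible codon is used
whenever the planted residue is compatible with the designed primer, so
designed motifs yield perfect primer sites and variant motifs yield
mismatches exactly at their codons — the property the in-silico PCR panel
tests rely on. Contigs with spurious primer sites are regenerated from a
derived sub-seed. Ground truth (CDS intervals, planted site footprints,
expected outer-edge product length, ARE offset) is recorded per locus and
written as a sidecar TSV; identical seeds give byte-identical outputs.

The two "query" proteins are deterministic synthetic sequences (210 and
300 residues) carrying the anchor contexts at fixed offsets (residue 30 of
the receptor — mimicking a DNA-binding-domain location — and residue 120
of the synthase); homologues are derived by uniform substitution outside
the protected motif down to a requested identity (0.3–1.0).

What the fixtures do **not** emulate: real domain architecture and
indel patterns, codon autocorrelation, Sanger read errors, PCR artefacts
and nonspecific annealing, or the phylogenetic structure of a real genome
corpus. Passing fixture tests therefore demonstrates correctness of the
algorithms and bookkeeping under controlled conditions, not expected
sensitivity/specificity on real strain collections; corpus-scale counts
(how many assemblies carry pairs, and in which orientations) depend on the
database snapshot and are not reproducible desk-side.

## Pipeline and problem sizes

`run_screen` composes the stages deterministically given a seed and
persists every intermediate, so each reported number is recomputable from
files on disk. Defaults follow the screening protocol: E < 0.02, 600 bp
maximum intergenic distance, divergent-only primer design, ARE widths
15–30.

The test suite and the acceptance script run at desk scale by design:
cohorts of 100–200 synthetic loci, homologue sets of 20–40 proteins,
7 × 500 bp ARE datasets with 100-shuffle nulls. These sizes give exact
recovery checks and stable empirical p-values while keeping a full run in
the low minutes on one core.
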