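"""Synthetic GC-rich genomes with planted synthase/receptor pairs.

Generates single-contig fixtures emulating a *Streptomyces*-like locus: two
protein-coding genes (a GBL/butenolide synthase homologue and a TetR-family
receptor homologue) in a controlled orientation separated by a controlled
intergenic gap, with chosen motif variants at the primer anchor windows, an
optional planted palindromic ARE in the gap, and order-0 background at 70%
GC. Every generated locus carries a machine-readable ground-truth record
(CDS intervals, strands, planted primer-site coordinates, expected amplicon
length) which is the universal oracle of the test suite; cohort generation
writes the truth as a sidecar TSV next to the sequence files.

Protein sequences are derived from two deterministic synthetic reference
proteins (the "queries"); homologues are produced by mutating non-anchor
residues down to a requested identity. Coding sequences are back-translated
by codon-usage sampling, except at the primer anchor window where a
primer-compatible codon is used whenever the residue is compatible with the
designed primer — mismatching variants therefore produce mismatching DNA
exactly at the motif codons, as in real divergent-pair loci.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .genome_io import (
    STANDARD_AAS,
    CdsFeature,
    CodonUsageTable,
    GenomeRecord,
    expand_degenerate,
    revcomp,
    write_fasta,
)
from .insilico_pcr import match_primer
from .primer_design import DegeneratePrimer, bundled_primers

# anchor geometry (residue offsets of the primer context within each protein)
RECEPTOR_LEN = 210
SYNTHASE_LEN = 300
RECEPTOR_ANCHOR = 30  # YFHFPSKER at residues 30..38 (DNA-binding domain)
SYNTHASE_ANCHOR = 120  # ETxRQSG at residues 120..126

RECEPTOR_CONTEXT = "YFHFPSKER"
SYNTHASE_CONTEXT_TEMPLATE = "ET{}RQSG"  # slot for the variable third residue

DEFAULT_ARE = "TGAGCGGACGTCCGCTCA"  # 18 bp perfect inverted repeat

_GC_BG = np.array([0.15, 0.35, 0.35, 0.15])  # A C G T at 70% GC
_BASES = np.array(list("ACGT"))


@dataclass
class PlantSpec:
    """Specification of one planted locus."""

    orientation: str = "divergent"
    gap: int = 180
    receptor_variant: str = "YFHF"
    synthase_variant: str = "ETLRQ"
    are: tuple[str, int] | None = None  # (consensus, offset within gap)
    identity: float = 1.0
    seed: int = 0
    flank: int = 150
    contig_id: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ("divergent", "convergent", "tandem"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if len(self.receptor_variant) != 4:
            raise ValueError("receptor variant must have length 4")
        if len(self.synthase_variant) != 5:
            raise ValueError("synthase variant must have length 5")
        if not 0.3 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0.3, 1.0]")
        if self.are is not None:
            consensus, off = self.are
            if off < 0 or off + len(consensus) > self.gap:
                raise ValueError("ARE does not fit in the intergenic gap")


@dataclass
class LocusTruth:
    """Ground truth for one generated locus."""

    contig_id: str
    orientation: str
    gap: int
    receptor_start: int
    receptor_end: int
    receptor_strand: str
    synthase_start: int
    synthase_end: int
    synthase_strand: str
    intergenic_start: int
    intergenic_end: int
    receptor_variant: str
    synthase_variant: str
    fwd_site: tuple[int, int, str] | None  # scb_F footprint (start, end, strand)
    rev_site: tuple[int, int, str] | None
    are_offset: int | None
    expected_amplicon: int | None  # outer-edge to outer-edge, None if no product

    def as_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items()
               if k not in ("fwd_site", "rev_site")}
        for name, site in (("fwd", self.fwd_site), ("rev", self.rev_site)):
            row[f"{name}_site_start"] = site[0] if site else -1
            row[f"{name}_site_end"] = site[1] if site else -1
            row[f"{name}_site_strand"] = site[2] if site else "."
        row["are_offset"] = -1 if self.are_offset is None else self.are_offset
        row["expected_amplicon"] = self.expected_amplicon or 0
        return row


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aas = np.array(list(STANDARD_AAS))
    return "M" + "".join(rng.choice(aas, size=length - 1))


def reference_proteins(seed: int = 20210) -> tuple[str, str]:
    """Deterministic synthetic query proteins (receptor, synthase).

    The receptor carries the YFHFPSKER anchor context at residue 30, the
    synthase carries ETLRQSG at residue 120. These stand in for real GBL
    receptor/synthase queries in fixture-based tests (synthetic sequences,
    not database entries).
    """
    rng = np.random.default_rng(seed)
    receptor = _random_protein(rng, RECEPTOR_LEN)
    receptor = receptor[:RECEPTOR_ANCHOR] + RECEPTOR_CONTEXT \
        + receptor[RECEPTOR_ANCHOR + len(RECEPTOR_CONTEXT):]
    synthase = _random_protein(rng, SYNTHASE_LEN)
    ctx = SYNTHASE_CONTEXT_TEMPLATE.format("L")
    synthase = synthase[:SYNTHASE_ANCHOR] + ctx \
        + synthase[SYNTHASE_ANCHOR + len(ctx):]
    return receptor, synthase


def _anchor_positions(role: str) -> set[int]:
    """Positions protected from mutation: the conserved motif itself.

    The 5'-context residues (PSKER / SG) are *not* protected — in real
    homologue sets only the motif is strongly conserved, and the primers
    accept mismatch risk over the context region.
    """
    if role == "receptor":
        return set(range(RECEPTOR_ANCHOR, RECEPTOR_ANCHOR + 4))
    return set(range(SYNTHASE_ANCHOR, SYNTHASE_ANCHOR + 5))


def mutate_protein(protein: str, identity: float, rng: np.random.Generator,
                   protected: set[int] = frozenset()) -> str:
    """Mutate unprotected residues uniformly to reach the target identity."""
    out = list(protein)
    candidates = [i for i in range(1, len(protein)) if i not in protected]
    n_mut = round((1.0 - identity) * len(protein))
    n_mut = min(n_mut, len(candidates))
    for i in rng.choice(len(candidates), size=n_mut, replace=False):
        pos = candidates[int(i)]
        choices = STANDARD_AAS.replace(out[pos], "")
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def _variant_protein(reference: str, role: str, variant: str) -> str:
    """Write a motif variant into the anchor window of a homologue protein."""
    anchor = RECEPTOR_ANCHOR if role == "receptor" else SYNTHASE_ANCHOR
    out = list(reference)
    for k, res in enumerate(variant):
        if res != "x":
            out[anchor + k] = res
    return "".join(out)


def _compatible_codon(residue: str, primer_codon_sets: list[str] | None,
                      table: CodonUsageTable, rng: np.random.Generator,
                      primer_codon: str | None) -> str:
    """Codon for a residue; inside the anchor, prefer a primer-compatible one."""
    codons = table.codons(residue)
    if primer_codon is not None:
        allowed = expand_degenerate(primer_codon)
        compatible = [(c, f) for c, f in codons if c in allowed]
        if compatible:
            return compatible[0][0]  # highest-usage compatible codon
    # usage-weighted sampling
    names = [c for c, _ in codons]
    freqs = np.array([f for _, f in codons])
    return names[int(rng.choice(len(names), p=freqs / freqs.sum()))]


def _back_translate_protein(protein: str, role: str, primer: DegeneratePrimer,
                            table: CodonUsageTable, rng: np.random.Generator) -> str:
    """Coding DNA for a homologue protein (stop codon appended).

    At the primer anchor window the most frequent primer-compatible codon is
    used when one exists, so designed motifs yield perfect primer sites and
    variant motifs yield mismatches exactly at their codons.
    """
    anchor = RECEPTOR_ANCHOR if role == "receptor" else SYNTHASE_ANCHOR
    primer_coding = revcomp(primer.sequence)
    n_ctx = len(primer_coding) // 3
    codons = []
    for i, res in enumerate(protein):
        pc = None
        if anchor <= i < anchor + n_ctx:
            k = i - anchor
            pc = primer_coding[3 * k:3 * k + 3]
        codons.append(_compatible_codon(res, None, table, rng, pc))
    return "".join(codons) + "TGA"


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_GC_BG)) if n else ""


def generate_pair_locus(spec: PlantSpec, codon_table: CodonUsageTable | None = None,
                        max_retries: int = 20) -> tuple[GenomeRecord, LocusTruth]:
    """Build one contig with a planted synthase/receptor pair.

    The receptor gene is placed left of the synthase gene; strands follow
    the requested orientation (divergent: receptor -, synthase +). Retries
    with derived sub-seeds until the contig contains no spurious primer
    sites beyond the planted ones.
    """
    codon_table = codon_table or CodonUsageTable.bundled()
    primers = bundled_primers(codon_table)
    scb_f, scb_r = primers["scb_F"], primers["scb_R"]
    ref_receptor, ref_synthase = reference_proteins()

    for attempt in range(max_retries):
        rng = np.random.default_rng((spec.seed, attempt))
        rec_prot = _variant_protein(
            mutate_protein(ref_receptor, spec.identity, rng, _anchor_positions("receptor")),
            "receptor", spec.receptor_variant)
        syn_prot = _variant_protein(
            mutate_protein(ref_synthase, spec.identity, rng, _anchor_positions("synthase")),
            "synthase", spec.synthase_variant)
        rec_cds = _back_translate_protein(rec_prot, "receptor", scb_f, codon_table, rng)
        syn_cds = _back_translate_protein(syn_prot, "synthase", scb_r, codon_table, rng)

        strands = {"divergent": ("-", "+"), "convergent": ("+", "-"),
                   "tandem": ("+", "+")}[spec.orientation]
        rec_strand, syn_strand = strands
        rec_plus = rec_cds if rec_strand == "+" else revcomp(rec_cds)
        syn_plus = syn_cds if syn_strand == "+" else revcomp(syn_cds)

        gap_seq = _random_dna(rng, spec.gap)
        are_offset = None
        if spec.are is not None:
            consensus, off = spec.are
            gap_seq = gap_seq[:off] + consensus + gap_seq[off + len(consensus):]
            are_offset = off

        flank_l = _random_dna(rng, spec.flank)
        flank_r = _random_dna(rng, spec.flank)
        seq = flank_l + rec_plus + gap_seq + syn_plus + flank_r
        rec_start = len(flank_l)
        rec_end = rec_start + len(rec_plus)
        syn_start = rec_end + spec.gap
        syn_end = syn_start + len(syn_plus)
        contig_id = spec.contig_id or f"synthetic_{spec.seed}"
        genome = GenomeRecord(contig_id, seq, source_path="<synthetic>")
        genome.features = [
            CdsFeature(contig_id, rec_start, rec_end, rec_strand,
                       f"{contig_id}_receptor", rec_prot),
            CdsFeature(contig_id, syn_start, syn_end, syn_strand,
                       f"{contig_id}_synthase", syn_prot),
        ]

        # locate planted sites; reject contigs with spurious extra sites
        f_matches = match_primer(scb_f, seq, 0, 3, contig_id)
        r_matches = match_primer(scb_r, seq, 0, 3, contig_id)
        f_expected = _planted_footprint(spec, "receptor", rec_start, rec_end,
                                        rec_strand, len(scb_f.sequence))
        r_expected = _planted_footprint(spec, "synthase", syn_start, syn_end,
                                        syn_strand, len(scb_r.sequence))
        f_site = _match_at(f_matches, f_expected)
        r_site = _match_at(r_matches, r_expected)
        spurious = (len(f_matches) > (1 if f_site else 0)
                    or len(r_matches) > (1 if r_site else 0))
        if spurious and attempt < max_retries - 1:
            continue

        expected = None
        if (spec.orientation == "divergent" and f_site and r_site
                and f_site[2] == "+" and r_site[2] == "-"):
            expected = r_site[1] - f_site[0]
        truth = LocusTruth(
            contig_id=contig_id, orientation=spec.orientation, gap=spec.gap,
            receptor_start=rec_start, receptor_end=rec_end, receptor_strand=rec_strand,
            synthase_start=syn_start, synthase_end=syn_end, synthase_strand=syn_strand,
            intergenic_start=rec_end, intergenic_end=syn_start,
            receptor_variant=spec.receptor_variant, synthase_variant=spec.synthase_variant,
            fwd_site=f_site, rev_site=r_site, are_offset=are_offset,
            expected_amplicon=expected)
        return genome, truth
    raise RuntimeError("unreachable")


def _planted_footprint(spec: PlantSpec, role: str, gene_start: int, gene_end: int,
                       strand: str, primer_len: int) -> tuple[int, int, str]:
    """Plus-strand footprint interval where the primer site was planted."""
    anchor = RECEPTOR_ANCHOR if role == "receptor" else SYNTHASE_ANCHOR
    nt0 = 3 * anchor
    if strand == "+":
        start = gene_start + nt0
        # primer anneals to plus-strand coding sequence -> '-' orientation match
        return (start, start + primer_len, "-")
    start = gene_end - nt0 - primer_len
    return (start, start + primer_len, "+")


def _match_at(matches, expected: tuple[int, int, str]):
    for m in matches:
        if (m.start, m.end, m.strand) == expected and m.mismatches == 0:
            return expected
    return None


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(n: int, orientation_mix: Mapping[str, float] | None = None,
                    receptor_variants: Mapping[str, float] | None = None,
                    synthase_variants: Mapping[str, float] | None = None,
                    seed: int = 0, gap_range: tuple[int, int] = (120, 400),
                    identity: float = 1.0):
    """Generate *n* loci with sampled orientations, variants and gaps.

    Returns ``(records, truth DataFrame)``; deterministic given *seed*.
    """
    import pandas as pd

    if n <= 0:
        raise ValueError("n must be positive")
    orientation_mix = dict(orientation_mix or {"divergent": 1.0})
    receptor_variants = dict(receptor_variants or {"YFHF": 1.0})
    synthase_variants = dict(synthase_variants or {"ETLRQ": 1.0})
    for name, mix in (("orientation_mix", orientation_mix),
                      ("receptor_variants", receptor_variants),
                      ("synthase_variants", synthase_variants)):
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"{name} proportions must sum to 1")
    rng = np.random.default_rng(seed)

    def draw(mix: dict[str, float]) -> str:
        keys = sorted(mix)
        return keys[int(rng.choice(len(keys), p=[mix[k] for k in keys]))]

    records, rows = [], []
    for i in range(n):
        spec = PlantSpec(
            orientation=draw(orientation_mix),
            gap=int(rng.integers(gap_range[0], gap_range[1] + 1)),
            receptor_variant=draw(receptor_variants),
            synthase_variant=draw(synthase_variants),
            identity=identity,
            seed=int(rng.integers(0, 2**31 - 1)),
            contig_id=f"cohort_{seed}_{i}",
        )
        genome, truth = generate_pair_locus(spec)
        records.append(genome)
        rows.append(truth.as_row())
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writing fixtures to disk
# ---------------------------------------------------------------------------

def write_fixture(genome: GenomeRecord, outdir: str | Path,
                  formats: tuple[str, ...] = ("genbank", "gff3", "fasta")) -> dict[str, Path]:
    """Write a generated contig as GenBank / GFF3+FASTA files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if "fasta" in formats or "gff3" in formats:
        fasta = outdir / f"{genome.contig_id}.fasta"
        write_fasta([(genome.contig_id, genome.sequence)], fasta)
        paths["fasta"] = fasta
    if "genbank" in formats:
        paths["genbank"] = _write_genbank(genome, outdir / f"{genome.contig_id}.gbk")
    if "gff3" in formats:
        paths["gff3"] = _write_gff3(genome, outdir / f"{genome.contig_id}.gff3")
    return paths


def _write_genbank(genome: GenomeRecord, path: Path) -> Path:
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    rec = SeqRecord(Seq(genome.sequence), id=genome.contig_id,
                    name=genome.contig_id[:16], description="synthetic fixture",
                    annotations={"molecule_type": "DNA", "date": "01-JAN-2023",
                                 "topology": "linear"})
    for f in genome.features:
        loc = FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1)
        rec.features.append(SeqFeature(loc, type="CDS", qualifiers={
            "locus_tag": [f.locus_tag], "transl_table": ["11"],
            "translation": [f.protein]}))
    SeqIO.write([rec], str(path), "genbank")
    return path


def _write_gff3(genome: GenomeRecord, path: Path) -> Path:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.contig_id} 1 {len(genome.sequence)}\n")
        for i, f in enumerate(genome.features):
            attrs = f"ID=cds{i};locus_tag={f.locus_tag};translation={f.protein}"
            fh.write("\t".join([genome.contig_id, "gblscreen", "CDS",
                                str(f.start + 1), str(f.end), ".", f.strand, "0",
                                attrs]) + "\n")
    return path


def write_cohort(records, truth, outdir: str | Path,
                 formats: tuple[str, ...] = ("genbank",)) -> Path:
    """Write a cohort with its sidecar ground-truth TSV; returns the TSV path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in records:
        write_fixture(genome, outdir, formats)
    tsv = outdir / "truth.tsv"
    truth.to_csv(tsv, sep="\t", index=False)
    return tsv


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def validation_panel(seed: int = 7) -> list[tuple[PlantSpec, str]]:
    """Loci spanning the qualitative outcome classes of a wet-lab panel:
    designed motifs on both sides (product expected), one conservative
    synthase variant (product expected), and two loci with 3'-anchor
    mismatches (no product at zero allowed mismatches)."""
    return [
        (PlantSpec(gap=102, receptor_variant="YFHF", synthase_variant="ETIRQ",
                   seed=seed, contig_id="panel_plasmid_like"), "product"),
        (PlantSpec(gap=180, receptor_variant="YFHF", synthase_variant="ETLRQ",
                   seed=seed + 1, contig_id="panel_designed"), "product"),
        (PlantSpec(gap=200, receptor_variant="HHHF", synthase_variant="EAIRQ",
                   seed=seed + 2, contig_id="panel_mismatch_a"), "none"),
        (PlantSpec(gap=170, receptor_variant="YHHF", synthase_variant="ESVRQ",
                   seed=seed + 3, contig_id="panel_mismatch_b"), "none"),
    ]


def simulate_homolog_proteins(n: int, role: str,
                              variant_mix: Mapping[str, float] | None = None,
                              identity: float = 0.7, seed: int = 0) -> list[str]:
    """Homologue protein sets for alignment/conservation tests.

    Index 0 is the unmutated reference (query); the rest are mutated to the
    requested identity with anchor-window residues set per *variant_mix*.
    """
    rng = np.random.default_rng(seed)
    ref = reference_proteins()[0 if role == "receptor" else 1]
    default = {"YFHF": 1.0} if role == "receptor" else {"ETLRQ": 1.0}
    variant_mix = dict(variant_mix or default)
    keys = sorted(variant_mix)
    p = np.array([variant_mix[k] for k in keys])
    out = [ref]
    for _ in range(n - 1):
        prot = mutate_protein(ref, identity, rng, _anchor_positions(role))
        variant = keys[int(rng.choice(len(keys), p=p / p.sum()))]
        out.append(_variant_protein(prot, role, variant))
    return out
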