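"""Reading annotated genomes and nucleotide/codon utilities.

This module provides the I/O substrate for the screen: annotated genomes
(GenBank flat files or GFF3 + genomic FASTA) are read into lightweight
:class:`GenomeRecord` / :class:`CdsFeature` objects with 0-based half-open
coordinates, CDS translations are taken from the annotation when present and
recomputed with the bacterial genetic code (table 11) otherwise, and IUPAC
degenerate-nucleotide arithmetic (reverse complement, expansion, degeneracy)
is implemented once for use by the primer-design and in-silico PCR stages.

A codon usage table for a high-GC *Streptomyces*-style genome is bundled as a
package data file (see :meth:`CodonUsageTable.bundled`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# IUPAC degenerate-nucleotide arithmetic
# ---------------------------------------------------------------------------

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"


class GenomeFormatError(ValueError):
    """An input file could not be parsed in the declared dialect."""


class PseudogeneError(ValueError):
    """A CDS translates with an internal stop codon."""


class DegeneracyError(ValueError):
    """Expanding a degenerate sequence would exceed the configured cap."""


def iupac_code(bases: Iterable[str]) -> str:
    """Return the single IUPAC code covering a set of concrete bases."""
    key = frozenset(bases)
    try:
        return _SET_TO_CODE[key]
    except KeyError:
        raise ValueError(f"not a valid base set: {sorted(key)}") from None


def revcomp(seq: str) -> str:
    """Reverse-complement an IUPAC DNA string (degenerate codes included).

    An involution: ``revcomp(revcomp(s)) == s``.
    """
    out = []
    for i, c in enumerate(reversed(seq.upper())):
        try:
            out.append(_COMPLEMENT[c])
        except KeyError:
            pos = len(seq) - 1 - i
            raise ValueError(f"invalid IUPAC character {c!r} at position {pos}") from None
    return "".join(out)


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate IUPAC string represents."""
    n = 1
    for i, c in enumerate(seq.upper()):
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC character {c!r} at position {i}")
        n *= len(IUPAC_SETS[c])
    return n


def expand_degenerate(seq: str, cap: int = 65536) -> set[str]:
    """Enumerate every concrete DNA string matching a degenerate one.

    Raises :class:`DegeneracyError` (reporting the required count) if the
    expansion would exceed *cap*.
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    n = degeneracy(seq)
    if n > cap:
        raise DegeneracyError(f"expansion of {seq!r} requires {n} sequences (cap {cap})")
    pools = [sorted(IUPAC_SETS[c]) for c in seq.upper()]
    out = {""}
    for pool in pools:
        out = {prefix + b for prefix in out for b in pool}
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CdsFeature:
    """A protein-coding gene on a contig, 0-based half-open coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    protein: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.locus_tag}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """One contig with its CDS annotation."""

    contig_id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_id}")

    def proteome(self) -> list[CdsFeature]:
        return [f for f in self.features if f.protein]


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

class CodonUsageTable:
    """Per-amino-acid relative codon frequencies.

    Frequencies for each amino acid sum to 1; all 20 standard amino acids
    must be present.
    """

    def __init__(self, table: Mapping[str, Sequence[tuple[str, float]]], organism: str = ""):
        self.organism = organism
        self._table: dict[str, list[tuple[str, float]]] = {}
        for aa, pairs in table.items():
            # descending frequency, codon string as deterministic tie-break
            self._table[aa] = sorted(pairs, key=lambda p: (-p[1], p[0]))
        missing = set(STANDARD_AAS) - set(self._table)
        if missing:
            raise ValueError(f"codon table missing amino acids: {sorted(missing)}")
        for aa, pairs in self._table.items():
            total = sum(f for _, f in pairs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies for {aa} sum to {total}, not 1")

    @classmethod
    def from_tsv(cls, path: str | Path, organism: str = "") -> "CodonUsageTable":
        table: dict[str, list[tuple[str, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("amino_acid"):
                    continue
                aa, codon, frac = line.split("\t")
                table.setdefault(aa, []).append((codon.upper(), float(frac)))
        return cls(table, organism=organism or Path(path).stem)

    @classmethod
    def bundled(cls) -> "CodonUsageTable":
        """The packaged high-GC *Streptomyces*-style table."""
        ref = resources.files("gblscreen.data") / "codon_usage_streptomyces.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path, organism="Streptomyces (bundled)")

    def codons(self, aa: str) -> list[tuple[str, float]]:
        """All codons of *aa* with frequencies, most frequent first."""
        return list(self._table[aa.upper()])

    def most_frequent(self, aa: str) -> str:
        return self._table[aa.upper()][0][0]

    def top_codons(self, aa: str, k: int) -> list[str]:
        return [c for c, _ in self._table[aa.upper()][:k]]

    def codons_above(self, aa: str, min_freq: float) -> list[str]:
        return [c for c, f in self._table[aa.upper()] if f >= min_freq]

    def frequency(self, codon: str) -> float:
        codon = codon.upper()
        for pairs in self._table.values():
            for c, f in pairs:
                if c == codon:
                    return f
        raise KeyError(codon)

    def amino_acids(self) -> list[str]:
        return sorted(self._table)


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def translate_dna(coding: str, table: int = 11) -> str:
    """Translate a coding-sense DNA string; trailing stop removed.

    Raises :class:`PseudogeneError` on internal stop codons.
    """
    if len(coding) % 3 != 0:
        raise ValueError(f"coding length {len(coding)} not divisible by 3")
    prot = str(Seq(coding).translate(table=table))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise PseudogeneError(f"internal stop codon at residue {prot.index('*')}")
    return prot


def translate_cds(feature: CdsFeature, genome: GenomeRecord, table: int = 11) -> str:
    """Translate a CDS from genomic sequence (minus strand reverse-complemented)."""
    sub = genome.sequence[feature.start:feature.end]
    if feature.strand == "-":
        sub = revcomp(sub)
    return translate_dna(sub, table=table)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _attach_translation(feat: CdsFeature, genome: GenomeRecord, annotated: str | None) -> None:
    try:
        computed = translate_cds(feat, genome)
    except (ValueError, PseudogeneError) as exc:
        computed = ""
        if not annotated:
            logger.warning("could not translate %s: %s", feat.locus_tag, exc)
    if annotated:
        # annotation wins; bacterial GTG/TTG starts are annotated M
        if computed and annotated not in (computed, "M" + computed[1:]):
            logger.warning("annotated translation of %s differs from recomputed one",
                           feat.locus_tag)
        feat.protein = annotated
    else:
        feat.protein = computed


def _read_genbank(path: Path) -> list[GenomeRecord]:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise GenomeFormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    out: list[GenomeRecord] = []
    for rec in records:
        seq = str(rec.seq).upper()
        genome = GenomeRecord(rec.id, seq, [], source_path=str(path))
        n_cds = 0
        for f in rec.features:
            if f.type != "CDS":
                continue
            n_cds += 1
            start, end = int(f.location.start), int(f.location.end)
            if start < 0 or end > len(seq):
                logger.warning("%s: CDS %s outside contig bounds, skipped", rec.id, n_cds)
                continue
            strand = "-" if f.location.strand == -1 else "+"
            tag = f.qualifiers.get("locus_tag", [f"cds_{n_cds}"])[0]
            feat = CdsFeature(rec.id, start, end, strand, tag)
            annotated = f.qualifiers.get("translation", [None])[0]
            _attach_translation(feat, genome, annotated)
            genome.features.append(feat)
        out.append(genome)
    return out


def _find_companion_fasta(gff_path: Path) -> Path:
    for ext in (".fasta", ".fa", ".fna"):
        cand = gff_path.with_suffix(ext)
        if cand.exists():
            return cand
    raise GenomeFormatError(f"no companion FASTA found next to {gff_path}")


def _read_gff3_fasta(gff_path: Path, fasta_path: Path | None) -> list[GenomeRecord]:
    import gffutils

    fasta_path = fasta_path or _find_companion_fasta(gff_path)
    try:
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    except Exception as exc:
        raise GenomeFormatError(f"{fasta_path}: not parseable as FASTA: {exc}") from exc
    if not contigs and gff_path.stat().st_size == 0:
        return []
    try:
        db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                                merge_strategy="create_unique", keep_order=True)
    except Exception as exc:
        raise GenomeFormatError(f"{gff_path}: not parseable as GFF3: {exc}") from exc
    genomes = {cid: GenomeRecord(cid, seq, [], source_path=str(gff_path))
               for cid, seq in contigs.items()}
    for f in db.features_of_type("CDS", order_by=("seqid", "start")):
        if f.seqid not in genomes:
            logger.warning("CDS on unknown contig %s skipped", f.seqid)
            continue
        genome = genomes[f.seqid]
        start, end = f.start - 1, f.end  # GFF3 is 1-based inclusive
        if start < 0 or end > len(genome.sequence):
            logger.warning("%s: CDS outside contig bounds, skipped", f.seqid)
            continue
        tag = (f.attributes.get("locus_tag") or f.attributes.get("ID") or [f.id])[0]
        feat = CdsFeature(f.seqid, start, end, f.strand, tag)
        annotated = (f.attributes.get("translation") or [None])[0]
        _attach_translation(feat, genome, annotated)
        genome.features.append(feat)
    return list(genomes.values())


def read_annotated_genome(path: str | Path, format: str = "auto",
                          fasta: str | Path | None = None) -> list[GenomeRecord]:
    """Read an annotated genome into :class:`GenomeRecord` objects.

    Parameters
    ----------
    path:
        GenBank flat file, or GFF3 file (with *fasta* or a same-stem
        companion ``.fasta``/``.fa``/``.fna``), or a bare FASTA (no features).
    format:
        ``"genbank"``, ``"gff3+fasta"``, ``"fasta"`` or ``"auto"`` (by
        extension).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        ext = path.suffix.lower()
        if ext in (".gb", ".gbk", ".gbff", ".genbank"):
            format = "genbank"
        elif ext in (".gff", ".gff3"):
            format = "gff3+fasta"
        elif ext in (".fa", ".fasta", ".fna"):
            format = "fasta"
        else:
            raise GenomeFormatError(f"cannot infer format from extension {ext!r}")
    if format == "genbank":
        return _read_genbank(path)
    if format == "gff3+fasta":
        return _read_gff3_fasta(path, Path(fasta) if fasta else None)
    if format == "fasta":
        out = []
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append(GenomeRecord(rec.id, str(rec.seq).upper(), [], source_path=str(path)))
        return out
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# FASTA writing (proteins, intergenic regions)
# ---------------------------------------------------------------------------

def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
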