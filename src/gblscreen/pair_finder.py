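"""Homology search and collocated synthase/receptor pair detection.

Homologues of the two query proteins (a butenolide/GBL synthase and its
TetR-family receptor) are found by local alignment of each query against
every annotated CDS translation (Smith–Waterman, BLOSUM62, affine gaps) with
a Karlin–Altschul expectation computed on an effective search space of
query length x summed proteome length. Hits of the two queries on the same
contig whose inter-CDS gap is at most ``max_intergenic`` (600 bp by default)
form a :class:`GenePair`, classified as divergent (back-to-back), convergent
or tandem; the intergenic regulatory region, where the receptor's operator
(ARE) sits, is defined for divergent pairs only.

The expectation model uses ungapped Karlin–Altschul parameters applied to
gapped scores — an approximation; tests rely on large score margins, not on
threshold parity with BLAST-family tools.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import STANDARD_AAS, CdsFeature, GenomeRecord

# Ungapped Karlin-Altschul parameters for BLOSUM62
KA_LAMBDA = 0.318
KA_K = 0.13

ORIENTATIONS = ("divergent", "convergent", "tandem")


class NonDivergentError(ValueError):
    """Intergenic regulatory region requested for a non-divergent pair."""


@dataclass
class HomologHit:
    query_id: str
    feature: CdsFeature
    score: float
    expectation: float
    identity: float

    def __post_init__(self) -> None:
        if self.expectation < 0:
            raise ValueError("expectation must be >= 0")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")


@dataclass
class GenePair:
    synthase_hit: HomologHit
    receptor_hit: HomologHit
    orientation: str
    intergenic_start: int
    intergenic_end: int
    intergenic_seq: str = ""

    @property
    def contig_id(self) -> str:
        return self.synthase_hit.feature.contig_id

    @property
    def gap(self) -> int:
        return self.intergenic_end - self.intergenic_start


def _make_aligner(matrix: str = "BLOSUM62", gap_open: float = -11.0,
                  gap_extend: float = -1.0, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _alignment_identity(alignment) -> float:
    """Identical residues / aligned columns of a pairwise alignment."""
    a, b = alignment[0], alignment[1]
    cols = ident = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            cols += 1
            continue
        cols += 1
        ident += x == y
    return ident / cols if cols else 0.0


def karlin_altschul_expectation(score: float, query_len: int, db_len: int) -> float:
    """E = K m n exp(-lambda S) with ungapped BLOSUM62 parameters."""
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


def find_homologs(proteome: Sequence[CdsFeature], query: str, query_id: str = "query",
                  matrix: str = "BLOSUM62", evalue_max: float = 0.02,
                  gap_open: float = -11.0, gap_extend: float = -1.0) -> list[HomologHit]:
    """Local-alignment homologue search over annotated CDS translations.

    Returns hits with expectation < *evalue_max*, sorted by descending
    score. Overlapping hits at one locus are deduplicated by best score.
    """
    if not proteome:
        raise ValueError("empty proteome")
    if len(query) < 20:
        raise ValueError("query too short (< 20 residues)")
    bad = set(query.upper()) - set(STANDARD_AAS)
    if bad:
        raise ValueError(f"query contains non-amino-acid characters: {sorted(bad)}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    db_len = sum(len(f.protein) for f in proteome if f.protein)
    hits: list[HomologHit] = []
    for feat in proteome:
        if not feat.protein:
            continue
        subject = feat.protein.replace("*", "").replace("X", "A")
        score = aligner.score(query.upper(), subject)
        expect = karlin_altschul_expectation(score, len(query), db_len)
        if expect >= evalue_max:
            continue
        alignment = aligner.align(query.upper(), subject)[0]
        hits.append(HomologHit(query_id, feat, float(score), expect,
                               _alignment_identity(alignment)))
    hits.sort(key=lambda h: (-h.score, h.feature.contig_id, h.feature.start))
    return _dedup_overlapping(hits)


def _dedup_overlapping(hits: list[HomologHit]) -> list[HomologHit]:
    """Keep the best-scoring hit per overlapping locus (same contig)."""
    kept: list[HomologHit] = []
    for h in hits:  # already sorted by descending score
        f = h.feature
        clash = any(k.feature.contig_id == f.contig_id
                    and min(k.feature.end, f.end) > max(k.feature.start, f.start)
                    for k in kept)
        if not clash:
            kept.append(h)
    return kept


def gap_between(a: CdsFeature, b: CdsFeature) -> int:
    """bp between the nearest boundaries of two CDS; 0 if they overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def classify_orientation(pair_or_left, right: CdsFeature | None = None,
                         overlap_tolerance: int = 30) -> str:
    """Orientation class of two collocated CDS.

    With L/R the left/right feature by coordinate: L(-) R(+) -> divergent
    (back-to-back, 5' ends flanking the gap); L(+) R(-) -> convergent; same
    strand -> tandem. Overlaps beyond *overlap_tolerance* bp are flagged
    ``"ambiguous"`` and excluded from the census proper.
    """
    if right is None:
        a = pair_or_left.synthase_hit.feature
        b = pair_or_left.receptor_hit.feature
    else:
        a, b = pair_or_left, right
    left, rgt = (a, b) if a.start <= b.start else (b, a)
    overlap = max(0, min(left.end, rgt.end) - max(left.start, rgt.start))
    if overlap > overlap_tolerance:
        return "ambiguous"
    if left.strand == rgt.strand:
        return "tandem"
    if left.strand == "-" and rgt.strand == "+":
        return "divergent"
    return "convergent"


def pair_colocated(synthase_hits: Iterable[HomologHit], receptor_hits: Iterable[HomologHit],
                   max_intergenic: int = 600,
                   genomes: Mapping[str, GenomeRecord] | None = None) -> list[GenePair]:
    """All same-contig (synthase, receptor) hit combinations within the gap cutoff.

    If *genomes* maps contig ids to records, intergenic sequences are filled
    in for divergent pairs.
    """
    pairs: list[GenePair] = []
    for s in synthase_hits:
        for r in receptor_hits:
            fs, fr = s.feature, r.feature
            if fs.contig_id != fr.contig_id:
                continue
            if fs.start == fr.start and fs.end == fr.end:
                continue  # same locus hit by both queries
            if gap_between(fs, fr) > max_intergenic:
                continue
            ig_start = min(fs.end, fr.end)
            ig_end = max(fs.start, fr.start)
            if ig_end < ig_start:  # overlapping CDS
                ig_start = ig_end = min(fs.end, fr.end)
            pair = GenePair(s, r, classify_orientation(fs, fr),
                            ig_start, ig_end)
            if genomes is not None and pair.orientation == "divergent":
                genome = genomes.get(fs.contig_id)
                if genome is not None:
                    pair.intergenic_seq = intergenic_sequence(pair, genome)
            pairs.append(pair)
    pairs.sort(key=lambda p: (p.contig_id, p.intergenic_start))
    return pairs


def orientation_census(pairs: Iterable[GenePair]) -> dict[str, int]:
    """Counts per orientation class; keys always present, sum == len(pairs)."""
    counts = {k: 0 for k in (*ORIENTATIONS, "ambiguous")}
    for p in pairs:
        counts[p.orientation] += 1
    return counts


def intergenic_sequence(pair: GenePair, genome: GenomeRecord) -> str:
    """Plus-strand sequence of the gap between a divergent pair's CDS."""
    if pair.orientation != "divergent":
        raise NonDivergentError(
            f"intergenic regulatory region is defined for divergent pairs only "
            f"(got {pair.orientation})")
    return genome.sequence[pair.intergenic_start:pair.intergenic_end]


# ---------------------------------------------------------------------------
# Tabular / FASTA output
# ---------------------------------------------------------------------------

def pairs_to_tsv(pairs: Sequence[GenePair], path) -> None:
    import pandas as pd

    rows = []
    for p in pairs:
        fs, fr = p.synthase_hit.feature, p.receptor_hit.feature
        rows.append({
            "contig": p.contig_id,
            "synthase_locus": fs.locus_tag, "synthase_start": fs.start,
            "synthase_end": fs.end, "synthase_strand": fs.strand,
            "receptor_locus": fr.locus_tag, "receptor_start": fr.start,
            "receptor_end": fr.end, "receptor_strand": fr.strand,
            "orientation": p.orientation, "gap_bp": p.gap,
            "synthase_evalue": f"{p.synthase_hit.expectation:.3g}",
            "receptor_evalue": f"{p.receptor_hit.expectation:.3g}",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def intergenic_to_fasta(pairs: Sequence[GenePair], path) -> None:
    from .genome_io import write_fasta

    entries = [(f"{p.contig_id}:{p.intergenic_start}-{p.intergenic_end}", p.intergenic_seq)
               for p in pairs if p.orientation == "divergent" and p.intergenic_seq]
    write_fasta(entries, path)
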