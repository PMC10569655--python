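"""Degenerate-primer matching, amplicon prediction and priming-class calls.

Matching uses IUPAC set-intersection semantics: a template position is
compatible with a primer position iff their base sets intersect, except that
an ``N`` in the template never matches (unknown template sequence is not
assumed to anneal). A site is accepted when it has at most ``max_mismatch``
incompatible positions and none of them fall within the 3'-terminal
``three_prime_exact`` bases — mismatches at the extending end abolish
priming.

Amplicons are every inward-facing pair of sites on opposite strands whose
product length (5'-most base of one primer footprint to the 5'-most base of
the other, both footprints included) lies within the size window.

:func:`classify_priming` reproduces the qualitative "will prime / will
likely prime / might not prime / will not prime" calls for protein motif
variants at the primer anchor, scored at nucleotide level against the
primer's 3'-proximal codons.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import IUPAC_SETS, CodonUsageTable, revcomp
from .primer_design import DegeneratePrimer

# 4-bit encoding: one bit per concrete base; template N encodes as 0 (never matches)
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_BITS = {code: sum(_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()}
_TEMPLATE_BITS = dict(_CODE_BITS, N=0)


@dataclass(frozen=True)
class PrimerMatch:
    """One annealing site, footprint in plus-strand template coordinates."""

    contig: str
    start: int  # half-open footprint [start, end)
    end: int
    strand: str  # '+': primer reads along plus strand (extends rightward)
    mismatches: int
    mismatch_positions_from_3p: tuple[int, ...] = ()

    @property
    def three_prime_pos(self) -> int:
        """Template position of the primer's 3'-terminal base."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class AmpliconPrediction:
    contig: str
    start: int
    end: int
    forward: PrimerMatch
    reverse: PrimerMatch

    @property
    def length(self) -> int:
        return self.end - self.start


class PrimeClass(enum.IntEnum):
    """Priming likelihood, best to worst (total order)."""

    WILL_PRIME = 0
    WILL_LIKELY_PRIME = 1
    MIGHT_NOT_PRIME = 2
    WILL_NOT_PRIME = 3

    def __str__(self) -> str:  # "will_prime" etc.
        return self.name.lower()


def _encode_template(template: str) -> np.ndarray:
    try:
        return np.array([_TEMPLATE_BITS[c] for c in template.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid template character {exc.args[0]!r}") from None


def _scan_one_strand(primer_bits: np.ndarray, tmpl_bits: np.ndarray,
                     max_mismatch: int, exact_idx: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """Offsets where primer_bits matches tmpl_bits with the 3' rule.

    exact_idx: primer indices (0-based from primer's left end in template
    orientation) that must match exactly.
    """
    L, T = len(primer_bits), len(tmpl_bits)
    n_off = T - L + 1
    if n_off <= 0:
        return []
    mism = np.zeros((n_off, L), dtype=bool)
    for k in range(L):
        mism[:, k] = (tmpl_bits[k:k + n_off] & primer_bits[k]) == 0
    total = mism.sum(axis=1)
    ok = total <= max_mismatch
    if len(exact_idx):
        ok &= ~mism[:, exact_idx].any(axis=1)
    return [(int(i), np.nonzero(mism[i])[0]) for i in np.nonzero(ok)[0]]


def match_primer(primer: DegeneratePrimer | str, template: str,
                 max_mismatch: int = 0, three_prime_exact: int = 3,
                 contig: str = "template") -> list[PrimerMatch]:
    """All annealing sites of a degenerate primer on both template strands."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    seq = seq.upper()
    L = len(seq)
    tmpl_bits = _encode_template(template)
    if L > len(tmpl_bits):
        return []
    fwd_bits = np.array([_CODE_BITS[c] for c in seq], dtype=np.uint8)
    rev_bits = np.array([_CODE_BITS[c] for c in revcomp(seq)], dtype=np.uint8)
    w = min(three_prime_exact, L)
    out: list[PrimerMatch] = []
    # '+': primer sequence aligns to plus strand; 3' end is rightmost base
    for off, mis in _scan_one_strand(fwd_bits, tmpl_bits, max_mismatch,
                                     np.arange(L - w, L)):
        d3 = tuple(sorted(L - 1 - int(k) for k in mis))
        out.append(PrimerMatch(contig, off, off + L, "+", len(mis), d3))
    # '-': revcomp(primer) aligns to plus strand; 3' end is leftmost base
    for off, mis in _scan_one_strand(rev_bits, tmpl_bits, max_mismatch,
                                     np.arange(0, w)):
        d3 = tuple(sorted(int(k) for k in mis))
        out.append(PrimerMatch(contig, off, off + L, "-", len(mis), d3))
    out.sort(key=lambda m: (m.start, m.strand))
    return out


def predict_amplicons(fwd: DegeneratePrimer | str, rev: DegeneratePrimer | str,
                      template: str, min_size: int = 100, max_size: int = 3000,
                      max_mismatch: int = 0, three_prime_exact: int = 3,
                      contig: str = "template") -> list[AmpliconPrediction]:
    """Predict PCR products from every inward-facing site pair.

    Symmetric in the primer labels: each product requires one site on each
    strand, one primer per strand, in either assignment.
    """
    mf = match_primer(fwd, template, max_mismatch, three_prime_exact, contig)
    mr = match_primer(rev, template, max_mismatch, three_prime_exact, contig)
    seen: set[tuple[int, int]] = set()
    out: list[AmpliconPrediction] = []
    for plus_set, minus_set in ((mf, mr), (mr, mf)):
        for a in plus_set:
            if a.strand != "+":
                continue
            for b in minus_set:
                if b.strand != "-":
                    continue
                if not (a.start <= b.start and a.end <= b.end):
                    continue  # outward-facing or nested
                length = b.end - a.start
                if not (min_size <= length <= max_size):
                    continue
                key = (a.start, b.end)
                if key in seen:
                    continue
                seen.add(key)
                out.append(AmpliconPrediction(contig, a.start, b.end, a, b))
    out.sort(key=lambda amp: (amp.start, amp.end))
    return out


def amplicons_to_tsv(amplicons: Sequence[AmpliconPrediction], path) -> None:
    import pandas as pd

    rows = [{
        "contig": a.contig, "start": a.start, "end": a.end, "length_bp": a.length,
        "fwd_site": f"{a.forward.start}-{a.forward.end}({a.forward.strand})",
        "rev_site": f"{a.reverse.start}-{a.reverse.end}({a.reverse.strand})",
        "fwd_mismatches": a.forward.mismatches, "rev_mismatches": a.reverse.mismatches,
    } for a in amplicons]
    pd.DataFrame(rows, columns=["contig", "start", "end", "length_bp", "fwd_site",
                                "rev_site", "fwd_mismatches", "rev_mismatches"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Priming-class calls for motif variants
# ---------------------------------------------------------------------------

def _min_codon_mismatch(residue: str, primer_codon: str,
                        table: CodonUsageTable) -> int:
    """Fewest incompatible bases between any codon of *residue* and the
    primer's degenerate codon."""
    best = 3
    for codon, _ in table.codons(residue):
        d = sum(1 for k in range(3)
                if not (IUPAC_SETS[codon[k]] & IUPAC_SETS[primer_codon[k]]))
        best = min(best, d)
    return best


def _codon_coverage(primer_codon: str) -> int:
    """Number of distinct residues the primer codon's expansions encode."""
    from .genome_io import expand_degenerate
    from Bio.Seq import Seq

    return len({str(Seq(c).translate(table=11)) for c in expand_degenerate(primer_codon)})


def classify_priming(variant: str, reference: str, primer: DegeneratePrimer,
                     codon_table: CodonUsageTable | None = None) -> PrimeClass:
    """Priming-likelihood class of a protein motif variant at a primer anchor.

    *variant* is a motif-length string over amino-acid letters plus the
    wildcard ``x`` (an aggregated/unknown residue); *reference* is the
    primer's designed motif pattern and fixes the expected length. Scoring is
    at nucleotide level against the primer's 3'-proximal codons (codon 1 =
    the primer's 3'-terminal codon):

    - any definite mismatch in codon 1, >=2 mismatching bases in codon 2, or
      >=3 mismatching bases overall -> ``will_not_prime``
    - any other definite mismatch before the last motif codon, or a wildcard
      at a position where the primer codon encodes <=2 residues
      -> ``might_not_prime``
    - mismatches confined to the last motif codon, or wildcards only at the
      last codon / at broadly degenerate primer codons (>=3 residues covered)
      -> ``will_likely_prime``
    - otherwise -> ``will_prime``
    """
    codon_table = codon_table or CodonUsageTable.bundled()
    if len(variant) != len(reference):
        raise ValueError(
            f"variant length {len(variant)} != reference length {len(reference)}")
    codons = primer.motif_codons()
    if len(variant) != len(codons):
        raise ValueError(
            f"variant length {len(variant)} != primer motif length {len(codons)}")
    m = len(codons)
    definite = [0] * m
    uncertain_narrow = False
    uncertain_any = False
    for i, (res, pcodon) in enumerate(zip(variant.upper(), codons)):
        if res == "X":
            uncertain_any = True
            if i < m - 1 and _codon_coverage(pcodon) <= 2:
                uncertain_narrow = True
        else:
            definite[i] = _min_codon_mismatch(res, pcodon, codon_table)
    total = sum(definite)
    if definite[0] >= 1 or (m > 1 and definite[1] >= 2) or total >= 3:
        return PrimeClass.WILL_NOT_PRIME
    if any(d >= 1 for d in definite[:-1]) or uncertain_narrow:
        return PrimeClass.MIGHT_NOT_PRIME
    if definite[-1] >= 1 or uncertain_any:
        return PrimeClass.WILL_LIKELY_PRIME
    return PrimeClass.WILL_PRIME
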