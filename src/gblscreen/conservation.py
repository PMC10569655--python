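"""Homologue alignment, per-column conservation and motif-based efficacy.

The homologue protein sets recovered by the pair search are aligned with a
star alignment around the query (each sequence globally aligned to the
reference, merged on reference coordinates), per-column information content
is computed from residue frequencies (log2(20) minus Shannon entropy, with a
1/20-per-residue pseudocount, scaled by column occupancy), and candidate
primer-anchor windows of 4-6 residues are ranked by mean information
content. Within a selected window, positions whose modal residue falls below
``wildcard_threshold`` are written as the wildcard ``x`` — this is how a
variable position such as the third residue of ``ETxRQ`` is reported.

Motif-variant counting over the window (wildcards match anything) and the
amplifiability estimate — the fraction of index-paired receptor/synthase
variants matching both anchor patterns — quantify how much of a pair cohort
the degenerate primers can be expected to amplify.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome_io import STANDARD_AAS
from .pair_finder import _make_aligner

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AAS)}
MAX_IC = math.log2(20.0)


@dataclass
class Msa:
    """A reference-anchored multiple alignment (gap character '-')."""

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def to_fasta(self, path) -> None:
        from .genome_io import write_fasta
        write_fasta(zip(self.ids, self.rows), path)


@dataclass
class ConservationProfile:
    """Per-column information content (bits), frequencies and occupancy."""

    information: np.ndarray  # (ncols,)
    frequencies: np.ndarray  # (ncols, 20), rows sum to 1
    occupancy: np.ndarray  # non-gap fraction per column

    def __len__(self) -> int:
        return len(self.information)

    def to_tsv(self, path) -> None:
        import pandas as pd

        consensus = ["-" if self.occupancy[i] == 0
                     else STANDARD_AAS[int(np.argmax(self.frequencies[i]))]
                     for i in range(len(self))]
        pd.DataFrame({
            "column": np.arange(len(self)),
            "information_bits": np.round(self.information, 4),
            "occupancy": np.round(self.occupancy, 4),
            "consensus": consensus,
        }).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MotifPattern:
    """Window pattern over amino-acid letters plus wildcard 'x'.

    *columns* are the alignment columns the window was read from (consecutive
    reference-anchored columns; insertion columns may intervene).
    """

    pattern: str
    start_col: int = 0
    columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not any(c != "x" for c in self.pattern):
            raise ValueError("pattern must have at least one non-wildcard position")
        if self.columns and len(self.columns) != len(self.pattern):
            raise ValueError("columns must match pattern length")

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, variant: str) -> bool:
        if len(variant) != len(self.pattern):
            raise ValueError(
                f"variant length {len(variant)} != pattern length {len(self.pattern)}")
        return all(p == "x" or p == v for p, v in zip(self.pattern, variant.upper()))


# ---------------------------------------------------------------------------
# Star alignment
# ---------------------------------------------------------------------------

def _pairwise_to_ref(reference: str, seq: str, aligner) -> tuple[list[str], list[str]]:
    """Align seq to reference; return (at, between).

    at[r]: seq character aligned to reference residue r ('-' for deletion).
    between[r]: seq residues inserted before reference residue r
    (between[len(ref)] holds a trailing insertion).
    """
    alignment = aligner.align(reference, seq)[0]
    at = ["-"] * len(reference)
    between = [""] * (len(reference) + 1)
    ref_blocks, seq_blocks = alignment.aligned
    prev_ref_end = 0
    prev_seq_end = 0
    for (rs, re), (ss, se) in zip(ref_blocks, seq_blocks):
        if ss > prev_seq_end:  # insertion relative to reference
            between[rs] += seq[prev_seq_end:ss]
        for k in range(re - rs):
            at[rs + k] = seq[ss + k]
        prev_ref_end, prev_seq_end = re, se
    if prev_seq_end < len(seq):
        between[len(reference)] += seq[prev_seq_end:]
    return at, between


def align_homologs(seqs: Sequence[str] | Mapping[str, str],
                   reference: str | int = 0) -> Msa:
    """Star alignment of homologue proteins around a reference sequence.

    *seqs* may be a list (reference given by index) or an id->sequence
    mapping (reference given by id). The reference row has a column for each
    of its residues; insertions in other sequences open gap columns.
    """
    if isinstance(seqs, Mapping):
        ids = list(seqs)
        sequences = [seqs[i] for i in ids]
        ref_idx = ids.index(reference) if isinstance(reference, str) else int(reference)
    else:
        sequences = list(seqs)
        ids = [f"seq{i}" for i in range(len(sequences))]
        ref_idx = int(reference)
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to align")
    for i, s in enumerate(sequences):
        bad = set(s.upper()) - set(STANDARD_AAS)
        if bad:
            raise ValueError(f"sequence {ids[i]} has invalid characters: {sorted(bad)}")
    ref = sequences[ref_idx].upper()
    aligner = _make_aligner(mode="global", gap_open=-10.0, gap_extend=-0.5)
    ats, betweens = [], []
    for s in sequences:
        at, between = (_pairwise_to_ref(ref, s.upper(), aligner)
                       if s.upper() != ref else
                       (list(ref), [""] * (len(ref) + 1)))
        ats.append(at)
        betweens.append(between)
    ins_len = [max(len(b[r]) for b in betweens) for r in range(len(ref) + 1)]
    rows = []
    for at, between in zip(ats, betweens):
        parts = []
        for r in range(len(ref)):
            parts.append(between[r].ljust(ins_len[r], "-"))
            parts.append(at[r])
        parts.append(between[len(ref)].ljust(ins_len[len(ref)], "-"))
        rows.append("".join(parts))
    return Msa(ids=ids, rows=rows, reference_id=ids[ref_idx])


def reference_columns(msa: Msa) -> list[int]:
    """Alignment columns that carry a reference residue (not an insertion)."""
    ref_row = msa.row(msa.reference_id)
    return [i for i, c in enumerate(ref_row) if c != "-"]


# ---------------------------------------------------------------------------
# Conservation profile
# ---------------------------------------------------------------------------

def column_information(msa: Msa, pseudocount: float = 1.0 / 20.0) -> ConservationProfile:
    """Information content per column: (log2 20 - H) * occupancy.

    *pseudocount* is added per residue type before normalising; no background
    composition or small-sample correction is applied.
    """
    if not msa.rows:
        raise ValueError("empty alignment")
    n = len(msa.rows)
    ncols = msa.ncols
    counts = np.zeros((ncols, 20))
    for row in msa.rows:
        for j, c in enumerate(row):
            k = _AA_INDEX.get(c)
            if k is not None:
                counts[j, k] += 1
    occupancy = counts.sum(axis=1) / n
    freqs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 20 * pseudocount)
    entropy = -(freqs * np.log2(freqs)).sum(axis=1)
    info = np.maximum(MAX_IC - entropy, 0.0) * occupancy
    info[occupancy == 0] = 0.0
    # renormalise frequencies rows to exactly 1 (guard against fp drift)
    freqs /= freqs.sum(axis=1, keepdims=True)
    return ConservationProfile(information=info, frequencies=freqs, occupancy=occupancy)


def select_motif_windows(profile: ConservationProfile, win_len: int, top_k: int,
                         wildcard_threshold: float = 0.5,
                         min_occupancy: float = 0.5,
                         columns: Sequence[int] | None = None) -> list[MotifPattern]:
    """Top-k non-overlapping windows ranked by mean information content.

    *columns* restricts candidates (e.g. to reference-anchored columns);
    windows must be contiguous in that column list and keep per-column
    occupancy >= *min_occupancy*. Ties break toward the smaller column
    index. Within a window, positions whose modal residue frequency is
    below *wildcard_threshold* become 'x'.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if not 4 <= win_len <= 6:
        raise ValueError("window length must be between 4 and 6")
    cols = list(columns) if columns is not None else list(range(len(profile)))
    if len(cols) < win_len:
        raise ValueError("profile shorter than window length")
    candidates = []
    for i in range(len(cols) - win_len + 1):
        window = cols[i:i + win_len]
        if any(profile.occupancy[j] < min_occupancy for j in window):
            continue
        mean_ic = float(np.mean(profile.information[window]))
        candidates.append((-mean_ic, window[0], window))
    candidates.sort()
    chosen: list[MotifPattern] = []
    used: set[int] = set()
    for _, start, window in candidates:
        if used.intersection(window):
            continue
        letters = []
        for j in window:
            k = int(np.argmax(profile.frequencies[j]))
            modal = profile.frequencies[j, k] * profile.occupancy[j]
            letters.append(STANDARD_AAS[k] if modal >= wildcard_threshold else "x")
        try:
            chosen.append(MotifPattern("".join(letters), start_col=start,
                                       columns=tuple(window)))
        except ValueError:
            continue  # all-wildcard window is uninformative
        used.update(window)
        if len(chosen) == top_k:
            break
    return chosen


def extract_window_variants(msa: Msa, window: MotifPattern | Sequence[int]) -> list[str]:
    """Per-sequence residues at the window's alignment columns."""
    if isinstance(window, MotifPattern):
        cols = window.columns or range(window.start_col, window.start_col + len(window))
    else:
        cols = window
    return ["".join(row[j] for j in cols) for row in msa.rows]


# ---------------------------------------------------------------------------
# Motif-variant counting and amplifiability
# ---------------------------------------------------------------------------

def count_motif_patterns(variants: Sequence[str],
                         patterns: Sequence[MotifPattern | str]) -> dict[str, int]:
    """Count variants matching each pattern (wildcard 'x' matches anything)."""
    pats = [p if isinstance(p, MotifPattern) else MotifPattern(p) for p in patterns]
    counts: dict[str, int] = {}
    for p in pats:
        counts[p.pattern] = sum(1 for v in variants if p.matches(v))
    return counts


def estimate_amplifiable(receptor_variants: Sequence[str], synthase_variants: Sequence[str],
                         receptor_pattern: MotifPattern | str,
                         synthase_pattern: MotifPattern | str) -> dict[str, float]:
    """Fraction of index-paired loci where both anchor patterns match.

    Returns ``{"n_pairs", "n_amplifiable", "percent"}`` with *percent*
    rounded to one decimal (0.0 for an empty input).
    """
    if len(receptor_variants) != len(synthase_variants):
        raise ValueError("variant lists must be index-paired (equal length)")
    rp = receptor_pattern if isinstance(receptor_pattern, MotifPattern) \
        else MotifPattern(receptor_pattern)
    sp = synthase_pattern if isinstance(synthase_pattern, MotifPattern) \
        else MotifPattern(synthase_pattern)
    n = len(receptor_variants)
    n_amp = sum(1 for r, s in zip(receptor_variants, synthase_variants)
                if rp.matches(r) and sp.matches(s))
    percent = round(100.0 * n_amp / n, 1) if n else 0.0
    return {"n_pairs": n, "n_amplifiable": n_amp, "percent": percent}
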