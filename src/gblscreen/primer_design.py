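"""Codon-usage-aware degenerate primer design.

A primer is designed from a short protein *context* whose N-terminal
positions carry the conserved anchor motif (e.g. ``YFHF`` in the receptor's
DNA-binding domain, ``ETxRQ`` in the synthase). The context is
back-translated codon by codon under a per-position :class:`DegeneracyPolicy`
— full synonymous degeneracy at the motif codons, top-two-codon wobble or a
single preferred codon toward the 5' clamp — and the result is
reverse-complemented so that the primer anneals antisense to the coding
strand with the motif's first codon at its 3' end.

Context strings may contain a wildcard residue set in braces, e.g.
``"ET{ILV}RQSG"`` for a position that tolerates Ile/Leu/Val.

The policies that produce the published screen primers (scb_F targeting the
receptor, scb_R targeting the synthase) are bundled as a data file; see
:func:`bundled_policies` and :func:`bundled_primers`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from Bio.Seq import Seq

from .genome_io import (
    IUPAC_SETS,
    CodonUsageTable,
    DegeneracyError,
    degeneracy,
    expand_degenerate,
    iupac_code,
    revcomp,
)

RULE_KINDS = ("full", "top2", "single", "residue_set")


@dataclass(frozen=True)
class PositionRule:
    """Back-translation rule for one context position.

    kind:
      - ``full``: positionwise IUPAC closure of all synonymous codons
      - ``top2``: closure of the two most frequent codons
      - ``single``: one codon (``codon`` if given, else the most frequent)
      - ``residue_set``: closure of the codons (frequency >= ``min_freq``)
        of the residues in ``residues`` — used for tolerant wildcard
        positions such as {I,L,V}
    """

    kind: str
    codon: str | None = None
    residues: str | None = None
    min_freq: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")


@dataclass(frozen=True)
class DegeneracyPolicy:
    """One :class:`PositionRule` per context position."""

    rules: tuple[PositionRule, ...]
    name: str = ""
    role: str = ""
    context: str = ""
    motif_length: int = 0


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC primer, written 5'->3', antisense to the coding strand."""

    name: str
    sequence: str
    role: str  # {"receptor", "synthase"}
    context: str  # raw context string, motif residues first
    motif_length: int
    degeneracy: int

    @property
    def motif_pattern(self) -> str:
        """Anchor motif with brace wildcard sets rendered as 'x'."""
        sets = parse_context(self.context)[: self.motif_length]
        return "".join(next(iter(s)) if len(s) == 1 else "x" for s in sets)

    def motif_codons(self) -> list[str]:
        """Coding-sense degenerate codons of the anchor motif (3'-proximal)."""
        coding = revcomp(self.sequence)
        return [coding[i:i + 3] for i in range(0, 3 * self.motif_length, 3)]


def parse_context(context: str) -> list[frozenset[str]]:
    """Parse ``"ET{ILV}RQSG"`` into per-position residue sets."""
    sets: list[frozenset[str]] = []
    i = 0
    while i < len(context):
        c = context[i]
        if c == "{":
            j = context.index("}", i)
            group = context[i + 1:j]
            if not group:
                raise ValueError("empty residue set in context")
            sets.append(frozenset(group.upper()))
            i = j + 1
        else:
            sets.append(frozenset(c.upper()))
            i += 1
    return sets


def _closure(codons: Sequence[str]) -> str:
    """Minimal positionwise IUPAC codon covering a codon set."""
    if not codons:
        raise ValueError("no codons to cover")
    return "".join(iupac_code({c[k] for c in codons}) for k in range(3))


def codon_for_position(residues: frozenset[str], rule: PositionRule,
                       table: CodonUsageTable) -> str:
    """Degenerate codon for one context position under its rule."""
    if rule.kind == "full":
        pool = [c for aa in sorted(residues) for c, _ in table.codons(aa)]
        return _closure(pool)
    if rule.kind == "top2":
        (aa,) = residues
        return _closure(table.top_codons(aa, 2))
    if rule.kind == "single":
        if rule.codon:
            return rule.codon.upper()
        (aa,) = residues
        return table.most_frequent(aa)
    # residue_set
    res = rule.residues or "".join(sorted(residues))
    pool = [c for aa in res for c in table.codons_above(aa, rule.min_freq)]
    return _closure(pool)


def back_translate(context: str, policy: DegeneracyPolicy,
                   table: CodonUsageTable) -> str:
    """Back-translate a context to a coding-sense IUPAC DNA string."""
    sets = parse_context(context)
    if len(sets) != len(policy.rules):
        raise ValueError(
            f"context has {len(sets)} positions but policy has {len(policy.rules)} rules")
    return "".join(codon_for_position(s, r, table)
                   for s, r in zip(sets, policy.rules))


def design_primer(context: str, policy: DegeneracyPolicy, table: CodonUsageTable,
                  role: str = "", name: str = "", motif_length: int = 0,
                  cap: int = 512) -> DegeneratePrimer:
    """Design a degenerate primer whose 3' end sits on the motif's first codon.

    The motif must occupy the N-terminal positions of *context*; the primer
    is the reverse complement of the back-translated context, so its
    3'-terminal base pairs with the first base of the motif's first codon.
    """
    coding = back_translate(context, policy, table)
    primer = revcomp(coding)
    d = degeneracy(primer)
    if d > cap:
        raise DegeneracyError(
            f"primer degeneracy {d} exceeds cap {cap}; tighten the policy "
            "(fewer 'full' positions or smaller residue sets)")
    return DegeneratePrimer(
        name=name or policy.name or "primer",
        sequence=primer,
        role=role or policy.role,
        context=context,
        motif_length=motif_length or policy.motif_length or len(parse_context(context)),
        degeneracy=d,
    )


def verify_primer(primer: DegeneratePrimer | str) -> list[set[str]]:
    """Translate every expansion of revcomp(primer): per-codon residue sets.

    Stop codons are reported as ``'*'`` in the corresponding position set.
    """
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    if len(seq) % 3 != 0:
        raise ValueError(f"primer length {len(seq)} not divisible by 3")
    coding = revcomp(seq)
    out: list[set[str]] = []
    for i in range(0, len(coding), 3):
        residues = set()
        for codon in expand_degenerate(coding[i:i + 3]):
            residues.add(str(Seq(codon).translate(table=11)))
        out.append(residues)
    return out


# ---------------------------------------------------------------------------
# Bundled policy / primers
# ---------------------------------------------------------------------------

def load_policies(path) -> dict[str, DegeneracyPolicy]:
    """Load a policy config (JSON mapping name -> {context, rules, ...})."""
    with open(path) as fh:
        raw = json.load(fh)
    out = {}
    for name, entry in raw.items():
        rules = tuple(PositionRule(**r) for r in entry["rules"])
        out[name] = DegeneracyPolicy(
            rules=rules, name=name, role=entry.get("role", ""),
            context=entry["context"], motif_length=entry.get("motif_length", 0))
    return out


def bundled_policies() -> dict[str, DegeneracyPolicy]:
    ref = resources.files("gblscreen.data") / "primer_policies.json"
    with resources.as_file(ref) as path:
        return load_policies(path)


def bundled_primers(table: CodonUsageTable | None = None) -> dict[str, DegeneratePrimer]:
    """The two screen primers designed from the bundled policies and table."""
    table = table or CodonUsageTable.bundled()
    return {name: design_primer(pol.context, pol, table, name=name)
            for name, pol in bundled_policies().items()}


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def gc_range(seq: str) -> tuple[float, float]:
    """Min/max GC fraction over the expansions of a degenerate primer."""
    lo = hi = 0
    for c in seq.upper():
        bases = IUPAC_SETS[c]
        gcs = {b in "GC" for b in bases}
        lo += gcs == {True}
        hi += True in gcs
    return lo / len(seq), hi / len(seq)


def wallace_tm_range(seq: str) -> tuple[float, float]:
    """Wallace-rule Tm (2AT + 4GC) range over primer expansions."""
    lo_gc, hi_gc = gc_range(seq)
    n = len(seq)
    return (2 * n + 2 * lo_gc * n, 2 * n + 2 * hi_gc * n)


def primers_to_tsv(primers: Sequence[DegeneratePrimer], path) -> None:
    import pandas as pd

    rows = []
    for p in primers:
        glo, ghi = gc_range(p.sequence)
        tlo, thi = wallace_tm_range(p.sequence)
        rows.append({
            "name": p.name, "sequence_5to3": p.sequence, "target_role": p.role,
            "context": p.context, "motif": p.motif_pattern, "degeneracy": p.degeneracy,
            "gc_min": round(glo, 3), "gc_max": round(ghi, 3),
            "tm_min": round(tlo, 1), "tm_max": round(thi, 1),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
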