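"""End-to-end screen orchestration.

``run_screen`` composes the stages — homologue pairing, conservation
profiling, primer design, in-silico PCR and ARE discovery — over a set of
annotated genomes, persisting every stage's intermediate files in the
output directory and writing a plain-text summary report. Deterministic
given the configured seed.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import are_discovery, conservation, insilico_pcr, pair_finder, primer_design
from .genome_io import CodonUsageTable, GenomeRecord, read_annotated_genome, write_fasta

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Parameters of the end-to-end screen (defaults follow the published
    protocol where it states them: E < 0.02, 600 bp max intergenic distance,
    divergent orientation, ARE widths 15-30)."""

    receptor_query: str = ""  # protein sequence (or FASTA path via loader)
    synthase_query: str = ""
    evalue_max: float = 0.02
    max_intergenic: int = 600
    orientation_filter: str = "divergent"
    receptor_window: int = 4
    synthase_window: int = 5
    wildcard_threshold: float = 0.5
    max_mismatch: int = 0
    three_prime_exact: int = 3
    min_size: int = 100
    max_size: int = 3000
    are_wmin: int = 15
    are_wmax: int = 30
    are_n_shuffles: int = 0  # 0: skip the significance estimate
    seed: int = 0
    outdir: str = "screen_out"


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_screen(config: ScreenConfig, genomes: list[str | Path] | list[GenomeRecord]) -> dict:
    """Run the full screen; returns a report dict (also written to disk)."""
    if not genomes:
        raise ValueError("need at least one genome")
    if not (config.receptor_query and config.synthase_query):
        raise ValueError("both query protein sequences are required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in vars(config).items()}}
    stage = "load"
    try:
        t0 = time.time()
        records: list[GenomeRecord] = []
        for g in genomes:
            if isinstance(g, GenomeRecord):
                records.append(g)
            else:
                records.extend(read_annotated_genome(g))
        by_contig = {r.contig_id: r for r in records}
        logger.info("stage load: %d contigs in %.1fs", len(records), time.time() - t0)

        stage = "pair"
        t0 = time.time()
        rec_hits, syn_hits = [], []
        for r in records:
            proteome = r.proteome()
            if not proteome:
                continue
            rec_hits += pair_finder.find_homologs(proteome, config.receptor_query,
                                                  "receptor", evalue_max=config.evalue_max)
            syn_hits += pair_finder.find_homologs(proteome, config.synthase_query,
                                                  "synthase", evalue_max=config.evalue_max)
        pairs = pair_finder.pair_colocated(syn_hits, rec_hits, config.max_intergenic,
                                           genomes=by_contig)
        census = pair_finder.orientation_census(pairs)
        pair_finder.pairs_to_tsv(pairs, outdir / "pairs.tsv")
        pair_finder.intergenic_to_fasta(pairs, outdir / "intergenic.fasta")
        report["orientation_census"] = census
        kept = [p for p in pairs if p.orientation == config.orientation_filter]
        logger.info("stage pair: %d pairs (%d kept) in %.1fs",
                    len(pairs), len(kept), time.time() - t0)

        stage = "conservation"
        t0 = time.time()
        report["patterns"] = {}
        variants: dict[str, list[str]] = {}
        for role, query, win in (("receptor", config.receptor_query, config.receptor_window),
                                 ("synthase", config.synthase_query, config.synthase_window)):
            prots = [query] + [
                (p.receptor_hit if role == "receptor" else p.synthase_hit).feature.protein
                for p in kept]
            if len(prots) < 3:
                logger.warning("too few %s homologues for conservation profiling", role)
                continue
            msa = conservation.align_homologs(prots, 0)
            msa.to_fasta(outdir / f"alignment_{role}.afa")
            profile = conservation.column_information(msa)
            profile.to_tsv(outdir / f"profile_{role}.tsv")
            windows = conservation.select_motif_windows(
                profile, win, 1, config.wildcard_threshold,
                columns=conservation.reference_columns(msa))
            if windows:
                pattern = windows[0]
                # drop the query row: variants describe the hit cohort
                variants[role] = conservation.extract_window_variants(msa, pattern)[1:]
                report["patterns"][role] = pattern.pattern
        if "receptor" in variants and "synthase" in variants:
            table = conservation.count_motif_patterns(
                variants["receptor"], [report["patterns"]["receptor"]])
            table.update(conservation.count_motif_patterns(
                variants["synthase"], [report["patterns"]["synthase"]]))
            report["motif_counts"] = table
            report["amplifiable"] = conservation.estimate_amplifiable(
                variants["receptor"], variants["synthase"],
                report["patterns"]["receptor"], report["patterns"]["synthase"])
        logger.info("stage conservation done in %.1fs", time.time() - t0)

        stage = "primers"
        t0 = time.time()
        table = CodonUsageTable.bundled()
        primers = primer_design.bundled_primers(table)
        primer_design.primers_to_tsv(list(primers.values()), outdir / "primers.tsv")
        report["primers"] = {n: p.sequence for n, p in primers.items()}
        logger.info("stage primers done in %.1fs", time.time() - t0)

        stage = "insilico_pcr"
        t0 = time.time()
        scb_f, scb_r = primers["scb_F"], primers["scb_R"]
        all_amps = []
        prime_rows = []
        for r in records:
            amps = insilico_pcr.predict_amplicons(
                scb_f, scb_r, r.sequence, config.min_size, config.max_size,
                config.max_mismatch, config.three_prime_exact, contig=r.contig_id)
            all_amps.extend(amps)
        insilico_pcr.amplicons_to_tsv(all_amps, outdir / "amplicons.tsv")
        report["n_amplicons"] = len(all_amps)
        report["amplicon_lengths"] = sorted(a.length for a in all_amps)
        if "receptor" in variants and "synthase" in variants:
            for i, (rv, sv) in enumerate(zip(variants["receptor"], variants["synthase"])):
                prime_rows.append({
                    "pair_index": i, "receptor_variant": rv, "synthase_variant": sv,
                    "receptor_class": str(insilico_pcr.classify_priming(
                        rv, scb_f.motif_pattern, scb_f, table)),
                    "synthase_class": str(insilico_pcr.classify_priming(
                        sv, scb_r.motif_pattern, scb_r, table)),
                })
            import pandas as pd
            pd.DataFrame(prime_rows).to_csv(outdir / "prime_classes.tsv",
                                            sep="\t", index=False)
            report["prime_classes"] = prime_rows
        logger.info("stage insilico_pcr: %d amplicons in %.1fs",
                    len(all_amps), time.time() - t0)

        stage = "are"
        t0 = time.time()
        intergenic = [p.intergenic_seq for p in kept
                      if p.intergenic_seq and len(p.intergenic_seq) >= config.are_wmax]
        if len(intergenic) >= 3:
            model = are_discovery.discover_motif(
                intergenic, config.are_wmin, config.are_wmax, seed=config.seed)
            if config.are_n_shuffles:
                model.significance = are_discovery.motif_significance(
                    model, intergenic, config.are_n_shuffles, seed=config.seed)
            model.to_text(outdir / "are_motif.txt")
            report["are"] = {
                "width": model.width, "consensus": model.consensus(),
                "llr": round(model.llr, 3),
                "palindromicity": round(are_discovery.palindromicity(model), 3),
                "significance": model.significance,
                "n_sites": len(model.sites),
            }
        else:
            logger.warning("too few intergenic sequences for ARE discovery")
        logger.info("stage are done in %.1fs", time.time() - t0)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    _write_report(report, outdir / "report.txt")
    return report


def _write_report(report: dict, path: Path) -> None:
    lines = ["# gblscreen report", ""]
    census = report.get("orientation_census", {})
    lines.append("[orientation census]")
    for k in ("divergent", "convergent", "tandem", "ambiguous"):
        lines.append(f"  {k}\t{census.get(k, 0)}")
    lines.append("")
    if "patterns" in report:
        lines.append("[anchor patterns]")
        for role, pat in report["patterns"].items():
            lines.append(f"  {role}\t{pat}")
        lines.append("")
    if "motif_counts" in report:
        lines.append("[motif counts]")
        for pat, n in report["motif_counts"].items():
            lines.append(f"  {pat}\t{n}")
        lines.append("")
    if "amplifiable" in report:
        amp = report["amplifiable"]
        lines.append("[amplifiability]")
        lines.append(f"  n_pairs\t{amp['n_pairs']}")
        lines.append(f"  n_amplifiable\t{amp['n_amplifiable']}")
        lines.append(f"  percent\t{amp['percent']}")
        lines.append("")
    lines.append("[primers]")
    for name, seq in report.get("primers", {}).items():
        lines.append(f"  {name}\t{seq}")
    lines.append("")
    lines.append("[in-silico PCR]")
    lines.append(f"  n_amplicons\t{report.get('n_amplicons', 0)}")
    lines.append(f"  lengths\t{report.get('amplicon_lengths', [])}")
    lines.append("")
    if "are" in report:
        lines.append("[ARE motif]")
        for k, v in report["are"].items():
            lines.append(f"  {k}\t{v}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")
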