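#!/usr/bin/env python
"""Fetch annotated public genomes for in-silico PCR (requires network).

Downloads GenBank flat files for a few *Streptomyces* reference assemblies
via the NCBI E-utilities, for running e.g.:

    gblscreen insilico-pcr --fwd CCGCTCCTTGCTSGGRAARTGRAARTA \
        --rev GCCGCTCTGGCGVABSGTYTC --genome genomes/<accession>.gbff

This script is a convenience for users with network access; nothing in the
package or its tests depends on it.
"""
from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

EUTILS = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&rettype=gbwithparts&retmode=text&id={acc}")

DEFAULT_ACCESSIONS = [
    "BA000030.4",   # Streptomyces avermitilis MA-4680 chromosome
    "AL645882.2",   # Streptomyces coelicolor A3(2) chromosome
    "AL589148.1",   # S. coelicolor plasmid SCP1 (mmfL/mmfR region)
    "CP009124.1",   # Streptomyces lividans TK24
    "CP018074.1",   # Streptomyces venezuelae ATCC 10712
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("accessions", nargs="*", default=None)
    parser.add_argument("-o", "--outdir", type=Path, default=Path("genomes"))
    args = parser.parse_args()
    accessions = args.accessions or DEFAULT_ACCESSIONS
    args.outdir.mkdir(parents=True, exist_ok=True)
    for acc in accessions:
        dest = args.outdir / f"{acc}.gbff"
        if dest.exists():
            print(f"{dest} exists, skipping")
            continue
        print(f"fetching {acc} ...")
        urllib.request.urlretrieve(EUTILS.format(acc=acc), dest)
        print(f"  -> {dest}")


if __name__ == "__main__":
    main()
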