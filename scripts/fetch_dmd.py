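#!/usr/bin/env python
"""OPTIONAL network helper: fetch the human dystrophin (DMD) CDS and check
its codon-usage extremes.

Downloads the RefSeq transcript NM_004006 CDS from NCBI efetch (requires
internet; nothing in the library or the test suite depends on this script),
writes it in the package's FASTA + metadata dialect, and reports:

* the extremely biased codons under the default degeneracy-dependent cutoff
  (expected: UCG, CCG, ACG, GCG);
* the zero-codon set under the family_present policy (expected: empty —
  dystrophin keeps every codon type in use).

Usage:  python scripts/fetch_dmd.py --out scratch/dmd
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

from cubkit.genetic_code import build_genetic_code
from cubkit.profiles import count_codons, cu_values, extremely_biased_codons, zero_codons
from cubkit.sequence_io import read_cds_fasta

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id=NM_004006&rettype=fasta_cds_na&retmode=text"
)

METADATA = (
    "accession\tgene_id\tspecies\ttissue\tcohort\texon_count\n"
    "NM_004006\tDMD\tHomo_sapiens\tmuscle\tDC\t79\n"
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("scratch/dmd"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    raw = urllib.request.urlopen(EFETCH, timeout=60).read().decode()
    lines = raw.strip().splitlines()
    fasta = args.out / "dmd.fasta"
    fasta.write_text(">NM_004006\n" + "\n".join(l for l in lines if not l.startswith(">")) + "\n")
    meta = args.out / "dmd_metadata.tsv"
    meta.write_text(METADATA)

    (rec,) = read_cds_fasta(fasta, meta)
    code = build_genetic_code()
    counts = count_codons(rec)
    profile = cu_values(counts, code)
    biased = sorted(extremely_biased_codons(profile, code=code))
    zeros = sorted(zero_codons(counts, code).zero_codons)
    print(f"DMD CDS: {rec.n_codons} codons, terminal stop {rec.terminal_stop}")
    print(f"extremely biased codons (default cutoff): {biased}")
    print(f"zero-codons (family_present): {zeros or '(none)'}")


if __name__ == "__main__":
    main()
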