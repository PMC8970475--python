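"""Shared fixtures: genetic code, random CDS factories, toy cohort files."""

from __future__ import annotations

from typing import Dict, List

import numpy as np
import pytest

from cubkit import CdsRecord, build_genetic_code
from cubkit.genetic_code import STOP, STOP_CODONS


@pytest.fixture(scope="session")
def code():
    return build_genetic_code()


@pytest.fixture(scope="session")
def sense_codons(code):
    """All 61 sense codons of the standard code."""
    return [c for c in code.all_codons if code.translate(c) != STOP]


def make_record(sequence: str, gene_id: str = "G", **kwargs) -> CdsRecord:
    defaults = dict(accession=f"ACC_{gene_id}", species="hsa")
    defaults.update(kwargs)
    return CdsRecord(gene_id=gene_id, sequence=sequence, **defaults).validate()


@pytest.fixture
def record_factory():
    return make_record


def random_cds(rng: np.random.Generator, n_codons: int, sense: List[str]) -> str:
    """An in-frame CDS of *n_codons* codons: sense body plus a terminal stop."""
    body = rng.choice(sense, size=n_codons - 1)
    stop = STOP_CODONS[int(rng.integers(3))]
    return "".join(body) + stop


@pytest.fixture
def random_cds_factory(sense_codons):
    def factory(rng, n_codons):
        return random_cds(rng, n_codons, sense_codons)

    return factory


def triplet_scan_counts(sequence: str) -> Dict[str, int]:
    """Independent counting oracle: a sliding-index 64-bin tally."""
    bins: Dict[str, int] = {}
    i = 0
    while i + 3 <= len(sequence):
        codon = sequence[i : i + 3]
        if all(b in "ACGU" for b in codon):
            bins[codon] = bins.get(codon, 0) + 1
        i += 3
    return bins


@pytest.fixture
def counting_oracle():
    return triplet_scan_counts


# Toy 3-gene cohort, small enough to hand-check every downstream number.
TOY_FASTA = """>NM_1
ATGCTGCTGTAA
>NM_2
ATGGAAGAGCTGTGA
>NM_3
ATGTCATCGTCATAA
"""

TOY_METADATA = """# toy cohort
accession\tgene_id\tspecies\ttissue\tcohort\texon_count
NM_1\tGENE_A\thsa\tmuscle\tDC\t79
NM_2\tGENE_B\thsa\tmuscle\tNDC\t10
NM_3\tGENE_C\thsa\tmuscle\tDC\t50
"""

TOY_VARIANTS = """gene_id\tcds_pos\tref\talt
GENE_B\t4\tG\tT
GENE_B\t5\tA\tT
GENE_B\t6\tA\tG
"""


@pytest.fixture
def toy_cohort(tmp_path):
    fasta = tmp_path / "toy.fasta"
    meta = tmp_path / "toy_metadata.tsv"
    variants = tmp_path / "toy_variants.tsv"
    fasta.write_text(TOY_FASTA)
    meta.write_text(TOY_METADATA)
    variants.write_text(TOY_VARIANTS)
    return {"fasta": fasta, "metadata": meta, "variants": variants}
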