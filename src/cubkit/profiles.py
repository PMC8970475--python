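"""Per-gene codon counting and within-family codon-usage (CU) values.

The CU value of a sense codon is its count divided by the total count of all
synonymous codons for the same amino acid in the same gene (or pooled
cohort), i.e. a relative frequency computed independently within each of the
18 multi-codon amino-acid families.  Methionine and tryptophan, encoded by a
unique triplet, carry no synonymous choice and are excluded, as are the stop
codons, whose usage is summarized separately across a cohort's terminal
stops.

A "zero-codon" is a synonymous codon a gene never uses — the extreme of
codon usage bias.  Under the default ``family_present`` policy a codon only
qualifies when its amino acid actually occurs in the gene (an absent family
reflects protein composition, not codon choice); the ``raw`` policy reports
every unused sense codon.  "Extremely biased" codons are those whose CU
value falls below a degeneracy-dependent cutoff (default: half the uniform
expectation, 0.5/d for a d-fold family).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set

import pandas as pd

from .genetic_code import (
    RNA_BASES,
    STOP_CODONS,
    GeneticCodeTable,
    build_genetic_code,
)
from .sequence_io import CdsRecord

__all__ = [
    "CodonCountVector",
    "CUProfile",
    "ZeroCodonReport",
    "count_codons",
    "cu_values",
    "stop_codon_usage",
    "zero_codons",
    "extremely_biased_codons",
    "default_bias_cutoffs",
    "pool_cohort_counts",
    "profiles_from_records",
    "cu_long_table",
]


@dataclass
class CodonCountVector:
    """Raw frame-0 codon counts for one gene (all 64 codons)."""

    gene_id: str
    counts: Dict[str, int]
    excluded_codons: int = 0  # triplets skipped for ambiguity letters
    terminal_stop: Optional[str] = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CUProfile:
    """Within-family codon-usage values for one gene over the 59 sense codons.

    ``cu[c]`` is ``count(c) / family_total(c)`` for every codon of a present
    family and 0.0 (masked via ``family_present``) otherwise.
    """

    gene_id: str
    cu: Dict[str, float]
    family_present: Dict[str, bool]
    terminal_stop: Optional[str] = None
    exon_count: int = 0

    def is_masked(self, codon: str, code: Optional[GeneticCodeTable] = None) -> bool:
        code = code or build_genetic_code()
        return not self.family_present[code.translate(codon)]


@dataclass
class ZeroCodonReport:
    """Unused synonymous codons of one gene under a stated policy."""

    gene_id: str
    zero_codons: Set[str]
    policy: str  # "family_present" | "raw"

    @property
    def count(self) -> int:
        return len(self.zero_codons)


def count_codons(rec: CdsRecord) -> CodonCountVector:
    """Count non-overlapping frame-0 triplets of a validated CDS.

    The terminal stop codon (when present) is included in the raw counts but
    never enters sense-codon statistics downstream.  Triplets containing
    ambiguity letters are skipped and tallied in ``excluded_codons``.
    """
    counts: Counter = Counter()
    excluded = 0
    valid = set(RNA_BASES)
    for codon in rec.codons:
        if set(codon) <= valid:
            counts[codon] += 1
        else:
            excluded += 1
    return CodonCountVector(
        gene_id=rec.gene_id,
        counts=dict(counts),
        excluded_codons=excluded,
        terminal_stop=rec.terminal_stop,
    )


def cu_values(
    counts: CodonCountVector,
    code: Optional[GeneticCodeTable] = None,
    *,
    exon_count: int = 0,
) -> CUProfile:
    """Within-family CU values, computed independently per amino-acid family.

    For each of the 18 considered families with a nonzero total, every codon
    gets ``count / family_total`` (so the family sums to exactly 1); families
    never used by the gene are flagged absent and their codons carry 0.
    The terminal stop, Met and Trp never appear in the result.
    """
    code = code or build_genetic_code()
    cu: Dict[str, float] = {}
    present: Dict[str, bool] = {}
    for fam in code.considered_families:
        fam_counts = [counts.counts.get(c, 0) for c in fam.codons]
        total = sum(fam_counts)
        present[fam.amino_acid] = total > 0
        for c, n in zip(fam.codons, fam_counts):
            cu[c] = n / total if total else 0.0
    return CUProfile(
        gene_id=counts.gene_id,
        cu=cu,
        family_present=present,
        terminal_stop=counts.terminal_stop,
        exon_count=exon_count,
    )


def stop_codon_usage(cohort: Sequence[CdsRecord]) -> Dict[str, float]:
    """Frequencies of UAA/UAG/UGA among the cohort's terminal stop codons.

    Genes without a terminal stop are excluded from the denominator.  When no
    gene has one, an empty mapping is returned with a warning.
    """
    stops = [rec.terminal_stop for rec in cohort if rec.has_terminal_stop]
    if not stops:
        warnings.warn("no gene in the cohort has a terminal stop codon")
        return {}
    tally = Counter(stops)
    return {s: tally.get(s, 0) / len(stops) for s in STOP_CODONS}


def zero_codons(
    counts: CodonCountVector,
    code: Optional[GeneticCodeTable] = None,
    policy: str = "family_present",
) -> ZeroCodonReport:
    """Sense codons with zero occurrences (the gene's "zero-codons").

    ``family_present`` (default) restricts to codons whose family is used at
    least once; ``raw`` reports every unused sense codon.  Stop, Met and Trp
    codons are never reported.
    """
    if policy not in ("family_present", "raw"):
        raise ValueError(f"unknown zero-codon policy {policy!r}")
    code = code or build_genetic_code()
    zeros: Set[str] = set()
    for fam in code.considered_families:
        fam_counts = {c: counts.counts.get(c, 0) for c in fam.codons}
        total = sum(fam_counts.values())
        if policy == "family_present" and total == 0:
            continue
        zeros.update(c for c, n in fam_counts.items() if n == 0)
    return ZeroCodonReport(gene_id=counts.gene_id, zero_codons=zeros, policy=policy)


def default_bias_cutoffs() -> Dict[int, float]:
    """Degeneracy-dependent extreme-bias cutoffs: half the uniform expectation."""
    return {d: 0.5 / d for d in (2, 3, 4, 6)}


def extremely_biased_codons(
    profile: CUProfile,
    cutoffs: Optional[Mapping[int, float]] = None,
    code: Optional[GeneticCodeTable] = None,
) -> Set[str]:
    """Codons of present families whose CU value falls below the cutoff.

    The cutoff depends on the family's redundancy (2, 3, 4 or 6 triplets);
    by default ``t(d) = 0.5/d``, overridable per degeneracy.
    """
    code = code or build_genetic_code()
    cuts = dict(default_bias_cutoffs())
    if cutoffs:
        cuts.update(cutoffs)
    flagged: Set[str] = set()
    for fam in code.considered_families:
        if not profile.family_present[fam.amino_acid]:
            continue
        t = cuts[fam.degeneracy]
        flagged.update(c for c in fam.codons if profile.cu[c] < t)
    return flagged


def pool_cohort_counts(
    cohort: Sequence[CodonCountVector], label: str = "pooled"
) -> CodonCountVector:
    """Element-wise sum of per-gene counts (cohort-level usage)."""
    if not cohort:
        raise ValueError("cannot pool an empty cohort")
    pooled: Counter = Counter()
    excluded = 0
    for vec in cohort:
        pooled.update(vec.counts)
        excluded += vec.excluded_codons
    return CodonCountVector(
        gene_id=label, counts=dict(pooled), excluded_codons=excluded
    )


def profiles_from_records(
    records: Sequence[CdsRecord], code: Optional[GeneticCodeTable] = None
) -> List[CUProfile]:
    """Convenience: count and profile each record, carrying exon counts."""
    code = code or build_genetic_code()
    return [
        cu_values(count_codons(rec), code, exon_count=rec.exon_count)
        for rec in records
    ]


def cu_long_table(
    records: Sequence[CdsRecord],
    code: Optional[GeneticCodeTable] = None,
    *,
    zero_policy: str = "family_present",
    cutoffs: Optional[Mapping[int, float]] = None,
) -> pd.DataFrame:
    """Long-format per-gene CU table: gene, codon, amino_acid, count, cu, flags."""
    code = code or build_genetic_code()
    rows = []
    for rec in records:
        counts = count_codons(rec)
        profile = cu_values(counts, code, exon_count=rec.exon_count)
        zeros = zero_codons(counts, code, policy=zero_policy).zero_codons
        biased = extremely_biased_codons(profile, cutoffs, code)
        for fam in code.considered_families:
            for c in fam.codons:
                rows.append(
                    {
                        "gene_id": rec.gene_id,
                        "codon": c,
                        "amino_acid": fam.amino_acid,
                        "count": counts.counts.get(c, 0),
                        "cu": profile.cu[c],
                        "family_present": profile.family_present[fam.amino_acid],
                        "zero_flag": c in zeros,
                        "biased_flag": c in biased,
                    }
                )
    return pd.DataFrame(rows)
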