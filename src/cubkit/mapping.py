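"""Mapping-on-codons: placing coding substitutions on their reference codon.

Each pathogenic single-base substitution, given in 1-based CDS coordinates,
is located on the codon it alters, its consequence is classified by
translating the substituted triplet under the standard code, and accepted
missense/nonsense variants are tallied per *reference* codon type — the
codon that is the site of the mutation.  Joining these tallies with the
gene's CU values asks whether rarely used codons are also rarely mutated;
the association is reported (as a Spearman correlation), never asserted.

Synonymous and stop-loss changes are classified but excluded from the
tallies by default, matching the restriction to unambiguously pathogenic
missense and nonsense variants; the classifier reports them so a
synonymous-variant analysis needs no structural change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .genetic_code import (
    RNA_BASES,
    STOP,
    GeneticCodeTable,
    build_genetic_code,
)
from .profiles import CUProfile, CodonCountVector, count_codons
from .sequence_io import CdsRecord, VariantRecord
from .stats import SpearmanResult, spearman_correlation

__all__ = [
    "MISSENSE",
    "NONSENSE",
    "SYNONYMOUS",
    "STOP_LOSS",
    "CodonMutationMap",
    "codon_index",
    "classify_substitution",
    "map_variants",
    "mutation_burden",
    "cu_mutation_correlation",
]

MISSENSE = "missense"
NONSENSE = "nonsense"
SYNONYMOUS = "synonymous"
STOP_LOSS = "stop_loss"


@dataclass
class CodonMutationMap:
    """Per-codon-type counts of accepted missense/nonsense variants."""

    gene_id: str
    per_codon_type: Dict[str, Tuple[int, int]]  # codon -> (missense, nonsense)
    occurrences: Dict[str, int]  # codon -> count of that codon in the CDS
    excluded: List[Tuple[VariantRecord, str]] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return sum(m + n for m, n in self.per_codon_type.values())


def codon_index(cds_pos: int) -> Tuple[int, int]:
    """1-based codon number and 0-based within-codon offset of a CDS position."""
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    return (cds_pos - 1) // 3 + 1, (cds_pos - 1) % 3


def classify_substitution(
    ref_codon: str,
    offset: int,
    alt_base: str,
    code: Optional[GeneticCodeTable] = None,
) -> str:
    """Consequence of substituting *alt_base* at *offset* of *ref_codon*.

    Returns one of ``missense``, ``nonsense`` (sense -> STOP), ``synonymous``
    or ``stop_loss`` (STOP -> sense).
    """
    code = code or build_genetic_code()
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0..2, got {offset}")
    if alt_base not in RNA_BASES:
        raise ValueError(f"invalid alt base {alt_base!r}")
    ref_aa = code.translate(ref_codon)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    alt_aa = code.translate(alt_codon)
    if alt_aa == ref_aa:
        return SYNONYMOUS
    if alt_aa == STOP:
        return NONSENSE
    if ref_aa == STOP:
        return STOP_LOSS
    return MISSENSE


def map_variants(
    rec: CdsRecord,
    variants: Sequence[VariantRecord],
    code: Optional[GeneticCodeTable] = None,
) -> CodonMutationMap:
    """Place substitutions on codons and tally missense/nonsense per codon type.

    Every variant is checked against the CDS: its reference base must match
    the sequence at the stated position (else excluded as ``ref_mismatch``),
    the position must fall inside the CDS (``out_of_range``), and only
    missense and nonsense consequences are accepted — synonymous and
    stop-loss calls are excluded with their classification as the reason.
    Tallies are indexed by the reference codon, and the result is invariant
    to the order of the input variants.
    """
    code = code or build_genetic_code()
    counts: CodonCountVector = count_codons(rec)
    per_type: Dict[str, Tuple[int, int]] = {}
    excluded: List[Tuple[VariantRecord, str]] = []
    valid = set(RNA_BASES)
    for var in variants:
        if var.gene_id != rec.gene_id:
            excluded.append((var, "gene_mismatch"))
            continue
        if var.cds_pos > len(rec.sequence):
            excluded.append((var, "out_of_range"))
            continue
        number, offset = codon_index(var.cds_pos)
        ref_codon = rec.sequence[(number - 1) * 3 : number * 3]
        if not set(ref_codon) <= valid:
            excluded.append((var, "ambiguous_codon"))
            continue
        if ref_codon[offset] != var.ref_base:
            excluded.append((var, "ref_mismatch"))
            continue
        consequence = classify_substitution(ref_codon, offset, var.alt_base, code)
        if consequence not in (MISSENSE, NONSENSE):
            excluded.append((var, consequence))
            continue
        mis, non = per_type.get(ref_codon, (0, 0))
        if consequence == MISSENSE:
            mis += 1
        else:
            non += 1
        per_type[ref_codon] = (mis, non)
    occurrences = {c: counts.counts.get(c, 0) for c in per_type}
    return CodonMutationMap(
        gene_id=rec.gene_id,
        per_codon_type=per_type,
        occurrences=occurrences,
        excluded=excluded,
    )


def mutation_burden(
    mut_map: CodonMutationMap,
    profile: CUProfile,
    code: Optional[GeneticCodeTable] = None,
    rec: Optional[CdsRecord] = None,
) -> pd.DataFrame:
    """Per-codon mutation burden joined with CU values.

    For every considered sense codon: its CU value, CDS occurrences, the
    missense/nonsense counts, the share of all accepted mutations and the
    occurrence-normalized rate (count / occurrences).  Both normalizations
    are exported because "mutation percentage" is ambiguous between them.
    """
    if mut_map.gene_id != profile.gene_id:
        raise ValueError("mutation map and profile are from different genes")
    code = code or build_genetic_code()
    occ = dict(mut_map.occurrences)
    if rec is not None:
        occ = dict(count_codons(rec).counts)
    total = mut_map.n_accepted
    rows = []
    for fam in code.considered_families:
        for c in fam.codons:
            mis, non = mut_map.per_codon_type.get(c, (0, 0))
            n_occ = occ.get(c, 0)
            count = mis + non
            rows.append(
                {
                    "codon": c,
                    "amino_acid": fam.amino_acid,
                    "cu": profile.cu[c],
                    "occurrences": n_occ,
                    "missense": mis,
                    "nonsense": non,
                    "count": count,
                    "share_of_all_mutations": count / total if total else 0.0,
                    "rate_per_occurrence": count / n_occ if n_occ else 0.0,
                }
            )
    return pd.DataFrame(rows)


def cu_mutation_correlation(burden: pd.DataFrame) -> SpearmanResult:
    """Spearman rho between CU values and per-occurrence mutation rates.

    Restricted to codons that occur in the CDS; this is the reported (not
    asserted) summary of whether mutation burden tracks codon usage.
    """
    present = burden[burden["occurrences"] > 0]
    if len(present) < 3:
        return SpearmanResult(rho=float("nan"), p_value=None, ok=False)
    return spearman_correlation(
        present["cu"].to_numpy(), present["rate_per_occurrence"].to_numpy()
    )
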