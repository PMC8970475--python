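"""Standard genetic code vocabulary: codons, synonymy families, degeneracy.

Everything downstream (codon counting, within-family codon-usage values,
zero-codon detection, variant consequence calls) is phrased in terms of the
standard nuclear genetic code.  Codons are spelled in RNA (``U``), matching
the convention of the codon-usage literature; DNA input is transliterated on
ingestion by :mod:`cubkit.sequence_io`.

Two amino acids, methionine (AUG) and tryptophan (UGG), are encoded by a
single triplet and therefore carry no synonymous-choice information; they are
excluded from all codon-usage statistics, as are the three stop codons.  The
remaining 18 amino acids carry the 59 "considered" sense codons on which
every CU value in this package is defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Mapping, Tuple

from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "STOP",
    "RNA_BASES",
    "STOP_CODONS",
    "SINGLE_CODON_AMINO_ACIDS",
    "CodonError",
    "normalize_codon",
    "AminoAcidFamily",
    "GeneticCodeTable",
    "build_genetic_code",
    "translate_codon",
    "family_of",
]

#: Symbol used for the translation-stop "amino acid".
STOP = "*"

RNA_BASES = "ACGU"

STOP_CODONS: Tuple[str, str, str] = ("UAA", "UAG", "UGA")

#: Met and Trp: encoded by a unique triplet, excluded from CU statistics.
SINGLE_CODON_AMINO_ACIDS: Tuple[str, str] = ("M", "W")


class CodonError(ValueError):
    """Raised for a string that is not a valid RNA codon."""


def normalize_codon(triplet: str) -> str:
    """Uppercase, transliterate T->U and validate a codon string.

    Raises
    ------
    CodonError
        If the result is not exactly three letters over {A, C, G, U}.
    """
    if not isinstance(triplet, str):
        raise CodonError(f"codon must be a string, got {type(triplet).__name__}")
    codon = triplet.upper().replace("T", "U")
    if len(codon) != 3 or any(base not in RNA_BASES for base in codon):
        raise CodonError(f"invalid codon {triplet!r}: need 3 letters over {{A,C,G,U}}")
    return codon


@dataclass(frozen=True)
class AminoAcidFamily:
    """One amino acid (or STOP) together with all codons encoding it."""

    amino_acid: str
    codons: Tuple[str, ...]

    @property
    def degeneracy(self) -> int:
        """Number of synonymous codons (1, 2, 3, 4 or 6 in the standard code)."""
        return len(self.codons)

    def __contains__(self, codon: str) -> bool:
        return codon in self.codons


@dataclass(frozen=True)
class GeneticCodeTable:
    """The standard genetic code grouped into synonymy families.

    Attributes
    ----------
    mapping
        Codon -> one-letter amino acid, with ``"*"`` for the stop codons.
        Exactly 64 entries.
    families
        One :class:`AminoAcidFamily` per amino acid plus one for STOP,
        ordered alphabetically by amino-acid letter with STOP last.
    """

    mapping: Mapping[str, str]
    families: Tuple[AminoAcidFamily, ...]

    def translate(self, codon: str) -> str:
        """Amino acid (or ``"*"``) encoded by *codon*; validates its input."""
        return self.mapping[normalize_codon(codon)]

    def family_of(self, codon: str) -> AminoAcidFamily:
        """The unique synonymy family containing *codon*."""
        return self._family_by_aa()[self.translate(codon)]

    def _family_by_aa(self) -> Dict[str, AminoAcidFamily]:
        index = self.__dict__.get("_aa_index")
        if index is None:
            index = {fam.amino_acid: fam for fam in self.families}
            object.__setattr__(self, "_aa_index", index)
        return index

    @property
    def stop_family(self) -> AminoAcidFamily:
        return self._family_by_aa()[STOP]

    @property
    def considered_families(self) -> Tuple[AminoAcidFamily, ...]:
        """The 18 multi-codon sense families carrying the 59 considered codons."""
        return tuple(
            fam
            for fam in self.families
            if fam.amino_acid != STOP and fam.amino_acid not in SINGLE_CODON_AMINO_ACIDS
        )

    @property
    def considered_codons(self) -> Tuple[str, ...]:
        """Canonical column order: families by amino-acid letter, codons A<C<G<U."""
        return tuple(c for fam in self.considered_families for c in fam.codons)

    @property
    def all_codons(self) -> Tuple[str, ...]:
        return tuple(sorted(self.mapping))

    def degeneracy(self, codon: str) -> int:
        return self.family_of(codon).degeneracy


@lru_cache(maxsize=1)
def build_genetic_code() -> GeneticCodeTable:
    """Build the standard nuclear genetic code (NCBI table 1).

    Deterministic and side-effect free; the result is cached and shared.
    """
    table = _BioCodonTable.unambiguous_rna_by_id[1]
    mapping: Dict[str, str] = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP
    if len(mapping) != 64:  # pragma: no cover - guards Biopython regressions
        raise RuntimeError("standard genetic code must have 64 codons")

    by_aa: Dict[str, list] = {}
    for codon in sorted(mapping):
        by_aa.setdefault(mapping[codon], []).append(codon)
    sense_letters = sorted(aa for aa in by_aa if aa != STOP)
    families = tuple(
        AminoAcidFamily(aa, tuple(by_aa[aa])) for aa in sense_letters + [STOP]
    )
    return GeneticCodeTable(mapping=mapping, families=families)


def translate_codon(code: GeneticCodeTable, codon: str) -> str:
    """Functional form of :meth:`GeneticCodeTable.translate`."""
    return code.translate(codon)


def family_of(code: GeneticCodeTable, codon: str) -> AminoAcidFamily:
    """Functional form of :meth:`GeneticCodeTable.family_of`."""
    return code.family_of(codon)
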