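"""Reading, validation and normalization of CDS FASTA, cohort metadata and variant tables.

A coding sequence enters the pipeline as one complete in-frame CDS per FASTA
record, paired with a tab-separated metadata table keyed by accession that
supplies the cohort annotations (gene, species, tissue, disease-causing /
non-disease-causing label, exon count).  Sequences are normalized to
uppercase RNA spelling; validation enforces frame (length divisible by 3) and
the absence of internal in-frame stop codons.  Pathogenic substitutions are
read from a TSV with 1-based CDS coordinates, either as explicit
``cds_pos / ref / alt`` columns or in the HGVS coding dialect (``c.123A>T``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import RNA_BASES, STOP_CODONS

__all__ = [
    "TISSUES",
    "COHORT_LABELS",
    "CdsValidationError",
    "MetadataError",
    "VariantTableError",
    "CdsRecord",
    "VariantRecord",
    "normalize_sequence",
    "read_cds_fasta",
    "write_cds_fasta",
    "select_longest_isoform",
    "read_variant_table",
    "write_variant_table",
]

TISSUES = ("muscle", "skin", "kidney", "other")
COHORT_LABELS = ("DC", "NDC", "unlabeled")
EXPRESSION_CLASSES = ("high", "medium", "low")

#: IUPAC nucleotide ambiguity letters tolerated inside a CDS (RNA spelling).
_IUPAC_RNA = frozenset("ACGURYSWKMBDHVN")

_HGVS_SUB = re.compile(r"^c\.(\d+)([ACGTUacgtu])>([ACGTUacgtu])$")


class CdsValidationError(ValueError):
    """A coding sequence violates the CDS invariants (frame, internal stop...)."""


class MetadataError(KeyError):
    """A FASTA accession has no row in the cohort-metadata table."""


class VariantTableError(ValueError):
    """One or more variant-table rows could not be parsed or validated."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and transliterate T->U; reject non-IUPAC letters."""
    out = seq.upper().replace("T", "U")
    bad = set(out) - _IUPAC_RNA
    if bad:
        raise CdsValidationError(f"invalid sequence letters: {sorted(bad)}")
    return out


@dataclass
class CdsRecord:
    """One validated, in-frame coding sequence with its cohort annotations.

    ``exon_count == 0`` means unknown.  Ambiguity letters (N etc.) may remain
    in ``sequence``; codons containing them are skipped by the counters.
    """

    gene_id: str
    accession: str
    species: str
    sequence: str
    tissue: str = "other"
    cohort: str = "unlabeled"
    exon_count: int = 0
    expression_class: Optional[str] = None

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    @property
    def codons(self) -> List[str]:
        """Frame-0, non-overlapping triplets (may include ambiguous ones)."""
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s) - 2, 3)]

    @property
    def has_terminal_stop(self) -> bool:
        return len(self.sequence) >= 3 and self.sequence[-3:] in STOP_CODONS

    @property
    def terminal_stop(self) -> Optional[str]:
        return self.sequence[-3:] if self.has_terminal_stop else None

    def validate(self, permissive: bool = False) -> "CdsRecord":
        """Check frame and internal-stop invariants; returns self.

        With ``permissive=True`` an internal in-frame stop codon is demoted
        to a warning (useful for deliberately broken or partial inputs).
        """
        if len(self.sequence) % 3 != 0:
            raise CdsValidationError(
                f"{self.accession}: length {len(self.sequence)} is not a multiple of 3"
            )
        for i, codon in enumerate(self.codons[:-1]):
            if codon in STOP_CODONS:
                msg = f"{self.accession}: internal stop {codon} at codon {i + 1}"
                if permissive:
                    warnings.warn(msg)
                    break
                raise CdsValidationError(msg)
        if self.tissue not in TISSUES:
            raise CdsValidationError(f"{self.accession}: unknown tissue {self.tissue!r}")
        if self.cohort not in COHORT_LABELS:
            raise CdsValidationError(f"{self.accession}: unknown cohort {self.cohort!r}")
        return self


@dataclass(frozen=True)
class VariantRecord:
    """A single-base substitution at a 1-based CDS coordinate."""

    gene_id: str
    cds_pos: int
    ref_base: str
    alt_base: str
    reported_class: Optional[str] = None  # missense | nonsense, if stated

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise VariantTableError(f"cds_pos must be >= 1, got {self.cds_pos}")
        for base in (self.ref_base, self.alt_base):
            if base not in RNA_BASES:
                raise VariantTableError(f"invalid base {base!r}")
        if self.ref_base == self.alt_base:
            raise VariantTableError(
                f"{self.gene_id} c.{self.cds_pos}: ref equals alt ({self.ref_base})"
            )


def _read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", comment="#", dtype=str)
    required = {"accession", "gene_id", "species", "tissue", "cohort", "exon_count"}
    missing = required - set(meta.columns)
    if missing:
        raise MetadataError(f"metadata table lacks columns: {sorted(missing)}")
    meta = meta.set_index("accession", drop=False)
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].tolist()
        raise MetadataError(f"duplicate accessions in metadata: {dupes}")
    return meta


def read_cds_fasta(
    fasta_path,
    metadata_path,
    *,
    permissive: bool = False,
    on_error: str = "raise",
) -> List[CdsRecord]:
    """Read a CDS FASTA plus its cohort-metadata TSV into validated records.

    The FASTA record id (first whitespace-delimited token) must appear in the
    metadata ``accession`` column.  Returned records keep FASTA file order.

    Parameters
    ----------
    permissive
        Allow internal in-frame stop codons (warning instead of error).
    on_error
        ``"raise"`` aborts on the first invalid sequence; ``"warn"`` skips
        invalid records, reporting each with its reason.
    """
    if on_error not in ("raise", "warn"):
        raise ValueError("on_error must be 'raise' or 'warn'")
    meta = _read_metadata(metadata_path)
    records: List[CdsRecord] = []
    for seqrec in SeqIO.parse(str(fasta_path), "fasta"):
        accession = seqrec.id
        if accession not in meta.index:
            raise MetadataError(f"no metadata row for accession {accession!r}")
        row = meta.loc[accession]
        expr = row.get("expression_class")
        if isinstance(expr, str) and expr not in EXPRESSION_CLASSES:
            raise MetadataError(
                f"{accession}: unknown expression_class {expr!r}"
            )
        try:
            rec = CdsRecord(
                gene_id=row["gene_id"],
                accession=accession,
                species=row["species"],
                tissue=row["tissue"],
                cohort=row["cohort"],
                exon_count=int(row["exon_count"]),
                sequence=normalize_sequence(str(seqrec.seq)),
                expression_class=expr if isinstance(expr, str) else None,
            ).validate(permissive=permissive)
        except CdsValidationError as exc:
            if on_error == "raise":
                raise
            warnings.warn(f"skipping {accession}: {exc}")
            continue
        if set(rec.sequence) - set(RNA_BASES):
            warnings.warn(
                f"{accession}: ambiguity letters present; affected codons are "
                "excluded from codon counts"
            )
        records.append(rec)
    return records


def write_cds_fasta(records: Sequence[CdsRecord], fasta_path, metadata_path) -> None:
    """Write records back out in the same FASTA + metadata-TSV dialect."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(fasta_path), "fasta")
    rows = [
        {
            "accession": r.accession,
            "gene_id": r.gene_id,
            "species": r.species,
            "tissue": r.tissue,
            "cohort": r.cohort,
            "exon_count": r.exon_count,
            "expression_class": r.expression_class if r.expression_class else "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def select_longest_isoform(records: Iterable[CdsRecord]) -> List[CdsRecord]:
    """Keep one transcript per (gene, species): the longest CDS.

    Ties on length are broken by the lexicographically smallest accession so
    the choice is deterministic.  Output preserves the order in which each
    (gene, species) pair is first seen; the operation is idempotent.
    """
    best: Dict[Tuple[str, str], CdsRecord] = {}
    order: List[Tuple[str, str]] = []
    for rec in records:
        key = (rec.gene_id, rec.species)
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            cur = best[key]
            if (-len(rec.sequence), rec.accession) < (-len(cur.sequence), cur.accession):
                best[key] = rec
    return [best[k] for k in order]


def _parse_variant_row(row: pd.Series) -> VariantRecord:
    gene = str(row["gene_id"])
    cls = row.get("class")
    cls = str(cls) if isinstance(cls, str) and cls else None
    if "hgvs_c" in row.index and isinstance(row["hgvs_c"], str) and row["hgvs_c"]:
        m = _HGVS_SUB.match(row["hgvs_c"].strip())
        if not m:
            raise VariantTableError(f"unparsable HGVS string {row['hgvs_c']!r}")
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
    else:
        try:
            pos = int(row["cds_pos"])
        except (KeyError, TypeError, ValueError) as exc:
            raise VariantTableError(f"bad cds_pos: {exc}") from exc
        ref, alt = str(row["ref"]), str(row["alt"])
    ref = ref.upper().replace("T", "U")
    alt = alt.upper().replace("T", "U")
    return VariantRecord(gene, pos, ref, alt, reported_class=cls)


def read_variant_table(path) -> List[VariantRecord]:
    """Parse a variant TSV into normalized :class:`VariantRecord` objects.

    Accepts either explicit ``cds_pos`` / ``ref`` / ``alt`` columns or an
    ``hgvs_c`` column holding substitutions like ``c.123A>T``.  All failing
    rows are collected and reported together with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "gene_id" not in df.columns:
        raise VariantTableError("variant table lacks a gene_id column")
    out: List[VariantRecord] = []
    errors: List[str] = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            out.append(_parse_variant_row(row))
        except VariantTableError as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise VariantTableError(
            f"{len(errors)} invalid variant row(s):\n" + "\n".join(errors)
        )
    return out


def write_variant_table(variants: Sequence[VariantRecord], path) -> None:
    rows = [
        {
            "gene_id": v.gene_id,
            "cds_pos": v.cds_pos,
            "ref": v.ref_base,
            "alt": v.alt_base,
            "class": v.reported_class or "",
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
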