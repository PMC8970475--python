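"""Seeded generator of CDS cohorts with controlled codon-preference structure.

The generator emulates the cohort structure the analysis assumes: each gene
is an in-frame CDS whose amino-acid composition and within-family codon
choices are drawn independently — amino-acid usage i.i.d. from a
composition vector over the 18 considered amino acids, then each residue's
codon from that family's preference vector.  This separation matches the
analysis's implicit premise that CU values are meaningful conditional on
amino-acid usage.  Injected zero-codons (preference mass forced to zero)
give ground truth for extreme-bias detection; paired low-bias/high-bias
cohorts emulate the disease-causing-like (multiple codon usage, few
extremely biased codons) versus non-disease-causing-like (concentrated
preferences, many zero-codons) contrast.  Variant lists with known
per-codon-type intensities give ground truth for mapping-on-codons.

All generators are pure functions of their spec plus seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .genetic_code import RNA_BASES, STOP_CODONS, GeneticCodeTable, build_genetic_code
from .mapping import MISSENSE, NONSENSE, classify_substitution
from .sequence_io import CdsRecord, VariantRecord

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_fingerprint_pair",
    "generate_variants",
    "write_ground_truth",
]


@dataclass
class CohortSpec:
    """Parameters of one synthetic gene cohort.

    ``length_range`` counts the variable body codons of a gene; every gene
    additionally gets a leading AUG and a terminal stop drawn from
    ``stop_distribution``.  ``preference`` maps an amino-acid letter to a
    probability vector aligned with that family's canonical codon order;
    unspecified families use uniform preferences.  Codons listed in
    ``injected_zero_codons`` get preference mass zero (their family's
    remaining mass is renormalized), so they can never be drawn.
    """

    n_genes: int = 20
    length_range: Tuple[int, int] = (300, 1500)
    preference: Optional[Mapping[str, Sequence[float]]] = None
    aa_composition: Optional[Sequence[float]] = None
    injected_zero_codons: Set[str] = field(default_factory=set)
    stop_distribution: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0
    label: str = "synthetic"
    species: str = "synthetic"
    tissue: str = "other"
    cohort: str = "unlabeled"


@dataclass
class GroundTruth:
    """What the generator actually did, for exact downstream checks."""

    per_gene_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    injected_zero_codons: Set[str] = field(default_factory=set)
    preferences: Dict[str, Dict[str, float]] = field(default_factory=dict)
    variant_tallies: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_gene_counts": self.per_gene_counts,
                "injected_zero_codons": sorted(self.injected_zero_codons),
                "preferences": self.preferences,
                "variant_tallies": {
                    c: list(v) for c, v in sorted(self.variant_tallies.items())
                },
            },
            indent=2,
            sort_keys=True,
        )


def _effective_preferences(
    spec: CohortSpec, code: GeneticCodeTable
) -> Dict[str, np.ndarray]:
    """Per-family codon probabilities after zero-codon injection."""
    prefs: Dict[str, np.ndarray] = {}
    for fam in code.considered_families:
        if spec.preference and fam.amino_acid in spec.preference:
            p = np.asarray(spec.preference[fam.amino_acid], dtype=float)
            if p.shape != (fam.degeneracy,) or np.any(p < 0):
                raise ValueError(
                    f"preference vector for {fam.amino_acid} must be "
                    f"{fam.degeneracy} nonnegative numbers"
                )
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"preference vector for {fam.amino_acid} must sum to 1"
                )
        else:
            p = np.full(fam.degeneracy, 1.0 / fam.degeneracy)
        zero_mask = np.array(
            [c in spec.injected_zero_codons for c in fam.codons], dtype=bool
        )
        p = np.where(zero_mask, 0.0, p)
        if p.sum() <= 0:
            raise ValueError(
                f"family {fam.amino_acid}: all preference mass sits on "
                "injected zero-codons"
            )
        prefs[fam.amino_acid] = p / p.sum()
    return prefs


def generate_cohort(
    spec: CohortSpec, code: Optional[GeneticCodeTable] = None
) -> Tuple[List[CdsRecord], GroundTruth]:
    """Draw a cohort of in-frame CDS records plus exact ground truth.

    Per gene: body length uniform over ``length_range``; amino acids i.i.d.
    from the composition vector; each codon from its family's (effective)
    preference vector; AUG prepended and a stop appended.  Deterministic for
    a fixed spec and seed.
    """
    code = code or build_genetic_code()
    families = code.considered_families
    if spec.aa_composition is None:
        aa_comp = np.full(len(families), 1.0 / len(families))
    else:
        aa_comp = np.asarray(spec.aa_composition, dtype=float)
        if aa_comp.shape != (len(families),) or abs(aa_comp.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"aa_composition must be {len(families)} probabilities summing to 1"
            )
    stop_p = np.asarray(spec.stop_distribution, dtype=float)
    if stop_p.shape != (3,) or abs(stop_p.sum() - 1.0) > 1e-9:
        raise ValueError("stop_distribution must be 3 probabilities summing to 1")
    prefs = _effective_preferences(spec, code)

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length_range {spec.length_range}")
    width = len(str(spec.n_genes))
    records: List[CdsRecord] = []
    truth = GroundTruth(
        injected_zero_codons=set(spec.injected_zero_codons),
        preferences={
            aa: {c: float(p) for c, p in zip(fam.codons, prefs[aa])}
            for fam in families
            for aa in [fam.amino_acid]
        },
    )
    for g in range(spec.n_genes):
        gene_id = f"{spec.label}_{g + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        aa_idx = rng.choice(len(families), size=length, p=aa_comp)
        body = np.empty(length, dtype=object)
        for fi, fam in enumerate(families):
            sites = np.flatnonzero(aa_idx == fi)
            if sites.size == 0:
                continue
            codon_idx = rng.choice(
                fam.degeneracy, size=sites.size, p=prefs[fam.amino_acid]
            )
            for s, ci in zip(sites, codon_idx):
                body[s] = fam.codons[ci]
        stop = STOP_CODONS[int(rng.choice(3, p=stop_p))]
        sequence = "AUG" + "".join(body) + stop
        exon_count = int(rng.integers(1, 80))
        rec = CdsRecord(
            gene_id=gene_id,
            accession=f"SYN_{gene_id}",
            species=spec.species,
            tissue=spec.tissue,
            cohort=spec.cohort,
            exon_count=exon_count,
            sequence=sequence,
        ).validate()
        records.append(rec)
        tally: Dict[str, int] = {}
        for codon in rec.codons:
            tally[codon] = tally.get(codon, 0) + 1
        truth.per_gene_counts[gene_id] = tally
    return records, truth


def generate_fingerprint_pair(
    base_spec: CohortSpec,
    biased_codons: Optional[Set[str]] = None,
    concentration: float = 0.9,
    code: Optional[GeneticCodeTable] = None,
) -> Tuple[List[CdsRecord], List[CdsRecord], GroundTruth, GroundTruth]:
    """Generate a low-bias and a high-bias cohort sharing a base spec.

    The LOW cohort uses uniform codon preferences (disease-causing-like: the
    full synonymous repertoire stays in use).  The HIGH cohort concentrates
    ``concentration`` of each family's mass on one preferred codon and
    spreads the remainder evenly (non-disease-causing-like: strong bias,
    many zero-codons).  Preferred codons default to the first codon of each
    family in canonical order; ``biased_codons`` overrides per family.
    """
    if not 0 < concentration < 1:
        raise ValueError("concentration must be in (0, 1)")
    code = code or build_genetic_code()
    preferred: Dict[str, str] = {}
    for fam in code.considered_families:
        preferred[fam.amino_acid] = fam.codons[0]
    if biased_codons:
        for c in biased_codons:
            preferred[code.translate(c)] = c
    high_pref: Dict[str, List[float]] = {}
    for fam in code.considered_families:
        d = fam.degeneracy
        rest = (1.0 - concentration) / (d - 1)
        high_pref[fam.amino_acid] = [
            concentration if c == preferred[fam.amino_acid] else rest
            for c in fam.codons
        ]
    low_spec = replace(
        base_spec, preference=None, label=f"{base_spec.label}_low", seed=base_spec.seed
    )
    high_spec = replace(
        base_spec,
        preference=high_pref,
        label=f"{base_spec.label}_high",
        seed=base_spec.seed + 1,
    )
    low_records, low_truth = generate_cohort(low_spec, code)
    high_records, high_truth = generate_cohort(high_spec, code)
    return low_records, high_records, low_truth, high_truth


def generate_variants(
    rec: CdsRecord,
    intensity: Mapping[str, float],
    n_variants: int,
    seed: int,
    code: Optional[GeneticCodeTable] = None,
) -> Tuple[List[VariantRecord], GroundTruth]:
    """Draw substitutions with per-codon-type intensities and exact tallies.

    Codon sites are sampled (with replacement) with probability proportional
    to ``intensity[codon_type]`` per occurrence; within a chosen codon the
    substitution is drawn uniformly among those producing a missense or
    nonsense change.  Every sense codon of the standard code admits at least
    one such substitution, so any codon with positive intensity can host
    variants.  The returned ground truth records the true per-reference-
    codon tallies, split into (missense, nonsense).
    """
    code = code or build_genetic_code()
    if n_variants < 0:
        raise ValueError("n_variants must be nonnegative")
    sites: List[Tuple[int, str]] = []  # (1-based codon number, codon)
    codons = rec.codons
    last = len(codons) - 1
    for i, codon in enumerate(codons):
        if i == last and rec.has_terminal_stop:
            continue
        if set(codon) <= set(RNA_BASES) and code.translate(codon) != "*":
            sites.append((i + 1, codon))
    weights = np.array([intensity.get(c, 0.0) for _, c in sites], dtype=float)
    if np.any(weights < 0):
        raise ValueError("intensities must be nonnegative")
    if weights.sum() <= 0:
        raise ValueError("no present codon has positive intensity")
    rng = np.random.default_rng(seed)
    site_draws = rng.choice(len(sites), size=n_variants, p=weights / weights.sum())
    variants: List[VariantRecord] = []
    tallies: Dict[str, Tuple[int, int]] = {}
    for si in site_draws:
        number, ref_codon = sites[si]
        candidates = [
            (offset, alt, cls)
            for offset in range(3)
            for alt in RNA_BASES
            if alt != ref_codon[offset]
            for cls in [classify_substitution(ref_codon, offset, alt, code)]
            if cls in (MISSENSE, NONSENSE)
        ]
        if not candidates:  # pragma: no cover - impossible in the standard code
            raise RuntimeError(f"no nonsynonymous substitution for {ref_codon}")
        offset, alt, cls = candidates[int(rng.integers(len(candidates)))]
        variants.append(
            VariantRecord(
                gene_id=rec.gene_id,
                cds_pos=(number - 1) * 3 + offset + 1,
                ref_base=ref_codon[offset],
                alt_base=alt,
                reported_class=cls,
            )
        )
        mis, non = tallies.get(ref_codon, (0, 0))
        tallies[ref_codon] = (mis + 1, non) if cls == MISSENSE else (mis, non + 1)
    truth = GroundTruth(variant_tallies=tallies)
    return variants, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
        fh.write("\n")
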