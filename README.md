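# cubkit

Codon usage bias (CUB) fingerprints for small gene cohorts: per-gene
within-family codon-usage values, zero-codon and extreme-bias detection,
hierarchical cohort fingerprints, rank-based differential codon
prioritization, and "mapping-on-codons" of pathogenic coding variants.

## Who this is for

Human and medical geneticists comparing synonymous codon choices between
small, curated gene cohorts — e.g. disease-causing (DC) versus
non-disease-causing (NDC) genes matched by tissue of highest expression, or
orthologous cohorts across mammalian species — and relating codon usage to
where pathogenic substitutions land in a gene such as dystrophin (*DMD*).

## The statistics at the core

For a gene *g* and a sense codon *c* belonging to the synonymy family of
amino acid *a* with degeneracy *d(a)*, the **CU value** is the within-family
relative frequency

```
CU_g(c) = n_g(c) / Σ_{c' ∈ family(a)} n_g(c')
```

computed independently for each of the 18 multi-codon amino acids (59 sense
codons). Methionine (AUG) and tryptophan (UGG) are encoded by a unique
triplet and carry no synonymous-choice information, so they are excluded;
stop-codon usage (UAA/UAG/UGA) is summarized separately over the cohort's
terminal stops.

On these values the package computes:

* **Zero-codons** — synonymous codons a gene never uses (extreme CUB), by
  default restricted to families the gene actually uses (`family_present`
  policy), with a `raw` policy available.
* **Extremely biased codons** — codons with `CU < t(d)` where the cutoff
  depends on the family's redundancy (2, 3, 4 or 6 triplets); default
  `t(d) = 0.5/d`, half the uniform expectation, overridable per degeneracy.
* **CUB fingerprints** — gene × codon CU matrices clustered with Euclidean
  distance and complete-linkage agglomeration; dendrograms export as Newick.
* **Differential codon usage** — per-codon two-sided Wilcoxon rank-sum tests
  between cohorts, prioritized at raw *P* < 0.05 (Benjamini–Hochberg
  optional), plus Spearman rank correlation of cohort CU profiles.
* **Mapping-on-codons** — each pathogenic substitution (1-based CDS
  coordinates or HGVS `c.` notation) is placed on its reference codon,
  classified (missense / nonsense / synonymous / stop-loss) under the
  standard code, and tallied per codon type; burden is reported both as a
  share of all mutations and as a per-occurrence rate, joined with CU values.

A seeded synthetic-cohort generator produces in-frame CDS cohorts with
controlled per-amino-acid codon preferences (including injected
zero-codons) and variant sets with known per-codon-type intensities, so
every stage can be verified against exact ground truth.

## Worked example

```python
from cubkit import (CohortSpec, generate_fingerprint_pair, count_codons,
                    zero_codons, build_matrix, euclidean_distance,
                    complete_linkage, cut_clusters, most_differential_codons)
from cubkit.profiles import profiles_from_records

low, high, *_ = generate_fingerprint_pair(
    CohortSpec(n_genes=10, length_range=(400, 400), seed=42), concentration=0.9
)
z_low = sum(zero_codons(count_codons(r)).count for r in low)
z_high = sum(zero_codons(count_codons(r)).count for r in high)
print(f"zero-codons, low-bias cohort:  {z_low}")
print(f"zero-codons, high-bias cohort: {z_high}")
```

prints

```
zero-codons, low-bias cohort:  3
zero-codons, high-bias cohort: 174
```

The low-bias cohort (uniform synonymous preferences, the DC-like condition)
keeps nearly the full codon repertoire in use, while the high-bias cohort
(90 % of each family's mass on one preferred codon, NDC-like) accumulates
many zero-codons. Clustering the 20-gene fingerprint matrix and cutting at
two clusters recovers the cohort labels perfectly here (20/20 genes), and
per-codon rank-sum tests prioritize all 59 codons at *P* < 0.05 — the
preference shift moves every family.

The same analyses run from the shell via the `cubkit` CLI
(`simulate`, `count`, `profile`, `cluster`, `compare`, `zerocodons`,
`mapmut`, `run`); `cubkit run --config run.yaml` executes the whole
pipeline into an output directory with a deterministic JSON manifest.

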