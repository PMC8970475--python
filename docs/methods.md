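# Methods

## The model of codon usage

The package treats a gene's coding sequence as a sequence of independent
codon choices made *conditionally on its amino-acid sequence*. For each
multi-codon amino acid, the gene's synonymous choices are summarized by the
within-family relative frequencies (CU values), which sum to exactly 1 over
each family the gene uses. This conditioning is the central modeling
assumption: CU values deliberately ignore amino-acid composition, so two
genes with different protein content but identical synonymous preferences
get identical profiles. Consequences of the assumption:

* A family the gene never uses carries no information about codon choice.
  Its codons are *masked* (flagged absent), not treated as zeros of
  preference. This drives the default `family_present` zero-codon policy —
  a codon is only called a zero-codon when its amino acid occurs in the
  gene but that synonymous spelling is never chosen. The `raw` policy
  (every unused sense codon) is retained because "never used" is also a
  meaningful, stricter notion; both are exported and the choice is a config
  switch, never inferred.
* Met (AUG), Trp (UGG) and the stop codons never enter CU statistics. The
  standard code then leaves 18 families with degeneracy 2, 3, 4 or 6,
  carrying 59 sense codons; these are the columns of every fingerprint
  matrix. Stop-codon usage is a separate cohort-level frequency over
  terminal stops; genes lacking a terminal stop are excluded from that
  denominator rather than imputed.

## Parameters that matter

| Parameter | Default | Meaning |
| --- | --- | --- |
| extreme-bias cutoff `t(d)` | `0.5/d` | A codon of a d-fold family is "extremely biased" when its CU value is below half the uniform expectation `1/d`. The cutoff is per-degeneracy and overridable (`--cutoff "2:0.25,6:0.083"`), because the natural definition of "rare" scales with family size: 0.2 is unremarkable in a 2-fold family and strong avoidance in a 6-fold one. |
| zero-codon policy | `family_present` | See above. |
| significance threshold `alpha` | 0.05 | Raw two-sided rank-sum threshold for codon prioritization. No multiplicity correction by default — prioritization is exploratory ranking, not confirmatory inference — but Benjamini–Hochberg is one flag away since 59 simultaneous codon tests invite it. |
| matrix mode | `per-gene` | Fingerprint rows are genes (ordered by decreasing exon count, ties by gene id); `pooled` collapses each (species, tissue, cohort) cell into one row of pooled-count CU values. Both are supported because gene-level and cohort-level fingerprints answer different questions. |
| isoform rule | longest CDS | One transcript per (gene, species); ties broken by smallest accession for determinism. |

## Numerical and procedural choices

* **Distances and clustering.** Euclidean distance on CU rows/columns;
  agglomerative clustering with complete (maximum) linkage, which
  guarantees monotone merge heights. Masked cells enter distances as 0 —
  the same convention heat maps use when painting absent families as the
  lowest color — and are flagged in output so a user can re-run with
  imputation if desired. Dendrograms serialize to Newick with branch
  lengths equal to parent-minus-child merge heights.
* **Rank-sum test.** Exact enumeration when the combined sample size is at
  most 12 with no ties (where enumeration is cheap and exactness free);
  otherwise the normal approximation with midranks, tie-corrected variance
  and continuity correction. The two regimes agree to the approximation's
  accuracy at the boundary.
* **Spearman correlation** uses midranks with the two-sided t
  approximation for p; zero-variance input is flagged as undefined rather
  than returned as 0.
* **Degenerate inputs.** Empty cohorts pool to an error; cohorts without
  terminal stops return an empty stop-usage table with a warning; codons
  containing ambiguity letters (N etc.) are excluded from counts (tallied
  separately) rather than failing the gene; variants are excluded — never
  silently dropped — with machine-readable reasons (`ref_mismatch`,
  `out_of_range`, `synonymous`, `stop_loss`, `gene_mismatch`).
* **Mapping-on-codons** tallies variants against the *reference* codon (the
  site of the mutation), not the mutant codon. Burden is exported under
  both normalizations — share of all accepted mutations and rate per codon
  occurrence — because a "mutation percentage" is ambiguous between them;
  the association between CU values and per-occurrence rates is reported as
  a Spearman coefficient, never asserted.

## What the synthetic generator emulates — and what it does not

`generate_cohort` draws, per gene: a body length uniform over a range
(default 300–1500 codons, typical of curated disease-gene cohorts, which
range up to dystrophin's ≈3,685 codons), amino acids i.i.d. from a
composition vector (default uniform over the 18 considered families),
codons from per-family preference vectors, a leading AUG and a terminal
stop from a stop-usage distribution. Injected zero-codons get preference
mass exactly 0 and are recorded as ground truth.
`generate_fingerprint_pair` emulates the DC/NDC contrast at the level where
it is testable: a low-bias cohort with uniform preferences versus a
high-bias cohort concentrating 90 % (configurable) of each family's mass on
one preferred codon. `generate_variants` samples substitution sites with
probability proportional to a per-codon-type intensity times occurrence and
draws a uniformly random missense- or nonsense-producing substitution at
the chosen codon, recording exact per-codon tallies.

Deliberately **not** emulated: phylogenetic correlation between species
(each cohort is independent; shared preference vectors are the only way to
couple cohorts), amino-acid composition differences between cohorts
(composition and preference are independent by construction, mirroring the
analysis's conditioning), codon autocorrelation along the sequence, GC
pressure, and expression-level stratification. Passing tests therefore
demonstrate that the *pipeline* recovers known preference structure from
sequence data exactly or within stated sampling bounds — not that real
cohorts satisfy the generative assumptions.

## Design choices where the design was open

* **Genetic-code bookkeeping**: 18 multi-codon sense families / 59 codons
  is the count the standard code forces once Met, Trp and stops are
  excluded, and is used consistently throughout.
* **Extreme-bias cutoff**: redundancy-dependent cutoffs are standard but no
  single published constant is canonical; half-of-uniform is the default
  here because it is parameter-free and symmetric across family sizes, and
  the per-degeneracy override keeps any alternative calibration one flag
  away.
* **Zero-codon cohort tables** export both aggregations — the sum of
  per-gene zero-codon counts and the pooled-cohort zero-codon count —
  because the two answer different questions (how often genes avoid codons
  vs. whether the whole cohort ever uses one) and neither subsumes the
  other.
* **Comparison sets** for "most differentially used codons" (which cohort
  pairs to test) are a configurable list, defaulting to all pairs of the
  chosen grouping variable, with codons ranked by their minimum p across
  comparisons.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` verify: codon counting on 1,000
random CDS of 2–2,000 codons against an independent triplet-scan oracle
(exact); CU normalization on 200 random genes (≤ 1e-12); complete-linkage
heights on 200 random instances with ≤ 12 leaves against a naive O(n³)
agglomeration oracle (≤ 1e-9); rank-sum null calibration over 5,000
replicates at n = 20 per group (rejection rate in [0.03, 0.07] at
α = 0.05); fingerprint recovery over 100 seeded cohort pairs of 20 genes ×
400 codons at concentration 0.9 (zero-codon contrast in every replicate,
perfect 2-cluster adjusted Rand index in ≥ 95); and 100 exact
mapping-on-codons round trips with spiked exclusions.

## Known limitations

* The clustering tie-break among equal-height merges follows the linkage
  routine's deterministic order; alternative valid dendrograms exist for
  tied data, so only the height multiset (not the merge tree) is
  oracle-checked.
* CU values from very short genes or rare amino acids are high-variance;
  the package reports family totals so users can filter, but applies no
  shrinkage.
* The asymptotic rank-sum p is approximate for small samples with ties;
  exact tie-handling enumeration is not implemented.
* HGVS parsing covers single-base coding substitutions (`c.<pos><ref>><alt>`)
  only — deletions, duplications, intronic and UTR coordinates are out of
  scope and rejected with row-level errors.
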