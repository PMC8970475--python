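"""Cohort-level statistics: fingerprint matrices, clustering, rank tests.

A cohort's "CUB fingerprint" is the gene x codon matrix of within-family CU
values, hierarchically clustered with Euclidean distance and complete
linkage.  Cohorts are compared per codon with the two-sided Wilcoxon
rank-sum test and summarized with Spearman rank correlation; codons are
prioritized by raw p < alpha (Benjamini-Hochberg optionally available, since
59 simultaneous codon tests invite it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import pdist, squareform
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .genetic_code import GeneticCodeTable, build_genetic_code
from .profiles import CUProfile, ZeroCodonReport

__all__ = [
    "CohortMatrix",
    "ClusterResult",
    "DifferentialResult",
    "SpearmanResult",
    "build_matrix",
    "euclidean_distance",
    "complete_linkage",
    "cut_clusters",
    "to_newick",
    "wilcoxon_rank_sum",
    "spearman_correlation",
    "differential_codon_usage",
    "prioritize_codons",
    "most_differential_codons",
    "zero_codon_table",
]


@dataclass
class CohortMatrix:
    """Genes (or pooled cohorts) x codons table of CU values.

    Masked cells mark absent amino-acid families; they carry the stored
    value 0.0, which is also how they enter Euclidean distances (absent
    families plot as the lowest-value color in the fingerprint heat maps).
    """

    row_ids: List[str]
    col_ids: List[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match row/col labels")
        if self.values.min(initial=0.0) < 0 or self.values.max(initial=0.0) > 1:
            raise ValueError("CU values must lie in [0, 1]")
        if np.any(self.values[self.mask] != 0.0):
            raise ValueError("masked cells must carry value 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


@dataclass
class ClusterResult:
    """Dendrogram for one axis of a :class:`CohortMatrix`.

    ``merges`` follows the scipy convention: leaves are 0..n-1 and the i-th
    merge creates node n+i; heights are non-decreasing under complete
    linkage.  ``leaf_order`` is the dendrogram's left-to-right traversal.
    """

    merges: List[Tuple[int, int, float]]
    leaf_order: List[str]
    axis: str
    labels: List[str]
    linkage_matrix: np.ndarray

    @property
    def heights(self) -> List[float]:
        return [h for _, _, h in self.merges]


@dataclass
class DifferentialResult:
    """Two-sided rank-sum comparison of one codon's CU values between cohorts."""

    codon: str
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    comparison: str = ""


@dataclass
class SpearmanResult:
    rho: float
    p_value: Optional[float]
    ok: bool = True  # False when an input had zero variance


def build_matrix(
    profiles: Sequence[CUProfile],
    ordering: str = "exon_count",
    code: Optional[GeneticCodeTable] = None,
) -> CohortMatrix:
    """Assemble CU profiles into a genes x 59-codons fingerprint matrix.

    ``ordering="exon_count"`` lists genes in decreasing exon-count order
    (ties broken by gene id, ascending), the convention used for every
    fingerprint figure; ``"given"`` keeps the input order.  Columns follow
    the canonical codon order.  Absent families are masked.
    """
    code = code or build_genetic_code()
    ids = [p.gene_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate row labels: {dupes}")
    if ordering == "exon_count":
        profiles = sorted(profiles, key=lambda p: (-p.exon_count, p.gene_id))
    elif ordering != "given":
        raise ValueError(f"unknown ordering {ordering!r}")
    cols = list(code.considered_codons)
    aa_of = {c: code.translate(c) for c in cols}
    values = np.array([[p.cu[c] for c in cols] for p in profiles], dtype=float)
    mask = np.array(
        [[not p.family_present[aa_of[c]] for c in cols] for p in profiles], dtype=bool
    )
    return CohortMatrix([p.gene_id for p in profiles], cols, values, mask)


def euclidean_distance(matrix: CohortMatrix, axis: str = "rows") -> np.ndarray:
    """Pairwise Euclidean distances between rows or columns (square form)."""
    data = matrix.values if axis == "rows" else matrix.values.T
    if axis not in ("rows", "cols"):
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to compute distances")
    return squareform(pdist(data, metric="euclidean"))


def complete_linkage(
    dist: np.ndarray, labels: Sequence[str], axis: str = "rows"
) -> ClusterResult:
    """Agglomerative clustering with complete (maximum) linkage.

    Inter-cluster distance is the maximum pairwise member distance, so merge
    heights are monotonically non-decreasing.  Tie handling is the linkage
    routine's deterministic order, making results reproducible across runs.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n != len(labels):
        raise ValueError("distance matrix and labels disagree")
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = _hier.linkage(squareform(dist, checks=False), method="complete")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    order = [labels[i] for i in _hier.leaves_list(Z)]
    return ClusterResult(
        merges=merges,
        leaf_order=order,
        axis=axis,
        labels=list(labels),
        linkage_matrix=Z,
    )


def cut_clusters(result: ClusterResult, k: int) -> Dict[str, int]:
    """Flat assignment of leaves to *k* clusters (maxclust cut)."""
    flat = _hier.fcluster(result.linkage_matrix, t=k, criterion="maxclust")
    return {label: int(c) for label, c in zip(result.labels, flat)}


def to_newick(result: ClusterResult, digits: int = 6) -> str:
    """Serialize the dendrogram as Newick with heights as branch lengths.

    Each branch length is the parent merge height minus the child's own
    height (leaves sit at height 0).
    """
    n = len(result.labels)
    nodes: Dict[int, Tuple[str, float]] = {
        i: (result.labels[i], 0.0) for i in range(n)
    }
    node_id = n
    for a, b, h in result.merges:
        na, ha = nodes.pop(a)
        nb, hb = nodes.pop(b)
        nodes[node_id] = (
            f"({na}:{h - ha:.{digits}g},{nb}:{h - hb:.{digits}g})",
            h,
        )
        node_id += 1
    ((_, (tree, _)),) = nodes.items()
    return tree + ";"


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the combined sample size is at most 12 and there
    are no ties; otherwise the normal approximation with midranks,
    tie-corrected variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = _sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> SpearmanResult:
    """Spearman rank correlation on midranks with two-sided t-approximation p.

    Zero-variance input yields an undefined coefficient, flagged via
    ``ok=False`` with the p-value omitted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return SpearmanResult(rho=float("nan"), p_value=None, ok=False)
    rho, p = _sps.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p), ok=True)


def _codon_samples(
    profiles: Sequence[CUProfile], codon: str, code: GeneticCodeTable
) -> np.ndarray:
    """Per-gene CU values for one codon, dropping genes whose family is absent."""
    aa = code.translate(codon)
    return np.array(
        [p.cu[codon] for p in profiles if p.family_present[aa]], dtype=float
    )


def differential_codon_usage(
    profiles_a: Sequence[CUProfile],
    profiles_b: Sequence[CUProfile],
    code: Optional[GeneticCodeTable] = None,
    comparison: str = "",
    codons: Optional[Sequence[str]] = None,
) -> List[DifferentialResult]:
    """Per-codon rank-sum comparison of CU values between two cohorts.

    Genes whose amino-acid family is absent are dropped from that codon's
    sample.  Codons left with an empty sample on either side are skipped.
    """
    code = code or build_genetic_code()
    out: List[DifferentialResult] = []
    for codon in codons or code.considered_codons:
        xa = _codon_samples(profiles_a, codon, code)
        xb = _codon_samples(profiles_b, codon, code)
        if xa.size == 0 or xb.size == 0:
            continue
        out.append(
            DifferentialResult(
                codon=codon,
                p_value=wilcoxon_rank_sum(xa, xb),
                median_a=float(np.median(xa)),
                median_b=float(np.median(xb)),
                n_a=int(xa.size),
                n_b=int(xb.size),
                comparison=comparison,
            )
        )
    return out


def prioritize_codons(
    results: Sequence[DifferentialResult],
    alpha: float = 0.05,
    method: str = "raw",
) -> List[str]:
    """Codons significant at *alpha*, ordered by ascending p-value.

    ``method="raw"`` thresholds unadjusted p-values (the default analysis
    convention); ``"bh"`` applies the Benjamini-Hochberg step-up over the
    supplied results before thresholding.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not results:
        return []
    if method == "raw":
        kept = [r for r in results if r.p_value < alpha]
    elif method == "bh":
        reject, *_ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="fdr_bh"
        )
        kept = [r for r, rej in zip(results, reject) if rej]
    else:
        raise ValueError(f"unknown method {method!r}")
    return [r.codon for r in sorted(kept, key=lambda r: (r.p_value, r.codon))]


def most_differential_codons(
    groups: Mapping[str, Sequence[CUProfile]],
    comparisons: Optional[Sequence[Tuple[str, str]]] = None,
    alpha: float = 0.05,
    method: str = "raw",
    code: Optional[GeneticCodeTable] = None,
) -> Tuple[List[str], pd.DataFrame]:
    """Prioritize codons by their minimum p-value across cohort comparisons.

    By default every unordered pair of groups is compared; a config-supplied
    comparison list restricts this.  Returns the prioritized codon list and
    the full long-format result table.
    """
    code = code or build_genetic_code()
    labels = list(groups)
    if comparisons is None:
        comparisons = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    all_results: List[DifferentialResult] = []
    for la, lb in comparisons:
        all_results.extend(
            differential_codon_usage(
                groups[la], groups[lb], code, comparison=f"{la}_vs_{lb}"
            )
        )
    best: Dict[str, DifferentialResult] = {}
    for r in all_results:
        if r.codon not in best or r.p_value < best[r.codon].p_value:
            best[r.codon] = r
    ranked = prioritize_codons(list(best.values()), alpha=alpha, method=method)
    table = pd.DataFrame(
        [
            {
                "codon": r.codon,
                "amino_acid": code.translate(r.codon),
                "comparison": r.comparison,
                "p_value": r.p_value,
                "median_a": r.median_a,
                "median_b": r.median_b,
                "n_a": r.n_a,
                "n_b": r.n_b,
            }
            for r in all_results
        ]
    )
    return ranked, table


def zero_codon_table(
    cohorts: Mapping[object, Sequence[ZeroCodonReport]],
) -> Dict[object, int]:
    """Per-cohort totals of zero-codons, summed over the cohort's genes.

    This is the per-gene-sum aggregation; the pooled-cohort alternative
    (codons unused by the whole cohort) is the size of a zero-codon report
    computed on pooled counts and is exported alongside by the pipeline.
    Empty cohorts yield 0 with a warning.
    """
    table: Dict[object, int] = {}
    for key, reports in cohorts.items():
        if not reports:
            warnings.warn(f"cohort {key!r} is empty")
            table[key] = 0
        else:
            table[key] = sum(r.count for r in reports)
    return table
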