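"""Fingerprint matrices, clustering, rank tests, prioritization, zero-codon tables."""

import io as _io

import numpy as np
import pytest
from Bio import Phylo

from cubkit.genetic_code import build_genetic_code
from cubkit.profiles import count_codons, cu_values, zero_codons
from cubkit.stats import (
    DifferentialResult,
    build_matrix,
    complete_linkage,
    cut_clusters,
    differential_codon_usage,
    euclidean_distance,
    prioritize_codons,
    spearman_correlation,
    to_newick,
    wilcoxon_rank_sum,
    zero_codon_table,
)
from conftest import make_record

CODE = build_genetic_code()


def naive_complete_linkage_heights(dist):
    """Independent O(n^3) agglomeration oracle returning merge heights."""
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def _profile(seq, gene, exons=0):
    rec = make_record(seq, gene)
    return cu_values(count_codons(rec), CODE, exon_count=exons)


class TestBuildMatrix:
    def test_rows_ordered_by_decreasing_exon_count(self):
        profs = [
            _profile("AUGCUGUAA", "A", exons=79),
            _profile("AUGCUGUAA", "B", exons=10),
            _profile("AUGCUGUAA", "C", exons=50),
        ]
        matrix = build_matrix(profs)
        assert matrix.row_ids == ["A", "C", "B"]
        assert matrix.col_ids == list(CODE.considered_codons)

    def test_single_profile_shape_and_mask_bookkeeping(self):
        matrix = build_matrix([_profile("AUGCUGCUGUAA", "A")])
        assert matrix.values.shape == (1, 59)
        # every considered codon slot of an absent family is masked: all but Leu's 6
        assert int(matrix.mask.sum()) == 59 - 6
        assert np.all(matrix.values[matrix.mask] == 0.0)

    def test_duplicate_row_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix([_profile("AUGCUGUAA", "A"), _profile("AUGCUGUAA", "A")])


class TestEuclideanDistance:
    def test_three_four_five_triangle(self):
        from cubkit.stats import CohortMatrix

        m = CohortMatrix(
            ["r1", "r2"],
            ["c1", "c2"],
            np.array([[0.0, 0.0], [0.6, 0.8]]),
            np.zeros((2, 2), bool),
        )
        D = euclidean_distance(m)
        assert D[0, 1] == pytest.approx(1.0)
        assert D[0, 0] == 0.0 == D[1, 1]

    def test_matches_double_loop_oracle(self):
        from cubkit.stats import CohortMatrix

        rng = np.random.default_rng(5)
        vals = rng.random((8, 12))
        m = CohortMatrix(
            [f"r{i}" for i in range(8)],
            [f"c{j}" for j in range(12)],
            vals,
            np.zeros((8, 12), bool),
        )
        D = euclidean_distance(m)
        for i in range(8):
            for j in range(8):
                expect = np.sqrt(((vals[i] - vals[j]) ** 2).sum())
                assert D[i, j] == pytest.approx(expect, abs=1e-12)


class TestCompleteLinkage:
    def test_one_dimensional_worked_example(self):
        pts = np.array([0.0, 1.0, 10.0])
        D = np.abs(pts[:, None] - pts[None, :])
        result = complete_linkage(D, ["p0", "p1", "p10"])
        assert result.heights == pytest.approx([1.0, 10.0])

    def test_identical_items_merge_at_zero(self):
        D = np.zeros((4, 4))
        result = complete_linkage(D, list("abcd"))
        assert result.heights == pytest.approx([0.0, 0.0, 0.0])

    def test_heights_match_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 13))
            pts = rng.random((n, 5))
            D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            result = complete_linkage(D, [f"x{i}" for i in range(n)])
            oracle = naive_complete_linkage_heights(D)
            assert result.heights == pytest.approx(oracle, abs=1e-9)
            assert result.heights == sorted(result.heights)  # monotone

    def test_merge_heights_invariant_to_input_permutation(self):
        rng = np.random.default_rng(3)
        pts = rng.random((9, 4))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        base = sorted(complete_linkage(D, [f"x{i}" for i in range(9)]).heights)
        for _ in range(5):
            perm = rng.permutation(9)
            Dp = D[np.ix_(perm, perm)]
            got = sorted(complete_linkage(Dp, [f"x{i}" for i in range(9)]).heights)
            assert got == pytest.approx(base, abs=1e-12)

    def test_two_cluster_cut_separates_clear_groups(self):
        pts = np.concatenate([np.zeros(4), np.full(4, 10.0)])
        D = np.abs(pts[:, None] - pts[None, :])
        labels = [f"x{i}" for i in range(8)]
        assignment = cut_clusters(complete_linkage(D, labels), 2)
        left = {assignment[f"x{i}"] for i in range(4)}
        right = {assignment[f"x{i}"] for i in range(4, 8)}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_newick_export_is_parseable_with_heights_as_depths(self):
        pts = np.array([0.0, 1.0, 10.0])
        D = np.abs(pts[:, None] - pts[None, :])
        result = complete_linkage(D, ["p0", "p1", "p10"])
        tree = Phylo.read(_io.StringIO(to_newick(result)), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == {"p0", "p1", "p10"}
        depths = tree.depths()
        by_name = {t.name: d for t, d in depths.items() if t.name}
        assert by_name["p10"] == pytest.approx(10.0)
        assert by_name["p0"] == pytest.approx(10.0)  # root sits at the last height


class TestWilcoxonRankSum:
    def test_exact_enumeration_example(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_perfect_symmetry_gives_p_one(self):
        assert wilcoxon_rank_sum([1, 2], [1, 2]) == pytest.approx(1.0)

    def test_two_sided_symmetry_in_arguments(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(2, 25)))
            b = rng.normal(size=int(rng.integers(2, 25)))
            assert wilcoxon_rank_sum(a, b) == pytest.approx(
                wilcoxon_rank_sum(b, a), abs=1e-12
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSpearman:
    def test_monotone_identity_and_antitone(self):
        x = [0.1, 0.4, 0.2, 0.9, 0.6]
        assert spearman_correlation(x, x).rho == pytest.approx(1.0)
        assert spearman_correlation(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        res = spearman_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8)

    def test_invariance_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.random(20)
        y = rng.random(20)
        base = spearman_correlation(x, y).rho
        assert spearman_correlation(np.exp(3 * x), y).rho == pytest.approx(base)
        assert spearman_correlation(x, y**3 + 5).rho == pytest.approx(base)

    def test_zero_variance_flagged(self):
        res = spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.ok and res.p_value is None and np.isnan(res.rho)


class TestPrioritization:
    def _results(self, pvals):
        return [
            DifferentialResult(codon=c, p_value=p, median_a=0, median_b=0, n_a=3, n_b=3)
            for c, p in pvals.items()
        ]

    def test_raw_threshold_and_ordering(self):
        results = self._results({"CGU": 0.01, "CCA": 0.2})
        assert prioritize_codons(results, alpha=0.05) == ["CGU"]

    def test_all_above_alpha_gives_empty(self):
        assert prioritize_codons(self._results({"CGU": 0.6, "CCA": 0.2})) == []

    def test_benjamini_hochberg_step_up(self):
        results = self._results({"AAA": 0.01, "CCC": 0.02, "GGG": 0.9})
        assert prioritize_codons(results, alpha=0.05, method="bh") == ["AAA", "CCC"]


class TestDifferentialAndZeroTable:
    def test_differential_skips_absent_family_genes(self):
        # Leu-only genes on side A; side B has Leu in two variants
        a = [_profile("AUGCUGCUGUAA", f"A{i}") for i in range(3)]
        b = [_profile("AUGCUUCUUUAA", f"B{i}") for i in range(3)]
        results = differential_codon_usage(a, b, CODE)
        codons = {r.codon for r in results}
        assert codons <= set(CODE.family_of("CUG").codons)
        for r in results:
            assert r.n_a == 3 and r.n_b == 3
            assert 0.0 <= r.p_value <= 1.0

    def test_zero_codon_table_sums_per_gene(self):
        g1 = zero_codons(count_codons(make_record("AUGCUGCUGUAA", "A")), CODE)
        g2 = zero_codons(count_codons(make_record("AUGCUUUAA", "B")), CODE)
        table = zero_codon_table({("hsa", "muscle", "DC"): [g1, g2]})
        assert table[("hsa", "muscle", "DC")] == g1.count + g2.count

    def test_empty_cohort_warns_and_yields_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert zero_codon_table({"empty": []}) == {"empty": 0}


def test_heatmap_renders_to_file(tmp_path):
    from cubkit.plotting import cu_heatmap

    profs = [
        _profile("AUGCUGCUGUAA", "A", exons=2),
        _profile("AUGCUUCUAUAA", "B", exons=1),
    ]
    out = tmp_path / "fingerprint.png"
    cu_heatmap(build_matrix(profs), out)
    assert out.stat().st_size > 0
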