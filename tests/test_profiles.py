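"""Codon counting, within-family CU values, zero-codons, extreme bias, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit.genetic_code import STOP, STOP_CODONS, build_genetic_code
from cubkit.profiles import (
    CodonCountVector,
    count_codons,
    cu_values,
    default_bias_cutoffs,
    extremely_biased_codons,
    pool_cohort_counts,
    stop_codon_usage,
    zero_codons,
)
from conftest import make_record, triplet_scan_counts

CODE = build_genetic_code()
SENSE = [c for c in CODE.all_codons if CODE.translate(c) != STOP]

sense_codon = st.sampled_from(SENSE)
codon_bodies = st.lists(sense_codon, min_size=1, max_size=120)


class TestCountCodons:
    def test_hand_counted_examples(self):
        vec = count_codons(make_record("AUGCUGCUGUAA"))
        assert vec.counts == {"AUG": 1, "CUG": 2, "UAA": 1}
        assert vec.terminal_stop == "UAA"
        vec2 = count_codons(make_record("AUGUAA"))
        assert vec2.counts == {"AUG": 1, "UAA": 1}

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(body=codon_bodies, stop_idx=st.integers(0, 2))
    def test_matches_sliding_index_oracle(self, body, stop_idx):
        seq = "".join(body) + STOP_CODONS[stop_idx]
        rec = make_record(seq)
        vec = count_codons(rec)
        assert vec.counts == triplet_scan_counts(seq)
        assert sum(vec.counts.values()) + vec.excluded_codons == rec.n_codons


class TestCuValues:
    def test_single_family_arithmetic(self):
        profile = cu_values(count_codons(make_record("AUGCUGCUGUAA")), CODE)
        assert profile.cu["CUG"] == 1.0
        for c in ("CUU", "CUC", "CUA", "UUA", "UUG"):
            assert profile.cu[c] == 0.0
        absent = [aa for aa, ok in profile.family_present.items() if not ok]
        assert len(absent) == 17  # every considered family but Leu

    def test_uniform_gene_gives_one_over_degeneracy(self):
        seq = "".join(SENSE) + "UAA"  # every sense codon exactly once
        profile = cu_values(count_codons(make_record(seq)), CODE)
        for codon in CODE.considered_codons:
            assert profile.cu[codon] == pytest.approx(
                1.0 / CODE.degeneracy(codon), abs=1e-15
            )

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(body=codon_bodies)
    def test_present_families_sum_to_one(self, body):
        profile = cu_values(count_codons(make_record("".join(body) + "UAA")), CODE)
        for fam in CODE.considered_families:
            total = sum(profile.cu[c] for c in fam.codons)
            if profile.family_present[fam.amino_acid]:
                assert total == pytest.approx(1.0, abs=1e-12)
            else:
                assert total == 0.0


class TestStopCodonUsage:
    def test_hand_counts(self):
        cohort = [
            make_record("AUGCUGUAA", "A"),
            make_record("AUGCUGUAA", "B"),
            make_record("AUGCUGUGA", "C"),
        ]
        assert stop_codon_usage(cohort) == {
            "UAA": pytest.approx(2 / 3),
            "UAG": 0.0,
            "UGA": pytest.approx(1 / 3),
        }

    def test_single_gene_and_stopless_exclusion(self):
        with_stop = make_record("AUGCUGUAG", "A")
        stopless = make_record("AUGCUGCUG", "B")
        assert stop_codon_usage([with_stop, stopless])["UAG"] == 1.0

    def test_no_terminal_stops_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="terminal stop"):
            assert stop_codon_usage([make_record("AUGCUG")]) == {}


class TestZeroCodons:
    def test_family_present_policy(self):
        report = zero_codons(count_codons(make_record("AUGCUGCUGUAA")), CODE)
        assert report.zero_codons == {"CUU", "CUC", "CUA", "UUA", "UUG"}

    def test_raw_policy_counts_complement(self):
        report = zero_codons(
            count_codons(make_record("AUGCUGCUGUAA")), CODE, policy="raw"
        )
        assert report.count == 58  # 59 considered codons minus the used CUG

    def test_uniform_gene_has_no_zero_codons(self):
        vec = count_codons(make_record("".join(SENSE) + "UAA"))
        assert zero_codons(vec, CODE).count == 0
        assert zero_codons(vec, CODE, policy="raw").count == 0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(body=codon_bodies, extension=st.lists(sense_codon, min_size=1, max_size=30))
    def test_appending_codons_never_increases_raw_zero_count(self, body, extension):
        before = zero_codons(
            count_codons(make_record("".join(body) + "UAA")), CODE, policy="raw"
        )
        after = zero_codons(
            count_codons(make_record("".join(body + extension) + "UAA")),
            CODE,
            policy="raw",
        )
        assert after.count <= before.count
        assert after.zero_codons <= before.zero_codons

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(body=codon_bodies, extension=st.lists(sense_codon, min_size=1, max_size=30))
    def test_family_present_zeros_shrink_within_present_families(self, body, extension):
        # A newly present family may add zero-codons, but within any family
        # already present the zero set can only shrink.
        vec_before = count_codons(make_record("".join(body) + "UAA"))
        vec_after = count_codons(make_record("".join(body + extension) + "UAA"))
        before = zero_codons(vec_before, CODE).zero_codons
        after = zero_codons(vec_after, CODE).zero_codons
        present_before = {
            fam.amino_acid
            for fam in CODE.considered_families
            if any(vec_before.counts.get(c, 0) for c in fam.codons)
        }
        restricted_after = {
            c for c in after if CODE.translate(c) in present_before
        }
        assert restricted_after <= before


class TestExtremelyBiasedCodons:
    def test_default_cutoff_is_half_uniform(self):
        assert default_bias_cutoffs() == {2: 0.25, 3: 0.5 / 3, 4: 0.125, 6: 0.5 / 6}

    def test_six_fold_family_threshold(self):
        # Ser cu = (0.9, 0.1, 0, 0, 0, 0): the zeros fall below t(6)=1/12, 0.1 does not.
        ser = CODE._family_by_aa()["S"]
        counts = {ser.codons[0]: 9, ser.codons[1]: 1}
        vec = CodonCountVector(gene_id="G", counts=counts)
        profile = cu_values(vec, CODE)
        flagged = extremely_biased_codons(profile, code=CODE)
        assert flagged == set(ser.codons[2:])

    def test_uniform_profile_unflagged(self):
        profile = cu_values(count_codons(make_record("".join(SENSE) + "UAA")), CODE)
        assert extremely_biased_codons(profile, code=CODE) == set()

    def test_absent_families_never_flagged(self):
        profile = cu_values(count_codons(make_record("AUGCUGCUGUAA")), CODE)
        flagged = extremely_biased_codons(profile, code=CODE)
        assert all(CODE.translate(c) == "L" for c in flagged)

    def test_cutoff_override(self):
        profile = cu_values(count_codons(make_record("".join(SENSE) + "UAA")), CODE)
        # raising every cutoff above uniform flags every considered codon
        cuts = {d: 1.0 for d in (2, 3, 4, 6)}
        assert extremely_biased_codons(profile, cuts, CODE) == set(
            CODE.considered_codons
        )


class TestPooling:
    def test_addition_and_identity(self):
        a = CodonCountVector("a", {"CUG": 2})
        b = CodonCountVector("b", {"CUG": 3})
        assert pool_cohort_counts([a, b]).counts == {"CUG": 5}
        assert pool_cohort_counts([a]).counts == a.counts

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            pool_cohort_counts([])

    def test_pooling_equals_counting_the_concatenation(self):
        rng = np.random.default_rng(11)
        bodies = ["".join(rng.choice(SENSE, size=30)) for _ in range(5)]
        records = [make_record(b + "UAA", f"G{i}") for i, b in enumerate(bodies)]
        pooled = pool_cohort_counts([count_codons(r) for r in records])
        concat = triplet_scan_counts("".join(r.sequence for r in records))
        assert pooled.counts == concat

    def test_pooled_cu_is_count_weighted_mixture(self):
        rng = np.random.default_rng(7)
        records = [
            make_record("".join(rng.choice(SENSE, size=50)) + "UAA", f"G{i}")
            for i in range(6)
        ]
        vecs = [count_codons(r) for r in records]
        profiles = [cu_values(v, CODE) for v in vecs]
        pooled_profile = cu_values(pool_cohort_counts(vecs), CODE)
        for fam in CODE.considered_families:
            totals = [
                sum(v.counts.get(c, 0) for c in fam.codons) for v in vecs
            ]
            grand = sum(totals)
            if grand == 0:
                continue
            for c in fam.codons:
                mixture = (
                    sum(t * p.cu[c] for t, p in zip(totals, profiles)) / grand
                )
                assert pooled_profile.cu[c] == pytest.approx(mixture, abs=1e-12)
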