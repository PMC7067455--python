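"""Hardy-Weinberg exact test, haplotype EM, TTT classes, associations."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.optimize import minimize

from tacpk2pd.pgx import (
    classify_ttt,
    genotype_association,
    haplotype_em,
    hwe_exact,
    pool_2677,
)


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-arithmetic enumeration of the conditional heterozygote
    distribution given allele counts (independent of the implementation:
    rational binomials, no logs)."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n - n_A
    if n_A == 0 or n_a == 0:
        return 1.0
    probs = {}
    for h in range(min(n_A, n_a) + 1):
        if (n_A - h) % 2:
            continue
        hom_A = (n_A - h) // 2
        hom_a = (n_a - h) // 2
        coeff = (
            Fraction(math.factorial(n))
            / (math.factorial(hom_A) * math.factorial(h) * math.factorial(hom_a))
            * Fraction(2) ** h
        )
        probs[h] = coeff
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return float(sum(p for p in (v / total for v in probs.values()) if p <= p_obs))


class TestHWE:
    def test_monomorphic_sample_is_one(self):
        assert hwe_exact(32, 0, 0) == 1.0

    def test_heterozygote_excess_detected(self):
        assert hwe_exact(1, 25, 6) < 0.05

    def test_mild_excess_in_a_small_cohort_is_borderline(self):
        # n = 32 with a moderate heterozygote excess: the exact
        # conditional test stays just above 0.05 (cross-checked against
        # the exact-arithmetic oracle below); only asymptotic chi-square
        # style tests call this significant
        assert 0.05 < hwe_exact(2, 21, 9) < 0.10

    @pytest.mark.parametrize(
        "counts",
        [(2, 21, 9), (10, 15, 7), (0, 5, 0), (1, 0, 1), (50, 100, 50), (3, 1, 28)],
    )
    def test_matches_exact_arithmetic_oracle(self, counts):
        assert hwe_exact(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-9
        )

    def test_random_counts_match_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 201))
            n_AA = int(rng.integers(0, n + 1))
            n_Aa = int(rng.integers(0, n - n_AA + 1))
            counts = (n_AA, n_Aa, n - n_AA - n_Aa)
            p = hwe_exact(*counts)
            assert 0.0 <= p <= 1.0
            assert p == pytest.approx(hwe_enumeration_oracle(*counts), rel=1e-9)


def _triple(call3435, call1236, call2677):
    return (tuple(call3435), tuple(call1236), tuple(pool_2677(call2677)))


def em_direct_oracle(triples, freq_result):
    """Directly maximize the multinomial mixture likelihood over the
    simplex with scipy (softmax parameterization) — an independent route
    to the same maximum-likelihood value."""
    from tacpk2pd.pgx import _consistent_diplotypes

    pair_lists = [_consistent_diplotypes(t) for t in triples]
    haps = sorted({h for pairs in pair_lists for p in pairs for h in p})
    idx = {h: i for i, h in enumerate(haps)}

    def negll(z):
        f = np.exp(z - z.max())
        f = f / f.sum()
        ll = 0.0
        for pairs in pair_lists:
            tot = sum(
                (1.0 if h1 == h2 else 2.0) * f[idx[h1]] * f[idx[h2]]
                for h1, h2 in pairs
            )
            ll += math.log(max(tot, 1e-300))
        return -ll

    best = math.inf
    for start in range(5):
        z0 = np.random.default_rng(start).normal(0, 1, len(haps))
        res = minimize(negll, z0, method="Nelder-Mead",
                       options={"maxiter": 20000, "fatol": 1e-12, "xatol": 1e-9})
        best = min(best, res.fun)
    return -best


def phase_assignment_oracle(triples):
    """Best single phase assignment: for every complete assignment of
    phases, the profile likelihood uses the empirical haplotype
    frequencies of that assignment.  The EM (mixture) optimum can only
    be at least as good."""
    from tacpk2pd.pgx import _consistent_diplotypes

    pair_lists = [_consistent_diplotypes(t) for t in triples]
    best = -math.inf
    for combo in itertools.product(*pair_lists):
        counts = {}
        for h1, h2 in combo:
            counts[h1] = counts.get(h1, 0) + 1
            counts[h2] = counts.get(h2, 0) + 1
        total = sum(counts.values())
        f = {h: c / total for h, c in counts.items()}
        ll = sum(
            math.log((1.0 if h1 == h2 else 2.0) * f[h1] * f[h2])
            for h1, h2 in combo
        )
        best = max(best, ll)
    return best


class TestHaplotypeEM:
    def test_all_homozygous_resolves_in_closed_form(self):
        triples = [
            _triple("CC", "CC", "GG"),
            _triple("TT", "TT", "TT"),
            _triple("CC", "CC", "GG"),
        ]
        res = haplotype_em(triples)
        assert res.frequencies[("C", "C", "G")] == pytest.approx(2 / 3)
        assert res.frequencies[("T", "T", "T")] == pytest.approx(1 / 3)

    def test_single_heterozygous_locus_is_phase_unambiguous(self):
        triples = [_triple("CT", "CC", "GG"), _triple("CC", "CC", "GG")]
        res = haplotype_em(triples)
        pair, prob = res.diplotypes[0]
        assert prob == pytest.approx(1.0)
        assert sorted(pair) == sorted(((("C", "C", "G")), (("T", "C", "G"))))

    def test_loglik_matches_direct_maximization_small_cohorts(self):
        cohorts = [
            [_triple("CT", "CT", "GT"), _triple("CC", "CC", "GG"),
             _triple("TT", "TT", "TT")],
            [_triple("CT", "CT", "GT"), _triple("CT", "CT", "GT"),
             _triple("CT", "CC", "GG"), _triple("TT", "CT", "GT"),
             _triple("CC", "CC", "GT")],
        ]
        for triples in cohorts:
            res = haplotype_em(triples)
            direct = em_direct_oracle(triples, res)
            assert res.loglik == pytest.approx(direct, abs=1e-5)
            # the frequency-change stopping rule (1e-8) leaves ~1e-7 slack
            # in the log-likelihood
            assert res.loglik >= phase_assignment_oracle(triples) - 1e-6

    def test_frequencies_form_a_simplex(self):
        triples = [_triple("CT", "CT", "GT"), _triple("CT", "CC", "GG")]
        res = haplotype_em(triples)
        assert sum(res.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(f >= 0 for f in res.frequencies.values())

    def test_missing_locus_excluded_with_finding(self):
        triples = [_triple("CT", "CT", "GT"), None]
        res = haplotype_em(triples)
        assert res.excluded == (1,)


class TestTTTClassification:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            ((("T", "T", "T"), ("T", "T", "T")), "HomTTT"),
            ((("T", "T", "T"), ("C", "C", "G")), "HetTTT"),
            ((("C", "C", "G"), ("C", "C", "G")), "other"),
            ((("T", "C", "G"), ("C", "T", "T")), "other"),
        ],
    )
    def test_classes(self, pair, expected):
        assert classify_ttt(pair) == expected

    def test_pooled_A_allele_counts_toward_T(self):
        assert pool_2677("GA") == "GT"
        assert pool_2677("TA") == "TT"


class TestAssociation:
    def test_exact_mann_whitney_enumeration_value(self):
        """Fully separated {1,2,3} vs {4,5,6}: U = 0 and the exact
        two-sided p is 2 / C(6,3) = 0.1."""
        res = genotype_association([1, 2, 3, 4, 5, 6], list("AAABBB"))
        assert res.test == "mann-whitney"
        assert res.p_raw == pytest.approx(0.1)

    def test_all_values_tied_gives_p_one(self):
        res = genotype_association([5.0] * 6, list("AAABBB"))
        assert res.p_raw == 1.0

    def test_bonferroni_adjustment_arithmetic(self):
        res = genotype_association(
            [1, 2, 3, 4, 5, 6], list("AAABBB"), family_size=2
        )
        assert res.p_adjusted == pytest.approx(0.2)
        res2 = genotype_association([1, 2, 3, 4, 5, 6], list("AAABBB"))
        assert res2.p_adjusted == res2.p_raw

    def test_three_groups_run_kruskal_with_posthoc(self, rng):
        values = np.concatenate([
            rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(3, 1, 10)
        ])
        groups = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        res = genotype_association(values, groups)
        assert res.test == "kruskal-wallis"
        assert len(res.posthoc) == 3
        for ph in res.posthoc:
            assert ph.p_adjusted == pytest.approx(min(1.0, ph.p_raw * 3))

    def test_single_subject_group_still_computed_exactly(self):
        res = genotype_association([1.0, 2.0, 3.0, 10.0], list("AAAB"))
        assert res.test == "mann-whitney"
        assert 0.0 < res.p_raw <= 1.0

    def test_type_i_error_calibration_under_null(self, rng):
        """Permuted labels: rejection rate at the 5% level stays near 5%."""
        values = rng.normal(0, 1, 24)
        labels = np.array(["A"] * 12 + ["B"] * 12)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            perm = rng.permutation(labels)
            res = genotype_association(values, perm)
            rejections += res.p_raw < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08
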