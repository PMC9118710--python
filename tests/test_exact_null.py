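"""Exact inversion-count nulls and asymptotic p-values."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from concordx import (
    InvalidInputError,
    InversionDistribution,
    MultisetSpec,
    PairedSample,
    UnsupportedTieStructureError,
    exact_ci_pvalue,
    inversion_distribution_multiset,
    inversion_distribution_no_ties,
    noether_ci_pvalue,
    pearson_t_pvalue,
    spearman_asymptotic_pvalue,
)
from concordx.exact_null import _discordant_count


def _enumerate_inversions(values):
    """Brute-force inversion histogram over distinct arrangements."""
    seen = Counter()
    for perm in set(itertools.permutations(values)):
        seen[sum(1 for i in range(len(perm)) for j in range(i + 1, len(perm))
                 if perm[i] > perm[j])] += 1
    return seen


class TestSetDistribution:
    def test_small_counts(self):
        assert inversion_distribution_no_ties(2).counts == (1, 1)
        assert inversion_distribution_no_ties(3).counts == (1, 2, 2, 1)

    def test_total_and_mean(self):
        d = inversion_distribution_no_ties(5)
        assert d.total == 120
        assert d.mean() == 5.0  # n(n-1)/4

    @pytest.mark.parametrize("n", range(1, 7))
    def test_matches_enumeration(self, n):
        seen = _enumerate_inversions(range(n))
        d = inversion_distribution_no_ties(n)
        assert d.counts == tuple(seen[k] for k in range(d.k_max + 1))
        assert sum(d.counts) == d.total == math.factorial(n)

    def test_symmetry_and_total_large(self):
        d = inversion_distribution_no_ties(60)
        assert d.counts == tuple(reversed(d.counts))
        assert sum(d.counts) == d.total == math.factorial(60)

    def test_invalid_n(self):
        with pytest.raises(InvalidInputError):
            inversion_distribution_no_ties(0)


class TestMultisetDistribution:
    def test_aab_enumeration(self):
        d = inversion_distribution_multiset(MultisetSpec((2, 1)))
        assert d.counts == (1, 1, 1)
        assert d.total == 3

    def test_single_class_concentrated(self):
        d = inversion_distribution_multiset(MultisetSpec((6,)))
        assert d.counts == (1,)
        assert d.total == 1

    def test_all_singletons_degenerates_to_set(self):
        d_ms = inversion_distribution_multiset(MultisetSpec((1,) * 6))
        d = inversion_distribution_no_ties(6)
        assert d_ms.counts == d.counts and d_ms.total == d.total

    @pytest.mark.parametrize("mult", [(2, 2), (3, 2, 1), (2, 2, 2), (4, 3),
                                      (1, 2, 1, 3)])
    def test_matches_enumeration(self, mult):
        values = [c for c, a in enumerate(mult) for _ in range(a)]
        seen = _enumerate_inversions(values)
        d = inversion_distribution_multiset(MultisetSpec(mult))
        assert d.counts == tuple(seen[k] for k in range(d.k_max + 1))
        total = math.factorial(sum(mult))
        for a in mult:
            total //= math.factorial(a)
        assert d.total == total

    def test_symmetry(self):
        d = inversion_distribution_multiset(MultisetSpec((5, 7, 3, 9)))
        assert d.counts == tuple(reversed(d.counts))


class TestExactCIPvalue:
    def test_perfect_concordance_n3(self):
        assert exact_ci_pvalue(PairedSample([1, 2, 3], [1, 2, 3])) == pytest.approx(1 / 3)

    def test_midpoint_p_is_one(self):
        # CI = 0.5 exactly: 3 of 6 pairs concordant
        s = PairedSample([1, 2, 3, 4], [2, 4, 1, 3])
        assert exact_ci_pvalue(s) == 1.0

    def test_both_tied_raises(self):
        with pytest.raises(UnsupportedTieStructureError):
            exact_ci_pvalue(PairedSample([1, 1, 2, 3], [1, 2, 2, 3]))

    def test_one_tied_matches_exhaustive_permutation(self):
        """Case with ties in one vector: p-value equals the exhaustive
        permutation-null tail computed by enumeration."""
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([0.3, 1.2, 0.7, 2.5, 1.9, 2.2])
        s = PairedSample(x, y)
        obs = _discordant_count(x, y)
        devs = []
        for perm in itertools.permutations(range(6)):
            devs.append(_discordant_count(x, y[list(perm)]))
        devs = np.array(devs)
        k_max = inversion_distribution_multiset(
            MultisetSpec.from_values(x)).k_max
        dev_obs = abs(2 * obs - k_max)
        p_enum = np.mean(np.abs(2 * devs - k_max) >= dev_obs)
        assert exact_ci_pvalue(s) == pytest.approx(p_enum)

    def test_pvalues_match_pmf_tails(self):
        d = inversion_distribution_no_ties(6)
        pm = d.pmf()
        for k in range(d.k_max + 1):
            lo = min(k, d.k_max - k)
            expected = pm[: lo + 1].sum() + pm[d.k_max - lo:].sum()
            assert d.pvalue(k) == pytest.approx(min(1.0, expected))


class TestDoublePrecisionBoundary:
    def test_pmf_finite_at_170(self):
        pm = inversion_distribution_no_ties(170).pmf()
        assert np.isfinite(pm).all()
        assert pm.sum() == pytest.approx(1.0)

    def test_pmf_overflows_at_171(self):
        d = inversion_distribution_no_ties(171)
        with pytest.raises(OverflowError):
            d.pmf()
        # exact-integer mode has no such limit
        assert d.sf(0) == 1.0
        assert sum(d.counts) == d.total


class TestAsymptoticTests:
    def test_noether_p_one_at_half(self):
        s = PairedSample([1, 2, 3, 4], [2, 4, 1, 3])  # CI exactly 0.5
        assert noether_ci_pvalue(s) == pytest.approx(1.0)

    def test_noether_monotone_in_deviation(self, rng):
        # stronger concordance -> smaller p at same n
        ps = []
        for r in (0.1, 0.4, 0.7):
            x = np.linspace(0, 1, 50)
            y = r * x + (1 - r) * rng.standard_normal(50) * 0.3
            ps.append(noether_ci_pvalue(PairedSample(x, y)))
        assert ps[0] > ps[1] > ps[2]

    def test_pearson_t_matches_scipy(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 80))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + 0.4 * x
            s = PairedSample(x, y)
            assert pearson_t_pvalue(s) == pytest.approx(
                stats.pearsonr(x, y).pvalue, rel=1e-9
            )

    def test_pearson_t_closed_form(self):
        # r=0.3, n=100: t = 0.3*sqrt(98/0.91) ~ 3.113, p ~ 0.00242
        t = 0.3 * math.sqrt(98 / 0.91)
        p = 2 * stats.t.sf(t, df=98)
        assert p == pytest.approx(0.00242, abs=5e-5)

    def test_spearman_matches_scipy(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 80))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + 0.4 * x
            s = PairedSample(x, y)
            assert spearman_asymptotic_pvalue(s) == pytest.approx(
                stats.spearmanr(x, y).pvalue, rel=1e-6
            )

    def test_pvalue_uniformity_under_null(self, rng):
        n, reps = 40, 1500
        ps = np.empty(reps)
        for i in range(reps):
            s = PairedSample(rng.standard_normal(n), rng.standard_normal(n))
            ps[i] = pearson_t_pvalue(s)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3
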