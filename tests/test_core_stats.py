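"""Unit and property tests for the association statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concordx import (
    InvalidInputError,
    PairedSample,
    RobustThresholds,
    SigmoidKernel,
    UndefinedStatisticError,
    concordance_index,
    kci,
    pearson_r,
    rci_brute,
    rci_fast,
    spearman_rho,
)
from concordx.core_stats import _rci_counts_brute, _rci_counts_fast


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [3, 2, 1], 0.0),
        ([1, 2, 3, 4], [2, 1, 4, 3], 4 / 6),
        # tied x pair is non-concordant under strict inequalities
        ([1, 1, 2], [1, 2, 3], 2 / 3),
    ],
)
def test_concordance_index_examples(x, y, expected):
    assert concordance_index(PairedSample(x, y)) == pytest.approx(expected)


def test_concordance_index_half_tie_mode():
    # one tied pair out of three gets half credit
    s = PairedSample([1, 1, 2], [1, 2, 3])
    assert concordance_index(s, ties="half") == pytest.approx((2 + 0.5) / 3)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3], [1, 3, 2], 0.5),
    ],
)
def test_pearson_examples(x, y, expected):
    assert pearson_r(PairedSample(x, y)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [1, 4, 9], 1.0),  # rank-invariance under monotone map
        ([1, 2, 3], [1, 3, 2], 0.5),
        ([1, 2, 3], [3, 2, 1], -1.0),
    ],
)
def test_spearman_examples(x, y, expected):
    assert spearman_rho(PairedSample(x, y)) == pytest.approx(expected)


def test_pearson_zero_variance_raises():
    with pytest.raises(UndefinedStatisticError):
        pearson_r(PairedSample([1, 1, 1], [1, 2, 3]))


@pytest.mark.parametrize("bad", [([1], [1]), ([1, np.nan], [1, 2]),
                                 ([1, np.inf], [1, 2]), ([1, 2, 3], [1, 2])])
def test_invalid_samples_raise(bad):
    with pytest.raises(InvalidInputError):
        PairedSample(*bad)


class TestRobustCI:
    def test_margin_excludes_close_pair(self):
        s = PairedSample([0, 0.05, 1], [0, 1, 2])
        t = RobustThresholds(0.1, 0.0)
        assert rci_brute(s, t) == 1.0
        assert rci_fast(s, t) == 1.0

    def test_no_valid_pairs_raises(self):
        s = PairedSample([0, 0.01], [0, 1])
        t = RobustThresholds(0.1, 0.0)
        with pytest.raises(UndefinedStatisticError):
            rci_brute(s, t)
        with pytest.raises(UndefinedStatisticError):
            rci_fast(s, t)

    def test_zero_delta_reduces_to_ci(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        s = PairedSample(x, y)
        assert rci_brute(s) == pytest.approx(concordance_index(s))
        assert rci_fast(s) == pytest.approx(concordance_index(s))

    def test_boundary_equal_delta_is_invalid(self):
        # |dx| exactly equal to delta does not count as valid
        s = PairedSample([0.0, 1.0, 3.0], [0.0, 1.0, 2.0])
        t = RobustThresholds(1.0, 0.0)
        # pairs: dx = 1 (invalid), 3, 2 -> 2 valid concordant pairs
        assert _rci_counts_brute(s, t) == (2, 2)
        assert _rci_counts_fast(s, t) == (2, 2)

    def test_fast_matches_brute_randomized(self, rng):
        """Exact integer count agreement on random instances with mixed
        deltas and injected ties."""
        for _ in range(200):
            n = int(rng.integers(2, 150))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            if rng.random() < 0.3:
                x = np.round(x, 1)
                y = np.round(y, 1)
            t = RobustThresholds(
                float(rng.uniform(0, 2)) * (rng.random() < 0.8),
                float(rng.uniform(0, 2)) * (rng.random() < 0.8),
            )
            s = PairedSample(x, y)
            assert _rci_counts_fast(s, t) == _rci_counts_brute(s, t)

    def test_delta_monotonicity_of_valid_pairs(self, rng):
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        s = PairedSample(x, y)
        prev = None
        n_pairs = 80 * 79 // 2
        for d in [0.0, 0.2, 0.5, 1.0, 2.0]:
            conc, valid = _rci_counts_fast(s, RobustThresholds(d, d))
            assert conc <= valid <= n_pairs
            if prev is not None:
                assert valid <= prev
            prev = valid


class TestKernelizedCI:
    def test_constant_kernel_equals_ci(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        s = PairedSample(x, y)
        est = kci(s, lambda dx, dy: np.ones_like(dx))
        assert est == pytest.approx(concordance_index(s))

    def test_heaviside_kernel_equals_rci(self, rng):
        """rCI is kCI with a Heaviside step kernel at the thresholds."""
        for _ in range(20):
            n = int(rng.integers(5, 60))
            s = PairedSample(rng.standard_normal(n), rng.standard_normal(n))
            dx, dy = float(rng.uniform(0, 1.5)), float(rng.uniform(0, 1.5))
            heaviside = lambda adx, ady: ((adx > dx) & (ady > dy)).astype(float)
            try:
                expected = rci_brute(s, RobustThresholds(dx, dy))
            except UndefinedStatisticError:
                with pytest.raises(UndefinedStatisticError):
                    kci(s, heaviside)
                continue
            assert kci(s, heaviside) == pytest.approx(expected)

    def test_single_discordant_pair(self):
        s = PairedSample([1, 2], [2, 1])
        assert kci(s, SigmoidKernel(-5.0, 0.0)) == 0.0

    def test_zero_total_weight_raises(self):
        s = PairedSample([1, 2, 3], [1, 2, 3])
        with pytest.raises(UndefinedStatisticError):
            kci(s, lambda dx, dy: np.zeros_like(dx))


class TestSigmoidKernel:
    def test_weights_bounded_and_monotone(self):
        k = SigmoidKernel(-27.52, 0.0646)
        d = np.linspace(0, 1, 200)
        w = k.weight(d)
        assert ((w > 0) & (w < 1)).all()
        assert (np.diff(w) >= 0).all()
        assert k.weight(50.0) > 0.999
        assert k.is_monotone_increasing()

    def test_combine_rules(self):
        k_prod = SigmoidKernel(-5.0, 0.0, "product")
        k_min = SigmoidKernel(-5.0, 0.0, "min")
        k_x = SigmoidKernel(-5.0, 0.0, "x_only")
        dx = np.array([0.1, 1.0])
        dy = np.array([1.0, 0.1])
        wx, wy = k_prod.weight(dx), k_prod.weight(dy)
        assert np.allclose(k_prod.pair_weights(dx, dy), wx * wy)
        assert np.allclose(k_min.pair_weights(dx, dy), np.minimum(wx, wy))
        assert np.allclose(k_x.pair_weights(dx, dy), wx)


# hypothesis property tests -------------------------------------------------

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(finite_floats, finite_floats), min_size=2, max_size=40),
       st.randoms(use_true_random=False))
def test_statistics_invariant_to_pair_reordering(pairs, rnd):
    x, y = map(np.array, zip(*pairs))
    order = list(range(len(x)))
    rnd.shuffle(order)
    s1 = PairedSample(x, y)
    s2 = PairedSample(x[order], y[order])
    assert concordance_index(s1) == pytest.approx(concordance_index(s2))
    try:
        assert rci_fast(s1, RobustThresholds(0.5, 0.5)) == pytest.approx(
            rci_fast(s2, RobustThresholds(0.5, 0.5))
        )
    except UndefinedStatisticError:
        pass
    if np.ptp(x) > 0 and np.ptp(y) > 0:
        assert pearson_r(s1) == pytest.approx(pearson_r(s2))
        assert spearman_rho(s1) == pytest.approx(spearman_rho(s2))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_ci_reflection_and_monotone_invariance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 50))
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    s = PairedSample(x, y)
    ci = concordance_index(s)
    # reversing one axis flips concordance (tie-free)
    assert concordance_index(PairedSample(x, -y)) == pytest.approx(1.0 - ci)
    # strictly monotone transforms leave CI unchanged
    assert concordance_index(PairedSample(np.exp(x), y**3)) == pytest.approx(ci)
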