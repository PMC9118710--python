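"""Null distributions for the concordance index.

Under the null of no association every ordering of one vector against the
other is equally likely, so the null distribution of the CI is the
distribution of the number of inversions of a uniformly random permutation
(tie-free case) or of a uniformly random arrangement of a multiset (ties in
exactly one vector). Both are computed exactly, in arbitrary-precision
integer arithmetic, from the inversion generating polynomial

    Phi_n(q) = prod_{j=1}^{n} (1 + q + ... + q^{j-1})
             = prod_{j=1}^{n} (1 - q^j) / (1 - q),

and its multiset analogue, the q-multinomial coefficient. Each factor
(1 - q^s) in a denominator is removed by an exact power-series sweep rather
than polynomial division: every prefix of the product is itself a
q-binomial and hence a polynomial with nonnegative integer coefficients,
so no rounding ever occurs.

The module also provides the asymptotic tests whose tail behaviour the
exact null is meant to replace: the Noether/Pencina normal test for CI (and
its restriction to rCI valid pairs), the Pearson t test, and a t-based
approximation for Spearman's rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _st

from .core_stats import PairedSample, RobustThresholds, _as_sample
from .exceptions import (
    InvalidInputError,
    UndefinedStatisticError,
    UnsupportedTieStructureError,
)

__all__ = [
    "InversionDistribution",
    "MultisetSpec",
    "inversion_distribution_no_ties",
    "inversion_distribution_multiset",
    "exact_ci_pvalue",
    "noether_ci_pvalue",
    "pearson_t_pvalue",
    "spearman_asymptotic_pvalue",
]


# ---------------------------------------------------------------------------
# exact integer polynomial machinery
# ---------------------------------------------------------------------------

def _mul_one_minus_qs(c: list[int], s: int) -> list[int]:
    """Multiply coefficient list ``c`` by (1 - q^s)."""
    out = c + [0] * s
    for k in range(len(c)):
        out[k + s] -= c[k]
    return out


def _div_one_minus_qs(c: list[int], s: int) -> list[int]:
    """Exactly divide ``c`` by (1 - q^s); caller guarantees divisibility."""
    m = len(c) - s
    out = [0] * m
    for k in range(m):
        out[k] = c[k] + (out[k - s] if k >= s else 0)
    return out


def _q_multinomial_counts(multiplicities: Sequence[int]) -> list[int]:
    """Coefficients of the q-multinomial [alpha; a_1..a_n]_q.

    Built class by class: merging a class of size a into m existing elements
    multiplies the generating polynomial by the q-binomial
    [m+a choose a]_q = prod_{i=1..a} (1 - q^{m+i}) / (1 - q^i).
    """
    c = [1]
    m = 0
    for a in multiplicities:
        for i in range(1, a + 1):
            c = _mul_one_minus_qs(c, m + i)
            c = _div_one_minus_qs(c, i)
        m += a
    return c


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultisetSpec:
    """Tie-class multiplicities of the vector whose values are permuted."""

    multiplicities: tuple[int, ...]

    def __post_init__(self) -> None:
        mult = tuple(int(a) for a in self.multiplicities)
        if len(mult) == 0 or any(a < 1 for a in mult):
            raise InvalidInputError("multiplicities must be positive integers")
        object.__setattr__(self, "multiplicities", mult)

    @property
    def alpha_total(self) -> int:
        return sum(self.multiplicities)

    @staticmethod
    def from_values(values: np.ndarray) -> "MultisetSpec":
        _, counts = np.unique(np.asarray(values), return_counts=True)
        return MultisetSpec(tuple(int(c) for c in counts))


@dataclass(frozen=True)
class InversionDistribution:
    """Exact distribution of the inversion count of a random arrangement.

    ``counts[k]`` is the (exact integer) number of distinct arrangements
    with k inversions; ``total`` is their sum (n! for a set, the multinomial
    coefficient for a multiset). Counts are symmetric about ``k_max / 2``.
    """

    n_elements: int
    counts: tuple[int, ...]
    total: int

    @property
    def k_max(self) -> int:
        return len(self.counts) - 1

    def mean(self) -> float:
        return self.k_max / 2.0

    def pmf(self) -> np.ndarray:
        """Probability mass in IEEE double precision.

        The normalization is ``float(total)``; for the tie-free null this is
        N!, finite in double precision up to N = 170 and overflowing beyond.
        The exact-integer p-value methods below have no such limit.
        """
        norm = float(self.total)  # OverflowError when total > double max
        return np.array([float(c) for c in self.counts]) / norm

    def sf(self, k: int) -> float:
        """Exact P(inversions >= k), via integer arithmetic."""
        k = max(0, k)
        mass = sum(self.counts[k:])
        return float(Fraction(mass, self.total))

    def cdf(self, k: int) -> float:
        """Exact P(inversions <= k)."""
        if k < 0:
            return 0.0
        mass = sum(self.counts[: min(k, self.k_max) + 1])
        return float(Fraction(mass, self.total))

    def pvalue(self, k_observed: int, sided: Literal["two", "one"] = "two") -> float:
        """Exact p-value for an observed inversion count.

        Two-sided: total mass at least as far from k_max/2 as the
        observation (equivalently, by symmetry, twice the smaller tail
        capped at 1). One-sided: P(inversions <= observed), i.e. evidence
        for concordance (few inversions).
        """
        if not 0 <= k_observed <= self.k_max:
            raise InvalidInputError(
                f"inversion count {k_observed} outside [0, {self.k_max}]"
            )
        if sided == "one":
            return self.cdf(k_observed)
        if sided != "two":
            raise InvalidInputError(f"unknown sidedness {sided!r}")
        # distance from the midpoint in half-integer units
        dev = abs(2 * k_observed - self.k_max)
        mass = sum(c for k, c in enumerate(self.counts)
                   if abs(2 * k - self.k_max) >= dev)
        return float(Fraction(mass, self.total))


def inversion_distribution_no_ties(n: int) -> InversionDistribution:
    """Exact inversion-count distribution of a random permutation of n
    distinct elements (k ranges over 0 .. n(n-1)/2, total = n!)."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    counts = _q_multinomial_counts([1] * n)
    return InversionDistribution(n, tuple(counts), math.factorial(n))


def inversion_distribution_multiset(spec: MultisetSpec) -> InversionDistribution:
    """Exact inversion-count distribution of a random arrangement of a
    multiset; ties within a class contribute no inversions."""
    counts = _q_multinomial_counts(spec.multiplicities)
    total = math.factorial(spec.alpha_total)
    for a in spec.multiplicities:
        total //= math.factorial(a)
    return InversionDistribution(spec.alpha_total, tuple(counts), total)


# ---------------------------------------------------------------------------
# exact CI test
# ---------------------------------------------------------------------------

def _discordant_count(x: np.ndarray, y: np.ndarray) -> int:
    iu, ju = np.triu_indices(x.size, k=1)
    dx = np.sign(x[iu] - x[ju])
    dy = np.sign(y[iu] - y[ju])
    return int(np.count_nonzero(dx * dy < 0))


def exact_ci_pvalue(sample, sided: Literal["two", "one"] = "two") -> float:
    """Exact CI p-value from the inversion-count null.

    Tie-free data routes to the permutation (set) null; ties in exactly one
    vector route to the multiset null built from that vector's tie classes.
    Ties in both vectors have no known exact null and raise
    :class:`UnsupportedTieStructureError` (use permutation testing).
    """
    s = _as_sample(sample)
    ties_x = np.unique(s.x).size < s.n
    ties_y = np.unique(s.y).size < s.n
    if ties_x and ties_y:
        raise UnsupportedTieStructureError(
            "both vectors contain ties; the exact null is unknown - "
            "use a permutation test"
        )
    if ties_x or ties_y:
        tied = s.x if ties_x else s.y
        dist = inversion_distribution_multiset(MultisetSpec.from_values(tied))
    else:
        dist = inversion_distribution_no_ties(s.n)
    return dist.pvalue(_discordant_count(s.x, s.y), sided=sided)


# ---------------------------------------------------------------------------
# asymptotic tests
# ---------------------------------------------------------------------------

def _noether_z_from_counts(c_i: np.ndarray, d_i: np.ndarray, n: int):
    """Normal z of CI = 0.5 from per-element concordant/discordant counts.

    Variance estimator in the Noether/Pencina U-statistic style: with
    pc, pd the pairwise concordance/discordance probabilities and pcc, pdd,
    pcd their shared-element second moments, all estimated from the
    per-element counts,

        var(CI_hat) ~= 4 [pd^2 pcc - 2 pc pd pcd + pc^2 pdd] / (pc+pd)^4 / n

    (with the small-sample factor n(n-1)/(n-2)).
    """
    C = float(c_i.sum())
    D = float(d_i.sum())
    if C + D == 0:
        return None
    CC = float((c_i * (c_i - 1.0)).sum())
    DD = float((d_i * (d_i - 1.0)).sum())
    CD = float((c_i * d_i).sum())
    ci = C / (C + D)
    varp = 4.0 * ((D * D * CC - 2.0 * C * D * CD + C * C * DD) / (C + D) ** 4)
    varp *= n * (n - 1.0) / (n - 2.0)
    if not varp > 0.0:
        return None if ci != 0.5 else (0.5, np.inf)
    return ci, math.sqrt(varp / n)


def noether_ci_pvalue(sample, thresholds: RobustThresholds | None = None) -> float:
    """Asymptotic (Noether-type) two-sided p-value for CI = 0.5.

    With ``thresholds`` given, the statistic and the per-element counts are
    restricted to rCI-valid pairs. This test is provided to reproduce its
    small-sample p-value inflation; it is not a recommended default.
    """
    s = _as_sample(sample)
    if s.n < 3:
        raise InvalidInputError("Noether test needs n >= 3")
    dx = s.x[:, None] - s.x[None, :]
    dy = s.y[:, None] - s.y[None, :]
    conc = (np.sign(dx) * np.sign(dy)) > 0
    disc = (np.sign(dx) * np.sign(dy)) < 0
    if thresholds is not None:
        valid = (np.abs(dx) > thresholds.delta_x) & (np.abs(dy) > thresholds.delta_y)
        conc &= valid
        disc &= valid
    c_i = conc.sum(axis=1).astype(float)
    d_i = disc.sum(axis=1).astype(float)
    out = _noether_z_from_counts(c_i, d_i, s.n)
    if out is None:
        raise UndefinedStatisticError("degenerate Noether variance estimate")
    ci, se = out
    if not np.isfinite(se) or se == 0.0:
        if ci == 0.5:
            return 1.0
        raise UndefinedStatisticError("degenerate Noether variance estimate")
    z = (ci - 0.5) / se
    return float(2.0 * _st.norm.sf(abs(z)))


def pearson_t_pvalue(sample) -> float:
    """Two-sided p for Pearson r via t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    from .core_stats import pearson_r

    s = _as_sample(sample)
    if s.n < 3:
        raise InvalidInputError("t test needs n >= 3")
    r = pearson_r(s)
    if abs(r) >= 1.0:
        return 0.0  # limiting value of the t test as |r| -> 1
    t = r * math.sqrt((s.n - 2) / (1.0 - r * r))
    return float(2.0 * _st.t.sf(abs(t), df=s.n - 2))


def spearman_asymptotic_pvalue(sample) -> float:
    """Two-sided p for Spearman rho via the t approximation with n-2 df.

    A stand-in for the Edgeworth-series expansion sometimes used for rho;
    adequate away from tiny n, and labelled an approximation.
    """
    from scipy.stats import rankdata

    s = _as_sample(sample)
    if s.n < 3:
        raise InvalidInputError("t approximation needs n >= 3")
    return pearson_t_pvalue(PairedSample(rankdata(s.x), rankdata(s.y)))


# ---------------------------------------------------------------------------
# batch versions (used by the type-I error experiments)
# ---------------------------------------------------------------------------

def _pairwise_batch_counts(X: np.ndarray, Y: np.ndarray,
                           thresholds: RobustThresholds | None = None):
    """Per-element concordant/discordant counts for a (B, n) batch."""
    dx = X[:, :, None] - X[:, None, :]
    dy = Y[:, :, None] - Y[:, None, :]
    sprod = np.sign(dx) * np.sign(dy)
    conc = sprod > 0
    disc = sprod < 0
    if thresholds is not None:
        valid = (np.abs(dx) > thresholds.delta_x) & (np.abs(dy) > thresholds.delta_y)
        conc &= valid
        disc &= valid
    return conc.sum(axis=2).astype(np.float64), disc.sum(axis=2).astype(np.float64)


def noether_pvalues_batch(X: np.ndarray, Y: np.ndarray,
                          thresholds: RobustThresholds | None = None) -> np.ndarray:
    """Vectorized Noether-type p-values for a (B, n) batch of samples.

    Degenerate variance estimates yield NaN (callers count them).
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n = X.shape[1]
    c_i, d_i = _pairwise_batch_counts(X, Y, thresholds)
    C = c_i.sum(axis=1)
    D = d_i.sum(axis=1)
    CC = (c_i * (c_i - 1.0)).sum(axis=1)
    DD = (d_i * (d_i - 1.0)).sum(axis=1)
    CD = (c_i * d_i).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = C / (C + D)
        varp = 4.0 * ((D * D * CC - 2.0 * C * D * CD + C * C * DD) / (C + D) ** 4)
        varp *= n * (n - 1.0) / (n - 2.0)
        se = np.sqrt(varp / n)
        z = (ci - 0.5) / se
    p = 2.0 * _st.norm.sf(np.abs(z))
    p[~np.isfinite(z)] = np.nan
    return p


def discordant_counts_batch(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Discordant (inversion) pair counts for a (B, n) batch."""
    dx = np.sign(X[:, :, None] - X[:, None, :])
    dy = np.sign(Y[:, :, None] - Y[:, None, :])
    return ((dx * dy) < 0).sum(axis=(1, 2)) // 2
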