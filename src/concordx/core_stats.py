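"""Association statistics for paired measurements.

Implements five statistics on a :class:`PairedSample`:

* Pearson product-moment correlation,
* Spearman rank correlation (mid-ranks for ties),
* the concordance index (CI), the fraction of observation pairs ordered the
  same way by the two variables,
* the robust concordance index (rCI), the CI restricted to "valid" pairs whose
  differences exceed noise thresholds ``delta_x``/``delta_y`` in both
  coordinates, and
* the kernelized concordance index (kCI), where every pair is weighted by a
  kernel of the absolute differences; rCI is the Heaviside-kernel special case.

``rci_brute`` is the O(N^2) enumeration used as the correctness oracle for the
O(N log N) ``rci_fast``; both report exact integer pair counts and divide once
at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Union

import numpy as np

from .exceptions import InvalidInputError, UndefinedStatisticError

__all__ = [
    "PairedSample",
    "RobustThresholds",
    "SigmoidKernel",
    "concordance_index",
    "rci_brute",
    "rci_fast",
    "kci",
    "pearson_r",
    "spearman_rho",
]


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length vectors of finite paired measurements.

    The unit of every correlation computation in this package. ``n >= 2`` is
    required for any statistic (``n >= 3`` for p-values elsewhere).
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64).ravel()
        y = np.asarray(self.y, dtype=np.float64).ravel()
        if x.shape != y.shape:
            raise InvalidInputError(
                f"x and y must have equal length, got {x.size} and {y.size}"
            )
        if x.size < 2:
            raise InvalidInputError("need at least 2 paired observations")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise InvalidInputError("x and y must be finite (no NaN/Inf)")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    def permuted_y(self, order: np.ndarray) -> "PairedSample":
        """Sample with ``y`` rearranged by ``order`` (x held fixed)."""
        return PairedSample(self.x, self.y[np.asarray(order)])


@dataclass(frozen=True)
class RobustThresholds:
    """Noise thresholds for rCI: a pair is valid iff |dx| > delta_x and
    |dy| > delta_y (strict; boundary-equal pairs are invalid)."""

    delta_x: float = 0.0
    delta_y: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_x < 0 or self.delta_y < 0:
            raise InvalidInputError("thresholds must be nonnegative")


@dataclass(frozen=True)
class SigmoidKernel:
    """Sigmoid pair-weight kernel w(d) = 1 / (1 + exp(slope * d - offset)).

    With ``slope < 0`` the weight increases monotonically from w(0) toward 1
    as the absolute difference grows, i.e. pairs separated by much more than
    the noise scale count fully. ``combine_rule`` maps the two per-axis
    weights to one pair weight.
    """

    slope: float
    offset: float
    combine_rule: Literal["product", "min", "x_only"] = "product"

    def weight(self, delta: np.ndarray) -> np.ndarray:
        """Per-axis weight of an absolute difference, in (0, 1)."""
        z = self.slope * np.asarray(delta, dtype=np.float64) - self.offset
        # clip to avoid overflow in exp; weights saturate at 0/1 anyway
        return 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))

    def pair_weights(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        wx = self.weight(dx)
        if self.combine_rule == "x_only":
            return wx
        wy = self.weight(dy)
        if self.combine_rule == "product":
            return wx * wy
        if self.combine_rule == "min":
            return np.minimum(wx, wy)
        raise InvalidInputError(f"unknown combine_rule {self.combine_rule!r}")

    def is_monotone_increasing(self) -> bool:
        """True iff the weight is non-decreasing in the difference and
        tends to 1 as the difference grows large."""
        return self.slope < 0


KernelLike = Union[SigmoidKernel, Callable[[np.ndarray, np.ndarray], np.ndarray]]


def _as_sample(sample) -> PairedSample:
    if isinstance(sample, PairedSample):
        return sample
    x, y = sample
    return PairedSample(x, y)


def _upper_triangle_diffs(s: PairedSample):
    """Signed pairwise differences x_i - x_j, y_i - y_j for unordered i<j."""
    iu, ju = np.triu_indices(s.n, k=1)
    return s.x[iu] - s.x[ju], s.y[iu] - s.y[ju]


def concordance_index(sample, *, ties: Literal["strict", "half"] = "strict") -> float:
    """Concordance index: fraction of pairs ordered identically by x and y.

    CI = (2 / (N(N-1))) * sum_{i!=j} I(x_i > x_j, y_i > y_j). Strict
    inequalities: tied pairs contribute 0 to the numerator but stay in the
    denominator. ``ties="half"`` instead credits pairs tied in either
    coordinate with 1/2 (off by default).
    """
    s = _as_sample(sample)
    dx, dy = _upper_triangle_diffs(s)
    prod = np.sign(dx) * np.sign(dy)
    n_pairs = dx.size
    concordant = int(np.count_nonzero(prod > 0))
    if ties == "strict":
        return concordant / n_pairs
    if ties == "half":
        tied = int(np.count_nonzero((dx == 0) | (dy == 0)))
        return (concordant + 0.5 * tied) / n_pairs
    raise InvalidInputError(f"unknown ties mode {ties!r}")


def _rci_counts_brute(s: PairedSample, t: RobustThresholds) -> tuple[int, int]:
    dx, dy = _upper_triangle_diffs(s)
    valid = (np.abs(dx) > t.delta_x) & (np.abs(dy) > t.delta_y)
    concordant = valid & (np.sign(dx) * np.sign(dy) > 0)
    return int(np.count_nonzero(concordant)), int(np.count_nonzero(valid))


def rci_brute(sample, thresholds: RobustThresholds | None = None) -> float:
    """Robust CI by O(N^2) pair enumeration (the correctness oracle).

    rCI = #{concordant valid pairs} / #{valid pairs}, a pair being valid when
    its absolute difference strictly exceeds the threshold in both coordinates.
    Raises :class:`UndefinedStatisticError` when no pair is valid.
    """
    s = _as_sample(sample)
    t = thresholds or RobustThresholds()
    conc, valid = _rci_counts_brute(s, t)
    if valid == 0:
        raise UndefinedStatisticError(
            "rCI undefined: no pair exceeds both thresholds"
        )
    return conc / valid


class _Fenwick:
    """Binary indexed tree holding insertion counts over value ranks."""

    __slots__ = ("tree", "size")

    def __init__(self, size: int) -> None:
        self.size = size
        self.tree = [0] * (size + 1)

    def add(self, rank: int) -> None:
        i = rank + 1
        tree = self.tree
        while i <= self.size:
            tree[i] += 1
            i += i & (-i)

    def count_below(self, idx: int) -> int:
        """Number of inserted ranks < idx."""
        s = 0
        tree = self.tree
        while idx > 0:
            s += tree[idx]
            idx -= idx & (-idx)
        return s


def _rci_counts_fast(s: PairedSample, t: RobustThresholds) -> tuple[int, int]:
    """Exact concordant-valid and valid pair counts in O(N log N).

    Points are swept in x order; a Fenwick tree over y-ranks holds every
    earlier point whose x lies more than delta_x below the sweep point
    (the +/- delta_x sentinel boundary). For each sweep point, inserted
    points with y below y - delta_y are concordant-valid and those above
    y + delta_y are discordant-valid; every valid pair is one or the other
    because validity forces a strict ordering in both coordinates.
    """
    order = np.argsort(s.x, kind="stable")
    xs = s.x[order]
    ys = s.y[order]
    yu = np.unique(s.y)
    ranks = np.searchsorted(yu, ys)
    lo_idx = np.searchsorted(yu, ys - t.delta_y, side="left")
    hi_idx = np.searchsorted(yu, ys + t.delta_y, side="right")

    bit = _Fenwick(yu.size)
    conc = 0
    disc = 0
    inserted = 0
    ptr = 0
    n = s.n
    for j in range(n):
        # admit points strictly more than delta_x to the left (same
        # difference-then-compare arithmetic as the brute-force oracle)
        while ptr < j and xs[j] - xs[ptr] > t.delta_x:
            bit.add(int(ranks[ptr]))
            inserted += 1
            ptr += 1
        conc += bit.count_below(int(lo_idx[j]))
        disc += inserted - bit.count_below(int(hi_idx[j]))
    return conc, conc + disc


def rci_fast(sample, thresholds: RobustThresholds | None = None) -> float:
    """Robust CI in O(N log N); result identical to :func:`rci_brute`."""
    s = _as_sample(sample)
    t = thresholds or RobustThresholds()
    conc, valid = _rci_counts_fast(s, t)
    if valid == 0:
        raise UndefinedStatisticError(
            "rCI undefined: no pair exceeds both thresholds"
        )
    return conc / valid


def kci(sample, kernel: KernelLike) -> float:
    """Kernelized CI: concordance with kernel-weighted pairs, O(N^2).

    kCI = sum_pairs w(|dx|, |dy|) * I(concordant) / sum_pairs w(|dx|, |dy|).
    ``kernel`` is a :class:`SigmoidKernel` or any callable mapping the two
    absolute-difference arrays to nonnegative weights. Raises
    :class:`UndefinedStatisticError` when the total weight is zero.
    """
    s = _as_sample(sample)
    dx, dy = _upper_triangle_diffs(s)
    adx, ady = np.abs(dx), np.abs(dy)
    if isinstance(kernel, SigmoidKernel):
        w = kernel.pair_weights(adx, ady)
    else:
        w = np.asarray(kernel(adx, ady), dtype=np.float64)
    if w.shape != dx.shape or (w < 0).any():
        raise InvalidInputError("kernel must return nonnegative per-pair weights")
    total = float(w.sum())
    if total <= 0.0:
        raise UndefinedStatisticError("kCI undefined: total pair weight is zero")
    concordant = np.sign(dx) * np.sign(dy) > 0
    return float(w[concordant].sum() / total)


def pearson_r(sample) -> float:
    """Pearson product-moment correlation."""
    s = _as_sample(sample)
    if np.ptp(s.x) == 0 or np.ptp(s.y) == 0:
        raise UndefinedStatisticError("Pearson r undefined: zero variance")
    xc = s.x - s.x.mean()
    yc = s.y - s.y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def spearman_rho(sample) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    from scipy.stats import rankdata

    s = _as_sample(sample)
    rx = rankdata(s.x)
    ry = rankdata(s.y)
    return pearson_r(PairedSample(rx, ry))
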