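"""Permutation significance tests: fixed budget and adaptive early stopping.

The null of no association is simulated by permuting ``y`` against a fixed
``x`` and recomputing the statistic. Two-sided extremeness is measured as
distance from the statistic's null center (0.5 for the CI family, 0 for
Pearson/Spearman), and the p-value estimator is add-one smoothed,
p = (1 + b) / (1 + K), so it can never be zero.

The adaptive variant implements a QUICK-STOP style sequential test deciding
between "p <= alpha - d" and "p >= alpha + d" with a generalized
log-likelihood-ratio boundary: stopping when the best binomial explanation
on one side of the indifference region beats the other side by the log
error bound. Defaults follow the indifference d = 0.001 * alpha, error
probability e^-10 and a hard cap of 100 / alpha permutations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Literal, Optional, Union

import numpy as np

from .core_stats import (
    PairedSample,
    RobustThresholds,
    SigmoidKernel,
    _as_sample,
    concordance_index,
    kci,
    pearson_r,
    rci_fast,
    spearman_rho,
)
from .exceptions import InvalidInputError, UndefinedStatisticError

__all__ = [
    "Statistic",
    "make_statistic",
    "PermTestConfig",
    "PermTestResult",
    "fixed_permutation_test",
    "quickstop_permutation_test",
]


# ---------------------------------------------------------------------------
# statistics with vectorized permutation kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Statistic:
    """A test statistic with a scalar form and a batched permutation form.

    ``batch(x, Y)`` evaluates the statistic of ``x`` against every row of a
    (B, n) matrix of permuted y vectors, returning a length-B array with NaN
    where the statistic is undefined on that resample.
    """

    name: str
    null_center: float
    scalar: Callable[[PairedSample], float]
    batch: Callable[[np.ndarray, np.ndarray], np.ndarray]


def _pair_indices(n: int):
    return np.triu_indices(n, k=1)


def _pearson_batch(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    xss = float(xc @ xc)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = Yc @ xc
    den = np.sqrt((Yc * Yc).sum(axis=1) * xss)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r[den == 0.0] = np.nan
    return r


def _spearman_batch(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return _pearson_batch(rankdata(x), rankdata(Y, axis=1))


def _ci_batch_factory(n: int):
    iu, ju = _pair_indices(n)

    def _ci_batch(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
        sx = np.sign(x[iu] - x[ju])
        sy = np.sign(Y[:, iu] - Y[:, ju])
        conc = (sy * sx) > 0
        return conc.sum(axis=1) / iu.size

    return _ci_batch


def _rci_batch_factory(n: int, thresholds: RobustThresholds):
    iu, ju = _pair_indices(n)

    def _rci_batch(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
        dx = x[iu] - x[ju]
        vx = np.abs(dx) > thresholds.delta_x
        sx = np.sign(dx)
        dy = Y[:, iu] - Y[:, ju]
        valid = vx & (np.abs(dy) > thresholds.delta_y)
        conc = valid & ((np.sign(dy) * sx) > 0)
        nval = valid.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = conc.sum(axis=1) / nval
        out[nval == 0] = np.nan
        return out

    return _rci_batch


def _kci_batch_factory(n: int, kernel: SigmoidKernel):
    iu, ju = _pair_indices(n)

    def _kci_batch(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
        dx = x[iu] - x[ju]
        sx = np.sign(dx)
        dy = Y[:, iu] - Y[:, ju]
        w = kernel.pair_weights(np.abs(dx), np.abs(dy))
        conc = (np.sign(dy) * sx) > 0
        den = w.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (w * conc).sum(axis=1) / den
        out[den == 0.0] = np.nan
        return out

    return _kci_batch


def make_statistic(
    name: str,
    *,
    n: Optional[int] = None,
    thresholds: Optional[RobustThresholds] = None,
    kernel: Optional[SigmoidKernel] = None,
) -> Statistic:
    """Build a named statistic (pearson, spearman, ci, rci, kci).

    ``n`` sizes the pairwise index cache for the CI family; it is filled in
    lazily by the test drivers when omitted. rCI defaults to zero thresholds;
    kCI requires a kernel.
    """
    name = name.lower()
    if name == "pearson":
        return Statistic("pearson", 0.0, pearson_r, _pearson_batch)
    if name == "spearman":
        return Statistic("spearman", 0.0, spearman_rho, _spearman_batch)
    if name in ("ci", "rci", "kci") and n is None:
        raise InvalidInputError("CI-family statistics need n to build pair indices")
    if name == "ci":
        return Statistic("ci", 0.5, concordance_index, _ci_batch_factory(n))
    if name == "rci":
        t = thresholds or RobustThresholds()
        return Statistic(
            "rci", 0.5, lambda s: rci_fast(s, t), _rci_batch_factory(n, t)
        )
    if name == "kci":
        if kernel is None:
            raise InvalidInputError("kCI needs a kernel")
        return Statistic(
            "kci", 0.5, lambda s: kci(s, kernel), _kci_batch_factory(n, kernel)
        )
    raise InvalidInputError(f"unknown statistic {name!r}")


def resolve_statistic(statistic, sample: PairedSample, *,
                      thresholds=None, kernel=None) -> Statistic:
    """Accept a Statistic, a name, or a plain callable on PairedSample."""
    if isinstance(statistic, Statistic):
        return statistic
    if isinstance(statistic, str):
        return make_statistic(
            statistic, n=sample.n, thresholds=thresholds, kernel=kernel
        )
    if callable(statistic):
        fn = statistic

        def _batch(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
            out = np.empty(Y.shape[0])
            for i in range(Y.shape[0]):
                try:
                    out[i] = fn(PairedSample(x, Y[i]))
                except UndefinedStatisticError:
                    out[i] = np.nan
            return out

        return Statistic(getattr(fn, "__name__", "custom"), 0.0, fn, _batch)
    raise InvalidInputError(f"cannot interpret statistic {statistic!r}")


# ---------------------------------------------------------------------------
# configuration / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermTestConfig:
    """Adaptive permutation test configuration.

    Defaults: indifference d = 0.001 * alpha, log error bound 10 (error
    probability e^-10), cap of 100 / alpha permutations.
    """

    alpha: float
    statistic: Union[Statistic, str, Callable] = "pearson"
    indifference: Optional[float] = None
    error_log_bound: float = 10.0
    max_permutations: Optional[int] = None
    seed: Optional[int] = None
    block_size: int = 1024

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidInputError("alpha must be in (0, 1)")
        d = self.indifference if self.indifference is not None else 0.001 * self.alpha
        if not 0.0 < d < self.alpha:
            raise InvalidInputError("indifference must be in (0, alpha)")
        cap = (
            self.max_permutations
            if self.max_permutations is not None
            else int(math.ceil(100.0 / self.alpha))
        )
        if cap < 1:
            raise InvalidInputError("max_permutations must be >= 1")
        object.__setattr__(self, "indifference", d)
        object.__setattr__(self, "max_permutations", cap)


@dataclass(frozen=True)
class PermTestResult:
    p_estimate: float
    decision: Literal["reject", "accept", "indeterminate"]
    permutations_used: int
    observed_statistic: float
    exceedances: int
    degenerate_redraws: int = 0

    def rejected(self, alpha: Optional[float] = None) -> bool:
        """Null rejected: an explicit reject decision, or (when the
        sequential test was indeterminate / no alpha was configured) a
        smoothed p-estimate below alpha."""
        if self.decision == "reject":
            return True
        if self.decision == "accept":
            return False
        if alpha is None:
            raise InvalidInputError("indeterminate result needs an alpha")
        return self.p_estimate < alpha


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _batch_extremeness(stat: Statistic, x: np.ndarray, Y: np.ndarray):
    vals = stat.batch(x, Y)
    return np.abs(vals - stat.null_center), np.isnan(vals)


def fixed_permutation_test(
    sample,
    statistic="pearson",
    n_perm: int = 1000,
    seed: Optional[int] = None,
    *,
    alpha: Optional[float] = None,
    thresholds: Optional[RobustThresholds] = None,
    kernel: Optional[SigmoidKernel] = None,
    exhaustive: bool = False,
    block_size: int = 2048,
) -> PermTestResult:
    """Two-sided permutation test with a fixed permutation budget.

    Resamples on which the statistic is undefined (e.g. rCI with zero valid
    pairs) are redrawn and counted in ``degenerate_redraws``. With
    ``exhaustive=True`` (n <= 9) every non-identity ordering is enumerated
    once instead of sampled.
    """
    s = _as_sample(sample)
    if s.n < 3:
        raise InvalidInputError("permutation test needs n >= 3")
    stat = resolve_statistic(statistic, s, thresholds=thresholds, kernel=kernel)
    t_obs = stat.scalar(s)
    ext_obs = abs(t_obs - stat.null_center) - 1e-12

    if exhaustive:
        if s.n > 9:
            raise InvalidInputError("exhaustive enumeration limited to n <= 9")
        perms = np.array(
            [p for p in itertools.permutations(range(s.n))][1:], dtype=np.intp
        )
        ext, bad = _batch_extremeness(stat, s.x, s.y[perms])
        if bad.any():
            raise UndefinedStatisticError(
                "statistic undefined on an enumerated ordering"
            )
        b = int((ext >= ext_obs).sum())
        k = perms.shape[0]
        p = (1 + b) / (1 + k)
        decision = (
            "indeterminate" if alpha is None else ("reject" if p < alpha else "accept")
        )
        return PermTestResult(p, decision, k, t_obs, b, 0)

    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    b = 0
    k = 0
    redraws = 0
    while k < n_perm:
        m = min(block_size, n_perm - k)
        Y = rng.permuted(np.broadcast_to(s.y, (m, s.n)), axis=1)
        ext, bad = _batch_extremeness(stat, s.x, Y)
        nbad = int(bad.sum())
        redraws += nbad
        ok = ~bad
        b += int((ext[ok] >= ext_obs).sum())
        k += int(ok.sum())
    p = (1 + b) / (1 + k)
    decision = (
        "indeterminate" if alpha is None else ("reject" if p < alpha else "accept")
    )
    return PermTestResult(p, decision, k, t_obs, b, redraws)


def _binom_loglik(b: int, k: int, p: float) -> float:
    if p <= 0.0:
        return 0.0 if b == 0 else -math.inf
    if p >= 1.0:
        return 0.0 if b == k else -math.inf
    return b * math.log(p) + (k - b) * math.log1p(-p)


def quickstop_permutation_test(sample, config: PermTestConfig) -> PermTestResult:
    """Adaptive permutation test with QUICK-STOP style early stopping.

    Permutations are drawn in growing blocks; after each block the
    generalized log-likelihood ratio between the best binomial explanation
    with p <= alpha - d and the best with p >= alpha + d is compared against
    the log error bound. Crossing it upward decides "reject" (significant),
    downward "accept"; hitting the cap yields "indeterminate" with the
    smoothed empirical p.
    """
    s = _as_sample(sample)
    if s.n < 3:
        raise InvalidInputError("permutation test needs n >= 3")
    stat = resolve_statistic(config.statistic, s)
    t_obs = stat.scalar(s)
    ext_obs = abs(t_obs - stat.null_center) - 1e-12

    alpha = config.alpha
    d = config.indifference
    bound = config.error_log_bound
    cap = config.max_permutations
    rng = np.random.default_rng(config.seed)

    p_lo = alpha - d
    p_hi = alpha + d
    b = 0
    k = 0
    redraws = 0
    block = min(64, config.block_size)
    decision = "indeterminate"
    while k < cap:
        m = min(block, cap - k)
        Y = rng.permuted(np.broadcast_to(s.y, (m, s.n)), axis=1)
        ext, bad = _batch_extremeness(stat, s.x, Y)
        nbad = int(bad.sum())
        redraws += nbad
        ok = ~bad
        b += int((ext[ok] >= ext_obs).sum())
        k += int(ok.sum())
        if k > 0:
            phat = b / k
            ll_lo = _binom_loglik(b, k, min(phat, p_lo))
            ll_hi = _binom_loglik(b, k, max(phat, p_hi))
            if ll_lo - ll_hi >= bound:
                decision = "reject"
                break
            if ll_hi - ll_lo >= bound:
                decision = "accept"
                break
        block = min(block * 2, config.block_size)
    p = (1 + b) / (1 + k) if k else 1.0
    return PermTestResult(p, decision, k, t_obs, b, redraws)
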