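"""Calibrating rCI thresholds, kCI kernels and noise models from replicates.

Replicate measurements of the same condition give the distribution of the
absolute difference Delta under the null hypothesis that two measurements
share a true value. With S0 the replicate deltas and S deltas from arbitrary
measurement pairs, Bayes' rule bounds the posterior of the null above a
threshold t:

    P(h0 | Delta > t) <= P(Delta > t | h0) / P(Delta > t)
                       = (1 - eCDF_S0(t)) / (1 - eCDF_S(t)),

since P(h0) <= 1, and P(h1 | Delta > t) = 1 - P(h0 | Delta > t). Treating
"Delta > t" as a classifier for "truly different", the rCI threshold tau is
the t that maximizes the Matthews correlation coefficient of the induced
confusion matrix (joint cells: conditionals times the empirical masses of
Delta > t under S). The kCI kernel is a sigmoid fitted to the posterior
curve P(h1 | Delta > t): the weight of a pair estimates the probability
that its two measurements differ truly.

Replicate noise itself is summarized by a maximum-likelihood Laplace fit,
which matches the heavy-tailed differences seen between screening
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_stats import SigmoidKernel
from .exceptions import CalibrationError, DegenerateModelError, InvalidInputError

__all__ = [
    "ReplicateDeltas",
    "ThresholdDiagnostics",
    "LaplaceNoiseModel",
    "delta_posterior_curves",
    "select_rci_threshold",
    "fit_kci_kernel",
    "fit_laplace_noise",
]


@dataclass(frozen=True)
class ReplicateDeltas:
    """Absolute measurement differences: replicate pairs (null) and
    arbitrary measurement pairs (population mixture)."""

    null_deltas: np.ndarray
    population_deltas: np.ndarray

    def __post_init__(self) -> None:
        s0 = np.asarray(self.null_deltas, dtype=np.float64).ravel()
        s = np.asarray(self.population_deltas, dtype=np.float64).ravel()
        if s0.size == 0 or s.size == 0:
            raise InvalidInputError("both delta sets must be non-empty")
        if (s0 < 0).any() or (s < 0).any():
            raise InvalidInputError("deltas are absolute differences, >= 0")
        object.__setattr__(self, "null_deltas", s0)
        object.__setattr__(self, "population_deltas", s)

    @staticmethod
    def from_measurements(replicate_a, replicate_b, population) -> "ReplicateDeltas":
        """Build S0 from paired replicate vectors and S from all pairwise
        deltas of a measurement vector (the default population construction;
        any pair set may be supplied directly instead)."""
        a = np.asarray(replicate_a, dtype=np.float64)
        b = np.asarray(replicate_b, dtype=np.float64)
        pop = np.asarray(population, dtype=np.float64)
        iu, ju = np.triu_indices(pop.size, k=1)
        return ReplicateDeltas(np.abs(a - b), np.abs(pop[iu] - pop[ju]))


@dataclass(frozen=True)
class ThresholdDiagnostics:
    """Posterior and confusion-matrix curves over a threshold grid.

    Confusion cells are joint probabilities at each t (they sum to 1);
    ``mcc`` is their Matthews correlation coefficient, 0 where a marginal
    vanishes; ``tau`` is the MCC-maximizing threshold once selected.
    """

    threshold_grid: np.ndarray
    posterior_h1_given_gt: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    mcc: np.ndarray
    tau: Optional[float] = None
    truncated: bool = False


def delta_posterior_curves(
    deltas: ReplicateDeltas, grid: Optional[np.ndarray] = None
) -> ThresholdDiagnostics:
    """Posterior curves and joint confusion cells over a threshold grid.

    The default grid is 0 plus the sorted unique population deltas (the
    eCDFs are step functions, so candidate optima lie on data points).
    Grid points at or beyond max(S), where P(Delta > t) = 0, are dropped
    and the result flagged as truncated.
    """
    s0 = deltas.null_deltas
    s = deltas.population_deltas
    if grid is None:
        grid = np.unique(np.concatenate([[0.0], np.unique(s)]))
    grid = np.asarray(grid, dtype=np.float64)
    surv_s = 1.0 - np.searchsorted(np.sort(s), grid, side="right") / s.size
    keep = surv_s > 0.0
    truncated = not keep.all()
    grid = grid[keep]
    surv_s = surv_s[keep]
    surv_s0 = 1.0 - np.searchsorted(np.sort(s0), grid, side="right") / s0.size

    bound_gt = np.clip(surv_s0 / surv_s, 0.0, 1.0)  # P(h0 | Delta > t) bound
    post_h1_gt = 1.0 - bound_gt
    cdf_s = 1.0 - surv_s
    cdf_s0 = 1.0 - surv_s0
    with np.errstate(divide="ignore", invalid="ignore"):
        bound_le = np.clip(cdf_s0 / cdf_s, 0.0, 1.0)  # P(h0 | Delta <= t) bound
    bound_le[cdf_s == 0.0] = 1.0  # empty negative class: all mass null
    post_h1_le = 1.0 - bound_le

    tp = post_h1_gt * surv_s
    fp = bound_gt * surv_s
    fn = post_h1_le * cdf_s
    tn = bound_le * cdf_s

    mcc = mcc_from_cells(tp, fp, fn, tn)
    return ThresholdDiagnostics(
        grid, post_h1_gt, tp, fp, fn, tn, mcc, tau=None, truncated=truncated
    )


def mcc_from_cells(tp, fp, fn, tn):
    """Matthews correlation coefficient from (joint) confusion cells,
    defined as 0 wherever a marginal vanishes."""
    tp, fp, fn, tn = (np.asarray(v, dtype=np.float64) for v in (tp, fp, fn, tn))
    num = tp * tn - fp * fn
    den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = np.zeros_like(num)
    ok = den2 > 0.0
    mcc[ok] = num[ok] / np.sqrt(den2[ok])
    return mcc


def select_rci_threshold(diag: ThresholdDiagnostics) -> float:
    """Threshold tau maximizing the MCC (ties broken toward smaller t)."""
    den_ok = (
        ((diag.tp + diag.fp) > 0)
        & ((diag.tp + diag.fn) > 0)
        & ((diag.tn + diag.fp) > 0)
        & ((diag.tn + diag.fn) > 0)
    )
    if not den_ok.any():
        raise CalibrationError("all confusion matrices degenerate on the grid")
    idx = int(np.argmax(diag.mcc))  # argmax returns the first (smallest t) maximum
    return float(diag.threshold_grid[idx])


def fit_kci_kernel(
    diag: ThresholdDiagnostics, combine_rule: str = "product"
) -> SigmoidKernel:
    """Least-squares sigmoid fit 1/(1+exp(k t - c)) to P(h1 | Delta > t).

    The fitted kernel must be monotone non-decreasing in the difference
    (k < 0), tending to 1 for large differences; a decreasing or
    non-convergent fit raises :class:`CalibrationError`.
    """
    from scipy.optimize import curve_fit

    t = diag.threshold_grid
    p = diag.posterior_h1_given_gt
    if t.size < 5:
        raise CalibrationError("need at least 5 grid points to fit a kernel")

    def sigmoid(tt, k, c):
        return 1.0 / (1.0 + np.exp(np.clip(k * tt - c, -700.0, 700.0)))

    # initial slope from the curve's rise scale
    span = float(t.max() - t.min()) or 1.0
    try:
        popt, _ = curve_fit(sigmoid, t, p, p0=(-8.0 / span, 0.0), maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - scipy convergence failure
        raise CalibrationError(f"sigmoid fit did not converge: {err}") from err
    kernel = SigmoidKernel(float(popt[0]), float(popt[1]), combine_rule)
    if not kernel.is_monotone_increasing():
        raise CalibrationError(
            f"fitted kernel is not increasing in Delta (slope {kernel.slope:.4g})"
        )
    return kernel


@dataclass(frozen=True)
class LaplaceNoiseModel:
    """Laplace(mu, b) noise: density exp(-|x - mu| / b) / (2 b)."""

    location: float
    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise DegenerateModelError("Laplace scale must be positive")

    def rvs(self, size, rng: np.random.Generator) -> np.ndarray:
        return rng.laplace(self.location, self.scale, size=size)

    def nll(self, data) -> float:
        """Negative log-likelihood of a sample under the model."""
        d = np.asarray(data, dtype=np.float64)
        return float(
            d.size * np.log(2.0 * self.scale)
            + np.abs(d - self.location).sum() / self.scale
        )


def fit_laplace_noise(differences) -> LaplaceNoiseModel:
    """Maximum-likelihood Laplace fit to signed replicate differences:
    location = sample median, scale = mean |deviation| from the median."""
    d = np.asarray(differences, dtype=np.float64).ravel()
    if d.size < 2:
        raise InvalidInputError("need at least 2 observations")
    mu = float(np.median(d))
    b = float(np.abs(d - mu).mean())
    if b == 0.0:
        raise DegenerateModelError("all differences identical; zero Laplace scale")
    return LaplaceNoiseModel(mu, b)
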