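"""Synthetic-data generators for the simulation studies.

Covers the simulation designs used throughout the package: bivariate
standard normal data with a target correlation; bivariate beta data with
Beta(1.2, 4.5) marginals built from a Dirichlet (X = U1 + U3, Y = U2 + U3),
the fourth Dirichlet parameter solved so that corr(X, Y) hits a target;
additive Laplace noise truncated to [0, 1], mimicking replicate noise in
AAC-like measurements; and paired synthetic "studies" (drug x cell-line
sensitivity matrices corrupted by independent replicate noise) for the
cross-study recall benchmark.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd

from .calibration import LaplaceNoiseModel
from .core_stats import PairedSample
from .exceptions import InvalidInputError

__all__ = [
    "BivariateBetaSpec",
    "NoiseSpec",
    "sample_bivariate_normal",
    "sample_bivariate_normal_batch",
    "solve_beta_coupling",
    "sample_bivariate_beta",
    "sample_bivariate_beta_batch",
    "add_truncated_laplace_noise",
    "generate_study_pair",
]

#: default marginal shapes: skewed, bounded AAC-like sensitivities
DEFAULT_MARGINAL = (1.2, 4.5)

#: Dirichlet shapes are kept this far from 0; below it the family
#: degenerates (X -> Y almost surely) and gamma sampling loses accuracy
_SHAPE_EPS = 0.01


def _rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_bivariate_normal(
    n: int, r: float, seed: Union[int, np.random.Generator, None] = None
) -> PairedSample:
    """Bivariate standard normal sample with population correlation r."""
    if not -1.0 < r < 1.0:
        raise InvalidInputError("correlation must lie in (-1, 1)")
    if n < 2:
        raise InvalidInputError("n must be >= 2")
    rng = _rng(seed)
    z = rng.standard_normal((2, n))
    return PairedSample(z[0], r * z[0] + np.sqrt(1.0 - r * r) * z[1])


def sample_bivariate_normal_batch(
    n_samples: int, n: int, r: float,
    seed: Union[int, np.random.Generator, None] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(B, n) matrices of bivariate normal samples, one sample per row."""
    if not -1.0 < r < 1.0:
        raise InvalidInputError("correlation must lie in (-1, 1)")
    rng = _rng(seed)
    X = rng.standard_normal((n_samples, n))
    Z = rng.standard_normal((n_samples, n))
    return X, r * X + np.sqrt(1.0 - r * r) * Z


@dataclass(frozen=True)
class BivariateBetaSpec:
    """Dirichlet construction of a bivariate beta with fixed marginals.

    (U1, U2, U3, U4) ~ Dirichlet(dirichlet_params); X = U1 + U3 and
    Y = U2 + U3 both have Beta(marginal_shape_a, marginal_shape_b)
    marginals, which forces params[0] == params[1]; the third parameter
    controls corr(X, Y).
    """

    marginal_shape_a: float
    marginal_shape_b: float
    dirichlet_params: tuple[float, float, float, float]
    target_r: float

    def __post_init__(self) -> None:
        a1, a2, a3, a4 = self.dirichlet_params
        if min(a1, a2, a3, a4) <= 0:
            raise InvalidInputError("Dirichlet parameters must be positive")
        ma, mb = self.marginal_shape_a, self.marginal_shape_b
        if not (
            np.isclose(a1 + a3, ma) and np.isclose(a2 + a4, mb)
            and np.isclose(a2 + a3, ma) and np.isclose(a1 + a4, mb)
        ):
            raise InvalidInputError("parameters violate the marginal constraints")


def beta_coupling_correlation(alpha3: float, marginal_a: float, marginal_b: float) -> float:
    """Closed-form corr(X, Y) of the Dirichlet construction.

    From the Dirichlet moments (S = sum of all four parameters =
    marginal_a + marginal_b): corr = (alpha3 * S - marginal_a^2) /
    (marginal_a * marginal_b); linear and increasing in alpha3.
    """
    s = marginal_a + marginal_b
    return (alpha3 * s - marginal_a**2) / (marginal_a * marginal_b)


def achievable_correlation_range(
    marginal_a: float = DEFAULT_MARGINAL[0], marginal_b: float = DEFAULT_MARGINAL[1]
) -> tuple[float, float]:
    """Attainable corr(X, Y) for the family at these marginals (with
    Dirichlet shapes bounded away from zero)."""
    lo = max(_SHAPE_EPS, marginal_a - marginal_b + _SHAPE_EPS)
    hi = marginal_a - _SHAPE_EPS
    return (
        beta_coupling_correlation(lo, marginal_a, marginal_b),
        beta_coupling_correlation(hi, marginal_a, marginal_b),
    )


def solve_beta_coupling(
    target_r: float,
    marginal_a: float = DEFAULT_MARGINAL[0],
    marginal_b: float = DEFAULT_MARGINAL[1],
) -> BivariateBetaSpec:
    """Solve the free Dirichlet parameter for a target corr(X, Y).

    Three of the four parameters are fixed by the marginal shapes; the
    remaining one is root-solved with Brent's method on the closed-form
    moment expression (residual below 1e-8). Targets outside the family's
    attainable range raise with the range reported.
    """
    from scipy.optimize import brentq

    r_min, r_max = achievable_correlation_range(marginal_a, marginal_b)
    if not r_min <= target_r <= r_max:
        raise InvalidInputError(
            f"target correlation {target_r} outside the attainable range "
            f"[{r_min:.4f}, {r_max:.4f}] for Beta({marginal_a}, {marginal_b}) marginals"
        )
    lo = max(_SHAPE_EPS, marginal_a - marginal_b + _SHAPE_EPS)
    hi = marginal_a - _SHAPE_EPS
    a3 = brentq(
        lambda a: beta_coupling_correlation(a, marginal_a, marginal_b) - target_r,
        lo, hi, xtol=1e-14,
    )
    a1 = a2 = marginal_a - a3
    a4 = marginal_b - a1
    return BivariateBetaSpec(
        marginal_a, marginal_b, (float(a1), float(a2), float(a3), float(a4)), target_r
    )


def sample_bivariate_beta(
    spec: BivariateBetaSpec, n: int,
    seed: Union[int, np.random.Generator, None] = None,
) -> PairedSample:
    """Draw n pairs from the bivariate beta construction."""
    rng = _rng(seed)
    u = rng.dirichlet(spec.dirichlet_params, size=n)
    return PairedSample(u[:, 0] + u[:, 2], u[:, 1] + u[:, 2])


def sample_bivariate_beta_batch(
    spec: BivariateBetaSpec, n_samples: int, n: int,
    seed: Union[int, np.random.Generator, None] = None,
) -> tuple[np.ndarray, np.ndarray]:
    rng = _rng(seed)
    u = rng.dirichlet(spec.dirichlet_params, size=n_samples * n)
    X = (u[:, 0] + u[:, 2]).reshape(n_samples, n)
    Y = (u[:, 1] + u[:, 2]).reshape(n_samples, n)
    return X, Y


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Laplace noise clamped to a bounded measurement range.

    ``model=None`` is the noise-free limit (output equals input).
    """

    model: Optional[LaplaceNoiseModel]
    truncation: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.truncation
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise InvalidInputError("truncation bounds must be finite with low < high")


def add_truncated_laplace_noise(
    sample, noise: NoiseSpec, which: Literal["x", "y", "both"] = "y",
    seed: Union[int, np.random.Generator, None] = None,
) -> PairedSample:
    """Add i.i.d. Laplace noise to one (or both) vectors, then clamp to the
    truncation interval. Noise on a single vector matches the replicate
    corruption model; values pushed outside the range are truncated."""
    s = sample if isinstance(sample, PairedSample) else PairedSample(*sample)
    if which not in ("x", "y", "both"):
        raise InvalidInputError("which must be 'x', 'y' or 'both'")
    rng = _rng(seed)
    if noise.model is None:
        return s
    lo, hi = noise.truncation
    x, y = s.x, s.y
    if which in ("x", "both"):
        x = np.clip(x + noise.model.rvs(s.n, rng), lo, hi)
    if which in ("y", "both"):
        y = np.clip(y + noise.model.rvs(s.n, rng), lo, hi)
    return PairedSample(x, y)


def generate_study_pair(
    n_drugs: int, n_lines: int, noise: NoiseSpec,
    seed: Union[int, np.random.Generator, None] = None,
    marginal_a: float = DEFAULT_MARGINAL[0],
    marginal_b: float = DEFAULT_MARGINAL[1],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two synthetic replicate "studies" sharing a latent sensitivity matrix.

    A latent drugs x cell-lines matrix of Beta-distributed sensitivities is
    corrupted twice, independently, by truncated Laplace noise -- a stand-in
    for two real screening studies assaying the same drugs and lines.
    Returns two labelled DataFrames (rows = drugs, columns = cell lines).
    """
    if n_drugs < 2 or n_lines < 2:
        raise InvalidInputError("need at least 2 drugs and 2 cell lines")
    rng = _rng(seed)
    latent = rng.beta(marginal_a, marginal_b, size=(n_drugs, n_lines))
    lo, hi = noise.truncation
    mdl = noise.model

    def corrupt() -> np.ndarray:
        if mdl is None:
            return latent.copy()
        return np.clip(latent + mdl.rvs(latent.shape, rng), lo, hi)

    drugs = [f"drug{i:04d}" for i in range(n_drugs)]
    lines = [f"line{i:04d}" for i in range(n_lines)]
    return (
        pd.DataFrame(corrupt(), index=drugs, columns=lines),
        pd.DataFrame(corrupt(), index=drugs, columns=lines),
    )
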