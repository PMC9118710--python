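"""Type-I-error and power experiments for the association statistics.

Drivers for two families of experiments:

* ``type1_error_experiment`` draws independent (null) samples, computes the
  asymptotic p-values (Noether-type CI/rCI, Pearson t, Spearman
  t-approximation) and the exact inversion-count CI p-value, and tabulates
  the observed P(p < alpha) against the nominal rate — the small-sample
  inflation of the asymptotic CI tests.

* ``run_power_experiment`` / ``delta_sweep`` simulate correlated data
  (bivariate normal or bivariate beta, optionally with truncated Laplace
  noise) and measure the rejection rate of the adaptive permutation test
  for each statistic at each effect size (the population Pearson
  correlation).

Default scale is desk-sized (1,000 replicates); pass larger ``reps`` for
survey-grade runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .core_stats import PairedSample, RobustThresholds, SigmoidKernel
from .exact_null import (
    discordant_counts_batch,
    inversion_distribution_no_ties,
    noether_pvalues_batch,
)
from .exceptions import ConcordxError, InvalidInputError
from .perm_test import PermTestConfig, make_statistic, quickstop_permutation_test
from .simgen import (
    NoiseSpec,
    add_truncated_laplace_noise,
    sample_bivariate_beta_batch,
    sample_bivariate_normal_batch,
    solve_beta_coupling,
)

__all__ = [
    "PowerExperimentSpec",
    "run_power_experiment",
    "pearson_level_set",
    "delta_sweep",
    "type1_error_experiment",
    "exact_ci_pvalues_from_counts",
]


@dataclass(frozen=True)
class PowerExperimentSpec:
    """One power experiment: distribution, effect sizes, test settings.

    ``distribution``: "bvnorm", "bvbeta" or "bvbeta+noise" (noise from
    ``noise``, added to y after sampling; the effect size is the pre-noise
    population correlation). ``rci_delta`` defaults to 1.0 on bvnorm data
    (units of the unit marginal sd) and 0.1 on beta data (AAC units).
    """

    distribution: str = "bvnorm"
    effect_sizes: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    n: int = 100
    reps: int = 1000
    alpha: float = 0.001
    statistics: tuple[str, ...] = ("pearson", "spearman", "ci", "rci")
    rci_delta: Optional[RobustThresholds] = None
    kci_kernel: Optional[SigmoidKernel] = None
    noise: Optional[NoiseSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distribution not in ("bvnorm", "bvbeta", "bvbeta+noise"):
            raise InvalidInputError(f"unknown distribution {self.distribution!r}")
        if self.reps < 1 or not 0 < self.alpha < 1:
            raise InvalidInputError("reps >= 1 and alpha in (0,1) required")
        if any(not 0.0 <= r < 1.0 for r in self.effect_sizes):
            raise InvalidInputError("effect sizes must lie in [0, 1)")
        if self.distribution == "bvbeta+noise" and self.noise is None:
            raise InvalidInputError("bvbeta+noise requires a NoiseSpec")
        if self.rci_delta is None:
            default = 1.0 if self.distribution == "bvnorm" else 0.1
            object.__setattr__(self, "rci_delta", RobustThresholds(default, default))


def _default_statistics(spec: PowerExperimentSpec) -> dict:
    stats = {}
    for name in spec.statistics:
        stats[name] = make_statistic(
            name, n=spec.n, thresholds=spec.rci_delta, kernel=spec.kci_kernel
        )
    return stats


def _sampler(spec: PowerExperimentSpec, r: float):
    if spec.distribution == "bvnorm":
        def draw(rng: np.random.Generator) -> PairedSample:
            X, Y = sample_bivariate_normal_batch(1, spec.n, r, rng)
            return PairedSample(X[0], Y[0])
        return draw
    beta = solve_beta_coupling(r)

    def draw(rng: np.random.Generator) -> PairedSample:
        X, Y = sample_bivariate_beta_batch(beta, 1, spec.n, rng)
        s = PairedSample(X[0], Y[0])
        if spec.distribution == "bvbeta+noise":
            s = add_truncated_laplace_noise(s, spec.noise, which="y", seed=rng)
        return s

    return draw


def run_power_experiment(spec: PowerExperimentSpec) -> pd.DataFrame:
    """Empirical power of the adaptive permutation test per statistic.

    For each replicate one sample is drawn and every statistic is tested on
    it at ``spec.alpha`` with QUICK-STOP early stopping. Returns a tidy
    frame with rejection counts, power and binomial standard errors; the
    ``errors`` column counts replicates on which a statistic was undefined
    on the observed sample (never silently dropped).
    """
    rng_root = np.random.SeedSequence(spec.seed)
    stats = _default_statistics(spec)
    rows = []
    for r in spec.effect_sizes:
        ss_draw, ss_test = np.random.SeedSequence(
            entropy=rng_root.entropy, spawn_key=(int(r * 1e6),)
        ).spawn(2)
        draw_rng = np.random.default_rng(ss_draw)
        test_seeds = ss_test.generate_state(spec.reps * len(stats))
        rejections = {name: 0 for name in stats}
        errors = {name: 0 for name in stats}
        perms_used = {name: 0 for name in stats}
        draw = _sampler(spec, r)
        for i in range(spec.reps):
            sample = draw(draw_rng)
            for j, (name, stat) in enumerate(stats.items()):
                cfg = PermTestConfig(
                    alpha=spec.alpha,
                    statistic=stat,
                    seed=int(test_seeds[i * len(stats) + j] % (2**31)),
                )
                try:
                    res = quickstop_permutation_test(sample, cfg)
                except ConcordxError:
                    errors[name] += 1
                    continue
                perms_used[name] += res.permutations_used
                if res.rejected(spec.alpha):
                    rejections[name] += 1
        for name in stats:
            n_ok = spec.reps - errors[name]
            power = rejections[name] / n_ok if n_ok else np.nan
            se = (
                np.sqrt(power * (1.0 - power) / n_ok) if n_ok else np.nan
            )
            rows.append(
                dict(
                    distribution=spec.distribution,
                    r=r,
                    n=spec.n,
                    statistic=name,
                    reps=spec.reps,
                    rejections=rejections[name],
                    power=power,
                    se=se,
                    errors=errors[name],
                    mean_permutations=perms_used[name] / max(n_ok, 1),
                )
            )
    return pd.DataFrame(rows)


def pearson_level_set(n: int, power: float = 0.5, alpha: float = 0.001) -> float:
    """Effect size holding the theoretical Pearson power constant.

    Fisher-z approximation: r = tanh((z_{1-alpha/2} + z_power) / sqrt(n-3)),
    monotone decreasing in n.
    """
    if n < 4:
        raise InvalidInputError("level set needs n >= 4")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise InvalidInputError("power and alpha must lie in (0, 1)")
    z = _st.norm.ppf(1.0 - alpha / 2.0) + _st.norm.ppf(power)
    if z <= 0:
        raise InvalidInputError("infeasible power/alpha combination")
    return float(np.tanh(z / np.sqrt(n - 3)))


def delta_sweep(
    spec: PowerExperimentSpec, delta_grid: Sequence[float]
) -> pd.DataFrame:
    """rCI power across a grid of thresholds (bvnorm: delta in sd units).

    Adds a percent-of-maximum normalization over the grid so the optimal
    threshold region is comparable across effect sizes.
    """
    frames = []
    for delta in delta_grid:
        sub = PowerExperimentSpec(
            distribution=spec.distribution,
            effect_sizes=spec.effect_sizes,
            n=spec.n,
            reps=spec.reps,
            alpha=spec.alpha,
            statistics=("rci",),
            rci_delta=RobustThresholds(float(delta), float(delta)),
            kci_kernel=spec.kci_kernel,
            noise=spec.noise,
            seed=spec.seed,
        )
        df = run_power_experiment(sub)
        df["delta"] = float(delta)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["percent_of_max"] = out.groupby("r")["power"].transform(
        lambda p: 100.0 * p / p.max() if p.max() > 0 else np.nan
    )
    return out


def exact_ci_pvalues_from_counts(n: int) -> np.ndarray:
    """Two-sided exact CI p-value indexed by inversion (discordant) count.

    Precomputed once from the tie-free inversion null of size n; used to
    turn batched inversion counts into exact p-values by lookup.
    """
    dist = inversion_distribution_no_ties(n)
    K = dist.k_max
    csum = [0]
    for c in dist.counts:
        csum.append(csum[-1] + c)
    total = dist.total
    p = np.empty(K + 1)
    for k in range(K + 1):
        lo = min(k, K - k)
        mass = 2 * csum[lo + 1]
        if 2 * lo == K:  # even K_max midpoint: both tails are everything
            mass -= dist.counts[lo]
        p[k] = min(1.0, mass / total)
    return p


def type1_error_experiment(
    n: int = 100,
    reps: int = 200_000,
    distribution: str = "bvnorm",
    alpha_grid: Sequence[float] = (1e-2, 1e-3, 1e-4),
    seed: int = 0,
    rci_delta: Optional[RobustThresholds] = None,
    batch: int = 2000,
    tests: Sequence[str] = (
        "noether_ci", "noether_rci", "pearson_t", "spearman_approx", "exact_ci",
    ),
) -> pd.DataFrame:
    """Observed tail mass of null p-values for each analytic test.

    Independent samples (r = 0) are drawn from the chosen distribution;
    asymptotic p-values (Noether CI, Noether rCI, Pearson t, Spearman
    t-approx) and the exact inversion-count CI p-value are computed for
    each, and the fraction with p < alpha is tabulated against alpha. An
    observed/expected ratio of 1 is calibrated; the asymptotic CI-family
    tests inflate it at small alpha.
    """
    if rci_delta is None:
        rci_delta = RobustThresholds(1.0, 1.0) if distribution == "bvnorm" \
            else RobustThresholds(0.1, 0.1)
    rng = np.random.default_rng(seed)
    beta = solve_beta_coupling(0.0) if distribution != "bvnorm" else None
    tests = tuple(tests)
    p_exact_lookup = (
        exact_ci_pvalues_from_counts(n) if "exact_ci" in tests else None
    )

    counts = {}
    degenerate = {}

    def _tally(name: str, p: np.ndarray) -> None:
        good = np.isfinite(p)
        degenerate[name] = degenerate.get(name, 0) + int((~good).sum())
        c = counts.setdefault(name, np.zeros(len(alpha_grid), dtype=np.int64))
        for i, a in enumerate(alpha_grid):
            c[i] += int((p[good] < a).sum())

    done = 0
    while done < reps:
        m = min(batch, reps - done)
        if distribution == "bvnorm":
            X, Y = sample_bivariate_normal_batch(m, n, 0.0, rng)
        else:
            X, Y = sample_bivariate_beta_batch(beta, m, n, rng)
        if "noether_ci" in tests:
            _tally("noether_ci", noether_pvalues_batch(X, Y))
        if "noether_rci" in tests:
            _tally("noether_rci", noether_pvalues_batch(X, Y, rci_delta))
        if "pearson_t" in tests:
            r = _pearson_batch_rows(X, Y)
            _tally("pearson_t", _t_pvalues(r, n))
        if "spearman_approx" in tests:
            from scipy.stats import rankdata

            rr = _pearson_batch_rows(rankdata(X, axis=1), rankdata(Y, axis=1))
            _tally("spearman_approx", _t_pvalues(rr, n))
        if "exact_ci" in tests:
            inv = discordant_counts_batch(X, Y)
            _tally("exact_ci", p_exact_lookup[inv])
        done += m

    rows = []
    for name, c in counts.items():
        for i, a in enumerate(alpha_grid):
            obs = c[i] / reps
            rows.append(
                dict(
                    test=name, alpha=a, observed=obs, expected=a,
                    ratio=obs / a, reps=reps,
                    degenerate=degenerate.get(name, 0),
                )
            )
    return pd.DataFrame(rows)


def _pearson_batch_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = (Xc * Yc).sum(axis=1)
    den = np.sqrt((Xc * Xc).sum(axis=1) * (Yc * Yc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def _t_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * _st.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return p
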