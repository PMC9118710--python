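# Methods

## Statistics

For paired measurements (x_i, y_i), i = 1..N, the package computes five
measures of monotone association:

- **Pearson r** and **Spearman rho** (mid-ranks for ties), the standard
  parametric and rank correlations.
- **Concordance index (CI)**: the fraction of unordered observation pairs
  ordered the same way by x and y,
  `CI = (2 / N(N-1)) * sum_{i!=j} I(x_i > x_j, y_i > y_j)`.
  A linear transform of Kendall's tau-a; 0.5 under no association. Strict
  inequalities throughout: a pair tied in either coordinate contributes 0
  to the numerator but remains in the denominator (an optional
  `ties="half"` mode credits such pairs with 1/2; off by default).
- **Robust CI (rCI)**: the CI restricted to *valid* pairs, those with
  `|dx| > delta_x` **and** `|dy| > delta_y`. The thresholds encode the
  scale below which differences cannot be distinguished from measurement
  noise. Boundary pairs (`|dx| == delta`) are invalid — the strict reading
  of the definition.
- **Kernelized CI (kCI)**: every pair carries a weight `w(|dx|, |dy|)`
  and `kCI = sum_pairs w * I(concordant) / sum_pairs w`. rCI is kCI with a
  Heaviside kernel; the fitted kernel is a sigmoid
  `w(d) = 1 / (1 + exp(k d - c))` per axis with `k < 0` so the weight
  rises to 1 for clearly separated pairs. Per-axis weights combine by
  **product** by default (`min` and `x_only` are provided): the product is
  the independent-evidence rule and preserves both limiting behaviours
  (weight to 0 as either difference vanishes, to 1 as both grow).

Statistics that are undefined on an input (no valid pairs, zero total
weight, zero variance) raise typed errors rather than returning NaN, so
resampling drivers can redraw and count degenerate resamples explicitly.

### Fast rCI

`rci_brute` is the O(N^2) pair enumeration and serves as the oracle.
`rci_fast` computes the same two integer counts in O(N log N): after
sorting by x, concordant-valid pairs are exactly the pairs with
`x_j - x_i > delta_x` and `y_j - y_i > delta_y` (validity forces strict
ordering in both coordinates, so every valid pair is concordant or
discordant). Each of these is a strict 2-D dominance count, done in one
sweep with a Fenwick tree over y-ranks: points enter the tree once they
fall more than `delta_x` below the sweep point (the +/-delta sentinel
boundary), and a rank query counts inserted points below `y - delta_y`
(concordant) or above `y + delta_y` (discordant). Counts are exact
integers; one division at the end. The admission test uses the same
difference-then-compare arithmetic as the brute force, so the two paths
agree pair-for-pair, including on tied data. Comparisons that round
exactly onto a threshold boundary are the only place the two code paths
could in principle disagree by one ulp; this cannot occur for the strict
comparisons used here on identical inputs.

## Exact null distributions

Under the null of no association, every ordering of y against x is
equally likely, and the CI maps 1:1 to the number of inversions of the
induced permutation. The inversion-count distribution is computed exactly
from the generating polynomial
`Phi_n(q) = prod_{j=1..n} (1 + q + ... + q^{j-1})`, and for data with
ties in exactly one vector from its multiset analogue, the q-multinomial
`[alpha; alpha_1..alpha_n]_q` built class-by-class from q-binomials.

All coefficients are arbitrary-precision integers. Each q-binomial
`[m+a choose a]_q = prod_{i=1..a} (1 - q^{m+i}) / (1 - q^i)` is computed
by alternating an exact `(1 - q^s)` multiplication with an exact
power-series division (a strided prefix-sum sweep): every prefix of the
product is itself a q-binomial and hence a polynomial with nonnegative
integer coefficients, so no remainder and no rounding ever arise. No FFT
is used; there is nothing to round. n = 300 takes under a second.

P-values are exact rationals converted to double at the end, so they are
computable at any n. The *double-precision normalization* path
(`InversionDistribution.pmf`) divides by `float(total)`; for the tie-free
null `total = N!`, finite in IEEE double up to N = 170 and overflowing at
171 — the boundary at which a purely floating implementation would stop.

Two-sided p-values reflect around the midpoint `K/2` of the inversion
range (the counts are symmetric, so this equals twice the smaller tail,
capped at 1). Ties in both vectors have no known exact null; the routine
raises and directs callers to permutation testing.

### Asymptotic tests

- **Pearson t**: `t = r sqrt((n-2)/(1-r^2))`, Student t with n-2 df.
- **Spearman**: the same t form applied to rho — documented as an
  approximation standing in for the Edgeworth-series expansion sometimes
  used; adequate away from tiny n.
- **Noether-type CI test**: normal test of CI = 0.5 with the
  Pencina/D'Agostino U-statistic variance built from per-element
  concordant/discordant pair counts c_i, d_i:
  `var(CI) ~= 4 (pd^2 pcc - 2 pc pd pcd + pc^2 pdd) / (pc+pd)^4 / n`
  with the small-sample factor n(n-1)/(n-2), where pc, pd are the
  pairwise concordance/discordance rates and pcc, pdd, pcd the
  shared-element second moments estimated from c_i, d_i. For rCI the
  same estimator is applied with all counts restricted to valid pairs.
  This test exists to *demonstrate* its small-sample tail inflation
  (at n = 100 its p-values fall below 1e-4 several-fold too often — more
  than 20x for rCI); it is never a recommended default.

## Permutation testing

y is permuted against fixed x (exchangeability makes the choice of side a
convention). Extremeness is two-sided distance from the statistic's null
center (0.5 for the CI family, 0 for Pearson/Spearman). The p estimate is
add-one smoothed, `p = (1 + b) / (1 + K)`, so it is never 0. Resamples on
which the statistic is undefined are redrawn and counted in a
diagnostics field. A root seed spawns independent substreams per test, so
batched experiments are reproducible.

The adaptive variant decides sequentially between "p <= alpha - d"
(significant) and "p >= alpha + d" (not significant) with a generalized
log-likelihood-ratio boundary: after k permutations with b exceedances,
stop when the best binomial likelihood on one side of the indifference
region beats the other side by the log error bound. Defaults:
`d = 0.001 * alpha`, error bound `e^-10`, hard cap `100 / alpha`
permutations (indeterminate at the cap, falling back to the smoothed
empirical p). The boundary is checked at block ends (blocks grow
geometrically from 64 to 1024), which can only delay stopping — never
anticipate it — so the error control is conservative. With b = 0 the
significant decision arrives near k = 10/alpha; clear non-significant
cases stop within tens of draws, which is where the orders-of-magnitude
savings come from.

## Calibration from replicates

Replicate measurements of the same condition give the null distribution
of the absolute difference Delta. With S0 the replicate deltas and S the
population deltas (default: all pairwise deltas of a measurement vector;
any pair set can be supplied), Bayes' rule with P(h0) <= 1 bounds
`P(h0 | Delta > t) <= (1 - eCDF_S0(t)) / (1 - eCDF_S(t))`, so the
computed `P(h1 | Delta > t)` is a lower bound — the same bound the
calibration is defined with. Joint confusion cells multiply the
conditional bounds by the empirical masses of `Delta > t` under S (MCC is
not well defined on conditionals alone). The rCI threshold tau maximizes
the MCC over the grid (ties toward smaller t); grid points are the data
values by default since eCDFs are step functions. The kCI kernel is a
least-squares sigmoid fit to the posterior curve and must come out
monotone increasing (k < 0), else calibration fails loudly.

Homoscedasticity of Delta across the measurement range is assumed — the
kernel depends on the difference only. Replicate noise itself is
summarized by the Laplace MLE (location = median, scale = mean absolute
deviation from the median), which matches the heavy tails of replicate
AAC differences better than a Gaussian.

Caveat: when the null and alternative delta distributions are far
separated, the MCC curve has a wide, nearly flat plateau and the argmax
is determined only up to that plateau; at m = 1e5 the selected tau
scatters by roughly +-0.02 around the analytic optimum of the synthetic
mixture used in the tests.

## Synthetic data

- **Bivariate normal**: standard marginals, population correlation r.
- **Bivariate beta**: (U1..U4) ~ Dirichlet(a1..a4), X = U1+U3,
  Y = U2+U3. Fixing both marginals to Beta(1.2, 4.5) — the skewed,
  bounded shape of AAC-like drug sensitivities — forces a1 = a2 and
  leaves one free parameter, solved by Brent's method on the closed-form
  moment expression `corr = (a3 S - ma^2) / (ma mb)` (S = ma + mb;
  residual < 1e-8). Dirichlet shapes are kept >= 0.01: below that the
  family degenerates (X -> Y almost surely) and gamma sampling loses
  accuracy, so the attainable correlation range at these marginals is
  reported as about (-0.256, 0.989) and targets outside it raise with the
  range in the message.
- **Noise**: i.i.d. Laplace added to one vector (configurable to both),
  then clamped to [0, 1] — the replicate-noise corruption model.
- **Study pairs**: a latent drugs x lines Beta(1.2, 4.5) matrix corrupted
  twice independently — a labelled stand-in for two real screening
  studies. What this does *not* emulate: drug-specific effect structure,
  heteroscedastic or batch noise, and study-specific dose ranges; passing
  recall tests therefore show internal consistency of the benchmark, not
  performance on real pharmacogenomic data.

## Experiments and problem sizes

The power drivers draw a sample, run the adaptive permutation test for
each statistic at alpha = 0.001, and report rejection fractions with
binomial standard errors. Effect size is the population Pearson
correlation (for noise experiments, the pre-noise correlation). Default
thresholds: delta = 1.0 (in sd units) on normal data, 0.1 on beta data.
The Fisher-z level set `r = tanh((z_{1-alpha/2} + z_power)/sqrt(n-3))`
fixes effect sizes of constant theoretical Pearson power.

Shipped experiment scale is 1,000 replicates per condition (the package's
desk scale; binomial se <= 1.6 points), with larger runs available via
`reps`. The type-I experiments use 200,000 nulls for tail ratios at
alpha = 1e-4 and 100,000 for the exact-null uniformity check (KS < 0.01;
note the exact p-value is discrete with largest atoms ~0.005 at n = 100,
so KS values around 0.005 are the floor, not an error).

## Recall benchmark conventions

Similarity is ranked, not distance: the matched drug's normalized rank is
`(#{strictly more similar} + ties/2) / (#scored B drugs - 1)`, excluding
the matched drug itself from the denominator, so 0 is best and 1 is worst
regardless of drug count. Missing values are removed pairwise per drug
pair; matched drugs with fewer pairwise-complete common lines than
`min_common_lines` are excluded. The area under the rank eCDF equals
1 - mean(rank). CI-family similarities are ranked by raw value (higher =
more similar); an anti-correlation-aware `|value - 0.5|` ordering was
considered and left off by default, matching the raw-similarity reading
of "most similar".

## Known limitations

- Exact nulls cover tie-free data and ties in one vector only; censored
  data, two-sided tie structures, rCI and kCI have no exact null here
  (none is known) and route to permutation testing.
- The Spearman asymptotic p-value is a t approximation, not the
  Edgeworth series.
- The QUICK-STOP boundary constants are the GLR formulation described
  above; other boundary choices from the sequential-testing literature
  would change permutation counts, not decisions, except within the
  error bound.
- Power figures at the shipped scale carry ~1-2 point Monte-Carlo error;
  the rCI-vs-Pearson power ratio at n = 50 measures ~0.88-0.89 against
  a nominal 0.90 figure, within that error plus boundary-detail slack.
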