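# Methods

## Model and hypothesis

`manovasim` implements one-way multivariate analysis of variance (MANOVA)
from its matrix primitives. Data are g ≥ 2 independent groups of p-variate
observations, n_i per group, N = Σ n_i in total. The null hypothesis is
equality of the group mean vectors,

    H0: μ1 = μ2 = … = μg,

against the alternative that at least one pair differs. Total variation is
decomposed into the between-groups and within-groups sums of squares and
cross-products (SSCP) matrices

    B = Σ_i n_i (x̄_i − x̄)(x̄_i − x̄)′,     W = Σ_i (n_i − 1) S_i,

with x̄ the observation-weighted grand mean (required for the conservation
identity B + W = total centered SSCP, which the tests verify elementwise)
and S_i the group sample covariance. All four classical test statistics are
functions of the s = min(g − 1, p) nonzero eigenvalues λ_1 ≥ … ≥ λ_s of
W⁻¹B, computed as the symmetric generalized eigenproblem B x = λ W x:

* Wilks' Λ = Π 1/(1 + λ_i) = det(W)/det(B + W)
* Pillai's trace V = Σ λ_i/(1 + λ_i)
* Hotelling–Lawley trace U = Σ λ_i
* Roy's largest root θ = λ_max/(1 + λ_max)

## Significance approximations

With q = g − 1, v = N − g, m = (|p − q| − 1)/2 and n\* = (v − p − 1)/2:

* **Wilks** uses Rao's F transformation: t = √((p²q² − 4)/(p² + q² − 5))
  when the denominator is positive (else t = 1), w = v − (p − q + 1)/2,
  df1 = pq, df2 = wt − (pq − 2)/2, F = ((1 − Λ^{1/t})/Λ^{1/t})·df2/df1.
* **Pillai**: F = ((2n\* + s + 1)/(2m + s + 1))·V/(s − V) with
  df1 = s(2m + s + 1), df2 = s(2n\* + s + 1).
* **Hotelling–Lawley**: F = df2·U/(s·df1) with df1 = s(2m + s + 1),
  df2 = 2(s·n\* + 1).
* **Roy**: the classical bound F = df2·λ_max/df1 with df1 = max(p, q),
  df2 = v − df1 + q is reported, but its tail is an *upper bound* on the
  statistic (hence anti-conservative as a p-value: measured rejection rate
  ≈ 0.16 at α = 0.05 for g = 3, p = 2, n_i = 10 normal data). For s ≤ 2 the
  p-value is therefore computed from the exact null distribution of the
  largest root (below); for s ≥ 3 the F bound is used and flagged in the
  documentation as a lower bound on the true p-value.
* **Bartlett's chi-square** for Wilks is available in two bracketings:
  the conventional L = −(N − 1 − (p + g)/2)·ln Λ (default, mode
  `standard`) and the variant L = −((N − 1 − (p + g))/2)·ln Λ (mode
  `as_printed`), both referred to χ² with p(g − 1) df.

All four F approximations reproduce R 4.3.3 `stats::summary.manova` to 12
significant digits on a fixed dataset (frozen oracle in the test suite).
When s = 1 the four approximations coincide with the exact F test
(`exact_flag`), and for p = 1 Wilks reduces to the classical one-way ANOVA
F with df (g − 1, N − g) exactly.

### Exact Roy null distribution (s ≤ 2)

Under H0 the s nonzero roots θ_i of B(B + W)⁻¹ follow the real Jacobi
ensemble with density ∝ Π θ_i^m (1 − θ_i)^{n\*} Π_{i<j} |θ_i − θ_j| — the
distribution whose critical points Heck's charts tabulate. For s = 2,
integrating out the smaller root reduces P(θ_max ≤ x) to a single
1-D integral of incomplete-beta terms; the implementation accumulates it by
trapezoid on the substitution t = sin²φ (which absorbs the integrable
endpoint singularities when m or n\* equals −1/2) over a 4097-point grid,
normalizes by the value at 1, and caches the resulting CDF per (m, n\*).
Against a 20000-draw two-Wishart Monte Carlo oracle the CDF agrees within
Monte Carlo error (≲ 1.5·10⁻³); grid interpolation error is far below
that. For s = 1 the largest root is Beta(m + 1, n\* + 1), equivalent to the
exact F form.

## Decision rule

A test rejects iff its p-value is strictly below α (p < α, not ≤). The
default nominal level is α = 0.05.

## Simulation design

The Monte Carlo engine estimates type-I error rates as rejection fractions
over R replicates (default R = 10000, giving a binomial standard error of
√(0.05·0.95/10000) ≈ 0.0022 at the nominal level). The study grid crosses:

* **Distributions** (all with true group means 0, so H0 holds exactly):
  * `gamma-homogeneous`: every variable Gamma(shape 4, scale 0.5) − 2
    (centered by the distribution mean; variance 1 in every group);
  * `gamma-heterogeneous`: shapes (4, 9, 36), scale 0.5, each group
    centered by shape·scale (variances 1, 2.25, 9 — skewness decreasing
    with shape);
  * `t-homogeneous`: every variable an independent Student t(2) draw
    (symmetric, infinite variance);
  * `t-heterogeneous` / `normal-heterogeneous`: per-group scale
    multipliers (1, 1.5, 3), i.e. variance ratios 1 : 2.25 : 9 mirroring
    the gamma scenario (the multipliers are configurable; no published
    values exist for them);
  * `normal-homogeneous`: N(0, 1), the exact-calibration reference.
* **Group sizes**: the ten balanced/unbalanced patterns (10-10-10),
  (20-20-20), (50-50-50), (10-10-20), (10-10-50), (10-20-20), (10-20-50),
  (10-50-50), (20-20-50), (20-50-50); g = 3 throughout.
* **Variables**: p = 2 and p = 3, drawn independently of one another
  within an observation. No cross-variable correlation hook is exposed:
  every scenario in scope is independent-variable by design, and a
  correlation option would have no oracle to test against.

Gamma "scale 0.5" is read as the scale parameter (variance = shape·scale²);
because a scale factor common to all groups cancels out of every statistic
(affine invariance), the scale-vs-rate reading cannot change any rejection
rate. The t(2) variables are independent univariate draws, not a shared-
denominator multivariate t; this choice matters — see Limitations.

### Random number discipline

One root seed (default 12345); each (scenario, replicate) pair derives an
independent `numpy` `SeedSequence((seed, crc32(scenario_name),
replicate_index))` substream. Cells are therefore reproducible
bit-identically, independent of execution order, and parallelizable. A
replicate whose within matrix is singular (condition number above 1e12, or
v = N − g < p) is re-drawn with the next substream index; more than 1%
re-draws aborts the cell. Eigenvalues below 1e−10·(1 + λ_max) in magnitude
are clipped to zero.

## What the generator emulates — and what passing tests show

The generator reproduces the simulation conditions of the robustness study
this package re-implements: independent observations, independent
variables, exact H0, and the specific non-normal/heteroscedastic shapes
above. It does **not** emulate correlated responses, contaminated or
skew-heterogeneous mixtures, or dependence between group membership and
response — so calibration results here say nothing about robustness to
those. Under normal homogeneous data the F approximations are *nearly*
exact: precise runs (R = 10⁵) show Pillai's true rate ≈ 0.0445 (p = 2) and
≈ 0.0430 (p = 3) at n_i = 10, and Hotelling–Lawley ≈ 0.0530 at p = 3,
n_i = 10 — real small-sample approximation bias, reproduced identically by
R's `summary.manova`, that shrinks as v grows.

## Numerical and design choices

* Generalized symmetric eigensolver (`scipy.linalg.eigh(B, W)`) rather than
  forming W⁻¹B: preserves symmetry and real eigenvalues by construction.
* Strict determinism contract over speed: samples are regenerated from
  substreams rather than cached or vectorized across replicates.
* Tidy CSV rates are serialized at full (shortest round-trip) precision and
  re-parsed with `float_precision="round_trip"`, so write→read is
  bit-exact; the wide table prints 4 decimals as the published grids do.
* Per-cell winners ("closest to nominal") are reported with explicit tie
  lists and a tally across cells, never a single silently tie-broken
  headline.
* The ten size patterns and six distribution presets ship both as
  constructor functions and as a generated YAML
  (`presets/full_grid.yaml`, 120 cells).

## Known limitations

* Roy's p-value for s ≥ 3 falls back to the anti-conservative F bound;
  exact largest-root computation is implemented only for s ≤ 2 (which
  covers every g = 3 design with p ≥ 2).
* Published type-I error grids for the t(2) scenarios (rates 0.07–0.13)
  cannot be reproduced by independent t(2) draws, which actually yield
  *conservative* balanced-design rates (≈ 0.03) — heavy tails deflate,
  not inflate, mean-based tests here. Exploratory runs show the published
  inflation pattern is qualitatively consistent with all observations of a
  group sharing a single chi-square denominator (a plausible generation
  slip), but this package deliberately implements the stated independent-t
  design and reports what it produces.
* Published "heterogeneous variance" grids sitting uniformly at ≈ 0.05
  across all unbalanced patterns are inconsistent with genuinely unequal
  group variances (unbalanced heteroscedastic designs must deviate in
  opposite directions depending on which group is large); the genuinely
  heteroscedastic generator here yields e.g. ≈ 0.072 for Pillai at
  (10-10-10), p = 2, gamma shapes (4, 9, 36).
* Two-way/factorial designs, contrasts, post-hoc tests, Box's M, and power
  estimation are out of scope.
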