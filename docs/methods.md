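# Methods

## The estimation problem

A usability study with `n` participants yields an observed discovery
matrix `d` (binary, `n × j`): column `l` records which participants hit
problem `l`, and only problems hit at least once appear. `d` is a
truncated view of a complete matrix `x` with `m ≥ j` columns. The target
of inference is `m`, the total number of problems affecting the device,
from which `m − j` — the problems still to find — follows.

## Margin-based comparators

The classical methods model each column sum as Binomial(`n`, `p`) with a
single detection probability `p` and deduce `m` from the discovery
proportion `j/m = 1 − (1−p)^n`:

* naive: `p̂ = x··/(n·j)` where `x··` is the total detection count.
  Upward-biased because the unobserved zero columns are excluded from
  the denominator, hence `m` is under-estimated.
* normalized: rescales `p̂` from its attainable range `[1/n, 1]` to
  `[0, 1]`. Degenerates (`m̂ = ∞`) when every problem is a singleton;
  implemented but excluded from the comparison harness for that reason.
* Good–Turing: divides `p̂` by `1 + GT`, with `GT` the share of
  singleton problems among all detection events. The double-deflation
  variant averages the GT estimate with `(p̂ − 1/n)(1 − 1/n)`. The
  deflation formula is taken with the same `GT` quantity in both places
  where a discount appears; no separately-defined adjustment exists.
* zero-truncated binomial: maximum likelihood for `p` under
  Binomial(`n`, `p`) conditioned on `k > 0`, a bounded 1-D search on
  `p ∈ (1e−9, 1 − 1e−9)` (the zero-truncated binomial likelihood is
  unimodal in `p` for fixed data).

## LNBzt

Real margins are overdispersed, so the LNBzt model gives each problem
its own `p_l` with `logit(p_l) ~ N(μ, σ)`. The margin pmf is the
logit-normal binomial

    P(X = k) = C(n,k) · E_p[ p^k (1−p)^{n−k} ] = C(n,k) · Q(k),

zero-truncated for fitting, and `m̂ = j / (1 − P(X=0))` with `P(X=0)`
from the *non*-truncated pmf. The 2-D likelihood in `(μ, log σ)` can be
flat or multimodal for small `j`; five deterministic starting points
(`σ₀ ∈ {0.25, 0.5, 1, 2, 4}`, `μ₀` at the naive logit) are tried and the
best converged optimum kept. Total failure is reported as a flag — in
simulation studies, failures are data. Estimates above a guard threshold
(default 500) are flagged `discarded_extreme`: they arise from near-flat
fits on singleton-heavy margins and are removed (and counted) by the
evaluation harness.

## The matrix-based model

The contribution of the package: the likelihood of the observed,
unlabeled-column matrix itself. Since a complete matrix with
column-exchangeable probability law truncates to `d` in exactly

    H(d, m) = m! / ((m−j)! · j₁! ⋯ j_r!)

ways (an anagram count over the r distinct column patterns plus the
null column repeated m − j times), and each of those complete matrices
is equally probable,

    P(d | θ, m) = H(d, m) · ∏ₗ Q(k_l) · Q(0)^{m−j}.

`log H` grows with `m` while `(m−j)·log Q(0)` falls — the trade-off that
makes `m` estimable from the matrix alone, where maximizing the padded
complete-matrix likelihood would collapse to the biased `m̂ = j`. The
multinomial constant `1/(j₁!⋯j_r!)` cancels in every posterior over `m`
but is retained so that exhaustive-enumeration normalization tests are
exact, not merely proportional.

## Priors and posterior over m

`μ ~ N(0, A)` with `A = 10⁸` (variance), effectively flat over the
likelihood's support; `σ² ~ inv-χ²_ν` with `ν = 1`, i.e. density
`∝ s^{−3/2} e^{−1/(2s)}` — written here as the unscaled form, which for
`ν = 1` coincides with the scale-1 scaled-inverse-chi-square; `m`
uniform on `{1..M}`. `M` defaults to `max(200, 5j)`: large enough that
the posterior tail is negligible in realistic studies, small enough to
keep the per-matrix cost low; a warning is raised whenever more than 1%
of posterior mass sits at `M`. The evidence is

    P(d | m) = ∫∫ P(d | μ, σ, m) P(μ) P(σ) dμ dσ,

and Bayes' theorem gives `P(m | d)`. The point estimate is the posterior
**median** (mode and mean are also reported): the posterior over a
discrete, right-skewed support is summarized more robustly by its median
than by the mode or mean. The credible interval is the smallest
equal-tailed [2.5%, 97.5%] quantile interval of the discrete posterior
(not highest-density — equal tails are what the coverage harness
evaluates).

### Grid backend (default, deterministic)

The integrand in `(μ, x = log σ)` is a smooth near-Gaussian bump: the
likelihood localizes both parameters even under the flat `μ` prior.
For each of ~7 anchor values of `m` (geometric between `j` and `M`) the
conditional mode and Laplace SDs are found; the union of mode ± 10 SD
boxes defines one shared grid, with trapezoid spacing at 0.35 of the
narrowest anchor SD (spectrally accurate for Gaussian-like integrands).
At fixed `(μ, σ)` the only `m`-dependence of the log likelihood is
`log H(d,m) + (m−j) log Q(0)`, so the shared grid serves every
`m ∈ {j..M}` at essentially the cost of one integral. A coarse pass over
64 values of `m` locates the window with non-negligible evidence
(within 35 log units of the peak); only that window is integrated
exactly, with grid nodes more than 45 log units below the local peak
dropped. Both cutoffs leave relative errors below ~1e−13, far inside
the 1e−10 normalization tolerance asserted for the posterior. The grid
backend is bit-reproducible for fixed settings.

### MC backend (stochastic cross-check)

Random-walk Metropolis on `(μ, log σ)` (proposal scaled by the Laplace
SDs), followed by the Meng–Wong iterative bridge estimator of the
marginal likelihood with a moment-matched Gaussian bridge proposal;
seed-reproducible. The latent per-problem probabilities are never
sampled: they integrate out exactly through `Q(·)`, so the sampler
works in 2-D regardless of `m`. The two backends must agree within 0.1
log units; measured agreement on test instances is below 0.02. When a
posterior is requested with the mc backend and the backends diverge
beyond tolerance, a warning is attached and the grid result is used.

## Numerical quadrature for Q(k)

`Q(k) = E_p[p^k (1−p)^{n−k}]` is computed by Gauss–Hermite quadrature in
the mixing Gaussian's own variable. Convergence slows as `σ` grows,
because the binomial kernel becomes much narrower than the mixing
distribution: 320 nodes give absolute pmf errors below ~1e−7 up to
`σ = 2.5` at `n = 50` (beyond, the order is raised to 640). Inside the
Bayes grid a fixed 160-node rule is used: grid nodes with `σ` large
enough to need more carry negligible posterior mass. `σ < 1e−8` falls
back to the exact binomial. The zero-truncated pmf sums to 1 within
1e−8 across the parameter range exercised by the tests.

## Simulator

One replicate draws `p_l = logistic(z_l)`, `z_l ~ N(μ, σ)` for
`l = 1..m`, fills an `n × m` Bernoulli matrix, and truncates zero
columns. Replicates use counter-based substreams keyed by
`(seed, setting-hash, replicate index)` (`numpy` `SeedSequence`
spawn keys), so any replicate regenerates independently of the others —
order-independent and parallelizable. All-zero draws yield a flagged
degenerate matrix; estimators skip it and the harness counts it (its
probability is negligible at the studied settings but not zero).

What the generator emulates: heterogeneous problem detectability with
independent problems and exchangeable participants. What it does not:
participant-level effects (some testers systematically find more),
correlated problems, severity structure, or learning across sessions.
Passing tests therefore certify the estimators under the heterogeneity
model's own assumptions, not under arbitrary real-world discovery
processes.

## Evaluation harness

The full design crosses `m ∈ {20, 50, 100}`, `n ∈ {15, 20, 30, 40, 50}`,
`μ ∈ {logit(0.1), logit(0.2)}`, `σ ∈ {0.5, 1, 2}` — 90 settings, with
`S = 2 × 10⁴` replicates each at full scale. Per setting and method the
harness reports the mean error `(m̂ − m)/m` (in %), the 95% fluctuation
interval (2.5/97.5% quantiles of `m̂`), `RMSE(m) = √(mean (m − m̂_i)²)`
as a % of `m`, and coverage. Coverage intervals are parametric-bootstrap
percentile intervals refit from each method's own fitted model —
`(m̂, p̂, n)` for the homogeneous methods (the heterogeneity tuple is
meaningless for a scalar-p̂ fit, an interpretation this package makes
explicit), `(m̂, μ̂, σ̂, n)` for LNBzt (B = 1000 at full scale) — and the
posterior credible interval directly for the matrix-based method. For
LNBzt, coverage is tallied both excluding guard-discarded replicates
(primary) and including them, since either convention is defensible.
`m̂` stays continuous in all summaries; rounding is display-only.

Desk-scale defaults are `S = 200` and `B = 200`; the test suite and the
acceptance script use `S = 200–300`, sized so the whole suite runs in
minutes on one CPU while keeping binomial standard errors on coverage
near 2–3 percentage points. The headline coverage quantity recomputed by
`scripts/acceptance.py` uses the design's hardest cell (`m = 100`,
`n = 15`, `μ = logit(0.1)`, `σ = 0.5`) with `S = 300` and `M = 500`.

## Known limitations

* Only logit-normal and homogeneous column models are implemented; the
  permutation-count likelihood itself is valid for any column-
  exchangeable law, and alternative mixing distributions (beta, gamma)
  would slot into `Q(k)` directly.
* No joint (reversible-jump) sampling over `m`; the evidence is computed
  per candidate `m`, which is exactly what the grid backend makes cheap.
* The mc backend is a cross-check, not a performance path: posteriors
  over large `M` with it cost one chain per `m`.
* Quadrature accuracy degrades for `σ` well above 4 at large `n`
  (detection probabilities then concentrate near 0 and 1); this is
  outside the studied range and flagged here rather than engineered
  around.
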