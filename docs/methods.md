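# Methods

## The junction exponent and its case taxonomy

A fork is reduced to the ratios a = d1/d0 and b = d2/d0 and the
exponent equation f(k) = a^k + b^k = 1. The solver's behaviour is
decided entirely by where the ratios sit relative to 1:

- **standard** (a, b < 1): f is strictly decreasing with f(0) = 2 and
  f → 0 as k → ∞, so a unique root k > 0 exists. It is bracketed by
  geometric growth from k = 0 and solved with Brent's method at
  xtol 1e−12; every reported root carries a residual certificate
  |a^k + b^k − 1| ≤ 1e−9.
- **both wider** (a, b > 1): the mirrored argument gives a unique root
  k < 0.
- **equal children** (a = b): closed form k = ln 2 / ln(d0/d1), no
  iteration.
- **mixed** (a > 1 > b): no real root exists — for k > 0 the wide
  child alone pushes f above 1, for k < 0 the narrow child does, and
  f(0) = 2. Measured surveys nevertheless report finite exponents for
  such forks, so the package defines k as the minimiser of f,
  available in closed form as k* = ln(ln(1/b)/ln a)/ln(a/b), and flags
  it `argmin` rather than `exact_root`. The magnitude of k* explodes
  as both ratios approach 1, which reproduces the empirical pattern of
  asymmetric forks with exponents below −100 or above 70.
- **degenerate** (a child exactly equals the parent) and
  **uncomputable** (|k| beyond the `k_bound` cap, default 1e6) carry
  no exponent; they are counted and excluded from k statistics.

The solver sees only ratios, so it is scale invariant, and the child
order never matters. Everything here is deterministic — `solve` output
is bit-identical across runs.

## Dataset variants

Four processed datasets mirror the standard cleaning choices for this
kind of survey: V1 keeps every computable exponent; V2 removes mixed
(asymmetric) forks; V3 additionally truncates k to [−14, 20]; V4 keeps
only standard forks and truncates above at 20. Deviation from the
Murray optimum is |k − 3|, recomputed from the possibly-truncated k.
Every drop and truncation is counted in a provenance record, and the
variants nest by row identity (V4 ⊆ V2 ⊆ V1).

Scatter summaries stable-sort by d0 (or angle) and average consecutive
groups of 20; a trailing remainder shorter than a bin is dropped from
the binned series only — all model fits run on the unbinned rows.
Large-diameter summaries (d0 ≥ threshold, or the top-n widest forks)
report mean k with a seeded 10,000-resample percentile bootstrap CI; a
t-interval is available as an option since the appropriate interval
for such means is a judgment call.

## Change-point model

Deviation is regressed on parent diameter with a two-segment Gaussian
model joined at the change point τ:

    y ~ Normal(mu(x), sigma^2)
    mu(x) = alpha + beta1*x                      x <= tau
    mu(x) = alpha + beta1*tau + beta2*(x - tau)  x >  tau

A disjoint variant (free second intercept) is exposed via
`joined=False`. Priors: alpha ~ N(0, (10*sd(y) + |mean(y)|)^2), slopes
~ N(0, (10*sd(y)/sd(x))^2), sigma half-normal with scale 5*sd(y), and
τ uniform between the 5th and 95th percentiles of x (`tau_trim=0.05`).

The trimmed τ support deserves a note. With a fixed-scale coefficient
prior, the marginal likelihood of a change-point model rewards τ
values that leave one segment nearly empty: the unidentified slope
then costs no Occam penalty, and under pure noise the τ posterior
piles up at the data edges instead of staying near its uniform prior.
Requiring both segments to retain 5% of the observations removes most
of this boundary artifact (pure-noise τ posterior is uniform to
KS ≈ 0.15) while leaving any interior threshold untouched, and is the
natural identification requirement anyway: a slope estimated from a
handful of extreme points is not a segment.

Sampling is seeded Metropolis-within-Gibbs, 3 chains × 9000 iterations
by default with the first third of each chain discarded as warm-up:

- τ: Metropolis with the linear coefficients integrated out
  analytically (their normal prior is conjugate, so the collapsed
  likelihood needs one 3×3 Cholesky); proposals are a 90/10 mixture of
  an adapted random walk and uniform independence jumps over the τ
  support, so multimodal posteriors still mix.
- (alpha, beta1, beta2): exact draw from the conditional multivariate
  normal.
- log sigma: adapted random-walk Metropolis with the Jacobian term.

The Gaussian likelihood depends on the data only through second-order
sums of the piecewise design, all O(1) functions of prefix sums over
the x-sorted data, so a full default fit on a few thousand rows takes
seconds. Input rows are canonically ordered (lexicographic in (x, y))
before sampling, making results invariant to row permutations at a
fixed seed. Proposal scales adapt toward 44% acceptance during
warm-up only. Convergence is certified when split-R-hat < 1.05 for
all parameters (arviz); otherwise the fit is returned flagged, never
silently. Credible intervals are central 95% posterior percentiles.

Degenerate inputs are rejected up front: fewer than 40 observations,
fewer than 10 distinct x values, or constant x.

## Synthetic venation generator

The generator emulates the statistical structure of a large wing-vein
survey, with every parameter fixed by `SyntheticTruth`:

- n = 2696 forks by default; parent diameters log-uniform over
  10–1000 µm (vein calibres span orders of magnitude across body
  sizes, and log-uniform gives the small-vein-dominated margin
  structure of such surveys).
- Children constructed to satisfy the exponent equation exactly at
  k_true = 3: a split fraction u ~ Uniform(0.2, 0.8) gives
  d1 = d0·u^(1/3), d2 = d0·(1−u)^(1/3).
- Multiplicative lognormal measurement noise on every diameter with
  log-sd sigma(d0) = 0.01 + 0.0025·max(0, 50 − d0): 1% relative error
  on well-resolved large veins, rising linearly to ~11% at 10 µm where
  the cavity boundary is only a few pixels wide. The noise lives on
  the diameters, not on k, so the solver — not the generator —
  produces the heavy-tailed k distribution. An additive-noise variant
  is available behind a switch.
- 17% of forks are perturbed into asymmetric geometry (one child
  inflated above the parent for mixed forks, both for both-wider, in
  ratio 338:127), matching the observed frequency of such forks.
- Angles are truncated normals on [0°, 180°): child–child angle
  (15° ± 10°) and parent–child angular differences (10.1° ± 7.3°),
  drawn independently of the diameters.

What the generator does **not** emulate: phylogenetic structure in the
taxon labels (they are uniform fakes), correlation between angles and
diameters, within-wing correlation among the up-to-three forks of a
specimen, vein taper, or atrophy. Tests passing on synthetic data
therefore validate the estimation machinery — solver taxonomy,
bookkeeping, threshold recovery — not any biological claim about real
wings.

With these defaults the expected deviation profile is convex rather
than exactly piecewise linear (|k − 3| responds nonlinearly to
diameter noise), so the two-segment fit tends to place τ slightly
below the true 50 µm. That misspecification is shared with analyses of
real data and is the realistic test of the model: over 20 seeded
replicates at n = 2000 the 95% credible interval still covers the true
threshold in ≥ 80% of replicates, and the plateau-slope interval
covers zero in ≥ 80%.

## Numerical choices

- Root residual tolerance 1e−12 (Brent), residual certificate 1e−9;
  argmin agreement with an independent numeric minimiser to 1e−4 over
  a bounded search.
- `k_bound` = 1e6: beyond this magnitude an exponent is recorded as
  uncomputable rather than returned, mirroring surveys that drop forks
  whose exponent underflows the software used.
- Bootstrap CIs: 10,000 resamples, percentile method, seeded
  `default_rng`.
- MCMC seeds: a `SeedSequence` per fit spawns one child per chain, so
  chains are independent and the whole fit is reproducible from one
  integer.
- Ties in binning are broken by input order (stable sort); ties in x
  for the sampler's canonical ordering are broken by y.

## Known limitations

- The mixed-case exponent is a best-fit convention, not a root; any
  statistic pooling it with exact roots (as the raw V1 dataset does)
  inherits its heavy tails.
- The Gaussian likelihood is not robust to those tails; the change
  point is still recovered at survey sizes, but sigma is inflated and
  the pre-threshold slope attenuated when extreme asymmetric forks are
  retained.
- Only two-child forks are supported; the n-children generalisation
  of the exponent equation is out of scope.
- The angle analyses treat pairs as independent even though each fork
  contributes two.
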