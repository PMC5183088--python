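# Methods

## Model and assumptions

The package fits a two-season dynamic occupancy model to paired
presence/absence censuses of many species over a fixed quadrat grid.  Year-1
occurrence, survival (persistence) and colonization are modelled on the
logit scale with one fixed intercept per process, a gap main effect and
gap-by-species interaction for the two transition processes, exchangeable
species random effects, and a spatially autocorrelated quadrat effect in the
year-1 occurrence predictor only.  Three assumptions matter:

* **Perfect detection.**  A single exhaustive search of a small (5 m x 5 m)
  quadrat is treated as a census: detection/nondetection equals
  presence/absence.  There is no false-negative layer, and none is planned
  (it would not be identifiable from one visit per season).
* **Conditional closure.**  Year-2 occupancy depends on year 1 only through
  the observed y1: `psi2 = y1*phi + (1-y1)*gamma`.
* **Truncation.**  All logit-scale effects live in [-10, 10].  This bounds
  probabilities away from exact 0/1 (inv_logit(+-10) ~ 5e-5) and makes every
  prior proper.  Computations stay on the logit scale via `log_expit`, so
  nothing underflows near the bounds.

## Priors

Fixed effects: Normal(0, 10^4) truncated to [-10, 10].  The BUGS-style
"Normal(0, 10^4)" is read as variance 10^4 (SD 100); inside a +-10 box the
density is flat to within 0.5%, so the precision-vs-variance ambiguity of
that notation is immaterial.  Species effects: Normal(0, sigma_f^2)
T(-10, 10) per family f, with the sd-dependent truncation mass included in
the density so that scale updates are exact.  Scales sigma_f and sigma_r:
Uniform(0, 10) — with effects truncated to +-10, larger scales are
indistinguishable, so the bound costs nothing; the hyperprior is a module
default, not hard-wired into the density code.

The spatial effect uses the intrinsic CAR prior: conditionals
`r_j | r_-j ~ Normal(mean of neighbours, sigma_r^2 / w_j+)`, joint kernel
`-(1/2 sigma_r^2) sum_{j<k} w_jk (r_j - r_k)^2 - (J-1) log sigma_r`.  The
quadratic form is the graph-Laplacian form r'Lr; the exponent J-1 is the
Laplacian's rank on a connected lattice, which is why a disconnected lattice
is rejected rather than silently accepted.  The intrinsic model is improper
along the constant direction; identification is by a sum-to-zero constraint
on r, with beta_o carrying the level.  Adjacency defaults to rook
(4-neighbour) — the natural reading of "adjacent" for edge-sharing square
quadrats and the standard ICAR lattice convention — with queen available in
`build_adjacency`.

## Sampler

A Metropolis-within-Gibbs scheme with a fixed update order (reproducibility
over randomized scans):

1. each fixed effect, scalar random-walk Metropolis;
2. each species-effect vector, element-wise Metropolis proposed and accepted
   in one vectorized pass (elements are conditionally independent given the
   fixed effects and scales);
3. a joint translation move per family (`beta_f + d, eps_f - d`), which
   leaves the likelihood invariant and is accepted on the prior ratio alone.
   Without it the intercepts and the means of their effect vectors form a
   near-flat ridge that single-site updates traverse very slowly (observed
   fixed-effect R-hat up to ~1.2 at 3,000 iterations; with the move, ~1.02
   and effective sizes an order of magnitude larger);
4. the spatial field, element-wise Metropolis against ICAR-conditional-plus-
   likelihood, swept over graph-colouring classes so simultaneously updated
   quadrats are never neighbours (on a rook lattice this is the red-black
   checkerboard), then re-centred: `r -= mean(r); beta_o += mean(r)`.  The
   translation is exact for the likelihood and the ICAR kernel; the only
   non-invariant factor is the essentially flat beta_o prior, so the
   projection introduces no measurable bias.  It is skipped in the (never
   observed) case where it would push beta_o out of the truncation box;
5. each scale, random-walk on log sigma with the Jacobian correction;
   proposals outside (0, 10) rejected.

Proposals at truncated bounds use plain rejection (valid since the target is
zero outside the box).  During burn-in every block's proposal scale adapts
by Robbins-Monro (`log-scale += t^-0.6 * (acc - 0.44)`) toward the 0.44
acceptance rate that is optimal for scalar updates, and is frozen at the end
of burn-in so retained draws come from a fixed kernel.  Per-chain RNG
streams are spawned from the master seed with `SeedSequence`, so runs are
bit-reproducible and chain-count changes never reuse a stream.

This sampler does not reproduce any particular BUGS implementation's draw
paths; equivalence is claimed in distribution only, and is tested that way:
a dense-grid brute-force posterior on a one-parameter reduction (total
variation < 0.02 at 50k draws), prior recovery with the likelihood disabled
(KS < 0.02 at 20k draws), and truth coverage in simulation.

The reference protocol is 4 chains x 13,000 iterations, 3,000 burn-in,
thinning 10 — 1,000 retained per chain, 4,000 total.  Analysis scripts and
the recovery experiments use a scaled-down 4 x 3,000 (1,000 burn-in,
thin 4; 2,000 retained) configuration, chosen because the adaptive sampler's
mixing makes the longer protocol unnecessary for these checks; the full
protocol runs in the test suite's bookkeeping check and in
`scripts/acceptance.py`.

## Diagnostics

R-hat is the classic between/within-chain PSRF — `sqrt(((n-1)/n W + B/n)/W)`
— matching BUGS-era practice; the degrees-of-freedom inflation of the
original formulation is omitted, as in common modern implementations.  The
more conservative split-chain variant (which also detects within-chain
trends) is available via `split=True` and is cross-checked against arviz in
the tests.  Parameters with zero within-chain variance report NaN and flag
as unconverged rather than raising.  ESS uses chain-averaged
autocovariances with Geyer's initial-positive-sequence truncation, capped at
the total draw count.

## Summaries and derived probabilities

Summary tables pool chains and use linear interpolation between order
statistics for quantiles (the mainstream software default; the exact
convention of legacy BUGS tools is not recoverable and differences are far
below posterior uncertainty).  Derived probabilities default to the plug-in
convention — inverse logit of summed posterior means, with a single varying
term's CI endpoints transformed directly — because that is how such tables
are conventionally reported; `mode="full_posterior"` transforms draw by draw
and is the better-justified alternative when draws are available.  Species
probability-scale CIs hold the other terms at their posterior means, exactly
as the plug-in arithmetic implies.

## Synthetic data

The generator runs the model forward at the study's dimensions: a 10 x 20
rook lattice (200 quadrats), 42 species, 20 gap quadrats, defaults taken
from the published posterior means (beta_o = -3.25, beta_s = -2.60,
beta_sg = -0.17, beta_c = -3.81, beta_cg = 1.51; sigma_o = 2.27,
sigma_s = 2.89, sigma_sg = 1.51, sigma_c = 1.89, sigma_cg = 1.35,
sigma_r = 0.44), so simulated surveys statistically resemble the original
data (sparse occupancy ~4% baseline with a heavy-tailed species spread).
Species effects are drawn by the exact inverse-CDF truncated-normal
transform (seed-stable, no rejection loops); the spatial field by
eigen-decomposition of the graph Laplacian with the null direction removed
and draws re-centred to sum to zero.  Clustered gap placement grows
rook-connected blocks by random accretion, the largest of 10 quadrats to
echo the ~250 m^2 largest real gap; the true spatial arrangement of the real
gaps is not reproducible from tabular information, so this layout is a
structural stand-in, not a claim of fidelity.

What the generator does *not* emulate: detection error (none in the model),
the tree-census layer that produced the gaps (gaps are exogenous), covariate
structure beyond the single gap flag, and any ecological correlation between
a species' effects across families (they are drawn independently, whereas
real palatability/shade-tolerance syndromes correlate them).  Passing
recovery tests therefore demonstrates correctness of the inferential
machinery under the model, not robustness to model misspecification in real
surveys.

## Numerical choices and edge cases

* Bernoulli log-probabilities via `log_expit(s * eta)`, s = 2y - 1; no
  log(0) anywhere inside the box.
* Truncated-normal log-density is hand-vectorized (the sampler needs cheap
  ratios) and cross-checked against `scipy.stats.truncnorm` in the tests.
* `log_prior` returns -inf (rejection semantics) for out-of-box effects or
  out-of-range scales; readers validate adjacency symmetry, zero diagonal,
  absence of isolated quadrats, and the run-length encoding consistency of
  BUGS-dump adjacency (`sum(num) == length(adj)`, 1-based indices in range).
* Species filtering uses the strict rule "more than `min_records` detection
  records summed over both years" (records = quadrat-year cells, i.e. out of
  J x 2); the union-of-quadrats reading is available as `count="quadrats"`.
* Quadrat indices are 1-based only inside the BUGS-dump dialect; converters
  at the reader/writer boundary are the only place indices shift.
* Draw serialization uses 17-significant-digit CSV and round-trip float
  parsing, so stored chains reload bit-identically.

## Known limitations

* Single-visit seasons mean detection and occurrence are confounded by
  design; estimates are of *apparent* occurrence/survival/colonization.
* The ICAR field enters year-1 occurrence only (as specified); transitions
  carry no spatial term, so spatially clustered colonization is absorbed by
  the gap covariate and species effects.
* With only 20 gap quadrats, gap-interaction scales (sigma_sg, sigma_cg) are
  weakly identified; their posteriors are prior-sensitive, and recovery
  intervals for them are wide (they cover, but not tightly).
* The sampler is serial; chains run sequentially.  At the study's scale a
  4 x 3,000 fit takes ~25 s on one CPU, the full 4 x 13,000 protocol about
  two minutes.
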