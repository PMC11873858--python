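# Methods

## The model

`rmmtree` fits Likert-scale item responses in which the middle ("neutral")
category can arise from two qualitatively different response processes.  A
respondent first decides whether to answer informatively.  If not, they
select the middle category and stop — a covert non-response.  If they do
answer informatively, they choose among *all* `h + 1` categories, the
middle one included, according to an ordinal probit model.  The observed
middle category is therefore a per-response mixture of two latent paths,
and for every observed middle response the model quantifies the posterior
probability that it was informative.

Let `X_pi ∈ {0, …, h}` (h even, middle category `m = h/2`) be the score of
person `p` on item `i`, and `Z_pi` the latent path indicator (1 =
informative).  Two latent traits per person drive the tree:

* node 1 (non-response): `P(Z_pi = 1) = Φ(−α₁ θ_p1 − β_i)` — θ₁ is a
  non-response *tendency* (the minus sign makes higher θ₁ mean more
  non-response), α₁ a slope common to all items, and −β_i an item
  intercept (items differ in how strongly they invite non-response);
* node 2 (substantive): a probit graded response model (GRM),
  `P(X_pi ≥ k | Z = 1) = Φ(α₂ᵢ θ_p2 − δ_ik)` for `k = 1..h`, with
  per-item slopes `α₂ᵢ ≥ 0` and ordered thresholds `δ_i1 ≤ … ≤ δ_ih`.

Non-middle scores identify `Z = 1`; middle scores leave `Z` latent with
`P(X = m) = P(Z = 0) + P(X = m | Z = 1) P(Z = 1)`.  Each item carries `h`
thresholds: the second node spans all `h + 1` categories (a genuinely
neutral answer is an ordinary category of the substantive scale).

Two nested baselines are provided.  The **GRM** treats every response as
informative (the `β → −∞` limit).  The **hard-tree (irtree)** baseline
treats every middle response as a non-response (`Z = 0` deterministic)
and models the remaining `h` categories with an `h − 1`-threshold GRM at
node 2 after a monotone remapping of the scores.

`(θ₁, θ₂)` get a bivariate normal population distribution whose mean is
fixed at 0 and variances at 1 by per-draw rescaling (below); the
off-diagonal — the correlation between non-response tendency and the
substantive trait — is estimated.

## Estimation

All three models are estimated by Gibbs sampling with probit data
augmentation.  Per sweep:

1. For every middle cell (mixture model only), `Z` is drawn from its
   Bernoulli conditional `P(Z = 1 | X = m, θ)`.
2. First-node propensities `Y₁ ~ N(−α₁θ₁ − β_i, 1)` are drawn truncated
   to the half-line matching `Z` (positive iff informative).
3. Thresholds receive a random-walk Metropolis move whose acceptance
   ratio uses the ordinal-probit likelihood with the node-2 propensities
   *marginalized out* (Cowles-style).  The naive uniform Gibbs step draws
   each threshold between the flanking augmented propensities, which at
   `N×K ≈ 50 000` cells moves thresholds by order-statistic-sized
   increments; on mixture data this creates a metastable ridge (middle
   thresholds absorbing the non-response excess) that pure Gibbs needs
   thousands of sweeps to cross.  The Metropolis move, proposed with
   per-item scale `2.4 / √(count + 1)`, reduces the transient to a few
   hundred sweeps.  It runs immediately before the propensity refresh so
   every subsequent conditional stays coherent.
4. Node-2 propensities `Y₂ ~ N(α₂ᵢθ₂, 1)` are drawn truncated to the
   observed category's threshold interval (cells with `Z = 0` never
   enter any conditional).
5. Item parameters update by conjugate normal regressions: `α₂ᵢ`
   per item (truncated to ≥ 0), a pooled regression for the common `α₁`
   (truncated) and per-item `β_i`; thresholds additionally get the exact
   uniform Gibbs draw between flanking propensities.
6. Persons update jointly from the bivariate normal conditional given
   their propensity rows and the `N(μ, Σ)` prior.
7. `μ` (flat prior) and `Σ` (inverse-Wishart, 4 df, identity scale)
   update from their standard conditionals; the inverse-Wishart draw uses
   a Bartlett construction on the package's single seeded generator so
   whole runs are bit-reproducible.
8. Identification rescaling: traits are centred at `μ` and scaled by
   `√diag(Σ)`, with compensating transforms (`α₁ ← α₁·sd₁`,
   `β ← β + α₁μ₁`, `α₂ ← α₂·sd₂`, `δ ← δ − α₂μ₂`) that leave the
   likelihood unchanged; `Σ` becomes a correlation matrix.  Constraints
   hold exactly in every retained draw.

Priors (variances, not SDs): `α₁, α₂ᵢ ~ N(0.5, 4)` truncated to ≥ 0,
`β_i ~ N(−2, 4)`, thresholds flat on the ordered region within `[−5, 5]`
(ties permitted; they give a zero-probability category and are handled
gracefully), `μ` flat, `Σ ~ IW(4, I)`.  With an empty data set the chain
samples from these priors, which is tested.

Truncated normals use inverse-CDF sampling for reproducibility; entries
whose interval carries negligible normal mass fall back to
`scipy.stats.truncnorm`, and zero-width intervals return their endpoint.

**Starting values.**  Thresholds start at probit-transformed empirical
cumulative category frequencies.  For the mixture model the start is
additionally corrected by a method-of-moments estimate of each item's
non-informative share (the excess of its middle-category share over the
average of the two neighbouring categories' shares), which also seeds
`β`, the initial `Z` draws, and θ₁ (standardized per-person middle
counts).  Without this correction the chain starts at the GRM-biased
configuration and, despite the Metropolis threshold moves, spends much of
a short run migrating out of it.  `fit(..., init=...)` can override any
start, e.g. for truth-initialized diagnostic chains.

Defaults follow the recovery study: 2500 iterations, 500 burn-in,
retaining every second draw; the desk-scale study configuration uses
1500/300.  Convergence tooling is deliberately simple: tidy trace
exports, split-R̂ and an autocorrelation ESS per scalar parameter; there
is no automated stopping.

## Model comparison

`dic()` computes `DIC = 2·mean D(draw) − D(posterior means)`
(Spiegelhalter pD form).  For models with a first node the deviance
integrates θ₁ out of each person's likelihood by 10-node Gauss–Hermite
quadrature against the conditional normal `θ₁ | θ₂` implied by `(μ, Σ)`;
the GRM deviance is its plain conditional likelihood.  The plug-in point
conditions on posterior means of the item parameters, θ₂ and Σ — the
deviance's conditioning set beyond the θ₁ marginalization is a design
choice; conditioning on θ₂ mirrors the quantity the per-draw deviances
use, keeping pD interpretable.

## Synthetic data and the recovery study

`generate_responses` literally traverses the tree per cell (Bernoulli
first node; categorical second node), returning scores plus the latent
`Z` truth.  The default design reproduces the factorial recovery study:

* persons: 1000 iid standard-normal `(θ₁, θ₂)` pairs, reused across
  conditions; the N=2000 condition duplicates the bank;
* items: a 25-item bank (duplicated for K=50) with locations `γ_i`
  equidistant on `[−1, 1]`; four thresholds per item drawn uniformly in
  `[−2,−1], [−1,0], [0,1], [1,2]`, rejection-sampled until all adjacent
  gaps exceed 0.5, then shifted by `γ_i`; `α₂ᵢ ~ U(0.44, 0.78)`;
  `α₁ = 0.61`;
* non-response rate: `β_i ~ N(μ_β, 0.2²)` with `μ_β` root-found so the
  population rate `1 − Φ(−μ_β/√(1 + α₁² + 0.2²))` hits the condition's
  target (20% → μ_β ≈ −1.00; 10% → μ_β ≈ −1.52).  Design values of −1.6
  and −2.4 are sometimes quoted for these rates, but under the probit
  convention used here they imply ≈ 9% and ≈ 2%; since the rate — not the
  intercept mean — is the experimentally meaningful factor, the
  calibrated means are used and the quoted values kept only as reference
  metadata (`REFERENCE_BETA_MEANS`).  The 0% condition sets `β = −1000`.

`run_simulation_study` regenerates responses per replication, fits the
requested models, and aggregates posterior means into recovery metrics:
per unit, bias is the across-replication mean estimate minus truth;
`avg_abs_bias` averages |bias| over units; `variance` is the
across-replication population variance; `mse` satisfies
`mse = mean(bias²) + variance` exactly.  Desk-scale defaults are 10
replications with 1500/300 chains (the full design uses 100 and
2500/500); per-replication seeds derive from the design seed by a
counter.

**What the desk scale can and cannot show.**  MSE-based contrasts are
stable at 10 replications.  The |bias| contrast is not: each unit's bias
estimate carries noise of variance `var/R`, so `avg_abs_bias` has a floor
of about `√(2·var/(πR))` (≈ 0.064 here at R = 10 against an RMM value of
≈ 0.104).  This floor inflates the better model's apparent bias and
compresses the RMM-vs-GRM reduction: measured ≈ 29% at R = 10 while the
MSE decomposition extrapolates to ≈ 45% as R grows.  Interpret
desk-scale bias contrasts as conservative lower bounds.

The generator emulates the study's idealised conditions — probit links
hold exactly, traits are exactly normal, items are conditionally
independent, and every non-informative response lands exactly in the
middle category.  Passing tests therefore demonstrate internal
consistency and correct estimation under the model's own assumptions,
not robustness to the misspecifications real questionnaire data carry
(DIF, local dependence, other response styles, missing data — the last
is rejected, not imputed).

## Numerical choices

* Probabilities are floored at 1e−300 before logs (probit tails
  underflow).
* Inverse-CDF truncated normals clip the uniform into `(1e−300,
  1 − 1e−16)`; deep-tail and degenerate intervals are handled as above.
* Threshold ties are permitted (the prior constraint is ≤); the
  generator's gap rule avoids them.
* Gauss–Hermite marginalization uses 10 nodes by default; on test
  instances 40 nodes move the result by < 1e−3.
* The DIC deviance average may subsample long chains evenly
  (`max_draws`); tests and the shipped defaults use all retained draws.

## Known limitations

Single unidimensional scale only; probit links only; no extreme- or
midpoint-response-style components; no person-mixture variant; no
missing-data support; single-chain estimation (multiple chains only via
seeds).  The DIC conditioning set beyond θ₁-marginalization is a
package design choice, as is the Metropolis threshold accelerant — both
are documented above because the corresponding conditional-posterior
details are otherwise underdetermined.
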