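# Methods

## The valuation model

A standard-gamble (SG) valuation study asks respondent *j* to value health
state *x<sub>ij</sub>*; after chaining through the respondent's own valuation
of the worst state ("the pits"), the adjusted value *y<sub>ij</sub>* lives on
the death = 0 / full health = 1 scale and may reach −1. The observation model
is

> y<sub>ij</sub> = 1 − α<sub>j</sub> (1 − u(x<sub>ij</sub>)) + ε<sub>ij</sub>,
> &nbsp;&nbsp; α<sub>j</sub> ~ LogNormal(t<sub>j</sub>ᵀγ, τ²),
> &nbsp;&nbsp; ε<sub>ij</sub> ~ N(0, v²).

`u` is the utility function of a reference respondent, anchored at
u(full health) = 1. The lognormal multiplier α<sub>j</sub> scales each
respondent's disutility 1 − u and produces the right-skew typical of SG data;
respondent covariates t<sub>j</sub> default to an intercept only. The
population mean utility is ū(x) = 1 − ᾱ(1 − u(x)) with
ᾱ = exp(γ₀ + τ²/2), the lognormal mean.

`u` carries a Gaussian-process prior with linear mean in the centred levels,
E u(x) = γ + βᵀ(x − 1), and squared-exponential covariance on the ordinal
levels, σ² c(x, x′) with c(x, x′) = exp{−Σ<sub>d</sub> b<sub>d</sub>
(x<sub>d</sub> − x′<sub>d</sub>)²}. The roughness rates are fixed at
b<sub>d</sub> = 2.5/(l<sub>d</sub> − 1)², which makes the two extreme levels
of any dimension correlate at exp(−2.5) ≈ 0.08. The anchor is imposed by
conditioning the GP on u(full health) = 1 (with raw levels the intercept is
unidentifiable against the slopes; centring plus anchoring resolves it). The
pits valuation enters the likelihood like any other observation.

### Cross-country transfer

A fitted donor country exports its posterior mean vector and covariance
matrix of `u` over any state set (states it never valued are filled in by GP
conditioning within the donor fit). The target country's GP prior then
becomes

> mean: Σ<sub>k</sub> E u<sub>k</sub>(x) + γ + βᵀ(x − 1) &nbsp;&nbsp;
> covariance: Σ<sub>k</sub> cov<sub>k</sub>(x, x′) + σ² c(x, x′)

summed over donors (equal weights by default; `donor_weights` exists as an
experimental hook). The offsets γ, β absorb the systematic country
difference; σ²c carries target-specific fluctuation. Donor posteriors are
plugged in fixed (two-stage estimation); they are never re-sampled and never
mutated. With one donor of vanishing uncertainty and zero offsets the target
prior collapses to the donor surface.

## Priors and identifiability

Variance parameters keep the conventional noninformative forms
p(τ²) ∝ τ⁻², p(v²) ∝ v⁻², p(σ²) ∝ σ⁻¹.

The likelihood is *exactly invariant* under the joint rescaling
α<sub>j</sub> → cα<sub>j</sub>, (1 − u) → (1 − u)/c: the data identify only
the products α<sub>j</sub>(1 − u(x)). With improper flat priors on the mean
coefficients and the multiplier location, the posterior is improper along
this gauge — chains equipped with a move that traverses it drift without
bound (the determinant terms from integrating out the mean coefficients and
the scale push the gauge systematically). The package therefore uses:

* a tight N(0, 0.05²) prior on the multiplier location γ₀, fixing the gauge
  at "median multiplier = 1";
* weakly-informative proper priors on the GP mean coefficients — intercept
  N(1, 1²) (the mean surface passes near 1 at full health) and slopes
  N(0, 0.3²). These are substantively generous: a utility bounded in
  [−1, 1] cannot have per-level decrements beyond 2/(l<sub>d</sub> − 1) ≤ 0.67.

Population quantities are unaffected: ᾱ(1 − u) is gauge-invariant, so
ū(x) — and every prediction, RMSE or agreement metric built from it — does
not depend on where the gauge is pinned. With the gauge pinned, the test
suite verifies near-nominal coverage of 95% credible intervals for all eleven
hyperparameters over 50 model-matched replicates; with improper flat priors
no such calibration is attainable for the location or scale, because the
likelihood is exactly constant along the gauge.

## Sampler

Metropolis-within-Gibbs, all blocks deterministic functions of one seeded
generator:

1. **u** over the valued states — block multivariate-normal full conditional
   (linear-Gaussian given the multipliers), sampled by Cholesky.
2. **log α<sub>j</sub>** — parallel random-walk Metropolis, accepted
   elementwise (the α's are conditionally independent).
3. **Scale move** — a joint Metropolis proposal that multiplies every
   α<sub>j</sub> by c and rescales 1 − u by 1/c. The likelihood cancels
   exactly; only the priors and the Jacobian c<sup>−m</sup> decide. Without
   it, elementwise updates mix across the gauge so slowly that posteriors
   look spuriously tight.
4. **γ₀, τ²** — conjugate normal / inverse-gamma updates;
   **v²** — inverse-gamma.
5. **GP mean coefficients** — 7-dimensional normal full conditional.
6. **log σ²** — random-walk Metropolis. (In the crude model σ² is actually
   conjugate given the anchored correlation matrix; the Metropolis step is
   kept because in the transfer model the prior covariance
   Σ<sub>k</sub>cov<sub>k</sub> + σ²c is no longer a pure scaling and the
   conjugacy is lost.)

Proposal scales adapt toward ~35% acceptance during burn-in (Robbins–Monro
style multiplicative updates every 50 iterations) and freeze afterwards, so
retained draws come from a fixed kernel. Defaults: 10,000 iterations, 2,000
burn-in, thinning 5, jitter 1e−8 on prior covariance diagonals. Boundary
values y = ±1 are treated as exact observations (no censoring likelihood).

Prediction at unvalued states draws, per retained draw, from the GP
conditional given that draw's utilities, mean coefficients and scale,
conditioning jointly on the anchor — so posterior sds at new states include
GP uncertainty. A `conditional_mean_only` flag suppresses the conditional
noise when only means are wanted.

## Synthetic data

The generator emulates the two linked valuation studies: 249 donor states ×
611 respondents × 6 values each (one being the pits), and 49 target states ×
126 respondents × 8 values, with missingness completely at random and a
`scale` knob that shrinks respondent counts for desk-speed runs. Donor truth
is one anchored GP draw; target truth adds a linear country offset
(γ*, β*) and an independent anchored GP fluctuation; respondent multipliers
and noise follow the observation model exactly; values are clipped to
[−1, 1] because the instrument cannot produce anything else.

Default truth: slopes (−0.030, −0.025, −0.025, −0.035, −0.025, −0.022)
giving a pits utility near 0.31 and observed means spanning roughly
0.3–0.95; σ² = 0.01 (deviations from linearity of about 0.1); τ² = 0.04;
v² = 0.01; offsets γ* = 0.03 and mixed-sign β* of magnitude ≤ 0.004.

What the generator does **not** emulate: probability-wheel granularity
(responses are continuous), informative missingness, respondent covariate
effects, and the elicitation's ranking stage. Passing recovery tests
therefore show the inference machinery is calibrated *under the model's own
assumptions*, not that real SG data satisfy them.

**Clipping.** With noise sd 0.1, an observation at a state of utility 0.9
exceeds 1 whenever the noise draw beats the whole disutility — roughly one
draw in six — so realistic state sets clip a few percent of draws overall;
the generator reports the clipped fraction. Because the fitted likelihood
treats boundary values as exact, clipping is a deliberate (mild) model
violation; parameter-recovery experiments therefore use a model-matched
design — state pools with total level decrement ≥ 6 and truth v² = 0.0025 —
which keeps censoring below about half a percent so that calibration is
measured under the model's assumptions. At the default noise level the main
visible effect is a small downward bias in the noise-variance estimate.

## Evaluation conventions

* Differences are observed − predicted; the full-health row (1, 1, 0) is
  included; the Bland–Altman sd uses the population (n) divisor. Limits of
  agreement are mean bias ± 1.96 sd; their range is 3.92 sd.
* RMSE is computed over all table rows including full health.
* The monotonicity audit samples primary states without replacement, pairs
  each with one uniformly chosen adjacent state (exactly one dimension, one
  level apart — every state of the default system has 6–12 such neighbours),
  and counts a violation when the dominating state (lower level in the
  differing dimension) is predicted *strictly* worse; ties are monotone, so a
  constant predictor scores 0 and an independent-noise predictor ~0.5.
* The packaged reference table ships verbatim at 4 decimal places; metrics
  recomputed from it carry rounding slack of about ±0.002–0.003 relative to
  values computed from unrounded draws.

## Numerical choices and degenerate inputs

* Kernel matrices get 1e−8 diagonal jitter before factorisation; a Cholesky
  failure is an error rather than a silent retry loop.
* Duplicate states in a kernel matrix are allowed (unit off-diagonals); the
  caller decides.
* τ² and v² inverse-gamma draws include a 1e−12 floor on the scale so an
  exact-zero residual cannot produce a zero variance.
* Fits require ≥ 2 distinct states, ≥ 2 respondents, and reject full health
  among the valued states (it is the anchor).
* σ² = 0, τ² = 0, v² = 0 are valid *generator* inputs and give the exact
  degenerate limits (linear truth; y ≡ u).

## Problem sizes used by the test suite

Desk-scale studies: ~30 states × 60 respondents, chains of 3,000 iterations
(1,000 burn-in, 2,000 retained). The coverage study uses 50 replicates; the
offset-recovery study 10; the paired donor-vs-crude precision comparison 20
replicates of a 20-state × 20-respondent target with 10 held-out states.
The target sample must keep more states than GP-mean coefficients: below
that, the crude model interpolates, its σ² posterior collapses, and its
claimed predictive sds are degenerately overconfident, which would corrupt a
precision comparison. These sizes give Monte-Carlo error comfortably inside
the asserted tolerances while keeping the whole suite in the minutes range.

## Known limitations

* Two-stage transfer: donor uncertainty enters only through the exported
  posterior covariance; donor and target are not jointly re-estimated.
* On very small datasets (a handful of states and respondents) the posterior
  is diffuse along weakly identified directions and chains mix slowly across
  them; cross-seed agreement of posterior means is only expected at
  realistic problem sizes.
* The gauge convention (median multiplier 1) is a modelling choice; only
  gauge-invariant quantities (ū, predictions, agreement metrics) should be
  compared across differently specified fits.
* Roughness parameters are fixed, not estimated; alternative kernels and
  formal donor-weighting schemes are out of scope.
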