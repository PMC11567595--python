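# Methods

## The reaction scheme

The package models the initiation step of coagulation: activation of
factor X (S) to factor Xa (P) by the tissue-factor–factor-VIIa complex
(E = TF:VIIa), and the inhibition of that activation by tissue factor
pathway inhibitor (I = TFPI) and by Xa itself.  Nine species are tracked
in nM: E, S, E:S, E:P, P, I, P:I, E:P:I and the tight quaternary complex
P:I:E.  Eight elementary reactions connect them:

| # | reaction | role |
|---|----------|------|
| 1 | E + S ⇌ E:S | substrate binding |
| 2 | E:S → E:P | catalysis |
| 3 | E + P ⇌ E:P | product rebinding (product inhibition) |
| 4 | P + I ⇌ P:I | Xa:TFPI formation in solution |
| 5 | E + P:I ⇌ P:I:E | one-step quaternary formation — **nullified** |
| 6 | E:P + I ⇌ E:P:I | direct binding of TFPI to enzyme-bound Xa |
| 7 | E:P:I ⇌ P:I:E | conformational lock (Kunitz-1 engagement) |
| 8 | E + P:I ⇌ E:P:I | indirect binding of the solution complex |

Reaction 5 would require two effectively simultaneous binding events, so
its rates default to zero while the terms remain in the equations; any
caller can switch it back on through the `RateSet` fields.  Mass-action
kinetics in a closed well-mixed volume conserve three moieties exactly
(enzyme, factor X, TFPI), which the test suite uses as a standing
invariant at 1e-8 nM.

The default rate constants are the fitted posterior medians of the full
scheme; an alternative set without the conformational step (reactions 5
and 7 nullified) is also shipped.  Both are reproduced by the package's
own estimation machinery on synthetic data rather than asserted.

## Flow model

Under flow the enzyme species are wall-bound at the injury and unaffected;
S and I are supplied at upstream concentrations S_up = 170 nM and
I_up = 2.4 nM, and S, P, I, P:I wash out, all with one mass-transfer rate
k_flow (s⁻¹).  From vessel geometry,

    k_flow = (3/4) · (V²·D / (R·L)²)^(1/3),

V the midstream velocity (µm/s), L the injury length (10 µm), D the
molecular diffusivity (50 µm²/s), R the vessel radius (µm); venous to
arterial conditions span roughly k_flow = 1e-3 … 1e3 s⁻¹.

Inhibition strength is measured by E_functional = [E] + [E:S], the enzyme
still able to turn over substrate, evaluated at steady state from the
standard start E(0) = 1 nM (all other species zero).  Four pathway
variants nullify subsets of reactions: NI (no TFPI; reactions 1–3 only),
DB (direct only; 4 off), IB (indirect only; 6 off) and DIB (all).  The
product-inhibition study repeats the NI sweep with the product off-rate
k₋₃ divided by φ, i.e. K_D,3 scaled to 520/φ nM, asking how much tighter
product binding would have to be to rival direct TFPI binding.

## Numerics

- **Integrator.** The system is stiff (k₊₇ ≈ 3.6e2 s⁻¹ against
  k₋₄ ≈ 1e-4 s⁻¹), so LSODA with the analytic Jacobian is used
  throughout; the right-hand side and Jacobian are numba-compiled.
  Simulation APIs default to rtol 1e-8 / atol 1e-12 nM, tight enough for
  the 1e-8-nM conservation checks.  Likelihood evaluations run at
  rtol 1e-6 / atol 1e-9: they occur tens of thousands of times per fit
  and measurement noise dominates far above that accuracy.
- **Negative undershoot.** Any species dipping below −1e-9 nM aborts the
  solve with an error rather than being clipped: silent clipping would
  mask a misconfigured integration.
- **Steady states** are found by stiff integration over geometrically
  expanding horizons, each followed by an algebraic polish
  (scipy's Powell-hybrid root-finder on the fixed-point system with the
  enzyme equation replaced by the conservation constraint), accepted only
  when the residual is below 1e-10 nM/s, all species are nonnegative and
  the enzyme total is exact.  Species whose dynamics vanish identically
  under a pathway variant (every touching reaction nullified, no flow
  term) are pinned during the polish; otherwise the root-finder can park
  enzyme in pools the dynamics can never reach.  The reaction network has
  no autocatalytic feedback, so the physically reachable steady state is
  unique in practice; the smoothness of the sweep curves across the flow
  grid and agreement with the closed-form no-TFPI solution corroborate
  this.
- **Pre-incubation** (TFPI with Xa, two hours) reduces to a single scalar
  ODE for the complex via the moiety totals; with the fitted rates the
  relaxation time ≈ 1/(k₊₄·I) is minutes, so the result sits at the
  binding-equilibrium quadratic, which the tests use as an independent
  check.

## Likelihood and parameter estimation

Measurements A_k(t_i) are independent draws from
N(μ(t_i|θ), σ·μ(t_i|θ)): a proportional-error model matching the
heteroscedasticity of Xa progress curves.  The observable μ is free Xa
([P]) by default; [P]+[E:P] is available as a sensitivity alternative and
differs by a few percent at most under the experimental conditions.

The free vector is θ = (k₊₁, k₊₂, k₊₃, k₊₄, k₊₆, k₋₆, k₊₇, k₋₇, k₊₈,
k₋₈, σ); three rates are tied to literature constants — k₋₁ = K_M·k₊₁ −
k₊₂ with K_M = 238 nM, k₋₃ = 520·k₊₃ nM, and k₋₄ = 2.63e-2·k₊₄ nM.  The
last tie reflects that the published median k₋₄/k₊₄ ratio equals the
fixed dissociation constant to three significant figures in both fitted
schemes, which would be implausible for two independently sampled rates;
a switch (`free_k_minus_4`) restores an independent k₋₄ on (0, 500].
Priors are uniform over a bounded box: bimolecular on-rates at most the
diffusion limit 1 nM⁻¹s⁻¹, off-rates and k₊₇ at most 500 s⁻¹, k₋₇ at
most 1e-2 s⁻¹, σ on (0, 1], and k₊₁ ≥ k₊₂/K_M so k₋₁ stays nonnegative.

The walk runs in **log coordinates** with the Jacobian term added to the
target, so the uniform-box prior is unchanged.  This choice was forced
by evidence: the rate constants span five orders of magnitude, and at
the default chain lengths a linear-scale walk stalls on the posterior
ridges (it reaches a log-posterior ~70 units below the mode and covers
few of the generating values), while the log-scale walk equilibrates in
a quarter of the adaptive phase.  `FitConfig(log_scale=False)` restores
the linear-scale walk for comparison.

Estimation follows four steps:

1. **Latin-hypercube pre-exploration** of the box.  At full scale this
   is 1e6 samples with the top 500 (the top 0.05%); the desk-scale
   default of 1e4 samples keeps the proportion sharp by taking the top
   50 — taking 500 of 1e4 would dilute the seed with sets five orders of
   magnitude worse in likelihood.  The walk starts from the single
   best-scoring set: the top sets are scattered across distinct ridges,
   so their componentwise centre scores ~100 log-units worse than any of
   them.  Their log-scale spread, shrunk by `ma_proposal_scale` (0.01),
   seeds the diagonal proposal covariance.
2. **Fixed-proposal random-walk Metropolis** (1e5 iterations at full
   scale, 1e3 by default).
3. **Adaptive Metropolis**: the proposal covariance is the empirical
   covariance of the recent chain history (window 3000; full history
   optionally) scaled by 2.38²/d (Haario scaling) with a 1e-10 diagonal
   regularizer, multiplied by a global factor adapted on a
   Robbins–Monro schedule toward 23.4% acceptance.  The global factor
   and the window are essential at desk scale: the pre-exploration seed
   sits far from the posterior mode, and pure full-history covariance
   adaptation cannot rescale or re-shape fast enough within 2e4
   iterations.  Near stationarity the factor converges and the sampler
   reduces to the classical recipe.
4. **Burn-in and thinning**: by default the MA phase plus the first half
   of the AM phase is dropped (at desk scale the early adaptive
   iterations are still travelling) and every 100th (full scale) or 10th
   (desk scale) sample kept; `FitConfig.paper_scale()` pins the burn-in
   to the MA phase alone, reproducing the published retained-sample
   arithmetic.  Lag-1 autocorrelations of the retained samples are
   reported and a warning is raised above the 0.05 decorrelation target.

Posterior summaries are per-parameter medians with equal-tailed 95%
intervals; derived constants (k₋₁, k₋₃, k₋₄, K_D,1, K_D,6, K_D,8 and the
reaction-7 ratio, reported in both directions) are computed per sample so
monotone transforms commute with the median.  Prediction bands are
pointwise quantiles of μ(t|θ) over (a subsample of) the chain.

## Synthetic data

The generator reproduces the statistical structure the likelihood
assumes.  Experiment One: TF:VIIa at 0.032–1.024 nM (six doublings by
default, extensible to eight levels), X = 170 nM, TFPI = 2.4 nM.
Experiment Two: TFPI 2.4 nM pre-incubated two hours with Xa at
{0, 0.1, 0.5, 1} nM, then mixed (without dilution) with enzyme 0.128 nM
and X 170 nM.  Twelve equally spaced non-zero measurement times over
720 s; proportional normal noise with σ_true = 0.05.  Negative draws are
redrawn (count logged) to preserve the normal shape near the bulk; t = 0
points are never generated since σ·μ degenerates there.  The Xa = 0
condition of Experiment Two is bit-for-bit the 0.128 nM condition of
Experiment One, a replicate identity the tests assert exactly.

What the generator does **not** emulate: figure-digitization error,
plate-reader chemistry (quench, chromogenic substrate), pipetting
dilution, or replicate-to-replicate batch effects.  Passing recovery
tests therefore demonstrate the estimation machinery is self-consistent
under the model's own assumptions, not that the model is correct for any
particular laboratory dataset.

## Problem sizes and defaults

| setting | desk-scale default | full scale |
|---|---|---|
| LHS samples / top-k | 1e4 / 50 | 1e6 / 500 |
| MA iterations | 1e3 | 1e5 |
| AM iterations | 2e4 | 6e6 |
| thinning stride | 10 | 100 |
| flow-sweep grid | 25 log-spaced points over 1e-3…1e3 s⁻¹ | same |

The desk-scale counts (roughly 100× below full scale) are the package's
test and example configuration; `FitConfig.paper_scale()` restores the
full counts.  A desk-scale fit makes ~3e4 likelihood evaluations (each
~10 ODE solves) and completes in a few minutes on one core.

## Known limitations

- The desk-scale sampler equilibrates, but its effective sample size is
  small; credible intervals for weakly identified rates (k₋₆, k₊₇, k₋₈)
  are noisy at this scale.
- No spatial transport: the reaction zone is a well-mixed compartment
  with a single mass-transfer coefficient.
- No lipid surfaces, platelets, or downstream coagulation species; the
  model ends at Xa.
- Steady-state uniqueness is a (well-corroborated) modelling judgment,
  not a theorem; pathological rate sets with near-degenerate dynamics
  could in principle defeat the polish-acceptance checks.
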