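# Methods

## The model

`bimhmm` implements a bivariate mixed hidden Markov model (MHMM) for
two continuous endpoints observed longitudinally in a two-arm parallel
trial: a lung-function biomarker (FEV1, L/s) and a patient-reported
outcome score (PRO).  A hidden first-order Markov chain with two states
— remission (R) and exacerbation (E) — advances on the weekly
observation grid; both endpoints are emitted from the current state.

**Individual parameters.**  Subject $i$ carries up to five independent
normal random effects $\eta \sim N(0, \omega^2)$:

- FEV1 state values are log-normal around the population modes:
  $\mathrm{FEV1}_R = \theta_{\mathrm{FEV1}_R} e^{\eta_1}$ and
  $\mathrm{FEV1}_E = \mathrm{FEV1}_R - \theta_{\mathrm{FEV1}_E} e^{\eta_2}$.
- PRO state values are additive-normal with a placebo time course:
  $\mathrm{PRO}_R(t) = (\theta_{\mathrm{PRO}_R} + \eta_3)\,
  [1 - PE\,(1 - e^{-\log 2\, t / PHL})]$ and
  $\mathrm{PRO}_E(t) = \mathrm{PRO}_R(t) + (\theta_{\mathrm{PRO}_E} + \eta_4)$.
  $PE$ is the maximum fractional placebo decrease (default 0.2) and
  $PHL$ its half-life in weeks (default 10), so the decrease is
  essentially complete by week 50.  (A variant of this term sometimes
  seen with $PHL \cdot t$ in the denominator of the exponent is
  singular at $t = 0$ and vanishes at late times; the half-life form
  above is the only one consistent with the intended behavior.)
- The chain starts in R with probability `init`; the weekly exit
  probabilities are
  $\pi_{RE} = \mathrm{expit}(\mathrm{logit}(\theta_{\pi_{RE}}) + \eta_5 -
  \mathrm{TRT}\cdot \mathrm{SLP})$ and
  $\pi_{ER} = \theta_{\pi_{ER}}$.  The treatment covariate TRT is 0/1;
  SLP > 0 lowers exacerbation onset (SLP = 1 cuts a baseline
  $\pi_{RE} = 0.05$ by 62%).

**Emissions.**  Given the state, the two endpoints are jointly Gaussian
with state-shared residual variances $\sigma^2_{\mathrm{FEV1}} = 0.015$,
$\sigma^2_{\mathrm{PRO}} = 0.05$ and state-specific residual correlation
$\rho_R$, $\rho_E$ (reference $-0.33$ in both states; the package
supports tied or free correlations, free by default in estimation).
With one endpoint missing the emission is the corresponding univariate
normal density with the standard constant $1/\sqrt{2\pi\sigma^2}$
(the only constant under which the bivariate density factorizes into
the univariate product at $\rho = 0$).  A row with neither endpoint
contributes no emission but still advances the chain.

**Asymmetry is intentional.**  FEV1 uses multiplicative $e^\eta$,
PRO additive $\eta$ — implemented exactly as specified, with a
consequence worth noting: the PRO exacerbation contrast
$\theta_{\mathrm{PRO}_E} + \eta_4 = 0.5 \pm 0.3$ varies far more across
subjects than FEV1's $0.25\,e^{\eta_2}$ (CV 17%), so PRO's per-subject
state separation is much less reliable even though its average
per-observation separation ($0.5/\sqrt{0.05} \approx 2.24\sigma$)
slightly exceeds FEV1's ($0.25/\sqrt{0.015} \approx 2.04\sigma$).
This drives the power comparisons below.

## Likelihood

Conditional on $\eta$, the subject log-likelihood is computed with the
scaled forward algorithm: per time step the normalized state
probabilities $\varphi$ are propagated through the transition matrix,
multiplied by the state emission densities, and renormalized; the
log-likelihood is the accumulated sum of log normalizers.  All emission
arithmetic is in log space, so the recursion cannot underflow for
finite inputs.  Viterbi decoding is the standard log-space dynamic
program; ties break toward remission (the lower state index).

The marginal likelihood integrates the conditional likelihood over the
active random effects (dimensions with $\omega^2 > 0$).  The default
scheme is a Laplace approximation: the posterior mode of $\eta$ is
found by a damped Newton iteration (finite-difference gradient and
Hessian, modified-eigenvalue descent direction, backtracking), and the
log marginal is the penalized log-likelihood at the mode plus
$\tfrac{k}{2}\log 2\pi - \tfrac12 \log |H|$.  Two verification modes
exist: fixed-seed Monte-Carlo importance sampling with a Gaussian
proposal at the Laplace mode, and adaptive quadrature when exactly one
dimension is active.  The test suite checks Laplace against quadrature
and against brute-force trapezoid integration.

**Multimodality.**  The penalized $\eta$ objective can have secondary
modes: a subject sitting below the population level can be explained
either by shifted individual modes (mostly-remission) or by extra
exacerbation time with compensating state effects.  Basin gaps of 10-20
log-units occur for occasional subjects, and a local mode search
started from a single point is not reliable.  The package therefore
evaluates marginals from several deterministic starts — the warm
incumbent mode tracked across optimizer iterations, zero, and a
moment-matched "mostly-remission" start — keeping the best.  For
paired-model statistics (likelihood-ratio OFV differences, per-subject
ΔiOFV for power mapping), `refine_paired_iofv` re-evaluates both fits
from the union of the eta banks both fits discovered, so the paired
difference reflects the models rather than mode-search luck.

## Estimation

Population parameters are estimated by maximizing the total Laplace
log marginal likelihood with L-BFGS-B on transformed scales (log for
variances and the placebo half-life, logit for probabilities, arctanh
for correlations, identity for modes and SLP), bound-constrained on the
transformed scale.  By default all Table-level parameters are free
except the placebo constants $PE$ and $PHL$, which we treat as
structural; any subset can be freed or fixed.  Convergence uses a
relative-OFV tolerance of $10^{-9}$ with up to 400 iterations, and the
optimizer is re-launched from its own solution — after refreshing the
warm-start eta bank with a multistart pass at that point, recovering
any basins the trajectory lost — until the OFV improves by less than
0.5 points ("restarts"), making convergence depth a property of the
configuration rather than line-search luck.  The
objective function value is OFV $= -2\log L$, reported in total and
per subject (iOFV); the reported values are the warm-path values the
optimizer converged on, refined by the multistart pass.

Standard errors come from the outer product of per-subject score
vectors (empirical Fisher information), with scores obtained by central
finite differences of each subject's log marginal on the natural scale
(relative step 0.02) from a fixed center bank of eta modes.  A
finite-difference Hessian of the total log-likelihood is not used: the
Laplace surface carries occasional basin kinks of order 10 log-units,
which one subject's score absorbs harmlessly but which destroy a
second-difference stencil of the total.

## Simulator

`simulate_trial` generates a placebo-controlled parallel-arm trial, by
default 250 subjects per arm followed for 60 weeks with both endpoints
sampled weekly (60 samples; week indices 0–59).  The sparse-biomarker
variant samples FEV1 monthly at weeks 0, 4, …, 56 (15 samples) while
PRO stays weekly; the hidden chain always advances on the weekly grid.
Subject streams are counter-based (`SeedSequence((seed, arm, index))`),
so a subject's data is invariant to the cohort size.  Simulation truth
(state chains and eta draws) is stored in sidecar files, never in the
analysis dataset.  The 14-scenario grid perturbs the drug effect
(0.5–2), the transition probabilities (0.05/0.15 vs 0.10/0.30 and
0.30/0.30), the transition-effect variance (0, 0.06, 0.12), the
correlation ($-0.33$ vs $-0.66$), and the FEV1 sampling frequency.

What the generator does *not* emulate: dropout or informative
missingness, demographic covariates, non-Gaussian endpoints, and
within-subject changes of treatment.  Passing tests therefore speak to
estimator behavior under the model's own assumptions, not to robustness
against real-data violations of them.

## Simulation studies and their reduced scales

The package's study harnesses default to the full designs (100
replicates, 250 subjects per arm, 5000-subject power mapping).  The
shipped test suite runs them at reduced scale, chosen so the whole
suite completes on a single CPU in well under half an hour; the
reductions and how the quantities scale are:

- **Parameter recovery**: one reference-design dataset (500 subjects),
  all 17 parameters estimated from a perturbed start; fixed effects are
  checked against ±3 empirical-Fisher SEs.  The transition-effect
  variance $\omega^2_{\pi_{RE}}$ is excluded from the bound: it is the
  model's known weak spot (the full-scale study reports RRMSE ≈ 187%),
  and we reproduce that weakness (typically a ~2x overestimate).
- **Cost of ignoring correlation**: OFV penalty of the $\rho = 0$
  emission model on $\rho = -0.33$ data, 10 replicates × 100 subjects
  with the emission block re-estimated.  The penalty is a
  per-observation information quantity, hence linear in the number of
  subjects; the full-scale mean of 2993 at 500 subjects corresponds to
  ≈ 600 at 100, and the study reproduces that share (and ≈ 0 on
  uncorrelated data).
- **Mapped power**: one 500-subject mapping dataset instead of 5000;
  per-variant full and reduced (SLP dropped) fits re-estimate every
  parameter entering the variant's likelihood, mirroring a
  full-estimation workflow — re-estimating only the transition block
  distorts the model comparison, because the reduced model must be able
  to inflate $\omega^2_{\pi_{RE}}$ to absorb the arm difference.
  Per-subject ΔiOFV values are resampled 10,000 times per sample size
  against the $\chi^2_1$ criterion (3.84 at $\alpha$ = 0.05; one
  dropped parameter).  Resampling is with replacement across both arms.
- **Drug-effect precision trend**: RRMSE of SLP across true effects
  0.5 / 1 / 2 at 10 replicates × 150 subjects with the transition block
  re-estimated.  RRMSE levels scale like $1/\sqrt{n}$, so reduced-scale
  levels sit above the full-scale ones; the trend (precision improves
  with effect size) is scale-free and is what the test asserts.

## Numerical choices and edge cases

- Inner Newton: gradient tolerance $10^{-7}$, at most 50 iterations,
  FD steps $5\times10^{-4}(1+|\eta|)$; non-positive-definite Hessians
  get eigenvalue flooring, both for the search direction and for
  $\log|H|$.
- Emission underflow at absurd parameter values returns $-\infty$
  rather than raising, so the outer optimizer can back away.
- $\omega^2 = 0$ dimensions are excluded from integration exactly; with
  all variances zero the marginal equals the conditional likelihood at
  $\eta = 0$.
- Viterbi and forward accept rows with either endpoint missing
  (univariate emission) and, in endpoint-restricted model variants,
  rows with both missing (no emission term).
- RRMSE and relative bias reject a zero true value (relative metrics
  undefined); SSE summaries use converged replicates only and report
  the count.

## Known limitations

- The Laplace approximation's accuracy is good for this model's 60-80
  observations per subject (checked against quadrature), but the
  residual mode-search ruggedness means OFV values carry an
  irreducible wiggle of a few points on rare datasets — comparable to
  the ~5-point OFV fluctuation the original estimation software
  reports across retries.  Statistics built on paired refinements are
  stable; single raw OFVs should not be over-interpreted to < 1 point.
- Monte-Carlo importance sampling degrades in 5 active dimensions
  (multimodal integrand); it is a verification tool for ≤ 2 active
  dimensions, not a production integrator.
- With the reference parameters, the PRO endpoint's average
  per-observation state separation slightly exceeds FEV1's, while its
  contrast reliability is far lower; which univariate model wins the
  power comparison is therefore delicately balanced, and reduced-scale
  mapped-power runs can rank the univariate models either way.
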