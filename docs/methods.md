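# Methods

## Problem and design

The pipeline quantifies familial aggregation of cancer, by sex, in a
population where family membership must be inferred rather than observed.
The inferential unit is the MNS combination — birth municipality + surname
at birth + sex — treated as a same-sex family line. Eligibility rules
mirror registry practice: persons born 1870–2010, cancers diagnosed before
age 80, one primary per site per person (earliest kept), and a minimum of
two persons per MNS combination. Follow-up ends at a fixed calendar year
(default 2016) for everyone.

## SCIR: expected counts without person-years

Registry extracts of this shape carry no death or emigration dates, so
person-years at risk — and hence a classical SIR — cannot be computed.
Instead each member contributes the reference *cumulative* incidence of the
site from birth to their attained age min(80, follow-up end − birth year),
and the family's expected count E is the sum of member contributions. The
SCIR is O/E.

Conventions, chosen where registry practice leaves room:

* attained age is completed years at the end of the follow-up year (floor);
* E accumulates from birth (age 0), not from any registry start year;
* birth cohorts are binned in 10-year bins (configurable width);
* a member born after the end of follow-up contributes 0, with a warning;
* E ≤ 0 rows are dropped as degenerate (SCIR undefined).

Families with O = 0 for a site are excluded from modelling (kept in the
SCIR table flagged `excluded`). This reproduces a deliberate property of
the study design: fitting an untruncated Poisson likelihood to the O ≥ 1
subset inflates the apparent risk level of every analysis set, so absolute
per-analysis risk metrics are intermediate quantities; contrasts (high
versus overall, male versus female) are the interpretable outputs. A
zero-truncated likelihood is available (`MixtureModelSpec(truncated=True)`)
for sensitivity analysis; it is not the default.

## The risk mixture

Per site and sex, family counts follow a two-component Poisson–gamma
mixture (see README for the generative statement). The two components
formalise "background" versus "elevated" familial risk; the latent
indicator z_j gives each family a posterior probability P(high) that is the
basis of cluster detection, and the hierarchical priors shrink small
families toward the population pattern, which is what controls multiplicity
over hundreds of thousands of comparisons.

### Priors (defaults, all configurable)

* π ~ Beta(1, 1): uniform mixture weight.
* Component means m_k = a_k/b_k ~ Gamma(1, 0.01) — weakly informative,
  prior mean 100, effectively flat over the plausible relative-risk range.
* Rates b_k log-uniform on [1e−4, 1e4]: scale-free over a wide box; the
  bounds only prevent numerical escape.
* Identifiability: m_high > m_low enforced by rejecting violating
  Metropolis proposals, so every stored draw is label-ordered and no
  post-hoc relabelling is needed.

### Sampler

Gibbs with one Metropolis block per iteration:

1. z_j | π, hyper — collapsed: θ_j is integrated out analytically, the
   component marginal of O_j being negative binomial with size a_k and
   success probability b_k/(b_k+E_j). Collapsing and then redrawing θ is a
   partially collapsed Gibbs step with the correct stationary distribution
   and much better mixing when components overlap.
2. θ_j | z_j, hyper ~ Gamma(a_k + O_j, b_k + E_j) (conjugate).
3. π | z ~ Beta(1 + n_high, 1 + n_low).
4. (m_k, b_k) per component: joint random-walk Metropolis on the log scale
   (Jacobian included), using sufficient statistics of the component's θ
   values. Proposal scales adapt toward ~30% acceptance during burn-in
   only; the post-burn-in kernel is fixed, so stored draws come from a
   valid time-homogeneous chain.

Defaults: 2 chains × 8,000 iterations, 3,000 burn-in, thinning 5, seeds
spawned deterministically from the spec seed. At the problem sizes used
for validation (≈2,000 groups) this runs in seconds per fit and recovers
generating parameters; convergence is monitored with split-R̂ on π and both
component means, warning (never failing) above 1.05. Skewed posteriors are
summarised by medians with central 95% intervals.

The zero-truncated variant replaces step 1 with the θ-conditional z-update
and step 2 with an independence-Metropolis step whose proposal is the
untruncated conjugate conditional; the acceptance ratio is the ratio of
(1 − e^{−Eθ}) correction factors.

### Numerical choices

* All component marginals are computed in log space via `gammaln`;
  assignment odds via `expit` of the log odds.
* Conjugate Gamma draws are floored at 1e−290 to avoid underflow to exact
  zero for tiny shapes (O = 0, small a_k).
* Normalised SCIRs use the sample SD (n−1) of the per-family posterior
  medians and are signed so that high-risk clusters are positive; a
  degenerate (zero-SD) set normalises to all zeros with a warning.
* Cluster thresholds (0.9, 0.95) are strict inequalities.
* Male and female chains are paired by stored-iteration index for ratio
  CIs (the posteriors are independent, so any exhaustive pairing is valid
  and index pairing is deterministic); unequal lengths are reconciled by a
  seeded bootstrap of the shorter chain.
* Table averages are rounded half-up to 3 decimals; sex percentages to
  integers.

## Synthetic registry generator

The generator is first-class, tested code: it defines the study conditions
under which the method is validated.

* Families: unique (municipality, surname) token pairs; sizes from a
  shifted negative binomial (min 2, r = 2, mean 14) giving a median family
  size of 12; member sexes Bernoulli(1/2); birth years clustered around a
  family anchor (SD 18 years) within 1870–2010.
* Incidence reference: 27 non-sex-specific site groups with per-sex
  lifetime risks of registry-like magnitude, 15% of lifetime risk before
  age 50 — piecewise-constant hazards, identical across birth cohorts.
* Events: a family is high-risk with probability π_true (default 0.10);
  its hazard for every site is multiplied by θ_high (default 5), others by
  θ_low (default 1). Per person, site and one-year age step an event
  occurs with probability min(1, θ·ΔΛ), at most one event per person and
  site. Family counts are then approximately Poisson(E·θ) with an error of
  order (θ·ΔΛ)² per step; validation keeps per-person expected values
  small so the approximation is within Monte-Carlo noise.

What the generator deliberately does **not** emulate: surname
misclassification (shared common surnames, name changes at marriage,
out-of-wedlock naming), death/emigration censoring, secular incidence
trends by cohort, and site-specific (rather than family-wide) risk
elevation. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the model's own assumptions, not
robustness to those real-data complications.

Model-recovery validation (π within ±0.03, component means within ±15%,
in ≥9/10 replicates at n = 2,000 groups, E ∈ [0.05, 2]) fits the *full*
generated record set including zero-count groups: recovery of the
generating truth is only a well-posed check when the likelihood matches
the data actually fitted. The pipeline's O ≥ 1 exclusion is validated
separately by the null-calibration check (π_true = 0: ≤1% of groups reach
P(high) > 0.95) and the planted-cluster check (O = 6, E = 0.04 flagged at
P(high) > 0.95 in ≥9/10 replicates), both run through the exclusion path.

## Validation problem sizes

Recovery uses 2,000 groups × 10 replicates; null calibration 2,000
simulated groups per seed across 3 seeds; planted-cluster detection 500
background groups × 10 replicates; the end-to-end demonstration 400–1,500
families over four sites. These sizes put Monte-Carlo error well inside
the asserted bands while keeping a full validation run in minutes.

## Known limitations

* Absolute π and SCIR levels from the O ≥ 1 pipeline path are biased
  upward by construction (see above); compare contrasts, not levels,
  across analyses.
* The group-proportion male–female ratio is weakly identified when
  per-family expected counts are small; its credible intervals are wide
  and the point ratio is unstable at demonstration scale.
* Split-R̂ can exceed 1.05 on short demonstration chains; the fit reports
  it and proceeds. For publication-grade runs increase iterations/chains
  in `MixtureModelSpec`.
* The two-component structure is a smoothing device; it does not claim
  there are literally two biological risk classes.
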