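# Methods

## The interpolation model

Each supported survival family is treated as a parametric curve S(t; θ) whose
parameter vector θ is *identified*, not estimated: the user supplies as many
(time, survival) coordinates as the family has parameters, and the survival
function is rearranged and solved as simultaneous equations. Points must
have strictly positive times, survival strictly inside (0, 1), strictly
increasing times and strictly decreasing survival; under those conditions
every family has exactly one solution.

* **Exponential** (one point): λ = −ln s / t.
* **Weibull / log-logistic / log-normal** (two points): the transformed
  survival — ln(−ln s), ln(1/s − 1) and Φ⁻¹(1 − s) respectively — is linear
  in ln t, so shape and scale come from the two-point slope/intercept in
  closed form.
* **Gompertz** (two points): no closed form exists. The shape b is the root
  of (e^{bt₂} − 1)/(e^{bt₁} − 1) = ln s₂ / ln s₁. The left side is
  continuous (value t₂/t₁ at the removable singularity b = 0), strictly
  increasing in b, with range (1, ∞); the right side is > 1 for any valid
  decreasing pair, so a unique root always exists. A sign-changing bracket is
  found by doubling outward from [−1, 1] (capped at |b| = 500/t₂, beyond
  which e^{bt₂} would overflow and which no realistic pair approaches) and
  Brent's method polishes it to machine precision; the rate is then
  a = −ln s₁ · b / (e^{bt₁} − 1).

Convergence is defined by plug-back: the solved model must reproduce every
coordinate with |S(t_i; θ̂) − s_i| < 1e−8, far below any decision-relevant
scale. Only exactly determined systems are accepted — three or more points
for a two-parameter family are rejected rather than least-squares fitted.

**Conditioning.** Nearly coincident times with well-separated survival values
imply astronomically large shape parameters (a near-vertical curve segment),
where double precision cannot hold the 1e−8 plug-back tolerance. The test
suite's random-pair generators therefore keep milestone times separated by at
least ~30%, which also reflects how such coordinates arise in practice
(annual or multi-year milestones). The solver itself does not forbid closer
pairs; it reports the achieved residuals and the convergence flag.

## Parameterisations and numerics in the distribution layer

The flexsurv-convention forms listed in the README are used throughout. The
Gompertz shape may be negative, zero or positive; at b = 0 the cumulative
hazard is evaluated as a·t (the series limit), and elsewhere through
`expm1`, which is accurate uniformly in |bt|. The log-normal survival and
hazard are computed through `log_ndtr`, keeping them finite far into the
right tail where Φ(−z) underflows. Hazards at t = 0 return the mathematical
limit (0 for shape > 1, the rate itself for exponential-like cases, +∞ for
Weibull/log-logistic shape < 1) rather than raising, so hazard panels have a
defined left endpoint. Quantiles use `log1p` so that tiny-|b| Gompertz
inversions do not lose precision; survival levels at or below an improper
family's plateau raise an infeasible-quantile error.

A mixture cure model wraps any base family as S(t) = π + (1 − π)S₀(t) with
π ∈ [0, 1). Cure interpolation points are specified on the *overall*
survival scale and transformed to (s − π)/(1 − π) before solving; any point
at or below π is infeasible by construction.

## Piecewise models

A piecewise model keeps a Kaplan-Meier prefix (or, with no data, a straight
line from (0, 1) to the anchor) up to a join time t₀ and attaches a
parametric tail on the conditional scale: S(t) = S(t₀) · S_tail(t − t₀) for
t ≥ t₀. User points for the tail are given *unconditionally* and converted
internally (divide by the anchor, shift by t₀). The unconditional reading is
the one under which an external milestone such as a published 5-year rate is
reproduced exactly by the assembled curve, which is the entire point of
anchoring on it. The anchor defaults to the KM step value at t₀
(right-continuous convention, so a step exactly at t₀ counts), with an
explicit (t₀, S₀) override for data-free use.

## Kaplan-Meier estimation

The product-limit estimate and its event table come from lifelines.
Greenwood's cumulative sum Σ d_i/(n_i(n_i − d_i)) — the variance of ln Ŝ —
and the 95% pointwise interval on the log(−log) scale (which cannot leave
[0, 1]) are assembled from that table. Event data arrive as CSV with
configurable time/status columns; rows with missing or non-positive times
are dropped with a counted warning, and non-numeric status codings must be
mapped explicitly.

## Background mortality

A life table supplies annual death probabilities q_x by age and sex; the
annual hazard is −ln(1 − q_x), treated as piecewise constant per year of age
and divided by the time-units-per-year constant (years 1, months 12, weeks
52.18, days 365.25). The adjusted hazard is max(h_model, h_population).
Rather than integrating the max directly, the survival is computed as
S_adj(t) = S_model(t) · exp(−∫₀ᵗ max(0, h_pop − h_model)): identical
mathematically, but the excess integrand is bounded by the population hazard
even where the model hazard diverges at t = 0, and the identity
S_adj = S_model is *exact* wherever the floor is inactive. The excess
integral is accumulated by trapezoid on a fixed 20,001-point grid over the
horizon (the default horizon is the life table's coverage). The floor is
applied after parameter identification, so specified points may no longer be
interpolated — that is the intended behaviour, and it is documented rather
than corrected. Evaluation beyond the horizon, or a horizon outrunning the
life table, raises a coverage error naming the last covered age.

## RMST and model averaging

RMST is the trapezoidal integral of the survival curve over [0, τ] on a
uniform grid (default 10,001 points; refining the grid moves the value by
less than 1e−6 relative for smooth curves). The horizon τ is an explicit
argument. Model averages are arithmetic means of member survival curves;
their hazard is the survival-weighted mean Σ h_i S_i / Σ S_i, which equals
−d ln S̄/dt exactly.

## Probabilistic sensitivity analysis

Interpolated parameters carry no sampling uncertainty of their own, so
uncertainty is borrowed from data: each family is fitted to uploaded
right-censored data by maximum likelihood (log-likelihood
Σ_events ln h(t_i) − Σ_all H(t_i)) on a transformed scale — log for strictly
positive parameters, identity for the Gompertz shape and log-normal meanlog
— and the inverse observed information provides the variance-covariance on
that scale. The exponential case is closed form: λ̂ = d/T with
var(ln λ̂) = 1/d. Two-parameter fits use BFGS with a Nelder-Mead fallback
and a final Newton polish on the numerically differentiated gradient until
its norm is below 1e−6 (BFGS alone stops early because the gradient scale
grows with n).

The covariance is then re-centred on the *interpolated* parameters and
sampled from a multivariate normal on the transformed scale, keeping all
draws in-domain; back-transformed draws are evaluated on a time grid and
summarised by pointwise 2.5/97.5 empirical percentiles over 1,000 iterations
by default. Any mismatch in curvature between the fitted and interpolated
centres is accepted as the method's stated approximation: the data's
uncertainty is a proxy for the extrapolation's.

For piecewise models the prefix has its own uncertainty with no standard
treatment; the bootstrap variant resamples records with replacement, rebuilds
the KM prefix and anchor, re-solves the tail through the re-anchored
conditional points and perturbs the tail with one covariance draw per
replicate. Replicates with no events, no follow-up beyond t₀, or an anchor
making the points infeasible are skipped and counted. The normal deviate for
each replicate is drawn before feasibility is known, so the random stream —
and hence reproducibility per seed — is independent of which replicates
survive.

## Synthetic data

The simulator draws event times by inverse-transform sampling through the
same quantile code path the rest of the package uses (one tested inversion,
no per-family special cases), with administrative cutoff and/or independent
exponential dropout. Improper families (negative-shape Gompertz, cure
mixtures) have an immortal fraction; those subjects are censored at the
cutoff, and simulation without any censoring mechanism is refused for such
families rather than looping forever.

The synthetic life table is Gompertz-Makeham, q_x = 1 − exp(−(A + B·c^x)),
with defaults A = 5e−4, B = 2.7e−5, c = 1.098 chosen to give a plausible
adult schedule (annual death probability ≈ 0.001 near age 30, above 0.1 by
the late 80s) and male hazards scaled by 1.4; q_x is capped at 0.999 with a
warning. It reproduces the *shape* of national tables, not any country's
actual rates — tests passing against it show the adjustment machinery is
correct, not that any specific population is represented.

The bundled example fixtures include a simulated uncensored exponential
dataset (n = 100) rescaled so its Kaplan-Meier median is exactly 7.7 months,
letting the data-anchored piecewise workflow reproduce the data-free one
exactly. Simulated datasets are idealised: no covariates, no informative
censoring, proportional nothing — properties demonstrated on them are
properties of the algorithms, not of any trial.

## Test and script problem sizes

The test suite exercises 500 random pairs for interpolation exactness, 200
pairs against an independent generic root-finder oracle (solving the
rearranged survival equations on the log-cumulative-hazard scale, where they
are well conditioned, from several neutral starts), and 200 repeated
simulated trials (n = 150, 1,000 PSA draws each) for band coverage at the
true median, checked against a 99% binomial interval around 0.95. These
sizes keep the full suite under ~10 s while leaving the stochastic checks
with comfortable power.

## Known limitations

* Exact interpolation only: no least-squares compromise across 3+ points,
  no preference weighting between early and late coordinates.
* No covariates, hazard ratios, left truncation, interval censoring or
  competing risks.
* The PSA transfers data uncertainty to interpolated centres on the
  transformed scale; when the interpolated curve is far from the fitted one,
  the borrowed covariance may under- or over-state the real uncertainty.
* Model choice is out of scope by design: the package reports every family
  that passes through the points and leaves plausibility judgements (hazard
  shape, external consistency) to the analyst.
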