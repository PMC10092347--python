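# Methods

## Model and parameterization

The package fits the cumulative probit model
Pr(Y ≤ j) = Φ(αⱼ − x′β) with strictly increasing cutpoints
α₁ < … < α_{J−1} and a unit-variance latent error. An equivalent
formulation puts an intercept in the linear predictor and shifts every
cutpoint by the same constant; all quantities computed here (surrogate,
McKelvey–Zavoina, McFadden R², likelihoods, bootstrap intervals) are
invariant to that location shift, so the standard intercept-free form is
stored and the mapping is: intercept c ⇔ cutpoints αⱼ + c.

Estimation is by damped Newton iteration on the exact log-likelihood,
which is concave in (α, β) for cumulative models with a log-concave link
(Pratt, 1981, *JASA* 76, 103–106). The score and Hessian are analytic;
steps that would break the cutpoint ordering or decrease the likelihood
are halved. The intercepts-only null model has the closed form
αⱼ = Φ⁻¹(cumulative frequency) with log-likelihood Σ fⱼ log(fⱼ/n), used
both as the McFadden denominator and as cold-start values. The fitter is
written in-package because the bootstrap experiments refit the model on
the order of 10⁵ times; warm-started refits take ~1–2 ms at n = 1000,
p = 10. Agreement with an independent general-purpose ordinal-MLE
implementation is pinned in the test suite to ≈1e−5 in log-likelihood.

Numerical choices:

* category probabilities are floored at 1e−300 before logs, so extreme
  fits yield large negative log-likelihoods rather than −∞ (keeps
  McFadden's index finite);
* interval probabilities Φ(u_hi) − Φ(u_lo) switch to log-CDF arithmetic
  when the interval lies in the far right tail (u_lo ≥ 5) or the plain
  difference underflows — otherwise Newton steps see zero probabilities
  and NaN ratios;
* ratios φ/P inside the score/Hessian use an additional 1e−12 floor on P
  (an optimizer safeguard only; likelihood values use the 1e−300 floor);
* a fitted standardized slope |β̂ₗ|·sd(Xₗ) > 40 is treated as complete or
  quasi-complete separation and raised as an error with the offending
  column named; non-convergence within the iteration budget is flagged on
  the fit object, never silently ignored.

Binary responses coded {0, 1} are normalized to {1, 2}; every level
1…J must be observed, otherwise interior cutpoints are unidentified.

## Surrogate sampling

Given parameters (α, β) and an observation with category j, the surrogate
is a draw from N(x′β, 1) truncated to (α_{j−1}, αⱼ]. Sampling is by
inverse CDF: u ~ U(Φ(a−μ), Φ(b−μ)) mapped through Φ⁻¹. When the whole
interval sits more than 8 sd into a tail the interpolation is done on
log-CDF values (`log_ndtr` / `ndtri_exp`, right tails by reflection), so
extreme linear predictors still produce finite draws. Boundaries have
probability zero; a draw landing exactly on one through floating-point
rounding is nudged one ulp into the interior, keeping the membership
invariant (every draw strictly inside its category interval) exact.

Seeding is counter-based: every stochastic routine derives its generator
from a `SeedSequence` over (master seed, context, index) — context 0 for
surrogate draws, 1 for bootstrap replicates, 2–4 for replication loops —
so results are independent of execution order and bit-reproducible. Point
estimates average the R² values of M = 30 draws (averaging the R²s, not
the surrogates); the default follows the multiple-sampling practice for
surrogate-based inference.

## The common-surrogate rule

Surrogate R² values for submodels always reuse the surrogate generated
from the full model; only the linear regression is restricted to the
subset columns. The submodel is *not* refit as a probit for this purpose
(McKelvey–Zavoina and McFadden comparisons *do* refit, which is exactly
what makes them non-monotone). With a common response, monotonicity along
nested models is an algebraic property of OLS and holds per draw, not
just on average; the API enforces the rule by rejecting evaluation
subsets that are not contained in the surrogate's full model. The
closed-form large-sample version
R²_{S,asym} = β̂′X₀′X_r(X_r′X_r)⁻¹X_r′X₀β̂ / (β̂′X₀′X₀β̂ + n) reduces
exactly to the McKelvey–Zavoina value when the subset is the full model,
and is tested at machine precision.

## Bootstrap interval

The percentile interval resamples rows with replacement, refits the full
probit (warm-started at the original-sample estimate), draws **one**
surrogate from the replicate fit, and computes the subset OLS R²; the
interval is the (α/2, 1−α/2) pair of type-1 (inverted-CDF) empirical
quantiles of the B = 2000 copies. One draw per replicate suffices because
resampling already averages over surrogate noise. Replicates that lose a
response category are redrawn and counted; a redraw rate above 5% aborts,
since quantiles from a censored resampling distribution would be
misleading. A McKelvey–Zavoina variant (refit the evaluation submodel per
replicate) exists solely for the comparison experiments; in the
strong-correlation design its intervals sit entirely above the population
limit and cover it with probability zero.

## Synthetic designs

The generators are the package's study conditions, not adjustable
fixtures:

* **example1** — binary, Pr(Y=1) = Φ(2 − X1 + 0.7·X2), X1 ~ U(−3, 3),
  X2 = X1 if X1 ≤ −0.2 else 2.8 − X1 (marginally U(−3, 3),
  corr ≈ .70; the analytic covariance 2.0898 is stored for limit
  calculations). The generator simulates the success-probability form
  literally and the fitting convention maps onto it as α₁ = −2,
  β = (−1, 0.7); the latent vector is returned for benchmarking.
* **setting1** — p = 10 equicorrelated (ρ = .2) standard normals,
  β = (.8, .7, .6, .6, .5, 0…0), cutpoints (1, 2.9), J = 3.
* **setting2** — p = 20, cutpoints (1.2, 3.6), β = .8/.6/.4 on X1/X3/X4
  and .5 on X11…X20, corr(X1, X2) = .7. Only that one pair is pinned
  down by the published design; all other pairs default to the setting-1
  value .2. Because that structure is partly a package choice, setting-2
  summary values are checked for self-consistency only.
* **setting3** — the example1 core plus two independent U(−3, 3) null
  covariates (their law is a package choice; being independent of Y, it
  does not move the targeted expectations).

Latent values and categories are generated jointly, so Y is exactly the
censoring of the returned z at the design cutpoints. What these designs
do *not* emulate about real data: covariate measurement error, missing
values, model misspecification of the full model, and non-normal latent
errors — passing tests say nothing about those regimes.

## Replication sizes and tolerances

The published tables average 2000 repetitions. The test suite and the
acceptance script use 200–500 repetitions (Monte-Carlo SE of the
replication means ≈ .001–.002, comfortably inside the ±.01–.02 bands
asserted) and the interval experiments use 100 replications at B = 2000
for the surrogate interval and 40 for the McKelvey–Zavoina breakdown
(whose claimed coverage is exactly zero, so moderate replication counts
are decisive). The choice trades a factor ~5 of Monte-Carlo precision for
a test suite that runs in minutes; every tolerance was set from the
stated precision of the targeted value, not from observed margins.

Two published side-quantities do not reproduce under their textbook
definitions and are deliberately not asserted: the setting-1 McFadden
means (.496 at n = 200 / .479 at n = 500 — the standard in-sample index
gives .52/.50 and the population value under the true parameters is
.485, so the printed pair straddles the population value and cannot come
from the in-sample definition) and the setting-1 accuracy row (argmax
classification has population accuracy .809 vs the printed .745). Both
measures are implemented with their standard definitions
(1 − ℓ/ℓ₀; argmax category probability, AUC for binary outcomes), and
the binary-design AUC values do reproduce (.951/.945/.500).

## Trimming workflow conventions

Step 1 drops covariates by Wald p-values from the full fit (normal
approximation, default threshold .05) — the original analysis stars
coefficients without naming the test, so this is a documented package
decision. Step 2 evaluates alternative collinearity-motivated drop sets
and keeps the cheapest in R². Percent reductions at every step are
relative to the *current working model's* R², not the step-0 value; this
convention is what makes a drop-one table read as "share of the working
model's explanatory power owed to this variable". All steps share the
step-0 surrogate bundle.

## Known limitations

* Probit link only; the surrogate idea extends to logit but that is out
  of scope here.
* No BCa or studentized bootstrap variants; percentile only.
* No weights, no missing-data handling (missing values are rejected).
* The surrogate R² is conditional on the specified full model; adding
  new covariates later requires regenerating the surrogate and
  recomputing every submodel value.
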