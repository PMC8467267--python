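# Methods

## The estimand

For a litigated occupant with crash profile x (delta V, direction of
force, airbag deployment, vehicle type and model year) the analysis
estimates two probabilities from a matched population cohort:

- p₁ = P(outcome | x, unbelted) — the actual scenario,
- p₀ = P(outcome | x, belted) — the counterfactual scenario,

and derives the relative risk RR = p₁/p₀, the attributable risk
AR = (RR − 1)/RR × 100% ≡ (p₁ − p₀)/p₁ × 100%, and the absolute risk
difference p₁ − p₀.  The outcome is death within 30 days of the crash, or
optionally any injury at or above an AIS severity cut (AIS 3+ "serious"
being the conventional threshold for non-nominal mortality risk).

## The legal decision rule

The civil "more probable than not" standard is a strict majority
standard: the analysis must show that more than 50% of the unbelted risk
would have been eliminated by the belt.  AR > 50% is algebraically
equivalent to RR > 2.0; both are applied as strict inequalities, so a
configuration sitting exactly at AR = 50% fails the gate.  The gate also
requires statistical reliability: the governing test is a two-sided Wald
z-test on p₁ − p₀ at α = 0.05, with standard errors carried from the
design-based model via the delta method.  The confidence-interval-overlap
heuristic (significant only if the two 95% intervals are disjoint) is
computed and reported alongside because it is what risk-curve charts show;
it is conservative and never governs the gate by default.  The two methods
can disagree, and the report surfaces both.

Only when the gate passes is a contributory share quantified, and the
share is the absolute risk difference: the exposed population for a
belt-non-use allegation is everyone in the crash, so survivors in both
belt groups dilute the attributable fraction down to the absolute excess.
Under the product-defect framing (`framing="product-defect"`, e.g. a latch
that failed during the injury event itself), the population at risk is
those who sustained the outcome, there is no intervening crash risk, and
the attributable fraction is the apportionment.  The gate is evaluated at
the point estimate of AR, with the interval printed beside it, so the
choice is visible rather than silently resolved.

A separate survivability note is emitted when both p₁ and p₀ exceed 50%:
death was then more probable than not regardless of restraint use, which
is itself a decisive medicolegal conclusion at very high delta V.

RR < 1 (non-use apparently protective, which genuinely occurs in
very-high-severity frontal cohorts where airbags and compartment intrusion
dominate) is reported as-is with a protective flag, never clamped.

## Cohort construction

Inclusion rules are applied in a fixed, declared order — role, crash
geometry (PDOF present and inside the clock arc), rollover exclusion, belt
knownness, airbag knownness, year range — and each excluded record is
charged to the first rule it fails, so the ledger conserves
n_in = n_out + Σ removals.  Permuting the rule order may shuffle per-rule
counts but provably never changes the surviving set (the rules are
conjunctive); a property test enforces this.  PDOF arcs are closed
(both endpoints included): a "9 to 11 o'clock" window keeps 270°–330°.
Records with missing delta V pass the filter and are dropped (and
counted) at fit time, keeping cohort membership and model usability as
separate, separately-reported decisions.

## The risk model

The model is a binary logistic regression

logit P = β₀ + β₁ΔV + β₂·unbelted + β₃·ΔV·unbelted + β₄·airbag
          [+ body-type dummies + centred model year + optional ΔV²],

fitted by iteratively reweighted least squares on the sampling-weighted
pseudo-likelihood (convergence when the largest coefficient step falls
below 1e-8 relative, maximum 100 iterations; a 1e-8 ridge is added to a
singular information matrix with a warning; runaway coefficients raise a
separation error naming the offending term).  Delta V enters linearly on
the logit scale by default; the ΔV × belt interaction is on by default
because the belted and unbelted curves in high-severity frontal cohorts
cross, which a main-effects model cannot represent.

Weights are treated strictly as sampling weights, never frequency
weights: they enter the score, and all uncertainty comes from the
Taylor-linearization (sandwich) estimator V = A⁻¹BA⁻¹, where A is the
weighted information and B pools between-PSU variation of weighted score
totals within strata with the with-replacement first-stage approximation
n_h/(n_h−1)·Σ_j (z_hj − z̄_h)(z_hj − z̄_h)ᵀ.  A stratum with a single PSU
cannot contribute between-PSU spread; its contribution is zero (its score
total centred at the stratum mean) and a warning is attached to the fit.
Risk estimates at a profile carry delta-method intervals computed on the
logit scale with the 1.959964 normal quantile and transformed back, which
guarantees the interval lies in [0, 1] and brackets the point estimate.
Profiles outside the fitted delta V support are evaluated but flagged as
extrapolations.

## The synthetic population generator

Real stratified crash samples are not redistributable, so the generator
provides populations with exactly known truth:

- **Delta V** ~ gamma parameterised by mode (default 12 mph) and standard
  deviation (default 11 mph), giving the right-skewed
  bell-with-sparse-upper-tail severity profile of towed frontal crashes;
  under the defaults 0.7% of crashes are at or above 56 mph, so a 56 mph
  case sits in the upper percentile of severity.
- **Death mechanism**: logit p = −5.45 + 0.12·ΔV + 0.52·unbelted −
  0.02·ΔV·unbelted − 0.30·airbag.  The defaults put both belt states in
  the 60–80% death-risk band at 56 mph with the curves crossing near
  26 mph (unbelted riskier below, belted riskier above), the qualitative
  pattern seen in high-severity frontal cohorts.  23% of drivers are
  unbelted; 25% have an airbag deployment; small fractions carry unknown
  belt/airbag status so knownness filters have work to do.
- **Sampling**: each record enters the sample independently with
  probability expit(−2.5 + 0.08·ΔV) (severe crashes oversampled, as
  police-report/tow-away criteria do), weight 1/Pr(inclusion), and a
  uniformly assigned PSU among 24 PSUs partitioned into 6 strata.  Sums
  of weights are therefore unbiased (Horvitz-Thompson) for the population
  size, which a 200-replicate Monte Carlo test verifies.

All randomness flows from the single integer seed; fixed seed means
byte-identical output.  What the generator does *not* emulate: real PSU
geography and year-specific weighting, correlation of airbag deployment
with delta V, non-frontal crash modes, misclassification of belt use, and
delta V measurement error.  Passing tests therefore demonstrate that the
estimators are correct under a faithful complex-sampling design — not that
any particular real-world cohort is well-specified by this model.

## Study sizes used in tests

Parameter recovery runs 100 replicate populations of 200,000 (a scale at
which the severity-biased sample is roughly 57,000 records) and requires
≤ 5% relative bias on the delta V and belt coefficients with 95% CI
coverage inside [90%, 98%].  The type-I study runs 200 replicates with the
belt effect and interaction set to zero and requires the Wald test at a
56 mph profile to reject in 2–10% of replicates.  The case-study scenario
uses a desk-scale population of 10,000 — about 30–60 crashes at or above
56 mph — which is the sparse-tail regime in which the confidence intervals
at 56 mph overlap and the non-significance-driven verdict emerges; at much
larger scales the same mechanism yields a significant (and protective-
direction) difference instead, which the decision layer also handles.

## Numerical and interface choices

- Canonical speed unit is mph; km/h is accepted on input via a flag and
  converted with the exact factor 1.609344.
- Canonical PDOF unit is degrees [0, 360), clockwise, 0° frontal; clock
  notation is accepted at every interface (hours·30 + minutes·0.5).
- AIS severity 7 ("unknown severity") never counts toward a maximum-AIS
  outcome; only the final digit of the 7-digit injury code is interpreted
  and the leading six digits are carried opaquely.
- Missing-value tokens on input: empty cell, `NA`, `unknown`
  (case-insensitive).  Unknown belt/airbag status is an explicit category
  because cohort rules test knownness; nothing is imputed.
- Malformed rows are collected into a reject report, never silently
  dropped; the reader refuses to proceed when more than 10% of rows
  reject (configurable).
- Ratios are displayed to one decimal and percents to whole numbers in
  narrative text, but every stored and serialised value is full
  precision.
- Report JSON is written with sorted keys so fixed-seed runs are
  byte-identical.

## Limitations

The analysis is conditional on the supplied crash reconstruction (delta V
and PDOF are inputs, not estimated here) and on the recorded 30-day death
flag.  Single-defendant apportionment only; no Bayesian posterior
probability of causation; linearization variance only (no jackknife or
BRR); no propensity balancing beyond the cohort rules.  Extrapolation
beyond the fitted delta V support is flagged but not prevented — at very
high delta V the data are sparse by nature and the report should say so.
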