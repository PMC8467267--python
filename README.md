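# crashcausal

Evidence-based quantification of the effect of seat belt non-use on crash
injury and death risk, for use in civil litigation.

When a crash-injury claim is defended on the theory that the claimant's own
failure to wear a seat belt caused or worsened their injuries (contributory
negligence), the question a court actually needs answered is counterfactual:
*given this specific crash — its delta V, direction of force, airbag
deployment, vehicle — how much more likely was the observed injury or death
because the occupant was unbelted, compared to the identical crash with the
belt worn?*  `crashcausal` answers that question with population data and
makes the legal decision rule explicit and reproducible.  It is written for
forensic epidemiologists, biostatisticians and expert witnesses who need an
auditable analysis they can disclose in full to the opposing side.

## The method

1. **Case-matched cohort.**  From a table of weighted occupant records (the
   interchange schema mirrors stratified national crash samples such as
   NASS-CDS: delta V, PDOF, belt use, airbag deployment, rollover, 30-day
   death, inflation weight, stratum, PSU), a cohort is selected that matches
   the litigated crash: occupant role, a planar frontal impact with PDOF in
   a clock arc (e.g. 9 to 11 o'clock), no rollover, known belt and airbag
   status, a year window.  Every exclusion is charged to exactly one rule in
   a conserved ledger.

2. **Survey-weighted logistic risk model.**  Death (or AIS-threshold
   injury) risk is modelled as

   logit P(death) = β₀ + β₁·ΔV + β₂·unbelted + β₃·ΔV·unbelted + covariates,

   fitted by pseudo-maximum likelihood with the sampling weights in the
   score, and design-based (Taylor-linearization / sandwich) variance with
   PSU-level clustering within strata — the same variance machinery as SAS
   SURVEYLOGISTIC or R `survey`, re-implemented here.  The interaction term
   lets the belted and unbelted risk curves cross at high severity.

3. **The decision calculus.**  With p₁ the risk unbelted and p₀ the risk
   belted at the case profile:

   - relative risk RR = p₁ / p₀
   - attributable risk AR = (RR − 1)/RR × 100% = (p₁ − p₀)/p₁ × 100%
   - absolute risk difference p₁ − p₀

   The civil "more probable than not" standard maps to a strict AR > 50%
   (equivalently RR > 2.0) gate, which must be met by statistically
   reliable evidence (a Wald test on the risk difference, with the
   CI-overlap heuristic reported alongside).  Only when the gate passes is
   the claimant's contributory share quantified — and it is the **absolute**
   risk difference, not the attributable fraction, because the exposed
   population is everyone in the crash: if unbelted occupants die 10 times
   in 10 million crashes and belted ones once, the non-use added 9 in 10
   million, not 90%.  (A product-defect framing, where the device failure is
   proximate to the injury and the attributable fraction applies, is
   available via `framing="product-defect"`.)

Because real stratified crash files cannot be redistributed, the package
ships a synthetic-population generator with a known logistic death
mechanism, a right-skewed delta V distribution, and severity-biased
sampling with Horvitz-Thompson weights, so every stage is testable against
exact ground truth.

## Worked example

```python
from crashcausal.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_dict({
    "seed": 7,
    "input": {"generator": {"n_population": 50_000}},
    "case": {
        "belt_used_actual": "not_used", "airbag_deployed": "deployed",
        "delta_v_mph": 56.0, "pdof_clock": [10, 30], "body_type": "pickup",
        "model_year": 2013, "peak_acceleration_g": 71.0,
        "cohort": {"pdof_window": [[9, 0], [11, 0]], "years": [2001, 2015]},
    },
    "model": {"include_body_type": False, "include_model_year": False},
})
result = run_pipeline(cfg, out_dir="demo_out")
print(result.report_text())
```

prints (abridged):

```
Cohort construction:
records in: 14298
  - excluded by crash_type_pdof: 10667
  - excluded by rollover: 75
  - excluded by belt_knownness: 100
  ...
records out: 3361

Case profile: delta V 56.0 mph, PDOF 315.0 deg, pickup, model year 2013, airbag deployed.
  risk if unbelted: 0.6014 (95% CI 0.4519-0.7342)
  risk if belted:   0.7558 (95% CI 0.6914-0.8105)
  relative risk: 0.7957 (reported 0.8)
  attributable risk: -25.67% (reported -26%)
  significance (wald_difference): not significant (z = -1.932, p = 0.0534)
  more-probable-than-not gate: NOT PASSED
  apportionment (contributory-negligence): 0.0000
```

Read: at this very high crash severity the estimated unbelted death risk
(60%) is *below* the belted risk (76%) — the curves have crossed — but the
confidence intervals overlap and the difference is not statistically
significant, so the only defensible conclusion is that belt non-use is not
proven causal at the >50% standard; both risks exceeding 50% additionally
supports a not-survivable-regardless opinion.  The same pipeline outputs
the plotting-ready risk curve (`risk_curve.csv`, risk by delta V for both
belt states with 95% bands), the exclusion ledger, the model with its
design-based covariance, and a narrative report whose every number is
traceable to the JSON.

A command-line interface mirrors the library: `crashcausal simulate`,
`filter`, `fit`, `quantify`, and `run --config case.json --out dir/`.

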