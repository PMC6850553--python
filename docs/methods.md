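# Methods

## Cohort construction

A *market* is one ingredient–route combination (furosemide–intravenous and
furosemide–oral are distinct markets). Keys are canonicalized by trimming,
upper-casing, and collapsing internal whitespace; multi-ingredient
combination products are keyed on the full ingredient string and flagged,
since no authoritative decomposition rule exists. The earliest NDA defines
the market's brand approval; generic entrants are **distinct ANDA
applicants**, each timed at its first approval — the quantity of interest
is the number of competing manufacturers, not the number of applications.
Applicants are not consolidated across corporate mergers.

Drug-product monographs attach on (ingredient, route); drug-substance
monographs describe the active ingredient itself and attach on ingredient
alone. When several match, the earliest official date wins.

Eligibility is a sequential flow-diagram cascade with first-failure
attribution: pre-1982 approvals (the source data carry no exact dates
before 1982, only a sentinel string), generic entry or loss of exclusivity
before 1998 (the sales panel starts in 1997 and market size needs the year
*before* the reference event), product monograph official before the NDA,
markets still under patent, markets unmatched to the sales panel, markets
without a therapeutic class, and OTC/discontinued products. Patent and
exclusivity status are input flags: no attempt is made to compute legal
status from litigation sources. Every step lands in an attrition ledger
whose counts telescope exactly; readers should audit `attrition.csv`
before trusting any downstream number.

## Models

All three estimands treat the therapeutic class as the clustering unit and
report 95% two-sided Wald intervals on the log scale.

* **GEE logistic / count models.** Population-averaged fits with an
  exchangeable working correlation (independence available as a config
  fallback) and sandwich variance. The count model uses Poisson
  mean–variance; no distributional commitment to Poisson is made — the
  sandwich variance keeps standard errors honest under the overdispersion
  that entrant counts always show. Point estimates from a log-link model
  with a correctly specified mean are consistent regardless.
* **Cox gap-time models.** Among markets with ≥ k generics, time from the
  k-th to the (k+1)-th approval, censored administratively at 2018-04-03.
  Exposure is a product monograph official before the k-th entrant. Ties
  are handled by Efron's method. Robust variance is clustered by class,
  also within route strata.
* **Design handling.** Adjusted fits drop markets with missing market size
  and count them (`n_dropped_missing`); zero-variance covariate columns are
  dropped automatically because they are collinear with the intercept.
  This is also how route dummies leave the design inside a single-route
  stratum, and why crude and adjusted fits coincide exactly when every
  covariate is constant. Market size enters as log10(dollars + 1); the
  transform is a config-level choice made because sales are heavy-tailed.
  Drug age is measured from NDA approval to the study end date, a
  time-fixed covariate.

The `sandwich_covariance` primitive (B⁻¹ · Σ_c s_c s_cᵀ · B⁻ᵀ over
cluster-summed score contributions) is exposed and tested against an
independently coded HC0 formula; the GEE and Cox fits use the equivalent
machinery inside statsmodels and lifelines.

Exposure timing is monotone by construction: monograph-before-first implies
monograph-before-second implies monograph-before-third. For a market with
fewer entrants than a timing requires, the monograph need only precede the
study end — a market whose monograph arrived after its only generic still
counts as "before second". Dates equal to the entrant's approval date do
not count (strict precedence).

## Counterfactual savings

The engine removes the monograph effect from exposed markets:
N_P = N_A / IRR (division is the only direction consistent with the
monograph *adding* entrants when IRR > 1), P_P = D(N_P)/D(N_A) · P_A,
predicted sales P_P · V_A, savings = predicted − actual, summed by year.
N_A for a market-year is the number of entrants approved by the end of
that year, so the counterfactual tracks the competition level that set that
year's price. Predicted counts stay continuous; the curve is interpolated
linearly between integer knots and extrapolated as constant beyond the
last knot; only the aggregate manufacturer difference is rounded, at the
total. Volume is held fixed — no demand response to price is modelled.
Savings are provably ≥ 0 row-wise whenever IRR ≥ 1 and the curve is
nonincreasing, monotone in the IRR, and additive over markets and years;
the tests assert all three.

The shipped competition–price curve is **illustrative only** (its shape —
a steep drop at the second entrant flattening toward ~25% of brand price
by ten entrants — is qualitatively typical of published analyses, but the
knots are invented). Any substantive use must supply an externally
estimated curve as a two-column CSV.

## Synthetic cohorts

The generator emits the three input tables in their native file formats at
known ground truth, emulating the analytic sample: 982 drugs in 30
therapeutic classes of uneven size (class weights decay geometrically, so
class-size sensitivity analyses bite), route mix fixed at the cohort
margins (3.2% inhalation, 18.6% intravenous, 56.3% oral, 9.5% topical,
12.4% other), product-monograph prevalence 40.3% with 51% of monographs
before the first generic (exposure prevalence ≈ 20.6%), substance
monograph prevalence 74.9%, NDA dates uniform over 1982–2004, log-normal
market sizes.

Outcome structure:

* a class-level frailty (sd 0.3 on the linear-predictor scale) induces
  within-class correlation;
* entrant counts are gamma–Poisson (negative binomial, dispersion 1.0 so
  the variance is roughly μ + μ²) with log-mean carrying the exposure
  effect (default IRR 1.53) plus covariate effects; the baseline mean 1.7
  matches the unexposed-arm average of the study sample. The exposure
  propensity depends mildly on route and market size, so crude and
  adjusted estimates genuinely differ;
* first generic entry falls 3–10 years after the NDA (forced past April
  1998 so the cohort is eligible by construction); later entrants follow
  exponential gaps with mean 245 days, chosen so the median 2nd-to-3rd gap
  (~170 days) sits between the two published stratum medians (180/163);
* monograph official dates are placed so the pipeline's exposure
  computation reproduces the planted indicator exactly — the planting is
  what lets recovery studies attribute any bias to the estimator rather
  than to exposure misclassification;
* the sales panel (1997–2016) prices each drug-year at a base price times
  the competition curve evaluated at that year's entrant count, with
  multiplicative log-normal noise; volume is log-normal around the
  market-size-implied level.

Two structural switches resolve over-determination that no single process
can avoid:

* `outcome_model`: under the count process the any-generic odds ratio is
  an emergent quantity, not a dial; logistic mode instead draws the
  indicator from a logistic model with the configured exposure
  coefficient (default OR 0.64) and draws the count conditionally. With
  frailty sd 0.3 the population-averaged attenuation of the log-odds
  coefficient is ≈ 0.007 — an order of magnitude inside the recovery
  tolerance.
* `timeline_model`: `count_driven` (default) places all drawn entrants
  within follow-up, so the count truth is exact; a drug with exactly two
  drawn entrants then *never* gets a third, and since exposure raises
  counts, that cure fraction contaminates the apparent third-entry hazard.
  `gap_hazard` mode instead gives every ≥2-entrant market an exponential
  time-to-third at h₀·HR^exposure with genuine administrative censoring —
  the Cox model's exact data-generating process — at the cost of the count
  no longer being pinned. Recovery studies use the mode that matches their
  estimand.

What the generator does **not** emulate: the strong confounding and
reverse causation of real data (drugs with many manufacturers attract
monograph donations), name-matching noise between data sources, authorized
generics, mergers, 180-day-exclusivity distortions of early entry timing,
and any real competition–price relationship. Passing recovery tests
therefore demonstrate that the estimators are unbiased with nominal
coverage *when their assumptions hold*, not that the published real-data
estimates are correct.

## Recovery studies and problem sizes

Each recovery study runs 200 replicates of 982 drugs (replicate r seeded
base_seed + r), fits the estimand on the full pipeline output, and
summarizes exp(mean log-estimate) and the share of replicate CIs covering
the truth. With per-replicate log-scale standard errors around 0.1, the
Monte-Carlo error of the mean is ≈ 0.007 — comfortably inside the 0.05
log-scale acceptance band. The whole battery takes a few minutes on one
CPU. Unit tests use smaller cohorts (150–400 drugs) where only structure,
not precision, is at stake.

## Numerical choices and edge cases

* Wald CIs with z = Φ⁻¹(0.975); no multiple-testing adjustment anywhere.
* GEE non-convergence, separation (|log estimate| > 30 or non-finite SE),
  a single cluster, an exposure with no variation, or a gap model with no
  events all raise a `FitError` carrying diagnostics; sensitivity runners
  record the error in the report instead of aborting the batch.
* Zero-length gap times are floored at half a day so the partial
  likelihood is defined.
* The Kaplan–Meier median is the first time survival ≤ 0.5 and is
  reported as "not reached" when survival never gets there; its CI uses
  the log-log transform of the survival band.
* Duplicate monograph rows deduplicate to the earliest official date with
  a logged warning; duplicate sales keys are a hard validation error.
* Vintage uses competition ranking (ties share the lower rank, next rank
  skipped).
* Rows with zero volume but positive dollars are flagged and skipped in
  the savings engine, never silently priced.

## Known limitations

* The class-size sensitivity thresholds (<10, <21, <54 drugs) are read as
  strict inequalities; with the generator's class-size distribution the
  smallest restriction can be unestimable, which the report records as
  such.
* The crude any-generic OR from a 2×2 table and the crude GEE OR can
  differ; the package reports the model-based crude fit.
* No proportional-hazards diagnostics, model selection, or price-volume
  feedback; the savings engine deliberately excludes demand response,
  rebates, and discounting.
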