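# Methods

`basalvig` analyses spontaneous adverse-event reports in the FAERS
quarterly data model for ocular safety signals of three long-acting basal
insulins.  This note records the models, the defaults and why, what the
synthetic generator does and does not emulate, and the numerical choices.

## Data model and cleaning

Quarterly extracts are `$`-delimited text tables read **by header name**
(the schema drifts across years; absent columns become missing fields).
Rows with stray `$` characters in free text are reconciled by column-count:
surplus splits fold back into the last column, short rows are padded, both
repairs are counted.

Deduplication reduces each case to its latest version in three steps:
rows sharing `(caseid, fda_dt)` collapse to one, the highest `primaryid`
per `caseid` survives, and cases on the official deleted list are removed.
Within the same-date collapse we keep the highest-`primaryid` row, which
makes the composite **order-invariant and idempotent** (asserted over all
permutations of adversarial fixtures).  Non-numeric `primaryid` values fall
back to zero-padded lexicographic comparison.

Completeness is **stage-specific** rather than global.  The signal stage
needs an adverse-event description (≥1 reaction PT) and a drug record; the
time-to-onset stage additionally needs full 8-digit therapy-start and event
dates; the regression stage drops nothing, because missing covariates
become explicit `missing` levels.  Rationale: requiring dates globally
would discard most of the corpus for analyses that never use them, and the
per-drug time-to-onset case counts then equal the endpoint cohort counts,
which is the behaviour large published FAERS analyses exhibit.  The
completeness filter and the primary-suspect restriction are both
per-report predicates, so their order only affects tally bookkeeping; the
pipeline applies the filter first and records every exclusion.

## Cohorting

Drug identification is case- and punctuation-insensitive substring matching
of lexicon patterns (ingredient plus trade names) against `drugname` and
`prod_ai`.  Substring is the default because FAERS free text carries dose
and device suffixes; exact matching is available for sensitivity analyses.
Combination products (the field names several ingredients) match but carry
a `combination` flag and are included by default; a row matching patterns
of two *different* target ingredients is `ambiguous` and excluded.

The ocular screen ships with the eight named preferred terms of the
full-corpus analysis (VISUAL IMPAIRMENT, CATARACT, BLINDNESS, MACULAR
DEGENERATION, EYE HAEMORRHAGE, DIABETIC RETINOPATHY, RETINOPATHY, DIABETIC
GLAUCOMA); the full 19-term screen was never published as a list, so the
remaining slots are user-supplied configuration.  The counting unit is the
deduplicated report throughout: a report contributes once to exactly one
cell of the fourfold table regardless of how many matching drug or
reaction rows it carries, and the default comparator is every other report
in the ingested store.

Age normalization: DEC ×10, YR ×1, MON /12, WK /52.14, DY /365.25,
HR /8766.  The ≥65 boundary goes to the `>65` bucket (the conventional
labels leave 65 itself ambiguous; documented here once).  Weight in LBS is
converted at 0.453592 kg.

## Disproportionality estimators

With cells (a, b, c, d), n = a+b+c+d and E = (a+b)(a+c)/n:

* **ROR** ad/bc with Woolf CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **PRR** [a/(a+b)]/[c/(c+d)] with its log-normal CI, and the Pearson
  χ² with Yates correction n(|ad−bc|−n/2)²/[(a+b)(c+d)(a+c)(b+d)], floored
  at 0 when |ad−bc| ≤ n/2.  The correction choice is configurable
  (uncorrected Pearson available) since published analyses rarely state it.
* **BCPNN IC** log2((a+½)/(E+½)); the observed/expected ratio has
  posterior Gamma(shape a+½, rate E+½) and IC025 is the log2 of its 2.5%
  quantile.  This is the gamma-Poisson credibility formulation; the
  original full-Dirichlet network formulation is out of scope.
* **MGPS** a two-component gamma mixture prior on the ratio, hyperparameters
  (α₁, β₁, α₂, β₂, p) fitted by maximizing the induced negative-binomial
  mixture marginal likelihood over the whole (PS drug, PT) pair universe.
  Optimization is L-BFGS-B on log shapes/rates and logit weight from the
  classical start (0.2, 0.1, 2.0, 4.0, ⅓) plus seven seeded perturbed
  starts; components are reported in ascending prior-mean order.  EBGM =
  exp(E[ln λ | a]) via the digamma closed form on the posterior mixture;
  EB05 is the 5% posterior quantile solved by bracketed root finding on
  the mixture CDF.  EB05 is a 5% quantile by convention even though some
  table legends call the lower bound a "95% CI limit" (2.5%); the quantile
  is configurable.  Caveat: the mixture is weakly identified — at 10⁴
  pairs individual hyperparameters can deviate tens of percent between
  replicates even when the implied prior (and hence EBGM) is stable.
* **Zero cells** make ROR/PRR non-estimable by default; Haldane +0.5 on
  all cells is an option.

Signal criteria: ROR CI lower bound > 1; PRR ≥ 2 with χ² ≥ 4; IC025 > 0;
EB05 > 1.  No multiple-testing correction is applied, matching standard
practice for these screens.  No age/sex stratification of MGPS is
performed (a configuration hook is reserved).

## Time-to-onset

TTO = event date − earliest full therapy-start date among THER rows linked
(via `dsg_drug_seq`) to the primary-suspect target drug, one sample per
report.  Same-day and negative intervals are excluded and tallied (reported
onsets start at day 1); partial dates are excluded, never imputed.

The two-parameter Weibull is fitted by maximum likelihood on (log shape,
log scale) — Nelder-Mead polish then BFGS at gtol 1e-10 — with 95% Wald
CIs from the numerically evaluated observed information on the log scale,
exponentiated back (always positive).  The model median is
scale·(ln 2)^(1/shape), reported next to the empirical median and an
empirical 2.5–97.5 percentile band (a display choice; the band definition
used by published tables is not standardized).  Classification uses the
shape CI: *early* if entirely below 1, *wear-out* if entirely above,
*random* otherwise — more conservative than the point-estimate rule, and
both shape and CI are reported.

## Regression

Per-report logistic model of endpoint presence on drug (reference insulin
degludec), sex, age group and weight group.  Weight bins default to
tertiles of the non-missing kilograms; with ~77–92% of weights missing, a
complete-case analysis would collapse the sample, so every categorical
carries an explicit `missing` level.  Fitting is maximum likelihood via
statsmodels' IRLS with Wald standard errors; a |coefficient| above 15 is
treated as complete separation and the term flagged non-estimable.  The
outcome is endpoint-vs-not among all target-drug PS reports (the
alternative endpoint-vs-other-ocular contrast is a configuration switch).

## Synthetic generator

The generator emits a FAERS-schema quarter plus ground truth.  Its defaults
are the package's reference study conditions, chosen once:

* per-PT association strengths: the full-corpus VISUAL IMPAIRMENT /
  CATARACT / DIABETIC RETINOPATHY reporting odds ratios per drug, converted
  to per-report probabilities against background rates 0.02 / 0.01 / 0.002
  by solving odds(p) = R·odds(q);
* demographic mix: 64.7% female, ~94% US, age N(60, 15) with 45%
  missingness, weight N(85, 20) kg emitted 90% KG / 10% LBS with per-drug
  missingness 0.884 / 0.768 / 0.915;
* onset laws: Weibull (0.40, 58.47 d), (0.31, 127.54 d), (0.44, 401.13 d),
  rendered as integer calendar-day intervals (≥1) and right-truncated at
  the 2025-Q2 data window, as any finite corpus is;
* report counts 2,000 / 2,500 / 8,000 target + 40,000 background — desk
  scale (the full corpus is ~10⁵ PS reports among millions), so cohort
  sizes, not rates, are scaled down;
* process noise: 10% of cases carry an extra earlier version (half with
  identical `fda_dt`), 2% are officially deleted, 10% of reports lose a
  date to 6-digit truncation; a planted protective odds ratio of 0.6 on
  the heaviest true-weight tertile drives the regression recovery checks.

Ground truth records the exact fourfold cells over surviving cases, the
planted onset intervals that survive the date filters, per-drug event
probabilities, and the duplicate/deleted ledgers, so pipeline recovery is
tested for **equality**, not approximation.

What it does not emulate: free-text drug-name noise beyond a small variant
list, reporting-trend dynamics (the Weber effect), MedDRA hierarchy
structure, correlated comorbidities, or diabetes-type composition.
Passing recovery tests therefore show the *pipeline arithmetic* is right
under realistic marginals — not that the estimators overcome real-world
reporting biases, which no spontaneous-report method can.

Two planted conditions interact by design: the target RORs are defined
against the *background* rate, while the pipeline's comparator is *all
other reports* (including the other insulins).  With all three cohorts
present the recovered RORs are correspondingly diluted — exactly as in the
real corpus, where glargine's bulk dominates the comparator; single-drug
configurations recover the planted value directly.

## Determinism and sizes

Every stochastic component (generator, GPS multi-starts) is driven by one
integer seed; identical seeds give byte-identical output files, which the
test suite asserts by hash.  The shipped analysis scripts and acceptance
checks run the generator at 400–5,000 target reports per drug with
backgrounds of 6,000–50,000 — sizes chosen so each script completes in
seconds while binomial error stays a small fraction of every planted
effect.  Known limitations: day-resolution rounding and window truncation
bias fitted Weibull shapes slightly upward at desk scale (classification
is unaffected); MGPS hyperparameters are weakly identified (above); and
the Wald CIs for Weibull parameters undercover for n below a few dozen,
where the fitter warns.
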