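# basalvig

Pharmacovigilance signal analysis of **visual-impairment adverse events
under long-acting basal insulins** (insulin degludec, insulin detemir,
insulin glargine) on FAERS-style spontaneous report data.

Spontaneous-report databases such as the FDA Adverse Event Reporting System
(FAERS) have no denominators, so drug–event associations are screened by
*disproportionality*: each (drug, event) pair is laid out as a fourfold
report table

|            | target event | other events | sum   |
|------------|--------------|--------------|-------|
| target drug| a            | b            | a + b |
| other drugs| c            | d            | c + d |

and compared against the database background.  `basalvig` implements the
full desk pipeline for this analysis, aimed at pharmacoepidemiologists and
methods researchers who want every step testable:

* **Ingestion** of the public `$`-delimited quarterly tables (DEMO, DRUG,
  REAC, THER, INDI, OUTC) with case-level deduplication — identical
  `(caseid, fda_dt)` rows collapsed, highest `primaryid` per case retained,
  officially deleted cases removed — and stage-specific completeness
  filters.
* **Cohorting** by primary-suspect (PS) role through name lexicons
  (ingredient + trade names, punctuation-insensitive substring match) and
  configurable MedDRA preferred-term sets, with `VISUAL IMPAIRMENT` as the
  primary functional endpoint.
* **Four estimators with standard signal criteria**:
  - ROR = ad/bc, signal when the 95% CI lower bound > 1;
  - PRR = [a/(a+b)]/[c/(c+d)], signal when PRR ≥ 2 and Yates χ² ≥ 4;
  - BCPNN information component IC = log2((a+½)/(E+½)) with
    E = (a+b)(a+c)/n and a Gamma(a+½, E+½) posterior on the
    observed/expected ratio; signal when IC025 > 0;
  - MGPS: empirical-Bayes geometric mean EBGM under a two-component gamma
    mixture prior fitted by negative-binomial marginal likelihood over the
    whole pair universe; signal when the 5% posterior quantile EB05 > 1.
* **Demographics and multivariate logistic regression** (drug with insulin
  degludec as reference, sex, age group, body-weight group; explicit
  `missing` levels since weight is absent in the vast majority of reports).
* **Weibull time-to-onset modelling**: days from therapy start to event
  onset fitted by maximum likelihood; shape < 1 (CI entirely below 1) is
  the *early failure* pattern — hazard highest right after initiation, the
  signature of early worsening of diabetic retinopathy under rapid
  glycemic correction.
* **A synthetic FAERS-schema generator** with planted ground truth
  (association strengths, onset laws, demographic mix, duplicate/deleted
  cases), so the whole pipeline is validated end-to-end without any
  download.

## Worked example

Generate the reference synthetic corpus and run the signal stage:

```bash
python analysis/01_simulate.py
python analysis/02_signals.py
```

which prints (seed 0):

```
visual impairment signals (report-level fourfold tables):
            drug    a      ROR  ROR_lo   ROR_hi     IC025     EB05  ror_sig  prr_sig  bcpnn_sig  mgps_sig
insulin_degludec  124  1.21609  1.0096  1.46481 -0.011473 0.996104     True    False      False     False
 insulin_detemir  165  1.30853  1.1118  1.54008  0.115412 0.997916     True    False       True     False
insulin_glargine 1713 11.89130 10.9500 12.91350  1.978400 3.969520     True     True       True      True
```

`a` is the number of deduplicated primary-suspect reports carrying the
endpoint term.  Glargine's planted association is the strongest and clears
all four criteria; the weaker degludec/detemir signals illustrate how the
comparator (which contains the other insulins) and the Bayesian shrinkage
temper small cohorts.  `analysis/03_demographics.py`,
`analysis/04_regression.py` and `analysis/05_tto.py` continue the flow:
the regression recovers the planted protective weight effect
(`wt_group[wt_q3]` OR 0.64, 95% CI 0.44–0.93) and the Weibull stage
classifies all three drugs as early failure.

The same flow is available as a CLI (`basalvig synth`, `basalvig run-all`,
per-stage subcommands) and programmatically via
`basalvig.pipeline.run(RunConfig(...))`, which also ingests real quarterly
extracts from a directory (`input_dir=...`).

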