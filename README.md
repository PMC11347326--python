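# faersig

Pharmacovigilance signal detection on FAERS quarterly extracts.

Spontaneous adverse-event reporting systems such as the FDA Adverse
Event Reporting System (FAERS) carry no denominator of exposed
patients, so drug safety signals are screened by *disproportionality*:
for each drug–event pair, the reporting frequency of the event among
the drug's reports is compared with its frequency in the database
background through a 2×2 contingency table

|                 | target term | other terms |
|-----------------|------------:|------------:|
| **target drug** | a           | b           |
| **other drugs** | c           | d           |

`faersig` implements the full screening pipeline used in FAERS safety
studies of single drugs — written for pharmacoepidemiologists who want
a tested, reproducible alternative to one-off analysis scripts:

- **Ingestion** of the dollar-delimited FAERS quarterly ASCII tables
  (DEMO, DRUG, REAC, THER) with partial-date handling.
- **Deduplication** by the FDA-recommended rule: per CASEID keep the
  report with the highest FDA receipt date, ties broken by the highest
  PRIMARYID.
- **Cohort selection** of reports naming the drug of interest as
  primary suspect, plus subgroup (sex, age band) and monotherapy
  sensitivity filters and a Table-1-style descriptive summary.
- **Four disproportionality statistics** per term, with positivity
  thresholds (all configurable):
  - ROR = ad/bc, 95% CI on the log scale; flag: a ≥ 3 and CI low > 1
  - PRR = [a/(a+b)]/[c/(c+d)] with Yates-corrected χ²; flag: a ≥ 3,
    PRR ≥ 2, χ² ≥ 4
  - BCPNN information component IC = log₂((a+½)/(E+½)), E = (a+b)(a+c)/N,
    with the Norén closed-form credibility bound; flag: IC025 > 0
  - MGPS EBGM, the posterior geometric mean of the relative reporting
    rate under DuMouchel's two-gamma mixture prior (fitted on the full
    drug–event corpus by marginal likelihood, canonical prior as
    fallback); flag: EBGM05 > 2
- **Weibull time-to-onset modelling**: days from the earliest
  day-precision therapy start to the event date, maximum-likelihood
  shape β and scale α with observed-information CIs, and failure-mode
  classification (β CI below 1 → early failure; containing 1 → random;
  above 1 → wear-out).
- **A synthetic FAERS generator** that plants known duplicates,
  signal terms with elevated relative reporting rates, Weibull onsets
  and partial dates, so every stage is verifiable against ground truth
  without downloading FDA data.

## Worked example

Run the whole pipeline on a simulated corpus (4000 cases, 10%
duplicates, a focal drug with two planted signal terms at relative
reporting rates 5 and 3, onsets from Weibull(0.74, 59.94)):

```sh
faersig run --simulate --seed 11 --out demo_run
```

prints the stage counts of the manifest:

```json
{
  "cohort_events": 1766,
  "cohort_reports": 588,
  "deduplicated_reports": 4000,
  "monotherapy_events": 1675,
  "monotherapy_reports": 559,
  "pt_terms": 60,
  "raw_reports": 4400,
  "soc_terms": 20,
  "tto_eligible": 495
}
```

4400 raw DEMO rows collapse to 4000 cases (the 400 planted duplicates
are removed exactly); 588 reports name the focal drug as primary
suspect, carrying 1766 distinct (report, PT) events. The PT-level
signal table (`demo_run/table3_pt_signals.csv`) starts:

```
term,cases,ROR (95% CI),PRR (chi2),EBGM (EBGM05),IC (IC025),...
PT_0005*,264,3.45 (2.94–4.04),3.08 (257.56),2.35 (2.12),1.24 (1.03),...
PT_0001,260,0.89 (0.77–1.02),0.90 (2.56),0.91 (0.82),-0.12 (-0.33),...
```

The planted rate-5 term `PT_0005` is flagged by all four methods
(asterisk); the most frequent background term `PT_0001` is not. The
time-to-onset fit (`table4_tto.csv`) recovers the generating Weibull:

```
n=495  median 38 days (IQR 12.5–95)  scale α 60.15 (53.48–67.66)
shape β 0.79 (0.74–0.84)  → EARLY failure
```

β significantly below 1 means the event hazard is highest in the first
weeks of treatment and declines — the "early failure" pattern that
motivates front-loaded safety monitoring.

The same pipeline runs on real extracts: put `DEMO.txt`, `DRUG.txt`,
`REAC.txt`, `THER.txt` (FAERS ASCII dialect) in a directory and call

```sh
faersig run --input-dir faers_2023Q1 --drug-name TRALOKINUMAB \
    --drug-name ADBRY --pt-soc-map meddra_pt_soc.csv --out results
```

with a user-supplied two-column `pt_term,soc_term` CSV for SOC-level
aggregation (MedDRA is licensed and not distributed here).

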