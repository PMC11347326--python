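# Methods

## Data model and deduplication

A FAERS quarterly extract is a set of dollar-delimited ASCII tables
keyed by PRIMARYID (one row per report version) and CASEID (one per
case). Column names are upper-cased on read; the `$` delimiter never
occurs inside a field, so no quoting layer exists. Dates are partial —
`YYYYMMDD`, `YYYYMM`, `YYYY` or blank — and are kept with explicit
precision; calendar-invalid values map to MISSING and are counted, not
raised. Only the post-2014 schema is supported.

Deduplication keeps, per CASEID, the row with the highest FDA_DT,
breaking ties by the numerically highest PRIMARYID. This is the
FDA-recommended practice for follow-up report chains. The operation is
idempotent and the output is sorted by CASEID for determinism.

Demographics are normalized at this stage:

- **Age**: AGE × unit factor (DEC = decades ×10, YR ×1, MON ÷12,
  WK ÷52.18, DY ÷365.25, HR ÷8766; a blank unit with numeric AGE is
  read as years, the common FAERS convention). Results outside
  [0, 125] years become null and are logged.
- **Age bands** are half-open — <18, [18, 65), [65, 85), ≥85 — so the
  bands partition the axis; published tables usually print the
  ambiguous "18–65 / 65–85 / >85".
- **Reporter**: OCCP_COD MD/PH/HP → healthcare professional; CN
  (consumer), LW (lawyer), OT (other) → non-healthcare; blank →
  unknown.
- **Quantiles** (median age, IQR, onset IQR) use linear interpolation
  between order statistics throughout.

The cohort is every deduplicated report with at least one DRUG row
whose normalized name (upper-cased, trimmed, trailing punctuation
stripped) contains any of the target names — substring matching by
default because FAERS verbatim strings embed brand names and
parentheses; exact matching is a flag. The role code must equal the
requested role (primary suspect by default). The monotherapy
sensitivity filter drops reports whose drug list contains anything that
does not match the target names. The **event counting unit everywhere
is one distinct (report, PT) pair**; SOC-level tables re-map events
through a user-supplied PT→SOC table, counting a report at most once
per SOC.

## Disproportionality statistics

Given the 2×2 table (a, b, c, d) with N = a+b+c+d and expected count
E = (a+b)(a+c)/N:

- **ROR** = ad/bc with 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
  A zero cell yields an undefined-statistic marker (NaN) rather than an
  exception; the Haldane–Anscombe +0.5 correction is available behind a
  flag but off by default.
- **PRR** = [a/(a+b)]/[c/(c+d)]; χ² is the Pearson statistic over the
  four cells with margin expectations, Yates-corrected by default
  (clamped at zero), matching common FAERS practice; a flag disables
  the correction. The uncorrected statistic equals the algebraic
  identity N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)], which the tests exploit as
  an oracle.
- **BCPNN IC** = log₂((a+0.5)/(E+0.5)); the lower 95% credibility bound
  uses Norén's closed form IC − 3.3(a+0.5)^−1/2 − 2.4(a+0.5)^−3/2.
  This gamma-approximation variant is the default for numerical
  robustness; the original 1998 beta-parameterized variant (posterior
  moments with a normal credibility bound) is selectable. The closed
  form tracks the exact gamma posterior quantile to <0.1 for a ≥ 3 and
  errs low (conservative) below that, where the penalty terms diverge.
- **MGPS**: the relative reporting rate λ has a two-component gamma
  mixture prior w·Γ(α₁, β₁) + (1−w)·Γ(α₂, β₂) (shape/rate). The
  marginal of a ~ Poisson(λE) is a negative-binomial mixture; the prior
  is fitted by maximizing the summed log marginal likelihood over the
  full drug–event corpus with L-BFGS-B on unconstrained transforms (log
  shapes/rates, logit weight), deterministic given the starting point.
  Non-convergence (after one retry from a neutral start) falls back to
  DuMouchel's canonical prior (0.2, 0.1, 2.0, 4.0, ⅓) with a warning;
  target-drug-only runs use the canonical prior directly, since a
  single drug's tables cannot identify a corpus prior. The posterior is
  the mixture of Γ(αₖ+a, βₖ+E) with data-updated weights; EBGM =
  2^E[log₂ λ | a] via digamma, EBGM05 = 5th posterior percentile by
  bracketed root-finding on the mixture CDF. EBGM05 is the standard
  5th-percentile definition, even though published tables sometimes
  label it a "95% CI lower limit". Note EBGM is a posterior *geometric*
  mean: for weakly-supported cells it can sit below 1 even when
  a/E > 1, because the canonical prior's geometric mean (≈0.19) is far
  below its arithmetic mean (exactly 1).

Positivity thresholds (each a config key): ROR — a ≥ 3 and CI low > 1;
PRR — a ≥ 3, PRR ≥ 2, χ² ≥ 4; BCPNN — IC025 > 0; MGPS — EBGM05 > 2. A
term is a potential signal when at least one method flags it. No
multiple-testing adjustment is applied — flags have raw-signal
semantics, the convention in spontaneous-report screening, and a signal
is a hypothesis, not a causal claim. The background is the same-window
set of deduplicated non-cohort reports.

## Time to onset

Onset = calendar days from the earliest day-precision therapy start of
a target-drug DRUG_SEQ to the DEMO event date; pairs with partial dates
or event-before-start are excluded and counted. Same-day onsets are
shifted to 0.5 day before fitting (Weibull support is positive); the
shifted count is reported.

The two-parameter Weibull is fitted by maximizing the log-likelihood in
(log α, log β) (Nelder–Mead polish then BFGS); 95% CIs come from the
observed information (finite-difference Hessian on the log scale),
back-transformed, giving asymmetric intervals on the natural scale.
The shape MLE of a complete sample is biased upward at small n, which
at spontaneous-report sample sizes (tens of onsets) materially erodes
the power to detect a declining hazard; the Ross-type unbiasing factor
(n−2)/(n−0.68) is therefore applied to the shape estimate and its CI
by default (≈0.2% at n = 1000, ≈1.8% at n = 74). `bias_correction=False`
returns the raw MLE, which the tests cross-check against
`scipy.stats.weibull_min.fit` and a dense grid search. A seeded
bootstrap CI is not implemented; the observed-information CI is the
single method, and the failure-mode call uses it: EARLY if β and its CI
upper bound are below 1, WEAROUT if β and the lower bound are above 1,
RANDOM otherwise.

The reported median and IQR of onset days are empirical sample
quantiles (matching how published tables present them); model-based
Weibull quantiles are also emitted under separate labels. The
cumulative incidence output is the empirical CDF plus a 30-day-bin
histogram.

## Synthetic corpus generator

The generator emulates the statistical structure the pipeline assumes,
not the content of real reports:

- Each case draws a drug (focal with probability `focal_drug_share`,
  default 0.15, else a uniform background drug among 20) and 1–5
  distinct PTs from a Zipf-like 60-term vocabulary. For the focal drug,
  selected PTs have their probability multiplied by a relative
  reporting rate ρ ≥ 1 and the vector renormalized.
- Duplicates (default 10% of cases) are re-emitted with a higher
  PRIMARYID and a later FDA_DT, copying their drug/reaction/therapy
  rows, so the deduplication survivor is well defined and resolvable.
- Onset days are Weibull(shape 0.74, scale 59.94) — the early-failure
  regime typical of injectable biologics — with the therapy start
  back-dated from the event date; a `partial_date_rate` fraction
  (default 15%) of events get month-precision dates and drop out of the
  time-to-onset set.
- Polypharmacy (default 5% of focal reports, mirroring the ~5%
  monotherapy-sensitivity attrition seen in single-drug FAERS cohorts)
  adds a concomitant background drug row.
- Demographics mirror a recent monoclonal-antibody safety cohort:
  sex M/F/missing = 38.5/60.5/1.0%, 44.4% missing age (otherwise
  normal(53, 16) clipped to [12, 95] years), US-dominant countries,
  ~65% healthcare-professional reporters. Report dates are uniform over
  the 2021Q4–2023Q4 window.

Everything is driven by one `numpy` generator seeded from the config,
so identical configs give byte-identical files. Ground truth (per-term
ρ, Weibull parameters, duplicate pairs, monotherapy flags, focal ids
and event counts) is emitted alongside.

What the generator does **not** emulate — and hence what passing tests
do not establish about real FAERS data: verbatim drug-name noise and
misspellings, correlated PTs within a report, reporting-latency
structure, masking/competition between signals, country- or
time-varying reporting rates, and indication confounding. One known
sampling artifact is documented: because a report carries a PT at most
once and draws up to five distinct PTs, frequent terms saturate, so the
*realized* disproportionality of a common injected signal term is
somewhat below its nominal ρ (a rate-5 term at baseline probability
0.04 realizes an odds ratio near 4); rare injected terms realize ρ
almost exactly, and recovery tests use them.

## Problem sizes and numerical choices

Simulation-based checks use corpora of 800–4000 cases, 200 replicates
for signal power, 1000 replicates for the n = 74 early-failure
classification rate, and 1000 random tables for the statistic oracles —
sizes chosen so the whole suite completes in a couple of minutes on one
CPU while keeping Monte-Carlo error well below the asserted margins.
Optimizer tolerances: L-BFGS-B tol 1e−8 for the prior fit; BFGS default
for the Weibull fit after a Nelder–Mead polish (xatol 1e−10); EBGM05
bisection xtol 1e−12. Ties in signal-table ordering break
alphabetically; equal dedup keys cannot occur (PRIMARYID is unique).

## Known limitations

- No censoring-aware survival modelling: spontaneous reports have no
  at-risk denominator, so the Weibull fit describes the distribution of
  *reported* onsets only.
- No probabilistic record linkage beyond the CASEID rule; true
  duplicates with different CASEIDs survive.
- SOC aggregation requires a user-supplied PT→SOC map (MedDRA is
  licensed); term matching is exact upper-case.
- The legacy (pre-2014 LAERS) dialect and the XML dialect are out of
  scope, as are OUTC/INDI/RPSR tables.
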