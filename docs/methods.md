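# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic registry does and does not
emulate, and the numerical conventions. It states no result that the test
suite or the analysis scripts do not themselves compute.

## Data model

A claims dataset is a stay-level table: patient ID, sex (F/M), the lower
bound of the patient's 5-year age band at admission, admission and
discharge dates, one primary and any number of secondary level-3 ICD-10
codes. Primary and secondary diagnoses are treated as equally relevant
throughout; a diagnosis' event time is the admission date of the earliest
stay carrying it (stays, not days, are the time resolution of the data).
Validation is structural: a code is accepted iff it matches letter A–N plus
two digits, the configured somatic-disease universe A00–N99. Codes outside
the universe are dropped and counted rather than rejected row-wise, because
a stay with an out-of-universe diagnosis is still a hospital contact (it
must, for instance, still trigger the washout rule). Four-character codes
are never accepted; there is no support for ICD-9 or outpatient records.

## Cohort construction

* **Washout.** Every stay of every patient with at least one admission in
  the washout window (default 1997-01-01 … 2002-12-31) is removed, so that
  diagnoses observed afterwards are plausibly incident. The filter is
  idempotent and reports removed/retained counts.
* **Age restriction.** Patients are kept if their 5-year band at first
  stay lies within the configured bounds. Bounds follow the 5-year grid of
  the data: the lower bound is a band start (multiple of 5) and the upper
  bound an inclusive age one below a band boundary — 20–79 for the main
  analysis, 20–49 / 50–79 for the menopause-motivated subgroup re-analysis.
* **Stratification.** Strata are (sex, 10-year age band, 2-year calendar
  period); with eight bands covering 0–79 and six periods tiling
  2003–2014 the key space is 48 per sex. Each patient belongs to exactly
  one stratum, keyed by their *first* observed stay, and carries their
  full-window diagnosis set. The alternative — letting one patient appear
  in several period strata — would make the CMH strata overlapping samples
  of the same people; the partition keeps them disjoint and matches the
  8 × 6 arithmetic. It is a declared convention, configurable only through
  the band/period lists.

## Co-occurrence screen

Per stratum and unordered pair (A, B), the patient-level 2×2 table
(a, b, c, d) = (both, A only, B only, neither). The inclusion rule is
strict — every cell must exceed 4 patients — and excluded tables are
dropped from pooling, not imputed. Pooling uses the Mantel–Haenszel
weighted averages for both the odds ratio and the risk ratio, the
Robins–Breslow–Greenland estimator for the standard error of log OR_MH
(the standard companion of MH pooling; any Wald interval built from it is
symmetric on the log scale, so the point estimate equals the geometric
mean of its CI bounds), and the CMH chi-square statistic (1 df) without
continuity correction — sample sizes in the intended regime make the
correction immaterial. These standard steps are delegated to
`statsmodels.stats.contingency_tables.StratifiedTable`; the test suite
checks them against independently hand-enumerated MH sums and the
hypergeometric moments of the CMH statistic.

Screening filters, all configurable: RR_MH > 1.5 and p < 0.01, applied per
sex with a pair retained when either sex passes (the screen looks for
comorbidities of either sex before comparing them; a "both" mode exists);
and ≥ 1000 patient-level occurrences of each code in each sex. Occurrences
count distinct patients, since the analysis is patient-level. No
multiple-testing correction is applied — the p < 0.01 threshold is taken at
face value, so isolated single-stratum false positives are expected and
visible in the demo output. Every pair, filtered or not, is emitted with
audit flags.

## Sex-difference statistic

SD = (ln ORm − ln ORf)/√(SEm² + SEf²), with SEs on the log scale, tested
two-sided against a standard normal. The two-sided choice is forced by the
tier table itself: the boundary |SD| = 2 corresponds to p = 0.0455, the
two-sided tail, not the one-sided 0.0228. Tiers are assigned from |SD| at
cutpoints {2, 3, 4, 5}; the sign is carried separately as the favored sex
(negative = stronger in women). Classifying on the magnitude is the only
reading consistent with reporting female-excess pairs as significant; the
SD-scale cutpoints are authoritative here, and the p-scale rendering of
the upper tiers is left to the formula (at |SD| = 4 the two-sided tail is
6.33e-5, at 5 it is 5.7e-7). A utility recovers SEs from printed 95%
intervals as (ln U − ln L)/(2·1.959964), which inverts the package's own
CI construction exactly.

## Time directionality

The gap between first diagnoses splits both-diagnosed patients into four
groups: same stay; |Δt| < 90 days; 90 ≤ |Δt| < 360; |Δt| ≥ 360 (months are
30 days, a year 360, and 360 itself falls in the over-one-year group).
Same-stay pairs have no order and are counted as ties; same-date firsts in
different stays are also ties, counted in the < 90-day group and flagged.
Ties enter neither directional count. Per group,
TOR = N(A→B)/N(B→A) (reciprocal under swapping the codes, infinite when
N(B→A) = 0 with a flagged value) and the p-value is the exact two-sided
binomial test at success probability ½, via the minimum-likelihood method
(`scipy.stats.binomtest`; enumeration-checked for n ≤ 12). No causal
reading is attached to a direction.

## Synthetic registry

The generator emulates what the screen needs from a claims registry:
sex (51% women), 5-year age bands (default uniform over 20–75), stays over
2003–2014 with a 1997–2002 washout window, per-(sex, band) baseline code
prevalences, planted pairwise odds ratios that differ by sex, and planted
diagnosis-order lags. Per patient: background codes are independent
Bernoulli draws at their prevalence; each planted pair draws A at its
marginal and B from conditionals tilted to hit a target odds ratio while
preserving B's marginal (closed-form quadratic, evaluated in a
cancellation-free form continuous through OR = 1); stay slots are
1 + Poisson(mean − 1) with admission dates uniform over the window and
lengths of stay Poisson-distributed; codes land on uniformly chosen slots
and only occupied slots become stays, since an admission always has a
primary diagnosis.

Two corrections keep the planted odds ratio exact in the *analyzed*
population rather than the notional simulated one:

1. **Observation correction.** A person with no diagnosed code never
   enters a registry. That thins only the neither-cell of a pair's 2×2
   table, by the probability 1 − q0 of carrying some other code, so the
   tilt targets OR/(1 − q0). With several planted pairs, q0 of one pair
   depends on the joint distribution of the others (their codes are
   positively correlated within a pair), so the joint probabilities are
   solved by fixed-point iteration; with one pair this is closed-form.
2. **Period anchoring.** When both codes of a pair are present they get
   dedicated stays, first event at lag max(1, round(Exp(lag_days_mean)))
   days before the second (direction A-first with probability
   `direction_prob`). The first event's date is copied from an existing
   stay slot, so the patient's first admission date — and with it the
   2-year period stratum — keeps exactly the same distribution as for
   every other patient; otherwise both-diagnosed patients would skew into
   early periods and bias the pooled estimate. Lags are truncated to the
   remaining window (and to ≥ 1 day, so direction_prob = 1 yields strictly
   ordered first diagnoses).

Washout violators (an independent Bernoulli fraction of patients) get one
extra pre-2003 stay carrying their earliest diagnosis, which preserves
first-diagnosis order; they exist to exercise the washout filter, which
must remove exactly them.

What the generator does **not** model: stay-level correlation beyond the
planted pairs (presence is generated at patient level, because the screen
is patient-level), mortality and censoring, seasonal admission patterns,
age- or period-varying effects, triple interactions, or any calibration to
real national prevalences. Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes — not that real
registries satisfy those assumptions. Coding-practice artefacts (the
strongest known threat to real-data validity) are out of scope.

Repeated same-code stays are not generated, so stays per patient in the
demo reflect each patient's diagnosis count rather than the slot mean; the
baseline summary reports the dispersion of such utilisation measures as a
population SD alongside the SE of the mean, and the Table-style column
uses the SD.

## Problem sizes and numerics

The bundled demo registry uses 50,000 simulated patients with three
planted pairs (female-excess 6 vs 4, male-excess 6.3 vs 7.2, neutral
4 vs 4) and a minimum-occurrence threshold of 200, the registry-scale 1000
rescaled to the cohort; parameter-recovery checks in the test suite use
200,000 patients (planted OR 3 in women vs 2 in men, direction probability
0.9) over 20 seeded replicates, sizes at which per-sex Wald intervals are
a few percent wide so systematic generator bias would be visible as
coverage failure. Tilt conditionals are validated to recover the target
OR to 1e-8 relative error; CI log-symmetry holds to 1e-12; determinism is
guaranteed by a single `numpy` Generator per run seeded from the config
(the pipeline manifest echoes config and seed, and reruns are
byte-identical). Degenerate inputs fail loudly: zero-denominator crude
estimates, all-excluded table sets, empty binomial samples and infeasible
tilts raise typed errors naming the offending pair and stratum.
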