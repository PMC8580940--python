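# Methods

## Analysis model

`pvsignal` performs a report-level disproportionality analysis of a
spontaneous-reporting database for one drug of interest against a
comparator drug class.  The unit of analysis is the individual case
safety report (ICSR): a report contributes at most once to any
drug–event count however many times a preferred term (PT) appears among
its reactions.  The underlying assumption of all disproportionality
methods applies: reporting rates, not incidence rates, are compared, so
the output is a screening statistic, never a risk estimate.

### Case selection

A report enters the analysis set when all of the following hold: its
receive date lies inside the study window (inclusive at both ends); it
is serious (at least one seriousness criterion) when seriousness is
required; it carries at least one drug entry that is either the target
drug (exact ATC code) or a comparator-class drug (ATC prefix), with a
*suspected* or *interacting* role — purely concomitant involvement
never qualifies; its age is present and at least the adult threshold
(strictly-below-18 is excluded, so exactly 18.0 is included); and it
has at least one informative PT (non-empty and different from the
`"no adverse event"` sentinel).  Exclusions are logged under the first
failing rule in the fixed order (window, serious, qualifying drug,
missing age, under-age, no PT); the included set itself does not depend
on that order.  Reports carrying both the target drug and comparator
drugs are assigned to the target arm (target priority), which matches
how single-drug case series are counted in practice: the target case
count includes reports with co-suspected drugs.

### Statistics

For each PT within an age stratum (default cut: 75 years, boundary in
the older group), with 2×2 cells `a, b, c, d` and margins fixed by the
arm sizes:

* `PRR = [a/(a+b)] / [c/(c+d)]`, 95% CI
  `exp(ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))` with
  `z = 1.959964`.  No continuity correction: `a = 0` or `c = 0` makes
  the PRR *not estimable*, rendered `NA`; estimable-but-not-significant
  renders `NS`.
* `IC = log₂((O+0.5)/(E+0.5))` with `O = a`,
  `E = (a+b)(a+c)/N`, `N = a+b+c+d`, and
  `IC025 = IC − 3.3(O+0.5)^−1/2 − 2(O+0.5)^−3/2`, the closed-form
  credibility approximation of the shrunk observed-to-expected measure.
  It is finite at `O = 0` and the bound always lies below the point
  value.

The expected count `E` is computed inside each age stratum of the
analysis set formed by the two arms, i.e. against the
comparator-class-restricted reference, which is the stated reference
group of the analysis; widening the reference is achieved by passing a
broader comparator set, no separate flag is needed.  The
`"no adverse event"` sentinel is never tabulated as an event.

### SDR rule and triage

A pair is a signal of disproportionate reporting (SDR) when `IC025 > 0`
**and** `PRR lower bound > 1`, with at least 3 observed cases; all three
thresholds and the and/or combination are configurable.  The IC
threshold default is 0 — the standard operating criterion for the
shrunk IC — rather than 1: the dual criterion is already conservative,
and published analyses of this design flag pairs with IC025 barely
above 0.  A threshold of 1 remains one constructor argument away.
The minimum-case rule is applied per analyzed stratum.

Expert expectedness review is modelled as two disjoint reference lists
of PT labels: *expected* (well described in the product label) and
*non-signal* (alternative explanation).  Every SDR whose PT is on
neither list is a *potential safety signal*.  Tallies are reported per
stratum with percentages of assessed SDRs; per-stratum outcomes can be
collapsed to unique drug–event pairs.  The package makes no clinical
claims: the lists are inputs.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not pharmacological reality.  Per report it draws demographics, region,
reporter, a seriousness set, a receive date, drugs and PTs:

* **Age**: two-component normal mixture, components (66, sd 9) and
  (80, sd 6) with weights 0.58/0.42, truncated to [18, 99].  These
  defaults put the median near 72.9 and the share aged ≥75 near 42.6%,
  the population profile of a serious-only extract for a drug
  prescribed mostly to elderly patients.
* **Sex/region/reporter**: categorical draws with defaults 64.9% male
  (≈64.2% after 1% missingness), two-thirds North America, 57%
  healthcare-professional reporters.
* **Seriousness**: independent per-criterion Bernoulli draws (death
  0.164, life-threatening 0.038, hospitalization 0.562, disability
  0.012, other-medically-important 0.241).  A report drawing no
  criterion is assigned *other medically important*, keeping the
  extract serious-only; the 0.241 is calibrated so that the realized
  marginal of that criterion lands near 0.505 after the fallback.
  A `nonserious_rate` flag adds non-serious contamination to exercise
  the seriousness filter (default 0).
* **Drugs**: the target drug with probability `target_drug_share`
  (default 0.3), else one of 13 weighted comparator-class drugs.
  Target reports receive 0/1/≥2 co-suspected comparator drugs with
  probabilities 0.847/0.100/0.053, and an indication drawn from a
  haematology-weighted list (65% chronic lymphocytic leukemia, 8%
  missing).
* **Reactions**: `1 + Poisson(mean_pts_per_report − 1)` PTs (mean
  exactly the configured value, minimum 1) sampled without replacement
  with probability proportional to `baseline_probability × multiplier`,
  via Gumbel top-k keys vectorised per group of reports sharing the
  same active signals.  An injected signal's multiplier applies when
  its drug is on the report and the patient's (true, pre-missingness)
  age falls in the signal's stratum, so stratum-restricted signals
  produce SDRs in one age group only.
* **Corruption**: age and sex are blanked independently (defaults 3%
  and 1%), and 0.5% of reports have their reactions replaced by the
  `"no adverse event"` sentinel.

The default vocabulary holds 200 PTs with baseline probabilities
log-spaced over 2.5 orders of magnitude and normalised to sum to
`mean_pts_per_report` (default 2.0).  Under that normalisation the
marginal probability that a PT appears on a report is approximately its
baseline, and an injected multiplier `m` raises it approximately
`m`-fold, which is what makes `truth_table` directly interpretable; the
approximation degrades if baselines are large or their sum departs from
the mean PT count.  All randomness flows from a single seeded
generator; identical configurations give field-identical databases.

**What the generator does not emulate**: duplicate reports, reporting
trends over time, drug–drug interaction structure, correlated events
within a report (beyond sampling without replacement), country-specific
reporting cultures, or realistic MedDRA term granularity.  Passing
tests on synthetic data therefore demonstrate the *statistical*
correctness and calibration of the pipeline, not performance on any
real database.

## Numerical and convention choices

* Percentages are rounded half-up to one decimal, the convention of
  printed characteristics tables; a section with k labels can
  accumulate up to 0.05·k of rounding slack around 100%.
* Quartiles default to median-unbiased interpolation
  (`h = (n + 1/3)p + 1/3`); the convention is configurable via any
  `numpy.quantile` method name since published tables rarely state
  theirs.
* Dates are ISO-8601 at day precision; window filtering is inclusive.
* The TSV extract is UTF-8 with header row, empty cell = missing,
  seriousness criteria `"|"`-joined; reading validates referential
  integrity (no silent row drops) and round-trips all fields exactly.
* Output ordering is deterministic everywhere: PTs ascending within a
  stratum, younger stratum first.

## Validation design and problem sizes

The statistic implementations are checked for exact (1e-9) agreement
against from-scratch recounts of raw report lists on 100 randomized
small databases (≤500 reports, 25 PTs).  Calibration and recovery use
20 replicates of 50,000 reports and 200 PTs each: under the null the
dual SDR criterion flags well under 5% of testable pairs (observed
≈0.3%), and injected 10-fold associations with expected observed count
above 20 are recovered in ≥95% of replicates, with stratum-restricted
injections flagged only in their stratum.  These sizes give the
experiments stable empirical rates while keeping a full run in the
low minutes on a laptop; the acceptance script reruns all of them from
scratch.

## Known limitations

* Disproportionality statistics inherit all spontaneous-reporting
  biases (under-reporting, notoriety effects, channelling); the package
  quantifies reporting imbalance only.
* The closed-form IC025 is an approximation to the Bayesian posterior
  quantile of the shrunk IC; it is the published operational formula,
  accurate to the displayed precision at the counts used here, but not
  an exact posterior computation.
* Expectedness triage is a lookup against user-supplied lists; no
  label parsing or causality assessment is attempted.
* The age-stratified design mitigates confounding by age only;
  indication and comorbidity confounding are out of scope.
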