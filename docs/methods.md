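# Methods

This note documents the modelling choices behind `rfskit`: what each stage
assumes, which knobs matter, what the simulator does and does not emulate,
and where the design was genuinely open.

## Indicators and landmarks

Events before the landmark date — definitive surgery plus 6 calendar
months by default (12 and 18 are supported) — are attributed to primary
treatment and never count as recurrence evidence. Calendar-month addition
clamps the day of month (Aug 31 + 6 months → Feb 28/29) so the landmark is
deterministic and independent of any date library's rollover convention.
For the small fraction of patients without definitive surgery, the
diagnosis date anchors both the landmark and RFS.

Nine default indicators are extracted per patient. Dated indicators
(second surgery, second radiation, new chemotherapy episode, post-landmark
imaging, post-landmark biopsy) carry the earliest qualifying event date; a
chemotherapy episode requires at least three administrations ("more than
two cycles", one administration = one cycle). The visit-cluster indicator
fires on the earliest anchor visit on/after the landmark such that at
least 3 oncology visits fall within 90 days of it, and carries the
`[first, last]` window of those visits; both thresholds are configuration,
not claims about any particular health system. Death, breast-cancer death
and stage III are copied from the baseline table; they carry the death
date or nothing. Hormone dispenses are modelled in the data layer but off
by default as an indicator, because routine adjuvant endocrine therapy
continues for years after primary treatment and would fire near-uniformly;
`include_hormone=True` enables it.

Raising the landmark is monotone by construction: every detector counts
events on/after the landmark, so a later landmark can only turn indicators
off. This is the property that makes the 6-vs-12-vs-18-month comparison
meaningful.

## The classifier

The classifier is a from-scratch CART over boolean features: greedy
recursive partitioning maximising the decrease in Gini impurity
`1 − Σₖ pₖ²`. Because every feature is binary there are no thresholds to
search and no predicted probabilities to re-threshold afterwards, so the
three operating points are produced by a single mechanism: an observation
weight `w` on recurrent-class rows entering both the split criterion and
the leaf majority vote. The presets are `w = 4` (high sensitivity),
`w = 1` (high accuracy) and `w = 0.5` (high PPV). How the original
operating points were obtained is not documented; per-class re-weighting
is this package's design, chosen because it reproduces the intended
sensitivity/PPV trade-off with one interpretable parameter.

Numerical conventions, all chosen for determinism: equal-gain ties break
to the earliest column in the documented indicator order; an exactly tied
leaf vote goes to the recurrent class (favouring sensitivity); each
indicator is tested at most once per path; splitting stops at depth 5, at
a weighted-pure node, at zero gain, or when a child would fall below
`min_leaf = 10` raw observations (a conventional floor at the ~600-patient
scale this targets). Trees serialise to an indented text format
(`indicator? / yes: / no:`) so a fitted rule can be read, versioned and
edited by eye.

## Dating and RFS

A flagged patient's recurrence date comes from the *triggering* indicator:
the last node on the decision path answered "present". Dated indicators
contribute their evidence date; the visit-cluster window contributes
`start + ⌊(end − start)/2⌋` (floor keeps odd spans deterministic). When
the trigger is undated (death status, cause of death, stage) — or when a
recurrent leaf is reached without any "present" answer — the fall-back
chain is: earliest evidence date among the patient's present dated
indicators, else the cluster-window midpoint, else the death date, else
the midpoint of the landmark-to-last-contact interval. The chain is this
package's invention; the source method is silent on dating when the
triggering node carries no date, and the chain is ordered to prefer
evidence tied to actual care events over pure interval guesses. A
recurrent call with no evidence and no post-landmark follow-up raises a
dating error rather than silently going undated.

RFS is counted in integer days from definitive surgery (diagnosis when no
surgery) and converted to months (30.4375 days) only at reporting
boundaries. Non-recurrent calls are censored at the last known date;
death without recurrence is censoring, not an event.

## Validation battery

* Confusion metrics are reported to one decimal with round-half-up.
  `reconstruct_confusion` inverts printed sensitivity/specificity into the
  unique integer confusion matrix given the gold class split, which is how
  the derived metrics (PPV, NPV, accuracy, flagged and censored counts)
  are tied together arithmetically.
* The timing-agreement table bins |estimated − gold date| at ≤1, 1–2, 2–3,
  3–6 and >6 months. Gold-recurrent patients the algorithm misses are
  assigned to the >6 bin, so every gold-recurrent patient is accounted
  for; this is the only convention under which the table's marginal total
  stays fixed across operating points that flag different numbers of
  patients.
* RFS lengths are compared with a two-sided rank-sum test (exact
  distribution when both groups are below 20 without ties, normal
  approximation with tie correction otherwise); a paired signed-rank
  variant is available behind a flag since the original description does
  not say which was used. The primary comparison uses all patients'
  RFS lengths (censored times included); the recurrent-only subset is
  selection-biased toward early recurrences and is not the headline test.
* Kaplan–Meier, log-rank and Cox proportional hazards are delegated to
  lifelines; Cox uses the Efron tie convention, appropriate for day-grid
  data with many ties. The log-rank comparison of estimated-vs-gold curves
  is over the *same* patients — the two samples are not independent — and
  the written report flags that caveat; the standard two-sample test is
  applied regardless, matching how such comparisons are reported in
  practice.
* Cox concordance compares, per covariate, the hazard-ratio direction
  (coefficient sign) and the 5%-level significance verdict between the
  gold-based and algorithm-based fits. The default covariate set is age
  group, stage, ER/PR/HER2, grade, diagnosis-year group, and receipt of
  chemo/radio/hormone therapy derived from the event stream; histology is
  not part of the baseline schema and is omitted. Models that fail to
  converge retry once with a small ridge and are otherwise flagged and
  excluded from the match fractions.
* Characteristic tables use chi-square (Fisher's exact on 2×2 tables with
  any expected cell below 5) for categorical variables, and a t-test or
  rank-sum for continuous variables depending on a Shapiro normality
  check.

## The simulator

The generator draws, per patient: covariates from the target-population
marginals (stage 0–I/II/III at 15.9/52.0/32.1%, mastectomy 72.6%, no
surgery 0.8%, and matching grade/receptor mixes); a diagnosis date in
2007–2014; follow-up from a shifted gamma (shape 6, scale 0.6243 y, shift
0.46 y, floor 0.5 y) calibrated once to a 4-year median with a 2-year
quartile width — a skewed law cannot also hit the symmetric printed
quartiles exactly, so median and IQR width were prioritised (achieved
quartiles ≈ 3.09/4.00/5.09 y). Recurrence risk follows a logistic model in
stage, grade-3 and HER2 whose intercept is bisection-calibrated per cohort
so the mean risk equals 20.2%; this is what gives the Cox comparison
non-trivial covariate effects to agree on. Recurrence latency is 180 days
plus a Weibull (shape 1.3, scale 1141 days), placing ~80% of recurrences
within 5 years of surgery with an early-peaked hazard.

Trajectories are piecewise-homogeneous Poisson processes: primary workup
and treatment (chemo cycles every 21 days, radiation fractions, hormone
dispenses for most ER-positive patients), background surveillance (2.5
visits/y, 0.6 imaging/y, 0.05 biopsies/y), and — for recurrent patients —
a second wave starting an administrative lag of U(0, 60) days after the
true recurrence date: a 12 visits/y burst for ~6 months, re-imaging
(p=0.9), re-biopsy (p=0.7), second surgery (p=0.35), a new chemo episode
(p=0.5) and second radiation (p=0.3). Two noise channels keep the
classification problem honest and the operating points genuinely distinct:
7% of recurrences are administratively silent, and 5% of non-recurrent
patients get a benign false workup (visit burst plus imaging, sometimes
biopsy, never a second treatment). Breast-cancer death follows recurrence
with hazard 0.45/y; other-cause death (0.005/y) can strike anyone, and
death truncates the event stream and sets the last-contact date.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: real billing/procedure code vocabularies and
their mapping noise, second primary cancers (indistinguishable from
recurrence by this method), local-vs-distant recurrence types,
comorbidity-driven utilisation, non-stationary visit rates, and cancer
deaths without a documented recurrence (which occur in real registries).
Results on simulated cohorts demonstrate internal consistency of the
pipeline under its own generative assumptions, not field performance.

## Problem sizes and determinism

All randomness flows through a single seeded `numpy` generator per
simulated cohort; the same parameters and seed give a byte-identical
cohort. The bundled tests and the acceptance script run at the method's
natural scale — 598-patient cohorts, with the multi-seed operating-point
comparison using 20 replicate cohorts and a 50/50 train/held-out split —
which completes in seconds on one CPU. Property checks (Gini/split-gain,
cluster detection, rank-sum vs exact permutation) use 1000 random
instances against independent brute-force oracles.

## Known limitations

* The induced trees are re-fitted on whatever cohort is supplied; the
  original published tree topologies are not transcribed, and no pruning
  or surrogate splits are implemented.
* The dating fall-back chain, the cluster window convention, and the
  operating-point weight presets are documented package choices where the
  source description is silent; they are exposed as configuration.
* Undated-trigger dating leans on the earliest dated evidence, which in
  data with routine surveillance imaging can pre-date the true recurrence
  by months; the median dating error among true positives remains well
  within a quarter at default noise levels, but the tail is long.
* Cox concordance on covariates with near-zero true effects is fragile by
  nature (the sign of a ~0 coefficient can flip under small call
  disagreements); the direction-match fraction should be read jointly
  with the hazard-ratio magnitudes in the report.
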