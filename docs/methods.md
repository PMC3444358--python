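# Methods

## Case-finding model

A *criterion* is a count predicate over one administrative event stream:
at least `min_count` qualifying events inside the lookback window
`(index_date − lookback_days, index_date]`. The window is half-open on
the far side and includes the index date; an event exactly
`lookback_days` before the index date is outside. "Preceding 5 years" is
encoded as 1826 days and "preceding 12 months" as 365 days; both are
ordinary config fields, not constants.

The three default criteria differ deliberately in their counting rules:

| criterion | stream | window | count rule |
|---|---|---|---|
| a | hospital contacts, chronic-lung ICD-10 codes | 1826 d | ≥ 1 event |
| b | prescription redemptions, ATC R03 | 365 d | ≥ 2 events, same-day repeats count |
| c | spirometries | 365 d | ≥ 2 **distinct dates** |

The asymmetry between b and c is intentional: a drug "redeemed at least
twice" is a statement about dispensing events, whereas "spirometries on
different dates" is a statement about calendar dates. Criterion a counts
any contact setting (inpatient, outpatient, emergency) and any diagnosis
position; optional `settings`/`diagnosis_roles` restrictions are provided
because registries differ in what a contact row means.

Eligibility is evaluated at the index date: completed age (birthday-based)
must reach `min_age_years` (35) and, when `require_alive` is set, the
person's death date must not precede the index date (death on the index
date counts as alive). Ineligible persons are never identified, whatever
their events.

Code matching is prefix matching after normalization (uppercase, strip
punctuation and spaces). The shipped ICD-10 list (J40–J47 chronic
lower-respiratory disease plus J96 respiratory failure) and ATC list
(R03, obstructive-airway drugs) are editable defaults chosen to be
clinically plausible cover for "chronic lung disease" and
"lung medication"; they are **not** a canonical validated code set and the
config file says so.

## Candidate enumeration and selection

`enumerate_algorithms` produces every OR-combination of 2–4 criteria from
a pool (sizes configurable), deterministically named and ordered.
`select_algorithm` scores each candidate against a reference case list by
PPV = |identified ∩ reference| / |identified| with an exact CI, and picks
the maximum-PPV candidate, breaking ties by fewer criteria and then by
name. Putting PPV before simplicity is a design choice: "simplest with
the highest PPV" is ambiguous when the two conflict, and predictive value
is the quantity the selection is meant to optimize; because an inert
extra criterion leaves PPV unchanged, the simplicity tie-break is what
prevents gratuitous criteria. A candidate identifying nobody has
undefined PPV, is reported as such, and ranks last.

## Validation statistics

* **Exact intervals.** Every proportion carries a Clopper–Pearson
  interval (beta-quantile form). The method reproduces, to within one
  rounding unit, the printed intervals of the validation study this
  machinery is patterned on, and is exact at the x = 0 and x = n
  boundaries. The method label is stored in every estimate.
* **Standardized PPV.** `PPV(π) = Se·π / (Se·π + (1−Sp)(1−π))`. This is
  algebraically identical to the 2×2 PPV when π is the sample prevalence
  (a property test asserts it), and lets PPV be restated at an assumed
  population prevalence — 9 % overall by default, the published Danish
  estimate for ages 45–84. Its CI is a delta-method propagation of the
  binomial variances of Se and Sp, clipped to [0, 1] and labelled
  `bayes-delta`; it is approximate, unlike the exact intervals elsewhere.
* **Age strata.** Bands 35–44 … 75–84 plus open-ended 85+. The
  prevalence source covers 45–84 only, so the 35–44 band borrows the
  45–54 prevalence and the 85+ band the 75–84 one; each output row
  records what was borrowed.
* **Verification.** Outcomes are confirmed / unsure / rejected.
  `ppv_definite` = confirmed/n; `ppv_broad` = (confirmed+unsure)/n.
  Broad ≥ definite always.
* **Comparisons.** Two-sample t from summary statistics (pooled default —
  the classical "two-sample t-test" — Welch available); Pearson χ²
  without continuity correction by default (Yates optional); Fisher's
  exact test two-sided by probability-mass ordering (sum of
  margin-fixed tables no more likely than the observed, with the usual
  1 + 1e−7 tolerance for floating ties). Percentages are reported to one
  decimal with round-half-up.

## Synthetic registry generator

The generator emulates three linked registries keyed by a shared person
identifier, with ground truth the real setting lacks.

* **Population.** Ages are drawn by 10-year band (weights default to a
  gently declining profile over 35–84 plus a small 85+ mass, for want of
  a published pyramid) and uniformly within band; birth dates are exact,
  so completed age at the index date equals the drawn age. Everyone is
  alive at the index date by default — tests plant deaths explicitly —
  and sex is Bernoulli (54 % female). The default index date is
  2007-01-01.
* **Disease.** True status is Bernoulli with a band-specific prevalence:
  a rising-with-age profile rescaled so the age-weighted overall
  prevalence equals the configured target (0.09).
* **Events.** Counts per stream are Poisson with status-conditional
  means inside each criterion's window; dates are uniform in the window.
  Spirometry dates are drawn *distinct within person* (collisions
  redrawn), so the distinct-date criterion's closed form is the plain
  Poisson tail. Decoy hospital and prescription events carry codes that
  never match the lung code lists, at status-independent rates, so code
  matching is exercised without disturbing the oracles. Streams are
  independent — real prescription and spirometry use are surely
  positively correlated, which this generator does not emulate; passing
  recovery tests therefore show correctness of the machinery under the
  stated model, not real-world transportability of any performance
  number.
* **Closed forms.** pᵢ± = P(Poisson(λᵢ±) ≥ kᵢ); for an OR-algorithm,
  Se = 1 − Π(1 − pᵢ⁺), Sp = Π(1 − pᵢ⁻), and PPV follows from the Bayes
  relation at the overall prevalence. The default rates are calibrated
  (by inverting the Poisson tails) so this chain sits at the operating
  point reported when patients verified their own diagnoses —
  Se 0.297, Sp 0.989, hence standardized PPV 72.8 % at π = 0.09. The
  split of that operating point across the three streams (hospital tail
  0.090/0.004, prescription 0.174/0.005, spirometry 0.065/0.002 for
  positives/negatives) is a modelling choice; only the aggregate point
  is anchored.
* **Verification and response.** Verification outcomes are multinomial
  conditional on true status; the defaults (confirm 0.55/0.20,
  unsure 0.20/0.17 for true/false) are illustrative values that put the
  confirmed and unsure fractions among identified persons near 46 % and
  19 % at the default operating point — they are not estimates of
  clinician behaviour. Response probability is
  `baseline + bias × (satisfied criteria)`, clamped to [0, 1]
  (defaults 0.65 + 0.03/criterion, overall response ≈ 68 %): the
  simplest mechanism that produces the documented selection effect where
  multi-criteria patients respond more often.

## Numerical and testing choices

* Identification is vectorized with pandas groupbys; an independent
  brute-force per-person evaluator (pure-Python date arithmetic and
  string prefix scans) lives in the test suite and must agree with it on
  hundreds of randomized small bundles (≤ 50 persons, ≤ 20 events each).
* Pipeline parameter recovery is checked on a 3×3 grid of positive/
  negative rate multipliers (×0.5, ×1, ×2) with 100,000 persons per
  cell, requiring empirical Se, Sp and PPV within 3 binomial standard
  errors of the closed form. Cell sizes were chosen to keep the whole
  suite to a few minutes while leaving the Monte-Carlo bands tight.
* Clopper–Pearson coverage is verified by simulation at n = 50, p = 0.1
  over 10,000 replicates (the interval is conservative, so empirical
  coverage must not fall materially below 95 %).
* Fisher's exact p is compared with exhaustive hypergeometric
  enumeration for **all** 2×2 tables with total ≤ 40.
* The null calibration of the responder comparison uses the single- vs
  multiple-criterion χ² (a continuous reference distribution with
  adequate cell counts behaves at the nominal level; small-cell Fisher
  tests are intrinsically conservative) over 400 replicates of
  6,000-person populations with the response bias set to zero.
* Degenerate inputs: empty bundles give empty cohorts; a criterion
  kind that needs a code list but lacks one is a configuration error;
  metrics with zero denominators are returned as undefined rather than
  failing the table; degenerate 2×2 tables give Fisher p = 1 and a χ²
  error (zero margin).

## Known limitations

* Event streams are generated independently; joint-criterion frequencies
  in real data (where one clinical episode produces hospital, drug and
  spirometry traces together) will exceed the simulator's.
* The shipped code lists are placeholders for a clinically validated
  set; real deployments must substitute their own.
* The standardized-PPV interval is a first-order approximation and can
  undercover near Se or Sp of 0/1.
* Hospital episodes carry a single contact date; admission intervals
  (an admission spanning the window boundary) are not modelled.
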