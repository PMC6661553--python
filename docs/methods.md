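# Methods

## Model structure

The model is a cohort expectation, not a microsimulation: one decision tree
covering the prehospital, in-hospital and first five post-discharge years,
followed by an annual-cycle Markov tail for long-term survival. Terminal
states are prehospital death, emergency-department (ED) death, in-hospital
(ICU) death, and discharge with CPC 1–2 or CPC 3–4. Payoffs are expected
discounted cost (£, NHS and personal social services perspective) and
expected discounted QALYs per OHCA patient, over a lifetime horizon.

Key structural assumptions:

* Patients who reach hospital but are not admitted to ICU receive palliative
  care and die in the ED, incurring ED cost only.
* Survival to hospital discharge is stated over all arrests; the tree node
  conditional on ICU admission is therefore
  `p_discharge / (p_hospital × p_icu)`. Combinations for which this ratio
  exceeds 1 are infeasible ("not achievable"); during PSA such draws are
  clamped to the boundary (conditional probability 1) and counted, rather
  than discarded, so sampling distributions are not biased.
* CPC 3–4 survivors have lower five-year survival than CPC 1–2; beyond five
  years both groups die at national age-specific rates with no excess
  mortality.
* CPC-specific utilities and annual healthcare costs persist for life. The
  CPC 3–4 annual cost (£43 670/yr) applied over a remaining lifetime is
  epidemiologically questionable but no alternative long-term value exists in
  the inputs; it is the dominant driver of the incremental cost per survivor.
* The no-treatment comparator is an empty pathway (zero cost, zero QALYs),
  which makes the ALS ICER a plain cost/QALY ratio.

## Parameters and distributions

The registry (`src/ohca_cea/data/parameters.yaml`) lists 22 parameters with
means, 95% CIs and families. PSA distributions are moment-matched: the CI is
converted to a standard deviation by the symmetric normal approximation
`sd = (hi − lo)/3.92` (also applied to the few asymmetric intervals, e.g.
five-year CPC 3–4 survival 0.408, 0.332–0.489), then gamma parameters are
`shape = mean²/var`, `scale = var/mean` and beta parameters `α = mean·k`,
`β = (1−mean)·k` with `k = mean(1−mean)/var − 1`. Parameters printed without
an interval (prehospital costs, annual healthcare costs) are fixed in PSA;
the cost grid varies the critical-care cost deterministically instead. The
discount rate is fixed at 3.5% by reference-case convention. ICU length of
stay and daily ICU cost are sampled independently and multiplied, as no
covariance is reported. Survival to hospital arrival for ALS uses the cohort
value 25.8% (the tabulated 0.26 is a rounding of the same quantity).

## Life table

The long-term phase needs a national period life table, which the inputs
reference but do not reproduce. The built-in stand-in is a synthetic Gompertz
hazard `q(x) = min(1, A·e^{B·x})` with `A = 3.0e−5`, `B = 0.09`, closed at
age 110 (`q = 1`): smooth, monotone, deterministic, with life expectancy
≈ 21.7 years at age 65 — a plausible national value. It emulates the level
and age-slope of adult mortality but none of the real features of a national
table (infant mortality, accident hump, sex differences, cohort trends), so
passing tests show internal correctness, not calibration to any particular
population. A real extract can be substituted as a CSV (`age,qx`, contiguous
ages from 0) via `--life-table` or the `life_table` configuration key; the
single default table is unisex because the model is nowhere sex-stratified.

## Time, discounting and accrual conventions

* Annual cycles. A cohort member alive at a cycle start accrues that full
  year's utility and cost; deaths apply at cycle end; no half-cycle
  correction. Under this convention a person facing `q = 1` lives exactly one
  final year, and the Markov tail with zero discounting and utility 1
  reproduces life expectancy exactly (this identity is tested across
  modules).
* The discount clock counts years since hospital discharge: year 1 is
  undiscounted, year `y ≥ 2` carries `(1.035)^{−(y−1)}`. Prehospital and
  in-hospital payoffs are undiscounted.
* Five-year decedents accrue their group's mean person-years per death spread
  over consecutive years from discharge, with the fractional final year
  pro-rated (the timing of deaths within the five years is not reported).
* The cohort's age at arrest defaults to 65 (not stated in the inputs;
  typical for UK OHCA cohorts) and is configurable; the tail runs from age 70
  to 110. Sensitivity is modest: moving start age from 55 to 70 changes the
  base-case ALS ICER only from ≈£13.1k to ≈£14.3k/QALY, because a longer
  tail adds QALYs and CPC 3–4 costs together.

## Sensitivity analyses

* PSA: 1000 iterations by default; all strategies are evaluated on the same
  per-iteration draw. Per-iteration ICER quantiles are computed over
  iterations with ΔQALY > 0; dominant iterations carry negative ratios and
  rank below all finite ICERs.
* The survival grid shifts hospital-arrival survival (−5 to +20 points) and
  discharge survival (+1 to +6 points) independently, holding arrival
  survival fixed within a row; the CEAC/MEID analyses and the cost grid
  instead scale arrival survival proportionally so the discharge/arrival
  ratio stays at its ALS value (0.258/0.09). Both constructions are exposed
  because the row-definition and the ratio-constant readings are equally
  defensible. Grid cells share one PSA seed so between-cell differences are
  parameter-driven, not noise. Display rounding is to the nearest £500; raw
  values are retained in the CSVs.
* MEID search: smallest delta in an ascending candidate list whose CEAC
  probability at the WTP threshold meets the required certainty (default
  50% at £20 000/QALY); returns none-found if no candidate qualifies.

## Numerical and degenerate-input choices

Moment recovery of every fitted distribution is exact to 1e−9 relative.
Tree evaluation agrees with an independent root-to-leaf path enumeration to
1e−9 relative; terminal probabilities close to 1 within 1e−12. A beta fit
whose CI implies `var ≥ mean(1−mean)` raises an infeasible-moments error
(with the /3.92 rule this can only occur for means very close to 0 or 1).
Strategies with zero hospital survival short-circuit to the all-death
outcome without forming the conditional discharge ratio. Person-years per
death above 5 are rejected rather than truncated. Seeded runs are
reproducible bit-for-bit; each output directory's manifest records the seed.

## Known limitations

The reported uncertainty is exactly what the printed 95% CIs imply under
moment matching, and those intervals are tight: the ALS-vs-none ICER
distribution has a relative IQR of ≈8%. Analyses built on wider input
uncertainty (for example, distributions reflecting patient-level spread
rather than precision of the means) produce much flatter acceptability
curves and can place the MEID one point lower; with this package that is
reproduced by widening the intervals in a user-supplied parameter registry,
not by changing code. Other limitations: no microcosting of the prehospital
services; no correlated parameter draws; no EVPI; no age-dependent utility
decrement for the general population; the synthetic life table is a
stand-in, not ONS data; results apply to adult non-traumatic OHCA only.
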