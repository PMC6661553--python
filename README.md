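# ohca-cea

Cost-effectiveness model of the care pathway for adult, non-traumatic
out-of-hospital cardiac arrest (OHCA) in an NHS setting, written for health
economists and prehospital-care researchers who want a transparent,
scriptable alternative to spreadsheet or TreeAge implementations.

## The model

OHCA care is modelled as a decision tree coupled to a Markov cohort tail:

* **Prehospital**: the strategy under evaluation — no treatment, standard
  paramedic advanced life support (ALS, £347/patient), or ALS plus a
  prehospital critical care team (an additional £1711/patient) — incurs its
  cost for every patient; a fraction *p*<sub>hosp</sub> survives to hospital.
* **In-hospital**: arrivals incur emergency-department (ED) cost; a fraction
  *p*<sub>ICU</sub> is admitted to intensive care, the rest die in the ED.
  ICU patients either die in hospital or survive to discharge. Because
  survival to discharge is stated over *all* arrests, the per-node discharge
  probability is *p*<sub>dis</sub> / (*p*<sub>hosp</sub> · *p*<sub>ICU</sub>) —
  which also defines the feasibility bound behind the "not achievable" cells
  of the two-way sensitivity analysis.
* **Post-discharge**: survivors split by Cerebral Performance Category
  (CPC 1–2 favourable vs CPC 3–4 poor), pass through a five-year phase with
  group-specific survival, utility and annual healthcare cost, and then enter
  an annual-cycle Markov tail in which they die at national age-specific
  rates from a period life table (a built-in Gompertz-style synthetic table,
  or any user-supplied ONS-style CSV).

Costs (£) and effects (QALYs) are summed along each root-to-leaf path and
weighted by path probability; everything after the first post-discharge year
is discounted at 3.5%/year. Parameter uncertainty is propagated by
probabilistic sensitivity analysis (PSA): gamma distributions for costs and
durations, beta for probabilities and utilities, each moment-matched to the
printed mean and 95% CI, with 1000 Monte-Carlo iterations. Results are
reported as incremental cost-effectiveness ratios (ICER = ΔC/ΔE),
cost-effectiveness acceptability curves (CEACs: P(λ·ΔE − ΔC > 0) as a
function of willingness-to-pay λ), two-way sensitivity grids, and the
minimally economically important difference (MEID) — the smallest absolute
gain in survival to hospital discharge at which critical care reaches a
target probability of cost-effectiveness at λ = £20 000/QALY.

## Worked example

```sh
$ ohca-cea evaluate --out out/
              expected_cost  expected_qaly  p_prehospital_death  p_ed_death  p_icu_death  p_discharge_cpc12  p_discharge_cpc34
strategy
no_treatment         0.0000         0.0000               1.0000      0.0000       0.0000             0.0000             0.0000
als              10034.7500         0.7272               0.7420      0.0903       0.0777             0.0765             0.0135
als_plus_ccm     11745.7500         0.7272               0.7420      0.0903       0.0777             0.0765             0.0135
Base-case ICER, ALS vs no treatment: 13,799 GBP/QALY
```

At the parameter means, an ALS-treated arrest costs an expected £10 035 and
yields 0.727 discounted QALYs: 74.2% die before hospital, 9.0% are discharged
alive (85% of them with good neurological outcome), and survivors carry the
five-year and lifetime payoffs. Dividing cost by QALYs gives the base-case
ICER versus no treatment. The `als_plus_ccm` row shows critical care at a
*null* effect: same survival, £1711 more per patient.

```sh
$ ohca-cea psa --seed 2019 --out out/
median ICER 13,797 GBP/QALY (IQR 13,228-14,380); 100% of iterations cost-effective at 20,000 GBP/QALY

$ ohca-cea meid --seed 2019 --out out/
MEID: +4 percentage points survival to discharge (P(CE) >= 50% at 20,000 GBP/QALY)
```

The PSA writes `psa_samples.csv`, `ceac.csv`, `summary.json` and a
`scatter.png` of the 1000 (ΔQALY, Δcost) pairs; `grid survival` and
`grid cost` emit the two-way sensitivity matrices with their "Not achievable"
cells; every output directory contains a `manifest.json` recording the seed
so any run can be reproduced byte-for-byte.

Note that under this implementation's uncertainty propagation — distributions
moment-matched to the printed 95% CIs — the ICER distribution is tight
(relative IQR ≈ 8%), and the MEID lands at +4 points; see
`docs/methods.md` for why wider input uncertainty shifts these figures.

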