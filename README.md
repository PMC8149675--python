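# scdcea

A lifetime Markov cohort model for the cost-effectiveness of a hypothetical
single-administration durable cure (cell or gene therapy, "DT") for sickle
cell disease, compared with standard-of-care management ("SOC"), from the US
healthcare-sector perspective in 2018 USD.

**Who it is for.** Health-economics researchers and modellers who want a
tested, scriptable implementation of this decision problem: the cohort
engine, the regression-based transition and cost machinery, waning scenarios,
deterministic and probabilistic sensitivity analyses, and value-of-information
output — plus a synthetic claims generator for validating the estimation
pipeline end to end, since the original commercial claims data are licensed
and unavailable.

## The model

Five health states: healthy (in remission after cure), mild / moderate /
severe sickle cell disease under SOC (severity defined by the annualized
vaso-occlusive crisis count: 0, (0, 2), ≥ 2 crises/year), and dead. The
cohort enters at birth and is followed for 100 annual cycles; costs and QALYs
are discounted at 3%/year; the base-case willingness-to-pay threshold is
λ = $150,000/QALY.

- **Transitions.** Year-to-year severity movement follows a cumulative
  (ordered) logit fit separately by gender: P(next ≤ k) = L(κ_k − xβ), with
  xβ linear in current-severity indicators, age, and their interactions.
  Death is resolved first each cycle from life tables (unaffected vs
  SCD-adjusted); progression and relapse are conditional on survival.
  Relapsed patients re-enter at mild severity and cannot return to remission.
- **Costs.** Annual direct medical cost is exp(xβ) from a gamma log-link GLM
  on severity, age, and interactions; the remission state uses the
  matched-control (unaffected) prediction. The durable therapy costs $2.1M
  once, at time zero, undiscounted. Dead patients cost nothing.
- **Utilities.** Age-band QALY weights: unaffected controls by gender
  (0.82–0.89), SCD patients 0.69 (ages 0–18) / 0.68 (19+), zero when dead.
- **Waning.** Cure durability is lifetime in the base case; scenario
  analyses convert a median time-to-relapse T to an annual probability via
  p_annual = 1 − (1 − p_T)^(1/T), e.g. 0.06697 for T = 10 years.
- **Decision statistics.** ICER = ΔC/ΔQ, net monetary benefit
  NMB(λ) = λ·Q − C, threshold pricing via the linear price–ICER identity,
  and from 10,000-draw Monte Carlo PSA: CEAC, CEAF, and
  EVPI(λ) = E[max NMB] − max E[NMB].

The published life tables behind the original analysis are not printed
anywhere, so the default mortality is a Gompertz–Makeham stand-in calibrated
to the model's undiscounted life expectancies (75.8 years unaffected, 54.9
years with SCD); supply your own `age,qx` CSVs to override
(see `docs/methods.md`).

## Worked example

```python
from scdcea import run_base_case, threshold_price

bundle = run_base_case()          # packaged base case, lifetime durability
cea = bundle["cea"]
print(f"dC = ${cea.delta_cost:,.0f}  dQ = {cea.delta_qaly:.2f}  "
      f"ICER = ${cea.icer:,.0f}/QALY")
print(f"threshold price at $150K/QALY: "
      f"${threshold_price(cea, 2.1e6, 150_000):,.0f}")
```

prints

```
dC = $1,165,268  dQ = 8.36  ICER = $139,344/QALY
threshold price at $150K/QALY: $2,189,115
```

That is: curing a newborn costs an extra $1.17M (discounted, lifetime) and
buys 8.36 discounted QALYs, an ICER of about $139K per QALY — cost-effective
at the $150K threshold — and the upfront price could rise to about $2.19M
before the ICER reaches the threshold. The same numbers per gender, the
undiscounted totals, and the cohort trace are in `bundle["table"]` and
`bundle["results"]`.

The same pipeline is scriptable from the shell:

```sh
scdcea run --waning 10 --out run10/        # 10-year median durability scenario
scdcea report --seed 7 --out report/       # base case + DSA + PSA + CEAC/EVPI
scdcea synth -n 10000 --out panel.csv      # synthetic claims panel
```

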