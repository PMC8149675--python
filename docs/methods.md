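# Methods

## Decision problem and model structure

The package evaluates a single-administration durable therapy (DT) for
sickle cell disease given at birth against standard-of-care (SOC)
management, from the US healthcare-sector perspective. The model is a
five-state Markov cohort: healthy/in-remission, mild SCD, moderate SCD,
severe SCD, and dead. Severity is an ordinal classification of the
annualized vaso-occlusive crisis count (mild = 0/year, moderate in (0, 2),
severe ≥ 2). The DT cohort starts fully in remission; the SOC cohort starts
in the affected states with the observed early-childhood severity mix
(females 50.8/22.1/27.1%, males 48.3/23.1/28.7%, each carried as a Dirichlet
over the underlying counts). Death is the only absorbing state and can occur
from any state. Relapsed DT patients enter mild SCD, are managed under SOC
thereafter, and cannot be re-treated or return to remission.

The cohort is propagated as exact expected occupancy proportions
(deterministic cohort analysis), not as sampled individuals; the nominal
cohort size (10,000) matters only for reporting totals.

## Cycle mechanics and accounting conventions

Cycles are annual; age equals the cycle index with birth at cycle 0.
Within a cycle, death is resolved first (annual probability from the
unaffected life table in remission, the SCD-adjusted table in any affected
state) and severity transitions or relapse apply only to survivors. Rewards
(annual cost, utility weight, one life-year while alive) accrue to the state
occupied at cycle start, and cycle t is discounted by (1+r)^(−t) with
r = 0.03/year on both costs and health outcomes. Year-0 rewards are
therefore undiscounted, consistent with the upfront DT price being paid at
time zero and never discounted. No half-cycle correction is applied by
default — the start-of-cycle convention is the natural partner of the
"death first, rewards to survivors' start state" ordering — but
`run_cohort(half_cycle=True)` averages start- and end-of-cycle occupancy for
users who prefer it. The published totals cannot adjudicate this choice
without the original life tables, so it is exposed rather than hidden.

Life years count one year per surviving cycle, which makes the engine's
undiscounted life-year total identical to the life-table life expectancy
computed by `mortality.life_expectancy` — the calibration below exploits
this identity.

## Transition probabilities

Severity movement uses a cumulative-logit ("ordered logit") regression per
gender with linear predictor

    xb = a_mod·[moderate] + a_sev·[severe] + a_age·age
         + a_mod_age·[moderate]·age + a_sev_age·[severe]·age

(mild is the reference) and P(next ≤ k) = L(κ_k − xb), k ∈ {mild,
moderate}, L the standard logistic. The cut points absorb the intercept;
this is the parameterisation used by `statsmodels.OrderedModel`, which the
synthetic-claims module uses as the refitting route, so recovered and
assumed coefficients are directly comparable. The regression applies at
every age through the age covariate, with no truncation at extreme ages.

## Rewards

Annual direct cost is exp(xb) from a gamma log-link GLM per gender with
mild/moderate/severe indicators against the unaffected matched-control
reference, age, and three severity-by-age interactions. The remission state
uses the control prediction (all indicators zero). Dead patients incur no
cost, and the transition to death carries no cost. All currency is 2018 USD;
no inflation machinery is included.

Utility weights are piecewise-constant in age: control weights by gender
over bands {1–44, 45–54, 55–64, 65–74, 75+}, SCD weights (severity- and
gender-invariant) over {1–18, 19+}, dead = 0. The first band of each table
extends down to age 0 because the cohort enters at birth: band edges are
inclusive ("45–54" means 45 ≤ age ≤ 54), and the SCD adult band starts at
age 19.

## Mortality and calibration

The original analysis used simulated life tables (unaffected Black or
African American population, and an SCD-adjusted variant) that are not
published. The default mortality here is a Gompertz–Makeham stand-in,
hazard h(age) = a·e^(b·age) + c, with b = 0.085 (a conventional adult
mortality slope), c = 0, and `a` solved by bracketed root-finding
(scipy's brentq on log10 a) so that the 100-cycle life expectancy matches
the model's undiscounted life-year totals: 75.8 years unaffected, 54.9 years
SCD. Life expectancy is strictly decreasing in `a`, so the root is unique;
calibration tolerance is 0.05 years. Mortality does not vary by gender or
severity (one SCD table covers all affected states), and the SCD table
applies from the cycle a relapsed patient becomes affected. Users can
substitute real tables via `age,qx` CSVs (ages contiguous from 0, terminal
qx = 1).

Because only the two life expectancies are matched, the *shape* of the
survival curve — and hence every discounted absolute total — differs from
the unpublished original tables. Incremental and ratio quantities are much
less sensitive to this: with the calibrated defaults the base-case ICER,
scenario ICERs, CEAC percentages, and EVPI peak all land within a few
percent of the published figures, but they should be read as properties of
this parameterisation, not reproductions.

## Waning scenarios

Durability is lifetime in the base case (relapse probability 0). Scenarios
express a cumulative relapse probability p_T at a median horizon T as a
constant-rate annual probability p_annual = 1 − (1 − p_T)^(1/T): 0.06697
for T = 10 and 0.03406 for T = 20 at p_T = 0.5. p_T = 1 is rejected — a
certain relapse has no finite exponential rate.

## Sensitivity analyses

**One-way DSA** moves each eligible parameter to its printed 95% CI bounds,
or ±20% of base when no CI is printed (the DT price and any derived
overrides), holding everything else at base, and re-runs the full pipeline —
both arms, both genders, pooled — at each bound. Both arms are always
re-evaluated, since several parameters (control utilities, control costs)
affect only the DT arm's remission years while others affect both. The
initial-severity Dirichlets and the cohort size are excluded from DSA; the
discount rate and cohort size are excluded from PSA. Regression
coefficients are varied one scalar at a time, as the published tornado
labels imply, even though they were jointly estimated.

**Two-way DSA** grids two parameters over their DSA ranges (11 points per
axis by default) and labels each cell with the lowest willingness-to-pay
level at which DT is cost-effective.

**PSA** runs 10,000 Monte Carlo iterations by default. Each iteration draws
every included parameter independently from its Table-style distribution
(betas for proportions and control utilities, truncated-on-[0,1] normals
for SCD utilities, normals for regression coefficients, uniform for the DT
price) and each gender's severity mix jointly as one Dirichlet vector.
Regression coefficients are drawn as independent normals because no
covariance matrix is available. A draw with κ1 ≥ κ2 is rejected and redrawn
(preserving the stated marginals rather than clamping); rejections are
counted and are essentially zero at the default standard errors. Randomness
derives from one master seed through `numpy.random.SeedSequence.spawn`, one
substream per iteration, so any iteration is reproducible in isolation and
reruns are bit-identical. Per-iteration storage is the six discounted totals
per stratum, not full traces.

**Decision statistics.** The CEAC counts, per λ, the fraction of iterations
in which each arm has the highest net monetary benefit, with ties awarded to
SOC (deterministic, conservative toward the incumbent). This coincides with
the simpler "ICER below λ" counting rule whenever ΔQ > 0 and ΔC > 0 — the
regime the base case occupies — and that literal rule is available as
`ceac_ceaf(..., rule="icer_threshold")`. The λ grid defaults to 0–300,000
in 5,000 steps. EVPI(λ) = E[max-arm NMB] − max-arm E[NMB] ≥ 0 by
construction. Threshold prices use the identity that the upfront price
enters incremental cost one-for-one and undiscounted, so
ICER(p) is linear in p and p* = p0 + (λ·ΔQ − ΔC).

## Synthetic claims generator

`scdcea.claims` emulates the statistical structure the estimation stage
assumes, standing in for licensed claims data. Per SCD patient: gender
(47% female), a uniform integer age in 0–64 (a commercially insured
population), year-1 severity from the initial-severity proportions, year-2
severity from the true ordered-logit row at the year-1 age, and annual costs
drawn Gamma(shape, mean/shape) with the GLM mean (shape 1.5 by default;
shape → ∞ gives noiseless costs, useful for exact-recovery checks). An
equal number of unaffected controls supplies the cost regression's reference
level — the original design's propensity matching is not simulated, controls
are drawn directly. Crisis rates are drawn consistently with the severity
class (0 / uniform(0, 2) / 2 + Exp(1)); only the class is used downstream,
so the within-class distributions are generator conventions. The panel is
two years long because the transition regression uses only consecutive-year
pairs.

What passing recovery tests show: with the generator's assumptions exactly
matching the estimators, all 30 regression coefficients are recovered within
4 standard errors from a 50,000-patient panel and aggregate error decays
monotonically in panel size. What they do not show: robustness to the ways
real claims deviate — enrollment gaps, coding error in crisis counts,
cost-severity feedback, non-gamma cost tails, or matching imbalance.

## Problem sizes and numerical choices

The test suite uses 50,000 patients for the single-seed recovery check and
{2,000, 8,000, 32,000} × 5 seeds (median of the mean absolute coefficient
error over the ordered-logit parameters) for the consistency check; these
sizes give stable verdicts while keeping the suite quick. PSA determinism
and distribution checks use 20–1,000 iterations; the full 10,000-iteration
PSA runs in well under a minute. Trace conservation is enforced at 1e-10,
row-stochasticity of transition matrices at 1e-12, cost-formula agreement
with a direct scalar oracle at relative 1e-12.

Known limitations: mortality shape (not just level) is a modelling choice;
no covariance between drawn regression coefficients; no societal
perspective, indirect costs, or treatment-specific SOC stratification; a
single two-arm comparison (no multi-comparator frontier, no EVPPI).
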