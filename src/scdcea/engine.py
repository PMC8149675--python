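"""Deterministic cohort engine: one arm, 100 annual cycles, discounted totals.

The cohort is followed as exact expected state-occupancy proportions (a
classical Markov cohort analysis, not a microsimulation).  Each cycle t
corresponds to age t (the cohort enters at birth).  Within a cycle, death is
resolved first; relapse out of remission and severity transitions apply only
to survivors.  Rewards (annual cost, utility weight, and an alive indicator
for life years) accrue to the state occupied at cycle start and cycle t is
discounted by (1+r)^-t, so year-0 rewards — including the durable therapy's
upfront price — are undiscounted.  An optional half-cycle correction averages
start- and end-of-cycle occupancy instead.

Cure durability ("waning") is expressed as an annual relapse probability.  A
median time-to-relapse T with cumulative relapse probability p_T converts to
an annual probability under a constant exponential rate:

    p_annual = 1 - (1 - p_T)**(1/T)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mortality import LifeTable, default_life_tables
from .parameters import ParameterDraw, ParameterSet
from .rewards import CostCoefficients, UtilityTable, cost_matrix, utility_matrix
from .states import Arm, Gender, as_arm, as_gender
from .transitions import OrderedLogitCoefficients, transition_stack

__all__ = [
    "WaningSpec",
    "CohortTrace",
    "ArmResult",
    "ModelInputs",
    "annual_relapse_probability",
    "build_model_inputs",
    "initial_state_vector",
    "run_cohort",
    "run_strategies",
    "pooled_result",
]

_TRACE_SUM_TOL = 1e-10


def annual_relapse_probability(p_T: float, T: float) -> float:
    """Annual relapse probability from a cumulative probability over T years."""
    if not 0.0 <= p_T < 1.0:
        raise ValueError(f"p_T must be in [0, 1); got {p_T}")
    if T < 1:
        raise ValueError(f"T must be >= 1 year; got {T}")
    return 1.0 - (1.0 - p_T) ** (1.0 / T)


@dataclass(frozen=True)
class WaningSpec:
    """Durability assumption for the cure: lifetime, or median T years."""

    mode: str = "lifetime"  # "lifetime" | "median_years"
    T: float | None = None
    p_T: float = 0.5

    @property
    def p_annual(self) -> float:
        if self.mode == "lifetime":
            return 0.0
        if self.mode == "median_years":
            if self.T is None:
                raise ValueError("median_years mode requires T")
            return annual_relapse_probability(self.p_T, self.T)
        raise ValueError(f"unknown waning mode: {self.mode}")

    @classmethod
    def lifetime(cls) -> "WaningSpec":
        return cls(mode="lifetime")

    @classmethod
    def median(cls, T: float, p_T: float = 0.5) -> "WaningSpec":
        return cls(mode="median_years", T=T, p_T=p_T)


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy proportions, rows = cycles 0..horizon, cols = 5 states."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 2 or occ.shape[1] != 5:
            raise ValueError(f"trace must be (cycles, 5); got {occ.shape}")
        if np.abs(occ.sum(axis=1) - 1.0).max() > _TRACE_SUM_TOL:
            raise ValueError("trace rows must sum to 1")
        if (np.diff(occ[:, 4]) < -_TRACE_SUM_TOL).any():
            raise ValueError("dead-state occupancy must be non-decreasing")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.occupancy, columns=["healthy", "mild", "moderate", "severe", "dead"]
        )
        df.insert(0, "cycle", np.arange(len(df)))
        return df


@dataclass(frozen=True)
class ArmResult:
    """Per-patient totals for one arm (and optionally the cohort trace)."""

    cost_disc: float
    cost_undisc: float
    qaly_disc: float
    qaly_undisc: float
    ly_disc: float
    ly_undisc: float
    trace: CohortTrace | None = None


@dataclass(frozen=True)
class ModelInputs:
    """Everything the engine needs, resolved from a ParameterSet or PSA draw."""

    tp_f: OrderedLogitCoefficients
    tp_m: OrderedLogitCoefficients
    cost_f: CostCoefficients
    cost_m: CostCoefficients
    utilities: UtilityTable
    severity_init_f: np.ndarray
    severity_init_m: np.ndarray
    dt_price: float
    percent_female: float
    discount_rate: float
    horizon: int
    n_patients: int
    wtp: float

    def tp(self, gender: Gender | str) -> OrderedLogitCoefficients:
        return self.tp_f if as_gender(gender) is Gender.FEMALE else self.tp_m

    def cost(self, gender: Gender | str) -> CostCoefficients:
        return self.cost_f if as_gender(gender) is Gender.FEMALE else self.cost_m


def build_model_inputs(
    params: ParameterSet, draw: ParameterDraw | None = None
) -> ModelInputs:
    """Resolve regression/utility/cohort inputs from base values or a PSA draw."""
    v = draw.values.__getitem__ if draw is not None else params.value

    def tp(g: str) -> OrderedLogitCoefficients:
        return OrderedLogitCoefficients(
            alpha_moderate=v(f"tp_{g}_moderate"),
            alpha_severe=v(f"tp_{g}_severe"),
            alpha_age=v(f"tp_{g}_age"),
            alpha_moderate_x_age=v(f"tp_{g}_moderate_age"),
            alpha_severe_x_age=v(f"tp_{g}_severe_age"),
            kappa1=v(f"tp_{g}_cut1"),
            kappa2=v(f"tp_{g}_cut2"),
            gender="female" if g == "f" else "male",
        )

    def cost(g: str) -> CostCoefficients:
        return CostCoefficients(
            beta0=v(f"cost_{g}_intercept"),
            beta_mild=v(f"cost_{g}_mild"),
            beta_moderate=v(f"cost_{g}_moderate"),
            beta_severe=v(f"cost_{g}_severe"),
            beta_age=v(f"cost_{g}_age"),
            beta_mild_x_age=v(f"cost_{g}_mild_age"),
            beta_moderate_x_age=v(f"cost_{g}_moderate_age"),
            beta_severe_x_age=v(f"cost_{g}_severe_age"),
            gender="female" if g == "f" else "male",
        )

    utilities = UtilityTable(
        control_f=tuple(
            v(f"utility_control_f_{band}")
            for band in ("1_44", "45_54", "55_64", "65_74", "75_plus")
        ),
        control_m=tuple(
            v(f"utility_control_m_{band}")
            for band in ("1_44", "45_54", "55_64", "65_74", "75_plus")
        ),
        scd=(v("utility_scd_1_18"), v("utility_scd_19_plus")),
    )
    if draw is not None:
        sev_f, sev_m = draw.severity_f, draw.severity_m
    else:
        sev_f, sev_m = params.severity_f.proportions, params.severity_m.proportions
    return ModelInputs(
        tp_f=tp("f"),
        tp_m=tp("m"),
        cost_f=cost("f"),
        cost_m=cost("m"),
        utilities=utilities,
        severity_init_f=np.asarray(sev_f, dtype=float),
        severity_init_m=np.asarray(sev_m, dtype=float),
        dt_price=v("dt_price"),
        percent_female=v("percent_female"),
        discount_rate=v("discount_rate"),
        horizon=params.cohort.horizon,
        n_patients=params.cohort.n_patients,
        wtp=params.cohort.wtp,
    )


def initial_state_vector(
    arm: Arm | str, gender: Gender | str, inputs: ModelInputs
) -> np.ndarray:
    """Cycle-0 occupancy: everyone cured (DT) or the observed severity mix (SOC)."""
    if as_arm(arm) is Arm.DT:
        return np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    sev = (
        inputs.severity_init_f
        if as_gender(gender) is Gender.FEMALE
        else inputs.severity_init_m
    )
    return np.concatenate([[0.0], sev, [0.0]])


def run_cohort(
    arm: Arm | str,
    gender: Gender | str,
    inputs: ModelInputs,
    tables: tuple[LifeTable, LifeTable] | None = None,
    waning: WaningSpec = WaningSpec.lifetime(),
    half_cycle: bool = False,
    keep_trace: bool = True,
) -> ArmResult:
    """Run one (arm, gender) cohort and accumulate per-patient totals.

    ``tables`` is the (unaffected, SCD) life-table pair; the packaged
    calibrated defaults are used when omitted.
    """
    arm = as_arm(arm)
    gender = as_gender(gender)
    if tables is None:
        tables = default_life_tables()
    unaffected, scd = tables
    H = inputs.horizon
    if H > unaffected.max_age + 1 or H > scd.max_age + 1:
        raise ValueError(f"horizon {H} exceeds life-table length")

    ages = np.arange(H)
    relapse = waning.p_annual if arm is Arm.DT else 0.0
    stack = transition_stack(
        inputs.tp(gender), ages, unaffected.qx[:H], scd.qx[:H], relapse
    )

    occ = np.empty((H + 1, 5))
    occ[0] = initial_state_vector(arm, gender, inputs)
    for t in range(H):
        occ[t + 1] = occ[t] @ stack[t]
    if np.abs(occ.sum(axis=1) - 1.0).max() > _TRACE_SUM_TOL:
        raise RuntimeError("non-stochastic transition encountered")  # unreachable

    occ_r = 0.5 * (occ[:H] + occ[1:]) if half_cycle else occ[:H]
    costs = cost_matrix(inputs.cost(gender), ages)
    utils = utility_matrix(inputs.utilities, gender, ages)
    alive = np.array([1.0, 1.0, 1.0, 1.0, 0.0])

    disc = (1.0 + inputs.discount_rate) ** (-ages.astype(float))
    cost_t = (occ_r * costs).sum(axis=1)
    qaly_t = (occ_r * utils).sum(axis=1)
    ly_t = occ_r @ alive

    upfront = inputs.dt_price if arm is Arm.DT else 0.0
    return ArmResult(
        cost_disc=float(disc @ cost_t) + upfront,
        cost_undisc=float(cost_t.sum()) + upfront,
        qaly_disc=float(disc @ qaly_t),
        qaly_undisc=float(qaly_t.sum()),
        ly_disc=float(disc @ ly_t),
        ly_undisc=float(ly_t.sum()),
        trace=CohortTrace(occ) if keep_trace else None,
    )


def run_strategies(
    inputs: ModelInputs,
    tables: tuple[LifeTable, LifeTable] | None = None,
    waning: WaningSpec = WaningSpec.lifetime(),
    half_cycle: bool = False,
    keep_trace: bool = False,
) -> dict[str, dict[str, ArmResult]]:
    """Both arms x {female, male, pooled}; waning applies to the DT arm only."""
    out: dict[str, dict[str, ArmResult]] = {}
    for arm in (Arm.DT, Arm.SOC):
        by = {
            g.value: run_cohort(
                arm, g, inputs, tables, waning, half_cycle=half_cycle, keep_trace=keep_trace
            )
            for g in (Gender.FEMALE, Gender.MALE)
        }
        by["pooled"] = pooled_result(by["female"], by["male"], inputs.percent_female)
        out[arm.value] = by
    return out


def pooled_result(
    result_f: ArmResult, result_m: ArmResult, percent_female: float
) -> ArmResult:
    """Gender-pooled per-patient totals (convex combination)."""
    if not 0.0 <= percent_female <= 1.0:
        raise ValueError(f"percent_female must be in [0, 1]; got {percent_female}")
    w = percent_female

    def mix(a: float, b: float) -> float:
        return w * a + (1.0 - w) * b

    trace = None
    if result_f.trace is not None and result_m.trace is not None:
        trace = CohortTrace(
            w * result_f.trace.occupancy + (1.0 - w) * result_m.trace.occupancy
        )
    return ArmResult(
        cost_disc=mix(result_f.cost_disc, result_m.cost_disc),
        cost_undisc=mix(result_f.cost_undisc, result_m.cost_undisc),
        qaly_disc=mix(result_f.qaly_disc, result_m.qaly_disc),
        qaly_undisc=mix(result_f.qaly_undisc, result_m.qaly_undisc),
        ly_disc=mix(result_f.ly_disc, result_m.ly_disc),
        ly_undisc=mix(result_f.ly_undisc, result_m.ly_undisc),
        trace=trace,
    )
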