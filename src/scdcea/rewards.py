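"""Per-cycle rewards: annual direct medical cost and health-utility weight.

Costs come from a gamma log-link GLM of annual direct cost on disease severity
(mild/moderate/severe indicators against an unaffected matched-control
reference), age, and severity-by-age interactions, fit separately by gender.
The remission state uses the control prediction (all indicators zero).  Dead
patients incur zero cost and zero utility; the transition to death carries no
cost.  All amounts are 2018 USD.

Utility weights are piecewise-constant in age: unaffected (control) weights by
gender over bands {1-44, 45-54, 55-64, 65-74, 75+} and gender-invariant SCD
weights over {1-18, 19+}, with the first band extended down to age 0 since the
cohort enters at birth.  Severity does not alter the SCD weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import Gender, State, as_gender, as_state

__all__ = [
    "CostCoefficients",
    "UtilityTable",
    "annual_cost",
    "cost_matrix",
    "utility_weight",
    "utility_matrix",
    "dt_upfront_cost",
]

_CONTROL_BREAKS = np.array([45, 55, 65, 75])  # band starts after age 44
_SCD_ADULT_AGE = 19


@dataclass(frozen=True)
class CostCoefficients:
    beta0: float
    beta_mild: float
    beta_moderate: float
    beta_severe: float
    beta_age: float
    beta_mild_x_age: float
    beta_moderate_x_age: float
    beta_severe_x_age: float
    gender: str = "both"

    def state_terms(self) -> tuple[np.ndarray, np.ndarray]:
        """(intercept, slope) per live state ordered healthy, mild, moderate, severe."""
        icepts = self.beta0 + np.array(
            [0.0, self.beta_mild, self.beta_moderate, self.beta_severe]
        )
        slopes = self.beta_age + np.array(
            [0.0, self.beta_mild_x_age, self.beta_moderate_x_age, self.beta_severe_x_age]
        )
        return icepts, slopes


@dataclass(frozen=True)
class UtilityTable:
    """Control weights by gender x age band; SCD weights by age band."""

    control_f: tuple[float, float, float, float, float]
    control_m: tuple[float, float, float, float, float]
    scd: tuple[float, float]  # (ages 0-18, ages 19+)

    def __post_init__(self) -> None:
        for w in (*self.control_f, *self.control_m, *self.scd):
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"utility weight outside [0, 1]: {w}")

    def control(self, gender: Gender | str) -> tuple[float, ...]:
        return self.control_f if as_gender(gender) is Gender.FEMALE else self.control_m


def annual_cost(coeffs: CostCoefficients, state: State | str, age: float) -> float:
    """Predicted annual direct medical cost (2018 USD) for one state at one age."""
    s = as_state(state)
    if age < 0:
        raise ValueError(f"age must be >= 0; got {age}")
    if s is State.DEAD:
        return 0.0
    icepts, slopes = coeffs.state_terms()
    i = (State.HEALTHY, State.MILD, State.MODERATE, State.SEVERE).index(s)
    return float(np.exp(icepts[i] + slopes[i] * age))


def cost_matrix(coeffs: CostCoefficients, ages: np.ndarray) -> np.ndarray:
    """Costs for all five states over a vector of ages, shape ``(len(ages), 5)``."""
    ages = np.asarray(ages, dtype=float)
    icepts, slopes = coeffs.state_terms()
    live = np.exp(icepts[None, :] + slopes[None, :] * ages[:, None])
    return np.concatenate([live, np.zeros((len(ages), 1))], axis=1)


def _control_band(age: float) -> int:
    return int(np.searchsorted(_CONTROL_BREAKS, age, side="right"))


def utility_weight(
    table: UtilityTable, state: State | str, age: float, gender: Gender | str
) -> float:
    """QALY weight in [0, 1]; dead -> 0, remission -> control, affected -> SCD."""
    s = as_state(state)
    if age < 0:
        raise ValueError(f"age must be >= 0; got {age}")
    if s is State.DEAD:
        return 0.0
    if s is State.HEALTHY:
        return table.control(gender)[_control_band(age)]
    return table.scd[0] if age < _SCD_ADULT_AGE else table.scd[1]


def utility_matrix(table: UtilityTable, gender: Gender | str, ages: np.ndarray) -> np.ndarray:
    """Utility weights for all five states over ages, shape ``(len(ages), 5)``."""
    ages = np.asarray(ages, dtype=float)
    bands = np.searchsorted(_CONTROL_BREAKS, ages, side="right")
    control = np.asarray(table.control(gender))[bands]
    scd = np.where(ages < _SCD_ADULT_AGE, table.scd[0], table.scd[1])
    out = np.empty((len(ages), 5))
    out[:, 0] = control
    out[:, 1] = out[:, 2] = out[:, 3] = scd
    out[:, 4] = 0.0
    return out


def dt_upfront_cost(config) -> float:
    """Single-administration durable-therapy price, charged once at cycle 0.

    Paid at time zero, so it is never discounted.
    """
    price = float(config.dt_price if hasattr(config, "dt_price") else config)
    if price < 0:
        raise ValueError(f"dt_price must be >= 0; got {price}")
    return price
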