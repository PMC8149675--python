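"""Annual severity-transition probabilities and the 5-state cycle matrix.

Year-to-year movement between the mild/moderate/severe states is governed by a
cumulative (ordered) logit regression of next-year severity on current
severity and age, with severity-by-age interactions, fit separately by gender:

    xb   = a_mod*[moderate] + a_sev*[severe] + a_age*age
           + a_mod_age*[moderate]*age + a_sev_age*[severe]*age
    P(next <= mild)     = L(kappa1 - xb)
    P(next <= moderate) = L(kappa2 - xb)

with L the standard logistic function and mild the reference category.  The
cut points absorb the intercept.  Death is resolved first each cycle; severity
transitions (and relapse out of remission) apply only to survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import AFFECTED_STATES, State, as_state

__all__ = [
    "OrderedLogitCoefficients",
    "linear_predictor",
    "severity_transition_row",
    "severity_rows_for_ages",
    "build_cycle_matrix",
    "transition_stack",
]

_DEAD_ROW = np.array([0.0, 0.0, 0.0, 0.0, 1.0])


@dataclass(frozen=True)
class OrderedLogitCoefficients:
    alpha_moderate: float
    alpha_severe: float
    alpha_age: float
    alpha_moderate_x_age: float
    alpha_severe_x_age: float
    kappa1: float
    kappa2: float
    gender: str = "both"

    def __post_init__(self) -> None:
        if not self.kappa1 < self.kappa2:
            raise ValueError(
                f"cut points must be ordered: kappa1={self.kappa1} >= kappa2={self.kappa2}"
            )


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


def _severity_check(current_severity: State) -> State:
    s = as_state(current_severity)
    if s not in AFFECTED_STATES:
        raise ValueError(
            f"severity regression is defined only on affected states; got {s.value}"
        )
    return s


def linear_predictor(
    coeffs: OrderedLogitCoefficients, current_severity: State | str, age: float
) -> float:
    """xb for one origin severity at one age (mild is the reference)."""
    s = _severity_check(current_severity)
    if age < 0:
        raise ValueError(f"age must be >= 0; got {age}")
    mod = 1.0 if s is State.MODERATE else 0.0
    sev = 1.0 if s is State.SEVERE else 0.0
    return (
        coeffs.alpha_moderate * mod
        + coeffs.alpha_severe * sev
        + coeffs.alpha_age * age
        + coeffs.alpha_moderate_x_age * mod * age
        + coeffs.alpha_severe_x_age * sev * age
    )


def severity_transition_row(
    coeffs: OrderedLogitCoefficients, current_severity: State | str, age: float
) -> np.ndarray:
    """(p_mild, p_moderate, p_severe) for survivors, summing to 1."""
    xb = linear_predictor(coeffs, current_severity, age)
    c1 = _expit(coeffs.kappa1 - xb)
    c2 = _expit(coeffs.kappa2 - xb)
    return np.array([c1, c2 - c1, 1.0 - c2])


def severity_rows_for_ages(coeffs: OrderedLogitCoefficients, ages: np.ndarray) -> np.ndarray:
    """Vectorised severity rows, shape ``(len(ages), 3 origins, 3 destinations)``."""
    ages = np.asarray(ages, dtype=float)
    mod = np.array([0.0, 1.0, 0.0])
    sev = np.array([0.0, 0.0, 1.0])
    xb = (
        coeffs.alpha_moderate * mod[None, :]
        + coeffs.alpha_severe * sev[None, :]
        + coeffs.alpha_age * ages[:, None]
        + coeffs.alpha_moderate_x_age * mod[None, :] * ages[:, None]
        + coeffs.alpha_severe_x_age * sev[None, :] * ages[:, None]
    )  # (n_ages, 3)
    c1 = _expit(coeffs.kappa1 - xb)
    c2 = _expit(coeffs.kappa2 - xb)
    return np.stack([c1, c2 - c1, 1.0 - c2], axis=-1)


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1]; got {p}")


def build_cycle_matrix(
    coeffs: OrderedLogitCoefficients,
    age: float,
    q_healthy: float,
    q_scd: float,
    relapse_prob: float,
) -> np.ndarray:
    """One-cycle 5x5 row-stochastic matrix at a given age.

    Death (probability ``q_healthy`` from remission, ``q_scd`` from any
    affected state) is applied first; relapse (remission -> mild) and severity
    transitions are conditional on survival.  Remission is unreachable from
    the affected states and the dead state is absorbing.
    """
    for name, p in (("q_healthy", q_healthy), ("q_scd", q_scd), ("relapse_prob", relapse_prob)):
        _check_prob(name, p)
    m = np.zeros((5, 5))
    m[0, 0] = (1.0 - q_healthy) * (1.0 - relapse_prob)
    m[0, 1] = (1.0 - q_healthy) * relapse_prob
    m[0, 4] = q_healthy
    for i, origin in enumerate(AFFECTED_STATES, start=1):
        m[i, 1:4] = (1.0 - q_scd) * severity_transition_row(coeffs, origin, age)
        m[i, 4] = q_scd
    m[4] = _DEAD_ROW
    return m


def transition_stack(
    coeffs: OrderedLogitCoefficients,
    ages: np.ndarray,
    q_healthy: np.ndarray,
    q_scd: np.ndarray,
    relapse_prob: float,
) -> np.ndarray:
    """All cycle matrices at once, shape ``(len(ages), 5, 5)``.

    Equivalent to stacking :func:`build_cycle_matrix` over ages; used by the
    cohort engine and the Monte Carlo PSA, where per-cycle Python-level matrix
    construction would dominate the runtime.
    """
    ages = np.asarray(ages, dtype=float)
    qh = np.asarray(q_healthy, dtype=float)
    qs = np.asarray(q_scd, dtype=float)
    _check_prob("relapse_prob", relapse_prob)
    if ((qh < 0) | (qh > 1)).any() or ((qs < 0) | (qs > 1)).any():
        raise ValueError("death probabilities must be in [0, 1]")
    n = len(ages)
    rows = severity_rows_for_ages(coeffs, ages)  # (n, 3, 3)
    m = np.zeros((n, 5, 5))
    m[:, 0, 0] = (1.0 - qh) * (1.0 - relapse_prob)
    m[:, 0, 1] = (1.0 - qh) * relapse_prob
    m[:, 0, 4] = qh
    m[:, 1:4, 1:4] = (1.0 - qs)[:, None, None] * rows
    m[:, 1:4, 4] = qs[:, None]
    m[:, 4, 4] = 1.0
    return m
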