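"""Annual death probabilities for the unaffected and SCD-affected populations.

The published analysis used simulated life tables (for Black or African
American individuals, and an SCD risk-adjusted variant) that are not publicly
printed.  This module therefore supports two sources:

* CSV life tables (``age,qx``; ages contiguous from 0; terminal qx = 1), and
* a Gompertz-Makeham synthesizer, hazard ``h(age) = a*exp(b*age) + c``, whose
  scale ``a`` is calibrated by root-finding so the table's undiscounted life
  expectancy over the model horizon matches a target.

The packaged defaults are calibrated to the model's undiscounted life-year
totals: 75.8 years for the unaffected (remission) population and 54.9 years
for the SCD population, with slope ``b = 0.085`` (a conventional adult
mortality slope) and ``c = 0``.  Mortality is shared across genders and
severity levels; the SCD table applies from the cycle a relapsed patient
enters mild SCD.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "LifeTable",
    "GompertzMakehamParams",
    "read_life_table",
    "synthesize_life_table",
    "life_expectancy",
    "calibrate_to_life_expectancy",
    "default_life_tables",
    "UNAFFECTED_LIFE_EXPECTANCY",
    "SCD_LIFE_EXPECTANCY",
    "DEFAULT_GOMPERTZ_SLOPE",
]

UNAFFECTED_LIFE_EXPECTANCY = 75.8
SCD_LIFE_EXPECTANCY = 54.9
DEFAULT_GOMPERTZ_SLOPE = 0.085
DEFAULT_MAX_AGE = 100


logger = logging.getLogger(__name__)


class LifeTableError(ValueError):
    pass


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``qx`` indexed by age 0..max_age."""

    qx: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "qx", qx)
        if qx.ndim != 1 or len(qx) < 2:
            raise LifeTableError("life table needs qx for at least ages 0 and 1")
        if ((qx < 0) | (qx > 1)).any():
            bad = int(np.argmax((qx < 0) | (qx > 1)))
            raise LifeTableError(f"qx outside [0, 1] at age {bad}: {qx[bad]}")
        if qx[-1] != 1.0:
            raise LifeTableError(f"terminal qx must be 1; got {qx[-1]}")

    @property
    def max_age(self) -> int:
        return len(self.qx) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": np.arange(len(self.qx)), "qx": self.qx})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class GompertzMakehamParams:
    a: float  # baseline hazard scale
    b: float  # age slope
    c: float = 0.0  # age-independent (Makeham) hazard

    def __post_init__(self) -> None:
        # degenerate limits (a=0 constant-free, b=0 constant hazard) are valid
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise LifeTableError(f"require a, b, c >= 0; got {self}")

    def hazard(self, age) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(age, dtype=float)) + self.c


def read_life_table(file, label: str = "") -> LifeTable:
    """Read an ``age,qx`` CSV; ages must be contiguous from 0.

    A terminal qx below 1 is forced to 1 (cohort extinction at the end of the
    table) with a logged notice; anything else is rejected rather than
    corrected, since silent fixes would mask data errors.
    """
    df = pd.read_csv(file)
    if not {"age", "qx"}.issubset(df.columns):
        raise LifeTableError(f"expected columns age,qx; got {list(df.columns)}")
    ages = df["age"].to_numpy()
    expected = np.arange(len(df))
    if not np.array_equal(ages, expected):
        missing = sorted(set(expected) - set(ages))
        where = f"age {missing[0]}" if missing else f"row {int(np.argmax(ages != expected))}"
        raise LifeTableError(f"ages must be contiguous from 0; problem at {where}")
    qx = df["qx"].to_numpy(dtype=float)
    if ((qx < 0) | (qx > 1)).any():
        row = int(np.argmax((qx < 0) | (qx > 1)))
        raise LifeTableError(f"qx outside [0, 1] at row {row} (age {row}): {qx[row]}")
    if qx[-1] != 1.0:
        logger.warning("terminal qx %.4f at age %d forced to 1", qx[-1], len(qx) - 1)
        qx = qx.copy()
        qx[-1] = 1.0
    return LifeTable(qx, label=label or str(file))


def synthesize_life_table(
    params: GompertzMakehamParams, max_age: int = DEFAULT_MAX_AGE, label: str = ""
) -> LifeTable:
    """qx(age) = 1 - exp(-h(age)) for age < max_age, with qx(max_age) = 1."""
    ages = np.arange(max_age + 1)
    qx = 1.0 - np.exp(-params.hazard(ages))
    qx[-1] = 1.0
    return LifeTable(qx, label=label)


def life_expectancy(table: LifeTable, horizon: int) -> float:
    """Expected years lived over ``horizon`` annual cycles.

    Survivor-years accounting identical to the Markov engine's life-year
    tally: sum over cycles t of S(t), with S(0) = 1 and
    S(t+1) = S(t) * (1 - qx(t)).
    """
    if horizon > len(table.qx):
        raise LifeTableError(f"horizon {horizon} exceeds table length {len(table.qx)}")
    surv = np.concatenate([[1.0], np.cumprod(1.0 - table.qx[: horizon - 1])])
    return float(surv.sum())


def calibrate_to_life_expectancy(
    target_le: float,
    fixed_b: float = DEFAULT_GOMPERTZ_SLOPE,
    horizon: int = DEFAULT_MAX_AGE,
    c: float = 0.0,
    max_age: int = DEFAULT_MAX_AGE,
    tol: float = 0.05,
) -> GompertzMakehamParams:
    """Solve for the Gompertz scale ``a`` matching a target life expectancy.

    Bracketed scalar root-finding on log10(a); life expectancy is strictly
    decreasing in ``a``, so a sign change across the bracket guarantees a
    unique root.
    """
    if not 1.0 < target_le < horizon:
        raise LifeTableError(f"target_le must be in (1, horizon={horizon}); got {target_le}")

    def gap(log_a: float) -> float:
        p = GompertzMakehamParams(10.0**log_a, fixed_b, c)
        return life_expectancy(synthesize_life_table(p, max_age), horizon) - target_le

    lo, hi = -14.0, 0.0
    if gap(lo) < 0 or gap(hi) > 0:
        raise LifeTableError(
            f"target {target_le} not attainable with b={fixed_b}, c={c} "
            f"(bracket a in [1e{lo:.0f}, 1e{hi:.0f}] gives LE "
            f"[{gap(hi) + target_le:.2f}, {gap(lo) + target_le:.2f}])"
        )
    root = brentq(gap, lo, hi, xtol=1e-13)
    params = GompertzMakehamParams(10.0**root, fixed_b, c)
    achieved = life_expectancy(synthesize_life_table(params, max_age), horizon)
    if abs(achieved - target_le) > tol:
        raise LifeTableError(
            f"calibration converged to LE {achieved:.3f}, outside {tol} of {target_le}"
        )
    return params


@functools.lru_cache(maxsize=None)
def _default_tables_cached(horizon: int) -> tuple[LifeTable, LifeTable]:
    unaff = synthesize_life_table(
        calibrate_to_life_expectancy(UNAFFECTED_LIFE_EXPECTANCY, horizon=horizon),
        label="unaffected (calibrated)",
    )
    scd = synthesize_life_table(
        calibrate_to_life_expectancy(SCD_LIFE_EXPECTANCY, horizon=horizon),
        label="scd (calibrated)",
    )
    return unaff, scd


def default_life_tables(horizon: int = DEFAULT_MAX_AGE) -> tuple[LifeTable, LifeTable]:
    """(unaffected, SCD) tables calibrated to the default life expectancies."""
    return _default_tables_cached(horizon)
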