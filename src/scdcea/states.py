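"""Model state space and enumerations.

The cohort model has five mutually exclusive health states: healthy (in
remission after a durable cure), three ordinal sickle cell disease severity
levels managed under standard of care, and death.  Severity is defined by the
annualized vaso-occlusive crisis count: mild = 0 crises/year, moderate = (0, 2)
crises/year, severe = >= 2 crises/year.
"""

from __future__ import annotations

import enum


class State(enum.Enum):
    HEALTHY = "healthy"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    DEAD = "dead"

    @property
    def index(self) -> int:
        return STATE_ORDER.index(self)

    @property
    def is_affected(self) -> bool:
        return self in AFFECTED_STATES

    @property
    def is_alive(self) -> bool:
        return self is not State.DEAD


class Gender(enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Arm(enum.Enum):
    DT = "dt"    # durable therapy at birth, SOC after any relapse
    SOC = "soc"  # standard-of-care management only


STATE_ORDER: tuple[State, ...] = (
    State.HEALTHY,
    State.MILD,
    State.MODERATE,
    State.SEVERE,
    State.DEAD,
)

AFFECTED_STATES: tuple[State, ...] = (State.MILD, State.MODERATE, State.SEVERE)

N_STATES = len(STATE_ORDER)


def as_state(value: "State | str") -> State:
    return value if isinstance(value, State) else State(str(value).lower())


def as_gender(value: "Gender | str") -> Gender:
    if isinstance(value, Gender):
        return value
    v = str(value).lower()
    if v in ("f", "female"):
        return Gender.FEMALE
    if v in ("m", "male"):
        return Gender.MALE
    raise ValueError(f"unknown gender: {value!r}")


def as_arm(value: "Arm | str") -> Arm:
    return value if isinstance(value, Arm) else Arm(str(value).lower())
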