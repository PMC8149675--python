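"""Incremental cost-effectiveness measures and value-of-information curves.

The decision problem compares two strategies: durable therapy at birth (DT)
and standard of care (SOC).  The headline statistic is the incremental
cost-effectiveness ratio ICER = ΔC/ΔQ on discounted per-patient totals,
judged against a willingness-to-pay threshold λ (base case $150,000/QALY).
Net monetary benefit NMB(λ) = λ·Q − C linearises the same decision; from PSA
output it yields the acceptability curve (probability each arm has the highest
NMB), the frontier (arm with highest expected NMB), and the expected value of
perfect information EVPI(λ) = E[max_arm NMB] − max_arm E[NMB].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import ArmResult

__all__ = [
    "CEAResult",
    "VOICurves",
    "icer",
    "nmb",
    "threshold_price",
    "ceac_ceaf",
    "evpi",
    "DEFAULT_LAMBDA_GRID",
]

# 0..300K in 5K steps: covers every WTP level discussed (50K-250K) with margin
DEFAULT_LAMBDA_GRID = np.arange(0, 300_001, 5_000, dtype=float)


@dataclass(frozen=True)
class CEAResult:
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None
    dominance: str  # "none" | "dt_dominant" | "dt_dominated" | "indeterminate"
    nmb_dt: float
    nmb_soc: float
    wtp: float

    @property
    def cost_effective(self) -> bool:
        return self.nmb_dt > self.nmb_soc


@dataclass(frozen=True)
class VOICurves:
    lambda_grid: np.ndarray
    ceac_dt: np.ndarray
    ceac_soc: np.ndarray
    ceaf: np.ndarray  # "dt" or "soc" per λ
    evpi: np.ndarray  # USD per patient per λ

    def to_frames(self):
        import pandas as pd

        ceac = pd.DataFrame(
            {
                "lambda": self.lambda_grid,
                "p_dt": self.ceac_dt,
                "p_soc": self.ceac_soc,
                "frontier_arm": self.ceaf,
            }
        )
        evpi = pd.DataFrame({"lambda": self.lambda_grid, "evpi_usd": self.evpi})
        return ceac, evpi


def nmb(result: ArmResult, wtp: float) -> float:
    """Net monetary benefit λ·QALY − cost on discounted totals."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0; got {wtp}")
    return wtp * result.qaly_disc - result.cost_disc


def icer(dt: ArmResult, soc: ArmResult, wtp: float = 150_000.0) -> CEAResult:
    """Incremental comparison of DT against SOC.

    A finite ICER is reported only in the trade-off quadrants (ΔC and ΔQ with
    the same sign); dominance is flagged otherwise and ΔQ = 0 with ΔC ≠ 0 is
    reported as indeterminate rather than an infinite ratio.
    """
    d_cost = dt.cost_disc - soc.cost_disc
    d_qaly = dt.qaly_disc - soc.qaly_disc
    d_ly = dt.ly_disc - soc.ly_disc
    if d_qaly == 0.0:
        ratio, dom = None, ("none" if d_cost == 0.0 else "indeterminate")
    elif d_qaly > 0 and d_cost <= 0:
        ratio, dom = None, "dt_dominant"
    elif d_qaly < 0 and d_cost >= 0:
        ratio, dom = None, "dt_dominated"
    else:
        ratio, dom = d_cost / d_qaly, "none"
    return CEAResult(
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
        icer=ratio,
        dominance=dom,
        nmb_dt=nmb(dt, wtp),
        nmb_soc=nmb(soc, wtp),
        wtp=wtp,
    )


def threshold_price(base: CEAResult, p0: float, wtp: float) -> float:
    """Upfront price at which the ICER equals the willingness-to-pay.

    The single-administration price enters the incremental cost one-for-one
    and undiscounted (it is paid at time zero), so
    ICER(p) = (ΔC + (p − p0)) / ΔQ is linear in p and
    p* = p0 + (λ·ΔQ − ΔC) solves ICER(p*) = λ exactly.
    """
    if base.delta_qaly <= 0:
        raise ValueError("threshold price requires a QALY-gaining intervention")
    return p0 + (wtp * base.delta_qaly - base.delta_cost)


def _nmb_matrices(psa, lambda_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam = np.asarray(lambda_grid, dtype=float)[:, None]
    nmb_dt = lam * psa.qaly_dt[None, :] - psa.cost_dt[None, :]
    nmb_soc = lam * psa.qaly_soc[None, :] - psa.cost_soc[None, :]
    return nmb_dt, nmb_soc


def ceac_ceaf(
    psa, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID, rule: str = "nmb"
) -> VOICurves:
    """Acceptability curve, frontier and EVPI over a λ grid.

    ``rule="nmb"`` (default) counts the arm with the highest net monetary
    benefit per iteration, ties going to SOC (the incumbent).  The
    compatibility rule ``"icer_threshold"`` counts iterations whose ICER is
    below λ; the two coincide whenever ΔQ > 0 and ΔC > 0, the regime the base
    case occupies, but the NMB rule also behaves sensibly in dominance
    quadrants.
    """
    if psa.n_iter == 0:
        raise ValueError("empty PSA sample set")
    lam = np.asarray(lambda_grid, dtype=float)
    nmb_dt, nmb_soc = _nmb_matrices(psa, lam)
    if rule == "nmb":
        dt_wins = nmb_dt > nmb_soc
    elif rule == "icer_threshold":
        d_cost = psa.cost_dt - psa.cost_soc
        d_qaly = psa.qaly_dt - psa.qaly_soc
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = d_cost / d_qaly
        dt_wins = (d_qaly > 0)[None, :] & (ratio[None, :] < lam[:, None])
    else:
        raise ValueError(f"unknown CEAC rule: {rule}")
    ceac_dt = dt_wins.mean(axis=1)
    frontier = np.where(nmb_dt.mean(axis=1) > nmb_soc.mean(axis=1), "dt", "soc")
    ev = np.maximum(nmb_dt, nmb_soc).mean(axis=1) - np.maximum(
        nmb_dt.mean(axis=1), nmb_soc.mean(axis=1)
    )
    return VOICurves(
        lambda_grid=lam,
        ceac_dt=ceac_dt,
        ceac_soc=1.0 - ceac_dt,
        ceaf=frontier,
        evpi=ev,
    )


def evpi(psa, wtp: float) -> float:
    """Expected value of perfect information at one λ, USD per patient."""
    if psa.n_iter == 0:
        raise ValueError("empty PSA sample set")
    nmb_dt, nmb_soc = _nmb_matrices(psa, np.array([wtp]))
    ev = np.maximum(nmb_dt, nmb_soc).mean() - max(nmb_dt.mean(), nmb_soc.mean())
    return float(ev)
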