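"""Deterministic (one- and two-way) and probabilistic sensitivity analyses.

One-way DSA moves each eligible input to the bounds of its 95% CI (or ±20% of
base when no CI is printed), re-runs the full pipeline — both arms, both
genders, pooled — and records the ICER swing for a tornado diagram.  Two-way
DSA grids two inputs simultaneously and labels each cell with the lowest
willingness-to-pay level at which the durable therapy is cost-effective.

The PSA draws every included parameter jointly from its distribution (10,000
Monte Carlo iterations by default), re-runs the pipeline per draw, and stores
per-iteration discounted totals for the acceptability/EVPI machinery.  Draws
that violate model structure (ordered-logit cut points out of order) are
rejected and redrawn so the stated marginal distributions are preserved;
rejections are counted.  Randomness is driven by a master seed with one
spawned substream per iteration, so any iteration is reproducible in
isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import icer
from .engine import ModelInputs, WaningSpec, build_model_inputs, run_strategies
from .mortality import LifeTable
from .parameters import DsaRule, ParameterSet, dsa_bounds, sample_psa_draw

__all__ = ["TornadoRecord", "PSASampleSet", "one_way_dsa", "two_way_dsa", "run_psa"]

logger = logging.getLogger(__name__)

_Tables = "tuple[LifeTable, LifeTable] | None"


@dataclass(frozen=True)
class TornadoRecord:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    error: str | None = None

    @property
    def swing(self) -> float:
        if self.error is not None:
            return np.nan
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PSASampleSet:
    """Per-iteration parameter draws and discounted totals for both arms."""

    seed: int
    draws: pd.DataFrame
    cost_dt: np.ndarray
    qaly_dt: np.ndarray
    ly_dt: np.ndarray
    cost_soc: np.ndarray
    qaly_soc: np.ndarray
    ly_soc: np.ndarray
    by_gender: dict = field(default_factory=dict)
    n_rejected: int = 0

    @property
    def n_iter(self) -> int:
        return len(self.cost_dt)

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iter),
                "cost_dt": self.cost_dt,
                "qaly_dt": self.qaly_dt,
                "ly_dt": self.ly_dt,
                "cost_soc": self.cost_soc,
                "qaly_soc": self.qaly_soc,
                "ly_soc": self.ly_soc,
            }
        )


def _pooled_icer(
    params: ParameterSet,
    tables,
    waning: WaningSpec,
    inputs: ModelInputs | None = None,
) -> float:
    inputs = inputs if inputs is not None else build_model_inputs(params)
    res = run_strategies(inputs, tables, waning)
    cea = icer(res["dt"]["pooled"], res["soc"]["pooled"], wtp=inputs.wtp)
    if cea.icer is None:
        # dominance has no finite ratio; signed infinity keeps the tornado sortable
        return -np.inf if cea.dominance == "dt_dominant" else np.inf
    return cea.icer


def one_way_dsa(
    params: ParameterSet,
    tables: _Tables = None,
    waning: WaningSpec = WaningSpec.lifetime(),
) -> list[TornadoRecord]:
    """Univariate DSA over every eligible entry, sorted by descending swing."""
    eligible = [e for e in params.entries.values() if e.dsa_rule is not DsaRule.EXCLUDED]
    if not eligible:
        raise ValueError("no DSA-eligible parameters")
    records = []
    for entry in eligible:
        low, high = dsa_bounds(entry)
        try:
            icer_low = _pooled_icer(params.with_values(**{entry.name: low}), tables, waning)
            icer_high = _pooled_icer(params.with_values(**{entry.name: high}), tables, waning)
            records.append(TornadoRecord(entry.name, low, high, icer_low, icer_high))
        except Exception as exc:  # flagged, run continues
            logger.warning("DSA failed for %s: %s", entry.name, exc)
            records.append(TornadoRecord(entry.name, low, high, np.nan, np.nan, str(exc)))
    records.sort(key=lambda r: (np.isnan(r.swing), -r.swing if not np.isnan(r.swing) else 0.0))
    return records


def tornado_frame(records: list[TornadoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in records],
            "low": [r.low for r in records],
            "high": [r.high for r in records],
            "icer_low": [r.icer_at_low for r in records],
            "icer_high": [r.icer_at_high for r in records],
            "swing": [r.swing for r in records],
        }
    )


def two_way_dsa(
    params: ParameterSet,
    param_a: str,
    param_b: str,
    grid_size: int = 11,
    wtp_levels: tuple[float, ...] = (150_000.0, 200_000.0, 250_000.0),
    tables: _Tables = None,
    waning: WaningSpec = WaningSpec.lifetime(),
) -> pd.DataFrame:
    """Joint grid over two DSA ranges; cells labeled by lowest WTP where DT is CE."""
    rows = []
    grid_a = np.linspace(*dsa_bounds(params[param_a]), grid_size)
    grid_b = np.linspace(*dsa_bounds(params[param_b]), grid_size)
    levels = sorted(wtp_levels)
    for va in grid_a:
        for vb in grid_b:
            ratio = _pooled_icer(
                params.with_values(**{param_a: va, param_b: vb}), tables, waning
            )
            region = next((f"ce_at_{int(w)}" for w in levels if ratio <= w), "not_ce")
            rows.append(
                {"value_a": va, "value_b": vb, "icer": ratio, "ce_region": region}
            )
    out = pd.DataFrame(rows)
    out.attrs["param_a"], out.attrs["param_b"] = param_a, param_b
    return out


def run_psa(
    params: ParameterSet,
    n_iter: int = 10_000,
    seed: int = 0,
    tables: _Tables = None,
    waning: WaningSpec = WaningSpec.lifetime(),
    max_redraws: int = 100,
) -> PSASampleSet:
    """Monte Carlo PSA: joint draws, full pipeline per draw, stored totals."""
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1; got {n_iter}")
    children = np.random.SeedSequence(seed).spawn(n_iter)
    draw_rows = []
    totals = {k: np.empty(n_iter) for k in ("cost_dt", "qaly_dt", "ly_dt", "cost_soc", "qaly_soc", "ly_soc")}
    by_gender = {
        g: {k: np.empty(n_iter) for k in ("cost_dt", "qaly_dt", "cost_soc", "qaly_soc")}
        for g in ("female", "male")
    }
    n_rejected = 0
    for k in range(n_iter):
        rng = np.random.default_rng(children[k])
        for attempt in range(max_redraws):
            draw = sample_psa_draw(params, rng)
            try:
                inputs = build_model_inputs(params, draw)
            except ValueError:
                n_rejected += 1
                continue
            break
        else:
            raise RuntimeError(f"iteration {k}: no valid draw in {max_redraws} attempts")
        res = run_strategies(inputs, tables, waning)
        totals["cost_dt"][k] = res["dt"]["pooled"].cost_disc
        totals["qaly_dt"][k] = res["dt"]["pooled"].qaly_disc
        totals["ly_dt"][k] = res["dt"]["pooled"].ly_disc
        totals["cost_soc"][k] = res["soc"]["pooled"].cost_disc
        totals["qaly_soc"][k] = res["soc"]["pooled"].qaly_disc
        totals["ly_soc"][k] = res["soc"]["pooled"].ly_disc
        for g in ("female", "male"):
            by_gender[g]["cost_dt"][k] = res["dt"][g].cost_disc
            by_gender[g]["qaly_dt"][k] = res["dt"][g].qaly_disc
            by_gender[g]["cost_soc"][k] = res["soc"][g].cost_disc
            by_gender[g]["qaly_soc"][k] = res["soc"][g].qaly_disc
        row = dict(draw.values)
        for i, name in enumerate(("mild", "moderate", "severe")):
            row[f"severity_f_{name}"] = draw.severity_f[i]
            row[f"severity_m_{name}"] = draw.severity_m[i]
        draw_rows.append(row)
    if n_rejected:
        logger.info("PSA: %d invalid draws rejected and redrawn", n_rejected)
    return PSASampleSet(
        seed=seed,
        draws=pd.DataFrame(draw_rows),
        by_gender=by_gender,
        n_rejected=n_rejected,
        **totals,
    )
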