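"""End-to-end orchestration: base case, scenarios, DSA, PSA, VOI, manifest.

All randomness flows from one master seed recorded in the manifest; rerunning
with the same configuration and seed reproduces every numerical output
byte-for-byte.  Outputs are plain CSV/JSON so figure data stay
machine-comparable; currency values are written to the cent.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cea import DEFAULT_LAMBDA_GRID, ceac_ceaf, icer, threshold_price
from .engine import WaningSpec, build_model_inputs, run_strategies
from .mortality import LifeTable, default_life_tables, read_life_table
from .parameters import ParameterSet, default_parameters
from .sensitivity import one_way_dsa, run_psa, tornado_frame, two_way_dsa

__all__ = ["RunManifest", "run_base_case", "run_full_report", "resolve_tables"]

_SCENARIOS: dict[str, WaningSpec] = {
    "lifetime": WaningSpec.lifetime(),
    "20yr": WaningSpec.median(20),
    "10yr": WaningSpec.median(10),
}


@dataclass
class RunManifest:
    seed: int | None
    config_hash: str
    version: str = __version__
    outputs: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)

    def register(self, path: Path) -> Path:
        self.outputs.append(path.name)
        return path

    def write(self, out_dir: Path) -> Path:
        """Write manifest JSON including a hash over all numerical outputs."""
        digest = hashlib.sha256()
        for name in sorted(self.outputs):
            digest.update(name.encode())
            digest.update((out_dir / name).read_bytes())
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "outputs": sorted(self.outputs),
            "outputs_sha256": digest.hexdigest(),
            "elapsed_seconds": round(time.time() - self.started, 3),
            **self.extra,
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _config_hash(params: ParameterSet) -> str:
    frame = params.to_frame().to_csv(index=False)
    cohort = json.dumps(
        {
            "n_patients": params.cohort.n_patients,
            "horizon": params.cohort.horizon,
            "wtp": params.cohort.wtp,
        },
        sort_keys=True,
    )
    return hashlib.sha256((frame + cohort).encode()).hexdigest()


def resolve_tables(life_table_dir: "str | Path | None") -> tuple[LifeTable, LifeTable]:
    """Load ``unaffected.csv``/``scd.csv`` from a directory, or use defaults."""
    if life_table_dir is None:
        return default_life_tables()
    d = Path(life_table_dir)
    return (
        read_life_table(d / "unaffected.csv", label="unaffected"),
        read_life_table(d / "scd.csv", label="scd"),
    )


def _results_table(results: dict, n_patients: int) -> pd.DataFrame:
    rows = []
    for arm, by in results.items():
        for stratum, r in by.items():
            rows.append(
                {
                    "arm": arm,
                    "stratum": stratum,
                    "cost_disc": round(r.cost_disc, 2),
                    "qaly_disc": r.qaly_disc,
                    "ly_disc": r.ly_disc,
                    "cost_undisc": round(r.cost_undisc, 2),
                    "qaly_undisc": r.qaly_undisc,
                    "ly_undisc": r.ly_undisc,
                    "cost_total_cohort": round(r.cost_disc * n_patients, 2),
                }
            )
    return pd.DataFrame(rows)


def run_base_case(
    params: ParameterSet | None = None,
    waning: WaningSpec = WaningSpec.lifetime(),
    life_table_dir=None,
    out_dir: "str | Path | None" = None,
    half_cycle: bool = False,
) -> dict:
    """Run both arms (per-gender and pooled) and the incremental comparison.

    Returns a bundle with the six ArmResults, the CEAResult, and the
    discounted/undiscounted results table; optionally writes
    ``results.csv``, ``cea.json`` and per-arm trace CSVs to ``out_dir``.
    """
    params = params if params is not None else default_parameters()
    tables = resolve_tables(life_table_dir)
    inputs = build_model_inputs(params)
    results = run_strategies(inputs, tables, waning, half_cycle=half_cycle, keep_trace=True)
    cea = icer(results["dt"]["pooled"], results["soc"]["pooled"], wtp=inputs.wtp)
    table = _results_table(results, params.cohort.n_patients)
    bundle = {
        "results": results,
        "cea": cea,
        "table": table,
        "inputs": inputs,
        "waning": waning,
        "relapse_prob": waning.p_annual,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = RunManifest(seed=None, config_hash=_config_hash(params))
        manifest.extra["relapse_prob"] = waning.p_annual
        table.to_csv(manifest.register(out_dir / "results.csv"), index=False)
        for arm in ("dt", "soc"):
            results[arm]["pooled"].trace.to_frame().to_csv(
                manifest.register(out_dir / f"trace_{arm}.csv"), index=False
            )
        cea_payload = {
            "delta_cost": round(cea.delta_cost, 2),
            "delta_qaly": cea.delta_qaly,
            "delta_ly": cea.delta_ly,
            "icer": cea.icer,
            "dominance": cea.dominance,
            "wtp": cea.wtp,
            "nmb_dt": round(cea.nmb_dt, 2),
            "nmb_soc": round(cea.nmb_soc, 2),
        }
        p = out_dir / "cea.json"
        p.write_text(json.dumps(cea_payload, indent=2))
        manifest.register(p)
        bundle["manifest"] = manifest.write(out_dir)
    return bundle


def run_full_report(
    params: ParameterSet | None = None,
    out_dir: "str | Path" = "scdcea_report",
    seed: int = 0,
    n_psa: int = 10_000,
    life_table_dir=None,
    two_way_pairs: tuple[tuple[str, str], ...] = (
        ("dt_price", "discount_rate"),
        ("dt_price", "utility_scd_1_18"),
        ("discount_rate", "utility_scd_1_18"),
    ),
) -> dict:
    """Base case + waning scenarios + DSA + PSA + VOI, all written to disk."""
    params = params if params is not None else default_parameters()
    tables = resolve_tables(life_table_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, config_hash=_config_hash(params))

    scenario_rows = []
    bundle: dict = {"scenarios": {}}
    for name, waning in _SCENARIOS.items():
        inputs = build_model_inputs(params)
        results = run_strategies(inputs, tables, waning, keep_trace=(name == "lifetime"))
        cea = icer(results["dt"]["pooled"], results["soc"]["pooled"], wtp=inputs.wtp)
        bundle["scenarios"][name] = {"results": results, "cea": cea}
        scenario_rows.append(
            {
                "scenario": name,
                "relapse_prob": waning.p_annual,
                "delta_cost": round(cea.delta_cost, 2),
                "delta_qaly": cea.delta_qaly,
                "icer": cea.icer,
                "threshold_price": round(
                    threshold_price(cea, inputs.dt_price, inputs.wtp), 2
                ),
            }
        )
        if name == "lifetime":
            _results_table(results, params.cohort.n_patients).to_csv(
                manifest.register(out_dir / "results.csv"), index=False
            )
            for arm in ("dt", "soc"):
                results[arm]["pooled"].trace.to_frame().to_csv(
                    manifest.register(out_dir / f"trace_{arm}.csv"), index=False
                )
    pd.DataFrame(scenario_rows).to_csv(
        manifest.register(out_dir / "scenarios.csv"), index=False
    )

    tornado = tornado_frame(one_way_dsa(params, tables))
    tornado.to_csv(manifest.register(out_dir / "tornado.csv"), index=False)
    bundle["tornado"] = tornado

    for a, b in two_way_pairs:
        grid = two_way_dsa(params, a, b, tables=tables)
        grid.to_csv(manifest.register(out_dir / f"twoway_{a}__{b}.csv"), index=False)

    psa = run_psa(params, n_iter=n_psa, seed=seed, tables=tables)
    psa.draws.to_csv(manifest.register(out_dir / "psa_draws.csv"), index=False)
    psa.results_frame().to_csv(manifest.register(out_dir / "psa_results.csv"), index=False)
    voi = ceac_ceaf(psa, DEFAULT_LAMBDA_GRID)
    ceac_df, evpi_df = voi.to_frames()
    ceac_df.to_csv(manifest.register(out_dir / "ceac.csv"), index=False)
    evpi_df.to_csv(manifest.register(out_dir / "evpi.csv"), index=False)
    bundle["psa"], bundle["voi"] = psa, voi

    manifest.extra["n_psa"] = n_psa
    manifest.extra["psa_rejected_draws"] = psa.n_rejected
    bundle["manifest"] = manifest.write(out_dir)
    return bundle
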