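"""Synthetic patient-year claims panel and regression refitting.

The transition and cost regressions that drive the model were originally
estimated from licensed commercial claims that cannot be shared.  This module
generates a panel with exactly the statistical structure those estimation
steps assume — year-2 severity drawn from the ordered-logit transition rows,
annual cost drawn from a gamma distribution whose mean follows the log-link
GLM — and refits both regressions, enabling end-to-end parameter-recovery
checks of the whole estimation-to-decision pipeline.

Each SCD patient contributes two panel years (the transition regression uses
only consecutive year pairs); unaffected control patients (the cost
regression's reference level, standing in for the propensity-matched controls
of the original design) contribute two years each with severity "healthy".
Crisis rates are drawn consistently with the severity class that defines the
health states: 0 for mild, uniform on (0, 2) for moderate, 2 plus an
exponential tail for severe.  The within-class rate distributions are
generator choices; only the class is used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .engine import build_model_inputs
from .parameters import ParameterSet, default_parameters
from .rewards import CostCoefficients
from .states import Gender, State
from .transitions import OrderedLogitCoefficients, severity_rows_for_ages

__all__ = [
    "GeneratorConfig",
    "classify_severity",
    "generate_panel",
    "fit_transition_model",
    "fit_cost_model",
    "FittedCoefficients",
]

_SEVERITY_LEVELS = ("mild", "moderate", "severe")


def classify_severity(crisis_rate: float) -> State:
    """Severity class from the annualized vaso-occlusive crisis count.

    0 crises/year -> mild; in (0, 2) -> moderate; >= 2 -> severe.
    """
    if crisis_rate < 0:
        raise ValueError(f"crisis_rate must be >= 0; got {crisis_rate}")
    if crisis_rate == 0:
        return State.MILD
    if crisis_rate < 2:
        return State.MODERATE
    return State.SEVERE


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 10_000
    n_controls: int | None = None  # defaults to n_patients
    seed: int = 0
    params: ParameterSet | None = None  # truths; packaged base case if None
    gamma_shape: float = 1.5  # cost dispersion; -> infinity = noiseless
    age_low: int = 0
    age_high: int = 64  # commercially insured population
    percent_female: float = 0.47

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")


@dataclass(frozen=True)
class FittedCoefficients:
    """Point estimates with standard errors from one refitted regression."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    gender: str


def _crisis_rate(sev_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rates consistent with the class: 0 / U(0,2) / 2+Exp(1)."""
    n = len(sev_idx)
    rate = np.zeros(n)
    mod = sev_idx == 1
    u = rng.uniform(0.0, 2.0, size=int(mod.sum()))
    u[u == 0.0] = 1.0  # open interval (0, 2); P(exactly 0) is negligible but not zero
    rate[mod] = u
    sev = sev_idx == 2
    rate[sev] = 2.0 + rng.exponential(1.0, size=int(sev.sum()))
    return rate


def _draw_costs(
    coeffs: CostCoefficients,
    sev_idx: np.ndarray,  # -1 = healthy control, 0/1/2 = mild/moderate/severe
    ages: np.ndarray,
    shape: float,
    rng: np.random.Generator,
) -> np.ndarray:
    icepts, slopes = coeffs.state_terms()
    mean = np.exp(icepts[sev_idx + 1] + slopes[sev_idx + 1] * ages)
    if np.isinf(shape):
        return mean
    return rng.gamma(shape, mean / shape)


def generate_panel(config: GeneratorConfig) -> pd.DataFrame:
    """Two-year patient panel with columns
    ``patient_id, gender, age, year, crisis_rate, severity, annual_cost``.

    SCD patients: year-1 severity from the initial severity Dirichlet
    proportions, year-2 severity from the true ordered-logit transition row at
    the year-1 age; costs from Gamma(shape, mean/shape) with the GLM mean.
    Controls: severity "healthy", control-arm cost prediction.
    """
    params = config.params if config.params is not None else default_parameters()
    inputs = build_model_inputs(params)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_controls = config.n_controls if config.n_controls is not None else n

    frames = []
    for scd in (True, False):
        size = n if scd else n_controls
        if size == 0:
            continue
        female = rng.random(size) < config.percent_female
        ages = rng.integers(config.age_low, config.age_high + 1, size=size)
        ids = np.arange(size) + (0 if scd else 10_000_000)
        for gender, mask in ((Gender.FEMALE, female), (Gender.MALE, ~female)):
            m = int(mask.sum())
            if m == 0:
                continue
            tp = inputs.tp(gender)
            cost_coef = inputs.cost(gender)
            age1 = ages[mask]
            if scd:
                sev1 = rng.choice(3, size=m, p=params.severity(gender).proportions)
                rows = severity_rows_for_ages(tp, age1)  # (m, 3, 3)
                probs = rows[np.arange(m), sev1, :]
                u = rng.random(m)
                sev2 = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
            else:
                sev1 = np.full(m, -1)
                sev2 = np.full(m, -1)
            for year, sev, age in ((1, sev1, age1), (2, sev2, age1 + 1)):
                cost = _draw_costs(cost_coef, sev, age, config.gamma_shape, rng)
                is_scd = sev >= 0
                severity = np.where(
                    is_scd, np.array(_SEVERITY_LEVELS + ("healthy",))[sev], "healthy"
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": ids[mask],
                            "gender": gender.value,
                            "age": age,
                            "year": year,
                            "crisis_rate": np.where(is_scd, _crisis_rate(np.where(is_scd, sev, 0), rng), 0.0),
                            "severity": severity,
                            "annual_cost": cost,
                        }
                    )
                )
    panel = pd.concat(frames, ignore_index=True)
    return panel.sort_values(["patient_id", "year"], kind="stable").reset_index(drop=True)


def _transition_pairs(panel: pd.DataFrame, gender: str) -> pd.DataFrame:
    scd = panel[(panel["gender"] == gender) & (panel["severity"] != "healthy")]
    y1 = scd[scd["year"] == 1].set_index("patient_id")
    y2 = scd[scd["year"] == 2].set_index("patient_id")
    common = y1.index.intersection(y2.index)
    return pd.DataFrame(
        {
            "severity_1": y1.loc[common, "severity"],
            "severity_2": y2.loc[common, "severity"],
            "age": y1.loc[common, "age"],
        }
    )


def fit_transition_model(panel: pd.DataFrame) -> dict[str, FittedCoefficients]:
    """Refit the cumulative-logit transition regression per gender.

    Covariates: moderate/severe indicators for year-1 severity (mild is the
    reference), age at year 1, and both severity-by-age interactions; two cut
    points.  Cut-point standard errors come from the delta method on the
    fitted threshold parameterisation.
    """
    out = {}
    for gender in ("female", "male"):
        pairs = _transition_pairs(panel, gender)
        if len(pairs) == 0:
            raise ValueError(f"panel has no SCD transition pairs for gender={gender}")
        if pairs["severity_2"].nunique() < 3:
            raise ValueError(f"need all 3 severity levels in year 2 for gender={gender}")
        if pairs["age"].nunique() < 2:
            raise ValueError("age has no variation; age coefficients are inestimable")
        exog = pd.DataFrame(
            {
                "moderate": (pairs["severity_1"] == "moderate").astype(float),
                "severe": (pairs["severity_1"] == "severe").astype(float),
                "age": pairs["age"].astype(float),
            }
        )
        exog["moderate_age"] = exog["moderate"] * exog["age"]
        exog["severe_age"] = exog["severe"] * exog["age"]
        endog = pd.Series(
            pd.Categorical(
                pairs["severity_2"], categories=list(_SEVERITY_LEVELS), ordered=True
            ),
            index=pairs.index,
        )
        model = OrderedModel(endog, exog, distr="logit")
        res = model.fit(method="bfgs", disp=False, maxiter=500)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(f"ordered logit did not converge for gender={gender}")
        k = exog.shape[1]
        par = np.asarray(res.params)
        bse = np.asarray(res.bse)
        thresh = model.transform_threshold_params(par)[1:-1]  # kappa1, kappa2
        # delta method for kappa2 = t1 + exp(t2)
        cov_t = np.asarray(res.cov_params())[k:, k:]
        se_k1 = float(np.sqrt(cov_t[0, 0]))
        grad = np.array([1.0, np.exp(par[k + 1])])
        se_k2 = float(np.sqrt(grad @ cov_t @ grad))
        names = ("moderate", "severe", "age", "moderate_age", "severe_age")
        est = {n: float(par[i]) for i, n in enumerate(names)}
        est["cut1"], est["cut2"] = float(thresh[0]), float(thresh[1])
        se = {n: float(bse[i]) for i, n in enumerate(names)}
        se["cut1"], se["cut2"] = se_k1, se_k2
        out[gender] = FittedCoefficients(est, se, gender)
    return out


def fit_cost_model(panel: pd.DataFrame) -> dict[str, FittedCoefficients]:
    """Refit the gamma log-link GLM of annual cost per gender.

    Covariates: mild/moderate/severe indicators against the healthy-control
    reference, age, and the three severity-by-age interactions.
    """
    if (panel["annual_cost"] <= 0).any():
        raise ValueError("annual costs must be positive")
    out = {}
    for gender in ("female", "male"):
        sub = panel[panel["gender"] == gender]
        if len(sub) == 0 or (sub["severity"] == "healthy").sum() == 0:
            raise ValueError(f"cost model needs control patients for gender={gender}")
        exog = pd.DataFrame(
            {
                "mild": (sub["severity"] == "mild").astype(float),
                "moderate": (sub["severity"] == "moderate").astype(float),
                "severe": (sub["severity"] == "severe").astype(float),
                "age": sub["age"].astype(float),
            }
        )
        exog["mild_age"] = exog["mild"] * exog["age"]
        exog["moderate_age"] = exog["moderate"] * exog["age"]
        exog["severe_age"] = exog["severe"] * exog["age"]
        exog = sm.add_constant(exog, prepend=True)
        model = sm.GLM(
            sub["annual_cost"].to_numpy(),
            exog,
            family=sm.families.Gamma(link=sm.families.links.Log()),
        )
        res = model.fit()
        names = {
            "const": "intercept",
            "mild": "mild",
            "moderate": "moderate",
            "severe": "severe",
            "age": "age",
            "mild_age": "mild_age",
            "moderate_age": "moderate_age",
            "severe_age": "severe_age",
        }
        est = {names[c]: float(res.params[c]) for c in exog.columns}
        se = {names[c]: float(res.bse[c]) for c in exog.columns}
        out[gender] = FittedCoefficients(est, se, gender)
    return out
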