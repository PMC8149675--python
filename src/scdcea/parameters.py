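"""Model input registry: base values, uncertainty distributions, DSA/PSA rules.

Every scalar input of the cost-effectiveness model lives here as a
:class:`ParameterEntry` with a base value, an optional 95% CI (used by the
deterministic sensitivity analysis), a sampling distribution (used by the
probabilistic sensitivity analysis), and flags controlling whether the entry
participates in each analysis.  The initial severity mix is carried separately
as a per-gender Dirichlet (:class:`SeverityDistribution`) and sampled jointly.

The packaged default configuration (``data/table1_defaults.yaml``) encodes the
published base case: a 47%-female birth cohort, 3%/year discounting, a 100-year
horizon, a $2.1M single-administration price for the durable therapy, and the
ordered-logit / gamma-GLM regression coefficients that drive transitions and
costs.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import stats

from .states import Gender

__all__ = [
    "DistKind",
    "DistributionSpec",
    "DsaRule",
    "ParameterEntry",
    "CohortConfig",
    "SeverityDistribution",
    "ParameterSet",
    "ParameterDraw",
    "load_parameters",
    "default_parameters",
    "dsa_bounds",
    "sample_psa_draw",
    "REQUIRED_PARAMETERS",
]


class ParameterError(ValueError):
    """Raised when a configuration violates the registry's invariants."""


class DistKind(enum.Enum):
    BETA = "beta"
    DIRICHLET = "dirichlet"
    NORMAL = "normal"
    TRUNCATED_NORMAL_01 = "truncated_normal_01"
    UNIFORM = "uniform"
    FIXED = "fixed"


class DsaRule(enum.Enum):
    CI95 = "ci95"
    PLUS_MINUS_20PCT = "plus_minus_20pct"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class DistributionSpec:
    kind: DistKind
    params: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        k, p = self.kind, self.params
        if k is DistKind.BETA:
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ParameterError(f"beta requires alpha, beta > 0; got {p}")
        elif k is DistKind.DIRICHLET:
            if len(p) < 2 or any(a <= 0 for a in p):
                raise ParameterError(f"dirichlet requires positive alphas; got {p}")
        elif k in (DistKind.NORMAL, DistKind.TRUNCATED_NORMAL_01):
            if len(p) != 2 or p[1] <= 0:
                raise ParameterError(f"normal requires mu, sigma > 0; got {p}")
        elif k is DistKind.UNIFORM:
            if len(p) != 2 or not p[0] < p[1]:
                raise ParameterError(f"uniform requires a < b; got {p}")
        elif k is DistKind.FIXED:
            if p:
                raise ParameterError("fixed distribution takes no parameters")

    def sample(self, rng: np.random.Generator, base_value: float) -> float:
        """Draw one value; ``fixed`` returns the base value unchanged."""
        k, p = self.kind, self.params
        if k is DistKind.FIXED:
            return base_value
        if k is DistKind.BETA:
            return float(rng.beta(p[0], p[1]))
        if k is DistKind.NORMAL:
            return float(rng.normal(p[0], p[1]))
        if k is DistKind.TRUNCATED_NORMAL_01:
            mu, sigma = p
            a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
            return float(stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, random_state=rng))
        if k is DistKind.UNIFORM:
            return float(rng.uniform(p[0], p[1]))
        raise ParameterError(f"scalar sampling not defined for {k}")


@dataclass(frozen=True)
class ParameterEntry:
    name: str
    base_value: float
    distribution: DistributionSpec
    ci95: tuple[float, float] | None = None
    dsa_rule: DsaRule = DsaRule.EXCLUDED
    psa_included: bool = False
    gender_scope: str = "both"  # female | male | both

    def __post_init__(self) -> None:
        if self.ci95 is not None:
            low, high = self.ci95
            # printed CIs are rounded, so the base may sit on a bound
            if not (low < high and low <= self.base_value <= high):
                raise ParameterError(
                    f"{self.name}: base {self.base_value} outside CI {self.ci95}"
                )
        if self.dsa_rule is DsaRule.CI95 and self.ci95 is None:
            raise ParameterError(f"{self.name}: dsa_rule=ci95 requires a 95% CI")


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 10_000
    percent_female: float = 0.47
    discount_rate: float = 0.03
    horizon: int = 100
    dt_price: float = 2_100_000.0
    wtp: float = 150_000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_female <= 1.0:
            raise ParameterError(f"percent_female must be in [0, 1]; got {self.percent_female}")
        if self.discount_rate < 0:
            raise ParameterError(f"discount_rate must be >= 0; got {self.discount_rate}")
        if self.horizon < 1:
            raise ParameterError(f"horizon must be >= 1; got {self.horizon}")
        if self.dt_price < 0:
            raise ParameterError(f"dt_price must be >= 0; got {self.dt_price}")
        if self.n_patients < 1:
            raise ParameterError(f"n_patients must be >= 1; got {self.n_patients}")


@dataclass(frozen=True)
class SeverityDistribution:
    """Initial mild/moderate/severe mix for one gender, as Dirichlet counts."""

    alphas: tuple[float, float, float]
    fixed: bool = False  # degenerate (point-mass) sampling for PSA equivalence checks

    def __post_init__(self) -> None:
        if len(self.alphas) != 3 or any(a <= 0 for a in self.alphas):
            raise ParameterError(f"severity alphas must be 3 positive counts; got {self.alphas}")

    @property
    def proportions(self) -> np.ndarray:
        a = np.asarray(self.alphas, dtype=float)
        return a / a.sum()

    @property
    def distribution(self) -> DistributionSpec:
        return DistributionSpec(DistKind.DIRICHLET, tuple(float(a) for a in self.alphas))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        if self.fixed:
            return self.proportions
        return rng.dirichlet(np.asarray(self.alphas, dtype=float))


# every name the packaged base case must define; completeness is validated on load
REQUIRED_PARAMETERS: tuple[str, ...] = (
    "discount_rate",
    "n_patients",
    "percent_female",
    "dt_price",
    "utility_control_f_1_44",
    "utility_control_f_45_54",
    "utility_control_f_55_64",
    "utility_control_f_65_74",
    "utility_control_f_75_plus",
    "utility_control_m_1_44",
    "utility_control_m_45_54",
    "utility_control_m_55_64",
    "utility_control_m_65_74",
    "utility_control_m_75_plus",
    "utility_scd_1_18",
    "utility_scd_19_plus",
    "tp_f_moderate",
    "tp_f_severe",
    "tp_f_age",
    "tp_f_moderate_age",
    "tp_f_severe_age",
    "tp_f_cut1",
    "tp_f_cut2",
    "tp_m_moderate",
    "tp_m_severe",
    "tp_m_age",
    "tp_m_moderate_age",
    "tp_m_severe_age",
    "tp_m_cut1",
    "tp_m_cut2",
    "cost_f_intercept",
    "cost_f_mild",
    "cost_f_moderate",
    "cost_f_severe",
    "cost_f_age",
    "cost_f_mild_age",
    "cost_f_moderate_age",
    "cost_f_severe_age",
    "cost_m_intercept",
    "cost_m_mild",
    "cost_m_moderate",
    "cost_m_severe",
    "cost_m_age",
    "cost_m_mild_age",
    "cost_m_moderate_age",
    "cost_m_severe_age",
)


@dataclass(frozen=True)
class ParameterSet:
    entries: dict[str, ParameterEntry]
    cohort: CohortConfig
    severity_f: SeverityDistribution
    severity_m: SeverityDistribution

    def __post_init__(self) -> None:
        missing = [n for n in REQUIRED_PARAMETERS if n not in self.entries]
        if missing:
            raise ParameterError(f"missing parameters: {', '.join(missing)}")

    def __getitem__(self, name: str) -> ParameterEntry:
        return self.entries[name]

    def value(self, name: str) -> float:
        return self.entries[name].base_value

    def severity(self, gender: Gender | str) -> SeverityDistribution:
        from .states import as_gender

        return self.severity_f if as_gender(gender) is Gender.FEMALE else self.severity_m

    def with_values(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the named entries' base values replaced."""
        entries = dict(self.entries)
        for name, value in overrides.items():
            if name not in entries:
                raise ParameterError(f"unknown parameter: {name}")
            # the override may leave the printed CI, which then no longer applies
            entries[name] = replace(
                entries[name],
                base_value=float(value),
                ci95=None,
                dsa_rule=DsaRule.EXCLUDED,
            )
        cohort = replace(
            self.cohort,
            percent_female=entries["percent_female"].base_value,
            discount_rate=entries["discount_rate"].base_value,
            dt_price=entries["dt_price"].base_value,
        )
        return ParameterSet(entries, cohort, self.severity_f, self.severity_m)

    def with_fixed_distributions(self) -> "ParameterSet":
        """Degenerate copy: every distribution becomes a point mass at base."""
        entries = {
            n: replace(e, distribution=DistributionSpec(DistKind.FIXED))
            for n, e in self.entries.items()
        }
        sev_f = replace(self.severity_f, fixed=True)
        sev_m = replace(self.severity_m, fixed=True)
        return ParameterSet(entries, self.cohort, sev_f, sev_m)

    def to_frame(self):
        """Tabular dump (name, base, ci, distribution, rules) as a DataFrame."""
        import pandas as pd

        rows = []
        for e in self.entries.values():
            rows.append(
                {
                    "name": e.name,
                    "base": e.base_value,
                    "ci_low": e.ci95[0] if e.ci95 else np.nan,
                    "ci_high": e.ci95[1] if e.ci95 else np.nan,
                    "dist_kind": e.distribution.kind.value,
                    "dist_params": ";".join(repr(p) for p in e.distribution.params),
                    "dsa_rule": e.dsa_rule.value,
                    "psa_included": e.psa_included,
                    "gender_scope": e.gender_scope,
                }
            )
        for g, sev in (("female", self.severity_f), ("male", self.severity_m)):
            rows.append(
                {
                    "name": f"severity_{g}",
                    "base": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "dist_kind": "dirichlet",
                    "dist_params": ";".join(repr(a) for a in sev.alphas),
                    "dsa_rule": "excluded",
                    "psa_included": True,
                    "gender_scope": g,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ParameterDraw:
    """One joint realisation of all model inputs (one PSA iteration)."""

    values: dict[str, float]
    severity_f: np.ndarray = field(default=None)  # type: ignore[assignment]
    severity_m: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _parse_entry(name: str, raw: dict) -> ParameterEntry:
    try:
        dist = DistributionSpec(
            DistKind(raw["dist"]["kind"]), tuple(float(p) for p in raw["dist"]["params"])
        )
        ci = tuple(float(v) for v in raw["ci95"]) if raw.get("ci95") else None
        return ParameterEntry(
            name=name,
            base_value=float(raw["base"]),
            distribution=dist,
            ci95=ci,  # type: ignore[arg-type]
            dsa_rule=DsaRule(raw.get("dsa", "excluded")),
            psa_included=bool(raw.get("psa", False)),
            gender_scope=raw.get("gender", "both"),
        )
    except (KeyError, TypeError) as exc:
        raise ParameterError(f"parameter {name!r}: malformed entry ({exc})") from exc


def load_parameters(config_source: "str | dict | None" = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet`.

    Parameters
    ----------
    config_source
        ``None`` for the packaged base case, a path to a YAML/JSON file with
        the same schema, or an already-parsed mapping.
    """
    if config_source is None:
        ref = importlib.resources.files("scdcea.data") / "table1_defaults.yaml"
        raw = yaml.safe_load(ref.read_text())
    elif isinstance(config_source, dict):
        raw = config_source
    else:
        with open(config_source) as fh:
            raw = yaml.safe_load(fh)

    if not isinstance(raw, dict) or "entries" not in raw:
        raise ParameterError("config must be a mapping with an 'entries' section")

    entries = {name: _parse_entry(name, spec) for name, spec in raw["entries"].items()}

    sev_raw = raw.get("severity", {})
    try:
        severity_f = SeverityDistribution(tuple(float(a) for a in sev_raw["female"]["alphas"]))
        severity_m = SeverityDistribution(tuple(float(a) for a in sev_raw["male"]["alphas"]))
    except KeyError as exc:
        raise ParameterError(f"missing severity section: {exc}") from exc

    cohort_raw = raw.get("cohort", {})
    missing = [n for n in REQUIRED_PARAMETERS if n not in entries]
    if missing:
        raise ParameterError(f"missing parameters: {', '.join(missing)}")
    cohort = CohortConfig(
        n_patients=int(cohort_raw.get("n_patients", entries["n_patients"].base_value)),
        percent_female=entries["percent_female"].base_value,
        discount_rate=entries["discount_rate"].base_value,
        horizon=int(cohort_raw.get("horizon", 100)),
        dt_price=entries["dt_price"].base_value,
        wtp=float(cohort_raw.get("wtp", 150_000.0)),
    )
    return ParameterSet(entries, cohort, severity_f, severity_m)


def default_parameters() -> ParameterSet:
    """The packaged base case."""
    return load_parameters(None)


def dsa_bounds(entry: ParameterEntry) -> tuple[float, float]:
    """Low/high evaluation points for one-way deterministic sensitivity analysis."""
    if entry.dsa_rule is DsaRule.EXCLUDED:
        raise ParameterError(f"{entry.name} is excluded from DSA")
    if entry.dsa_rule is DsaRule.CI95:
        return entry.ci95  # type: ignore[return-value]
    low, high = 0.8 * entry.base_value, 1.2 * entry.base_value
    return (min(low, high), max(low, high))


def sample_psa_draw(params: ParameterSet, rng: np.random.Generator) -> ParameterDraw:
    """Draw one joint PSA realisation.

    Entries flagged ``psa_included`` are drawn independently from their
    distributions; everything else stays at base.  The two severity Dirichlets
    are drawn jointly (one 3-vector per gender).
    """
    values = {}
    for name, e in params.entries.items():
        if e.psa_included:
            values[name] = e.distribution.sample(rng, e.base_value)
        else:
            values[name] = e.base_value
    return ParameterDraw(
        values=values,
        severity_f=params.severity_f.sample(rng),
        severity_m=params.severity_m.sample(rng),
    )
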