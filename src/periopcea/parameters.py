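"""Typed container and file I/O for all model inputs.

The base-case inputs are a flat table of scalar parameters (unit drug prices,
event costs, utilities, SAE risks, cohort anthropometrics, trial proportions)
each carrying a deterministic-sensitivity range and a probabilistic class,
plus structured blocks (parametric survival specifications and the
chemotherapy regimen) kept in a JSON sidecar.  A packaged fixture reproduces
the published base-case table; missing mandatory names are an error, never a
silent default.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PSA_CLASSES",
    "MANDATORY_NAMES",
    "Parameter",
    "ParameterTable",
    "Regimen",
    "load_parameters",
    "save_parameters",
    "default_ranges",
    "packaged_table",
    "packaged_survival_specs",
]

PSA_CLASSES = ("gamma", "beta", "normal", "uniform", "fixed")

#: every scalar parameter referenced by the downstream model
MANDATORY_NAMES = (
    "body_weight_kg",
    "bsa_m2",
    "discount_rate",
    "p_surgery_mortality_30d",
    "proportion_surgery_or_rt_pembrolizumab",
    "proportion_surgery_or_rt_placebo",
    "proportion_adjuvant_uptake",
    "nonsquamous_fraction",
    "fraction_radiotherapy",
    "price_pembrolizumab_mg",
    "price_cisplatin_mg",
    "price_pemetrexed_mg",
    "price_gemcitabine_mg",
    "cost_radiotherapy",
    "cost_surgery",
    "infusion_first_hour",
    "infusion_additional_hour",
    "infusion_subsequent_hour",
    "cost_best_supportive_care",
    "cost_end_of_life",
    "cost_follow_up",
    "sae_cost_anemia",
    "sae_cost_neutropenia",
    "sae_cost_thrombocytopenia",
    "utility_radiotherapy",
    "utility_surgery",
    "utility_PD",
    "utility_PF",
    "disutility_anemia",
    "disutility_neutropenia",
    "disutility_thrombocytopenia",
    "sae_risk_anemia_pembrolizumab",
    "sae_risk_neutropenia_pembrolizumab",
    "sae_risk_thrombocytopenia_pembrolizumab",
    "sae_risk_anemia_placebo",
    "sae_risk_neutropenia_placebo",
    "sae_risk_thrombocytopenia_placebo",
)

_UTILITY_UNITS = ("utility", "disutility")
_WIDE_UNITS = ("USD", "USD/mg", "probability", "m2", "kg", "hours")  # +/-25% classes


@dataclass(frozen=True)
class Parameter:
    """One model input with its base value, sensitivity range and PSA class."""

    name: str
    base_value: float
    low: float | None = None
    high: float | None = None
    psa_class: str = "fixed"
    units: str = ""

    def __post_init__(self) -> None:
        if self.psa_class not in PSA_CLASSES:
            raise ValueError(f"{self.name}: unknown psa_class {self.psa_class!r}")
        if not math.isfinite(self.base_value):
            raise ValueError(f"{self.name}: base value must be finite")
        if self.units in ("probability", "utility", "disutility") and not 0.0 <= self.base_value <= 1.0:
            raise ValueError(f"{self.name}: value {self.base_value} outside [0, 1]")
        if self.units.startswith("USD") and self.base_value < 0:
            raise ValueError(f"{self.name}: cost must be nonnegative")
        if self.low is not None and self.high is not None:
            if not (self.low <= self.base_value <= self.high):
                raise ValueError(
                    f"{self.name}: base {self.base_value} outside range "
                    f"[{self.low}, {self.high}]")

    @property
    def has_range(self) -> bool:
        return self.low is not None and self.high is not None


@dataclass(frozen=True)
class Regimen:
    """Drug doses per administration and the chemotherapy-backbone mix.

    Cisplatin is paired with pemetrexed (nonsquamous histology, day 1) or
    gemcitabine (squamous, days 1 and 8); ``nonsquamous_fraction`` mixes the
    two backbones.  Pembrolizumab is a 200 mg flat dose every 21 days.
    """

    pembrolizumab_mg: float = 200.0
    cisplatin_mg_m2: float = 75.0
    pemetrexed_mg_m2: float = 500.0
    gemcitabine_mg_m2: float = 1000.0
    gemcitabine_administrations: int = 2
    infusion_hours_per_visit: float = 3.0
    nonsquamous_fraction: float = 0.568

    def __post_init__(self) -> None:
        for f in ("pembrolizumab_mg", "cisplatin_mg_m2", "pemetrexed_mg_m2",
                  "gemcitabine_mg_m2"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")
        if not 0.0 <= self.nonsquamous_fraction <= 1.0:
            raise ValueError("nonsquamous_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ParameterTable:
    """All scalar inputs keyed by name, plus cohort anthropometrics."""

    parameters: dict = field(default_factory=dict)
    arm_labels: tuple = ("pembrolizumab", "placebo")
    age_years: float = 65.0

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError("cohort age must be positive")

    def __getitem__(self, name: str) -> Parameter:
        try:
            return self.parameters[name]
        except KeyError:
            raise KeyError(f"parameter {name!r} is not defined in the table") from None

    def __contains__(self, name: str) -> bool:
        return name in self.parameters

    def value(self, name: str) -> float:
        return self[name].base_value

    @property
    def cohort(self) -> dict:
        return {"age_years": self.age_years,
                "weight_kg": self.value("body_weight_kg"),
                "bsa_m2": self.value("bsa_m2")}

    def with_value(self, name: str, value: float) -> "ParameterTable":
        """Copy of the table with one base value replaced (range left as-is)."""
        p = self[name]
        low = min(p.low, value) if p.low is not None else None
        high = max(p.high, value) if p.high is not None else None
        new = replace(p, base_value=value, low=low, high=high)
        params = dict(self.parameters)
        params[name] = new
        return replace(self, parameters=params)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"name": p.name, "base": p.base_value, "low": p.low, "high": p.high,
                 "psa_class": p.psa_class, "units": p.units}
                for p in self.parameters.values()]
        return pd.DataFrame(rows)


def _table_from_frame(df: pd.DataFrame, *, require_all: bool = True) -> ParameterTable:
    params = {}
    for row in df.itertuples(index=False):
        low = None if pd.isna(row.low) else float(row.low)
        high = None if pd.isna(row.high) else float(row.high)
        params[row.name] = Parameter(name=row.name, base_value=float(row.base),
                                     low=low, high=high,
                                     psa_class=str(row.psa_class), units=str(row.units))
    unknown = sorted(set(params) - set(MANDATORY_NAMES))
    if unknown:
        warnings.warn(f"unknown parameter name(s) in table: {unknown}", stacklevel=3)
    if require_all:
        missing = sorted(set(MANDATORY_NAMES) - set(params))
        if missing:
            raise KeyError(f"parameter table is missing mandatory name(s): {missing}")
    return ParameterTable(parameters=params)


def load_parameters(path) -> ParameterTable:
    """Load and validate a parameter table from a CSV file.

    Expected header: ``name,base,low,high,psa_class,units``.  Every mandatory
    name must be present; unknown names produce a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    expected = {"name", "base", "low", "high", "psa_class", "units"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}")
    return _table_from_frame(df)


def save_parameters(table: ParameterTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def default_ranges(table: ParameterTable) -> ParameterTable:
    """Fill missing sensitivity bounds: +/-25% for costs, proportions and
    anthropometrics, +/-10% for utilities; the discount rate gets [0, 0.08].

    Idempotent: parameters that already carry explicit bounds are untouched.
    """
    params = dict(table.parameters)
    for name, p in params.items():
        if p.has_range:
            continue
        if name == "discount_rate":
            low, high = 0.0, 0.08
        elif p.units in _UTILITY_UNITS:
            low, high = p.base_value * 0.9, p.base_value * 1.1
        else:
            low, high = p.base_value * 0.75, p.base_value * 1.25
        if p.units in ("probability", "utility", "disutility"):
            high = min(high, 1.0)
        params[name] = replace(p, low=low, high=high)
    return replace(table, parameters=params)


def fractional_ranges(table: ParameterTable) -> ParameterTable:
    """Recompute every non-fixed range from the stated variance rule.

    The deterministic sensitivity method defines the limits as exact +/-25%
    (costs, proportions, anthropometrics) or +/-10% (utilities) of the base
    value, while printed tables round them; this restores the exact bounds.
    The discount rate keeps [0, 0.08].
    """
    params = {}
    for name, p in table.parameters.items():
        if p.psa_class == "fixed":
            params[name] = p
            continue
        if name == "discount_rate":
            low, high = 0.0, 0.08
        elif p.units in _UTILITY_UNITS:
            low, high = p.base_value * 0.9, p.base_value * 1.1
        else:
            low, high = p.base_value * 0.75, p.base_value * 1.25
        if p.units in ("probability", "utility", "disutility"):
            high = min(high, 1.0)
        params[name] = replace(p, low=low, high=high)
    return replace(table, parameters=params)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("periopcea").joinpath("data", name)


def packaged_table() -> ParameterTable:
    """The packaged base-case parameter table."""
    with resources.as_file(_data_path("table1.csv")) as p:
        return load_parameters(p)


def packaged_survival_specs() -> dict:
    """Base-case parametric survival specifications per arm (months).

    Returns ``{arm: {"os": SurvivalModelSpec, "efs": SurvivalModelSpec}}``.
    """
    from periopcea.survival_models import SurvivalModelSpec

    raw = json.loads(_data_path("survival_specs.json").read_text())
    return {arm: {endpoint: SurvivalModelSpec.from_dict(spec)
                  for endpoint, spec in endpoints.items()}
            for arm, endpoints in raw.items()}


def regimen_from_table(table: ParameterTable, **overrides) -> Regimen:
    """Build the regimen, wiring the histology mix from the parameter table."""
    kw = {"nonsquamous_fraction": table.value("nonsquamous_fraction")}
    kw.update(overrides)
    return Regimen(**kw)
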