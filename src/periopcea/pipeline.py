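"""Glue between the parameter table and the model layers: the base-case run.

`run_base_case` assembles the engine configuration, cost and utility models
from a :class:`~periopcea.parameters.ParameterTable`, runs both strategy arms
over the horizon, and returns the incremental comparison at the chosen
willingness-to-pay threshold.  Every analysis layer (tornado, PSA, scenarios)
funnels through this function so that a single set of structural settings
governs all results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from periopcea.economics import ArmResult, CEResult, CostModel, UtilityModel, accrue, compare
from periopcea.markov_engine import EngineConfig, run_cohort
from periopcea.parameters import ParameterTable, Regimen, packaged_survival_specs, packaged_table, regimen_from_table

__all__ = ["ModelSettings", "horizon_cycles", "build_engine_config", "build_cost_model",
           "build_utility_model", "run_arm", "run_base_case"]


@dataclass(frozen=True)
class ModelSettings:
    """Structural choices held fixed across an analysis (not Table-1 inputs)."""

    horizon_years: float = 10.0
    wtp: float = 150_000.0
    half_cycle: str = "half"
    use_background_mortality: bool = True
    neoadjuvant_cycles: int = 4
    adjuvant_max_cycles: int = 13
    pd_chemo_cycles: int = 6
    window_neo_to_surg: tuple[int, int] = (5, 6)
    window_surg_to_adj: tuple[int, int] = (6, 10)
    follow_up_every_cycles: int = 1
    bsc_every_cycles: int = 3
    charge_pd_radiotherapy: bool = False
    survival_specs: dict | None = None  # arm -> {"os": spec, "efs": spec}; None = packaged


def horizon_cycles(years: float) -> int:
    """Number of whole 21-day cycles in a horizon of ``years`` (10 y -> 174)."""
    return round(years * 365.25 / 21.0)


def build_engine_config(table: ParameterTable, settings: ModelSettings) -> EngineConfig:
    specs = settings.survival_specs or packaged_survival_specs()
    return EngineConfig(
        os_specs={arm: specs[arm]["os"] for arm in table.arm_labels},
        efs_specs={arm: specs[arm]["efs"] for arm in table.arm_labels},
        horizon_cycles=horizon_cycles(settings.horizon_years),
        window_neo_to_surg=settings.window_neo_to_surg,
        window_surg_to_adj=settings.window_surg_to_adj,
        proportion_surgery_or_rt={
            "pembrolizumab": table.value("proportion_surgery_or_rt_pembrolizumab"),
            "placebo": table.value("proportion_surgery_or_rt_placebo"),
        },
        proportion_adjuvant_uptake=table.value("proportion_adjuvant_uptake"),
        fraction_radiotherapy=table.value("fraction_radiotherapy"),
        p_surgery_mortality_30d=table.value("p_surgery_mortality_30d"),
        adjuvant_max_cycles=settings.adjuvant_max_cycles,
        pd_chemo_cycles=settings.pd_chemo_cycles,
        start_age=table.age_years,
        use_background_mortality=settings.use_background_mortality,
    )


def build_cost_model(table: ParameterTable, settings: ModelSettings) -> CostModel:
    return CostModel(
        price_pembrolizumab_mg=table.value("price_pembrolizumab_mg"),
        price_cisplatin_mg=table.value("price_cisplatin_mg"),
        price_pemetrexed_mg=table.value("price_pemetrexed_mg"),
        price_gemcitabine_mg=table.value("price_gemcitabine_mg"),
        cost_surgery=table.value("cost_surgery"),
        cost_radiotherapy=table.value("cost_radiotherapy"),
        cost_end_of_life=table.value("cost_end_of_life"),
        cost_best_supportive_care=table.value("cost_best_supportive_care"),
        cost_follow_up=table.value("cost_follow_up"),
        infusion_first_hour=table.value("infusion_first_hour"),
        infusion_additional_hour=table.value("infusion_additional_hour"),
        infusion_subsequent_hour=table.value("infusion_subsequent_hour"),
        sae_costs={s: table.value(f"sae_cost_{s}")
                   for s in ("anemia", "neutropenia", "thrombocytopenia")},
        follow_up_every_cycles=settings.follow_up_every_cycles,
        bsc_every_cycles=settings.bsc_every_cycles,
        charge_pd_radiotherapy=settings.charge_pd_radiotherapy,
    )


def build_utility_model(table: ParameterTable) -> UtilityModel:
    saes = ("anemia", "neutropenia", "thrombocytopenia")
    return UtilityModel(
        u_pf=table.value("utility_PF"),
        u_surgery=table.value("utility_surgery"),
        u_radiotherapy=table.value("utility_radiotherapy"),
        u_pd=table.value("utility_PD"),
        sae_disutilities={s: table.value(f"disutility_{s}") for s in saes},
        sae_risks={arm: {s: table.value(f"sae_risk_{s}_{arm}") for s in saes}
                   for arm in table.arm_labels},
    )


def run_arm(table: ParameterTable, arm: str, settings: ModelSettings | None = None) -> ArmResult:
    """Run the cohort model for one arm and accrue discounted outcomes."""
    settings = settings or ModelSettings()
    cfg = build_engine_config(table, settings)
    trace = run_cohort(cfg, arm)
    return accrue(
        trace,
        build_cost_model(table, settings),
        build_utility_model(table),
        regimen_from_table(table),
        bsa=table.value("bsa_m2"),
        discount_rate=table.value("discount_rate"),
        half_cycle=settings.half_cycle,
        neoadjuvant_cycles=settings.neoadjuvant_cycles,
    )


def run_base_case(table: ParameterTable | None = None,
                  settings: ModelSettings | None = None) -> CEResult:
    """Full two-arm run on a parameter table (packaged fixture by default)."""
    table = table or packaged_table()
    settings = settings or ModelSettings()
    pem = run_arm(table, "pembrolizumab", settings)
    pla = run_arm(table, "placebo", settings)
    return compare(pem, pla, wtp=settings.wtp)
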