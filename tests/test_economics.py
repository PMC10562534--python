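import math
from dataclasses import replace

import numpy as np
import pytest

from periopcea.economics import (
    ArmResult,
    CostModel,
    UtilityModel,
    accrue,
    compare,
    cycle_cost,
    per_cycle_discount,
)
from periopcea.markov_engine import run_cohort
from periopcea.parameters import Regimen
from periopcea.pipeline import ModelSettings, build_engine_config, run_base_case
from periopcea.survival_models import SurvivalModelSpec


def test_discount_factor_boundaries():
    assert per_cycle_discount(0.03, 0) == 1.0
    assert per_cycle_discount(0.0, 100) == 1.0
    one_year_cycles = 365.25 / 21.0
    assert per_cycle_discount(0.03, one_year_cycles) == pytest.approx(1.0 / 1.03, abs=1e-12)
    with pytest.raises(ValueError):
        per_cycle_discount(-0.01, 1)


def test_drug_cost_arithmetic():
    costs = CostModel()
    regimen = Regimen()
    neo = cycle_cost("NEOADJ", 1, "pembrolizumab", costs, regimen, bsa=1.86)
    assert neo["drug_pembrolizumab"] == pytest.approx(200 * 54.81)  # 10,962.00 USD
    # cisplatin backbone: 75 mg/m2 x 1.86 m2 x 0.32 USD/mg = 44.64 USD
    neo_placebo = cycle_cost("NEOADJ", 1, "placebo", costs, regimen, bsa=1.86)
    assert neo_placebo["drug_pembrolizumab"] == 0.0
    cis_only = cycle_cost("NEOADJ", 1, "placebo", costs, replace(regimen, pemetrexed_mg_m2=0.0,
                                                                 gemcitabine_mg_m2=0.0),
                          bsa=1.86)
    assert cis_only["drug_chemotherapy"] == pytest.approx(44.64)
    # placebo arm accrues no drug cost in the adjuvant phase
    assert cycle_cost("ADJ_3", 20, "placebo", costs, regimen, bsa=1.86) == {}
    with pytest.raises(ValueError):
        cycle_cost("LIMBO", 1, "placebo", costs, regimen, bsa=1.86)


def _idle_trace(table, settings):
    """Trace with no deaths, no progression, no window moves."""
    inert = SurvivalModelSpec("exponential", {"rate": 1e-12})
    cfg = build_engine_config(table.with_value("p_surgery_mortality_30d", 0.0), settings)
    return run_cohort(replace(cfg,
                              os_specs={a: inert for a in cfg.os_specs},
                              efs_specs={a: inert for a in cfg.efs_specs},
                              proportion_surgery_or_rt={a: 0.0 for a in cfg.os_specs},
                              proportion_adjuvant_uptake=0.0,
                              use_background_mortality=False), "placebo")


def test_qaly_accrual_identity_without_death_or_discount(table, settings):
    trace = _idle_trace(table, settings)
    utilities = UtilityModel(u_pf=1.0, u_surgery=1.0, u_radiotherapy=1.0, u_pd=1.0,
                             sae_risks={"placebo": {"anemia": 0, "neutropenia": 0,
                                                    "thrombocytopenia": 0},
                                        "pembrolizumab": {"anemia": 0, "neutropenia": 0,
                                                          "thrombocytopenia": 0}})
    res = accrue(trace, CostModel(), utilities, Regimen(), bsa=1.86, discount_rate=0.0)
    assert res.total_qaly == pytest.approx(174 * 21.0 / 365.25, abs=1e-9)  # ~10.004 years
    assert res.life_years == pytest.approx(174 * 21.0 / 365.25, abs=1e-9)


def test_higher_discount_lowers_both_streams(table, settings):
    res0 = run_base_case(table.with_value("discount_rate", 0.0), settings)
    res8 = run_base_case(table.with_value("discount_rate", 0.08), settings)
    for arm in ("intervention", "comparator"):
        assert getattr(res8, arm).total_cost < getattr(res0, arm).total_cost
        assert getattr(res8, arm).total_qaly < getattr(res0, arm).total_qaly


def test_discounted_totals_below_undiscounted(base_result):
    for arm in (base_result.intervention, base_result.comparator):
        assert arm.total_cost < arm.total_cost_undiscounted
        assert arm.total_qaly < arm.total_qaly_undiscounted


def test_cost_ledger_sums_to_total(base_result):
    for arm in (base_result.intervention, base_result.comparator):
        assert sum(arm.cost_breakdown.values()) == pytest.approx(arm.total_cost, rel=1e-9)


def _arm(cost, qaly, name="x"):
    return ArmResult(arm=name, total_cost=cost, total_qaly=qaly,
                     total_cost_undiscounted=cost, total_qaly_undiscounted=qaly,
                     life_years=qaly, cost_breakdown={"all": cost})


def test_published_incremental_identities():
    # ICER and NMB follow from the printed deltas: 114,752.8 USD and 1.217894 QALY
    res = compare(_arm(224779.1, 4.19), _arm(110026.3, 4.19 - 1.217894), wtp=150_000.0)
    assert res.delta_cost == pytest.approx(114752.8, abs=0.01)
    assert res.icer == pytest.approx(114752.8 / 1.217894, abs=0.01)
    assert res.icer == pytest.approx(94222.29, abs=0.5)
    assert res.nmb == pytest.approx(67931.3, abs=0.5)


def test_identical_arms_and_dominance_flags():
    same = compare(_arm(100.0, 1.0), _arm(100.0, 1.0))
    assert (same.delta_cost, same.delta_qaly, same.nmb) == (0.0, 0.0, 0.0)
    assert math.isnan(same.icer)
    dominant = compare(_arm(90.0, 2.0), _arm(100.0, 1.0))
    assert dominant.dominant and not dominant.dominated
    dominated = compare(_arm(110.0, 0.5), _arm(100.0, 1.0))
    assert dominated.dominated and not dominated.dominant


def test_nmb_positive_iff_icer_below_threshold():
    rng = np.random.default_rng(11)
    for _ in range(200):
        dc = float(rng.uniform(1.0, 2e5))
        de = float(rng.uniform(0.01, 3.0))
        res = compare(_arm(dc, de), _arm(0.0, 0.0), wtp=150_000.0)
        assert (res.nmb > 0) == (res.icer < 150_000.0)


def test_scaling_all_costs_scales_delta_cost_and_icer(table, settings):
    base = run_base_case(table, settings)
    scaled = table
    for name, p in table.parameters.items():
        if p.units.startswith("USD"):
            scaled = scaled.with_value(name, 2.0 * p.base_value)
    doubled = run_base_case(scaled, settings)
    assert doubled.delta_cost == pytest.approx(2.0 * base.delta_cost, rel=1e-9)
    assert doubled.icer == pytest.approx(2.0 * base.icer, rel=1e-9)
    assert doubled.delta_qaly == pytest.approx(base.delta_qaly, rel=1e-12)


def test_sae_burden_charged_once_up_front(table, settings):
    trace = _idle_trace(table, settings)
    risks = {"anemia": 0.06, "neutropenia": 0.20, "thrombocytopenia": 0.06}
    util = UtilityModel(sae_risks={"placebo": risks, "pembrolizumab": risks})
    costs = CostModel()
    res = accrue(trace, costs, util, Regimen(), bsa=1.86, discount_rate=0.0)
    expected = sum(risks[s] * costs.sae_costs[s] for s in risks)
    assert res.cost_breakdown["sae_management"] == pytest.approx(expected)


def test_half_cycle_options_bracket_each_other(table, settings):
    cfg = build_engine_config(table, settings)
    trace = run_cohort(cfg, "placebo")
    kw = dict(costs=CostModel(), utilities=UtilityModel(), regimen=Regimen(), bsa=1.86)
    q = {m: accrue(trace, kw["costs"], kw["utilities"], kw["regimen"], 1.86,
                   half_cycle=m).total_qaly for m in ("start", "half", "end")}
    assert q["end"] < q["half"] < q["start"]
    assert q["half"] == pytest.approx(0.5 * (q["start"] + q["end"]), rel=1e-9)
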