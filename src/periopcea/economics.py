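"""Cost and utility accrual over a cohort trace, discounting, and CE statistics.

Costs are 2023 USD from the payer perspective: drug acquisition priced per mg
(pembrolizumab 200 mg flat; cisplatin-based backbone scaled by body-surface
area), CMS infusion-administration fees, one-off surgery/radiotherapy and
end-of-life costs, routine follow-up, best supportive care in progressive
disease, and expected severe-adverse-event management charged once up front.
Utilities are annual health-state weights accrued per 21-day cycle.  Both
streams are discounted at 3% per year by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from periopcea.markov_engine import CohortTrace

__all__ = [
    "CostModel",
    "UtilityModel",
    "ArmResult",
    "CEResult",
    "per_cycle_discount",
    "cycle_cost",
    "accrue",
    "compare",
]

_SAES = ("anemia", "neutropenia", "thrombocytopenia")


@dataclass(frozen=True)
class CostModel:
    """Unit costs (USD) and cost-attribution settings."""

    price_pembrolizumab_mg: float = 54.81
    price_cisplatin_mg: float = 0.32
    price_pemetrexed_mg: float = 6.45
    price_gemcitabine_mg: float = 0.02
    cost_surgery: float = 15687.42
    cost_radiotherapy: float = 16335.11
    cost_end_of_life: float = 17909.24
    cost_best_supportive_care: float = 3674.65  # per PD cycle
    cost_follow_up: float = 545.92  # per follow-up visit
    infusion_first_hour: float = 132.16
    infusion_additional_hour: float = 28.47
    infusion_subsequent_hour: float = 65.06
    sae_costs: dict = field(default_factory=lambda: {
        "anemia": 2024.32, "neutropenia": 1276.52, "thrombocytopenia": 2220.14})
    # attribution knobs (documented model assumptions, not Table 1 inputs)
    follow_up_every_cycles: int = 1  # follow-up visits per cycle in pre-PD residency
    bsc_every_cycles: int = 3  # supportive-care billing events: one per k PD cycles
    charge_pd_radiotherapy: bool = False  # radiotherapy event at PD entry

    def __post_init__(self) -> None:
        for name in ("price_pembrolizumab_mg", "price_cisplatin_mg", "price_pemetrexed_mg",
                     "price_gemcitabine_mg", "cost_surgery", "cost_radiotherapy",
                     "cost_end_of_life", "cost_best_supportive_care", "cost_follow_up",
                     "infusion_first_hour", "infusion_additional_hour",
                     "infusion_subsequent_hour"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def infusion_multi_agent(self) -> float:
        """Fee for one multi-agent chemotherapy visit (first + additional + subsequent)."""
        return self.infusion_first_hour + self.infusion_additional_hour + self.infusion_subsequent_hour

    @property
    def infusion_mono(self) -> float:
        """Fee for a single-agent infusion visit (first hour only)."""
        return self.infusion_first_hour


@dataclass(frozen=True)
class UtilityModel:
    """Annual health-state utilities, SAE disutilities and per-arm SAE risks."""

    u_pf: float = 0.75
    u_surgery: float = 0.73
    u_radiotherapy: float = 0.79
    u_pd: float = 0.65
    sae_disutilities: dict = field(default_factory=lambda: {
        "anemia": 0.25, "neutropenia": 0.07, "thrombocytopenia": 0.35})
    sae_risks: dict = field(default_factory=lambda: {
        "pembrolizumab": {"anemia": 0.07, "neutropenia": 0.21, "thrombocytopenia": 0.05},
        "placebo": {"anemia": 0.06, "neutropenia": 0.20, "thrombocytopenia": 0.06}})

    def __post_init__(self) -> None:
        for u in (self.u_pf, self.u_surgery, self.u_radiotherapy, self.u_pd):
            if not 0.0 <= u <= 1.0:
                raise ValueError("state utilities must lie in [0, 1]")
        for d in self.sae_disutilities.values():
            if not 0.0 <= d <= 1.0:
                raise ValueError("SAE disutilities must lie in [0, 1]")
        for arm in self.sae_risks.values():
            for r in arm.values():
                if not 0.0 <= r <= 1.0:
                    raise ValueError("SAE risks must lie in [0, 1]")


@dataclass(frozen=True)
class ArmResult:
    """Discounted (and undiscounted) totals for one strategy, with a cost ledger."""

    arm: str
    total_cost: float
    total_qaly: float
    total_cost_undiscounted: float
    total_qaly_undiscounted: float
    life_years: float
    cost_breakdown: dict

    def __post_init__(self) -> None:
        ledger = sum(self.cost_breakdown.values())
        if abs(ledger - self.total_cost) > 1e-6 * max(1.0, abs(self.total_cost)):
            raise ValueError("cost breakdown does not sum to the total")


@dataclass(frozen=True)
class CEResult:
    """Incremental cost-effectiveness of intervention vs comparator."""

    delta_cost: float
    delta_qaly: float
    icer: float  # NaN when delta_qaly == 0
    nmb: float
    wtp: float
    dominant: bool  # cheaper and more effective
    dominated: bool  # dearer and less effective
    intervention: ArmResult | None = None
    comparator: ArmResult | None = None

    def to_dict(self) -> dict:
        d = {"delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly,
             "icer": self.icer, "nmb": self.nmb, "wtp": self.wtp,
             "dominant": self.dominant, "dominated": self.dominated}
        for label, arm in (("intervention", self.intervention), ("comparator", self.comparator)):
            if arm is not None:
                d[label] = {"arm": arm.arm, "cost": arm.total_cost, "qaly": arm.total_qaly,
                            "life_years": arm.life_years,
                            "cost_breakdown": dict(arm.cost_breakdown)}
        return d


def per_cycle_discount(rate_annual: float, cycle: float) -> float:
    """Discount factor (1 + r)^(-cycle * 21/365.25); factor(0) = 1."""
    if rate_annual < 0:
        raise ValueError("discount rate must be >= 0")
    return float((1.0 + rate_annual) ** (-(cycle * 21.0 / 365.25)))


def _neoadjuvant_drug_cost(arm: str, costs: CostModel, regimen, bsa: float) -> dict:
    """Per-cycle drug + infusion cost during active neoadjuvant treatment."""
    nsq = regimen.nonsquamous_fraction
    pembro = costs.price_pembrolizumab_mg * regimen.pembrolizumab_mg if arm == "pembrolizumab" else 0.0
    cis = costs.price_cisplatin_mg * regimen.cisplatin_mg_m2 * bsa
    pem_partner = costs.price_pemetrexed_mg * regimen.pemetrexed_mg_m2 * bsa
    gem_partner = (costs.price_gemcitabine_mg * regimen.gemcitabine_mg_m2 * bsa
                   * regimen.gemcitabine_administrations)
    chemo = cis + nsq * pem_partner + (1.0 - nsq) * gem_partner
    # multi-agent visit on day 1; gemcitabine backbone adds a day-8 single-agent visit
    infusion = costs.infusion_multi_agent + (1.0 - nsq) * costs.infusion_mono
    return {"drug_pembrolizumab": pembro, "drug_chemotherapy": chemo, "infusion": infusion}


def _pd_chemo_cost(costs: CostModel, regimen, bsa: float) -> dict:
    """Platinum-doublet cost per cycle for the first PD cycles (no pembrolizumab)."""
    d = _neoadjuvant_drug_cost("placebo", costs, regimen, bsa)
    return {"pd_chemotherapy": d["drug_chemotherapy"], "infusion": d["infusion"]}


def cycle_cost(state: str, cycle: int, arm: str, costs: CostModel, regimen,
               bsa: float, *, neoadjuvant_cycles: int = 4) -> dict:
    """Per-cycle occupancy cost (USD, by category) for one public/tunnel state.

    ``state`` accepts the public names plus the tunnel labels ``ADJ_<j>``,
    ``PD_<j>`` and ``PD_LATE``; one-off entrant costs (surgery, end of life,
    SAEs) are attributed separately in :func:`accrue`.
    """
    if state == "DEATH":
        return {}
    if state == "NEOADJ":
        if cycle <= neoadjuvant_cycles:
            return _neoadjuvant_drug_cost(arm, costs, regimen, bsa)
        return {"follow_up": costs.cost_follow_up / costs.follow_up_every_cycles}
    if state in ("POST_SURG_RT", "POST"):
        return {"follow_up": costs.cost_follow_up / costs.follow_up_every_cycles}
    if state.startswith("ADJ"):
        if arm == "pembrolizumab":
            return {"drug_pembrolizumab": costs.price_pembrolizumab_mg * regimen.pembrolizumab_mg,
                    "infusion": costs.infusion_mono}
        return {}
    if state == "PD_LATE":
        return {"best_supportive_care": costs.cost_best_supportive_care / costs.bsc_every_cycles}
    if state.startswith("PD"):
        out = _pd_chemo_cost(costs, regimen, bsa)
        out["best_supportive_care"] = costs.cost_best_supportive_care / costs.bsc_every_cycles
        return out
    raise ValueError(f"unknown state {state!r}")


def accrue(trace: CohortTrace, costs: CostModel, utilities: UtilityModel, regimen,
           bsa: float, *, discount_rate: float = 0.03, half_cycle: str = "half",
           neoadjuvant_cycles: int = 4) -> ArmResult:
    """Accrue discounted costs and QALYs over a trace.

    ``half_cycle`` selects the occupancy used for within-cycle accrual:
    ``"half"`` (life-table correction, the default), ``"start"`` or ``"end"``.
    One-off entrant costs are attributed at the cycle they occur, undiscounted
    within the cycle.
    """
    if half_cycle not in ("half", "start", "end"):
        raise ValueError("half_cycle must be 'half', 'start' or 'end'")
    cfg = trace.cfg
    arm = trace.arm
    idx = cfg.idx
    H = cfg.horizon_cycles
    dt_years = cfg.cycle_years
    f_surg = 1.0 - cfg.fraction_radiotherapy

    # per-cycle occupancy under the chosen correction, expanded states
    X = trace.expanded
    if half_cycle == "half":
        occ = 0.5 * (X[:-1] + X[1:])
    elif half_cycle == "start":
        occ = X[:-1]
    else:
        occ = X[1:]

    disc = np.array([per_cycle_discount(discount_rate, c - 1) for c in range(1, H + 1)])

    # map expanded state index -> (cost-category dict builder, utility)
    u_post = f_surg * utilities.u_surgery + (1.0 - f_surg) * utilities.u_radiotherapy
    state_labels: list[str] = [""] * cfg.n_expanded
    state_util = np.zeros(cfg.n_expanded)
    state_labels[idx["NEOADJ"]] = "NEOADJ"
    state_util[idx["NEOADJ"]] = utilities.u_pf
    state_labels[idx["POST"]] = "POST_SURG_RT"
    state_util[idx["POST"]] = u_post
    for j, i in enumerate(idx["ADJ"], start=1):
        state_labels[i] = f"ADJ_{j}"
        state_util[i] = utilities.u_pf
    for j, i in enumerate(idx["PD"], start=1):
        state_labels[i] = f"PD_{j}"
        state_util[i] = utilities.u_pd
    state_labels[idx["PD_LATE"]] = "PD_LATE"
    state_util[idx["PD_LATE"]] = utilities.u_pd
    state_labels[idx["DEATH"]] = "DEATH"

    ledger: dict[str, float] = {}
    ledger_undisc: dict[str, float] = {}

    def add(cat: str, amount: float, factor: float) -> None:
        ledger[cat] = ledger.get(cat, 0.0) + amount * factor
        ledger_undisc[cat] = ledger_undisc.get(cat, 0.0) + amount

    qaly = 0.0
    qaly_undisc = 0.0
    life_years = 0.0
    for c in range(1, H + 1):
        fac = disc[c - 1]
        row = occ[c - 1]
        for i in range(cfg.n_expanded):
            w = row[i]
            if w <= 0.0:
                continue
            label = state_labels[i]
            if label != "DEATH":
                q = w * state_util[i] * dt_years
                qaly += q * fac
                qaly_undisc += q
                life_years += w * dt_years
            for cat, amount in cycle_cost(label, c, arm, costs, regimen, bsa,
                                          neoadjuvant_cycles=neoadjuvant_cycles).items():
                add(cat, w * amount, fac)
        # one-off entrant costs
        surg = trace.surgery_rt_entrants[c]
        if surg > 0.0:
            add("surgery_radiotherapy",
                surg * (f_surg * costs.cost_surgery + (1.0 - f_surg) * costs.cost_radiotherapy),
                fac)
        if costs.charge_pd_radiotherapy and trace.pd_entrants[c] > 0.0:
            add("pd_radiotherapy", trace.pd_entrants[c] * costs.cost_radiotherapy, fac)
        if trace.death_entrants[c] > 0.0:
            add("end_of_life", trace.death_entrants[c] * costs.cost_end_of_life, fac)

    # SAE management and disutility: expected value, charged once in cycle 1
    risks = utilities.sae_risks[arm]
    sae_cost = sum(risks[s] * costs.sae_costs[s] for s in _SAES)
    add("sae_management", sae_cost, disc[0])
    sae_dq = sum(risks[s] * utilities.sae_disutilities[s] for s in _SAES) * dt_years
    qaly -= sae_dq * disc[0]
    qaly_undisc -= sae_dq

    ledger = {k: float(v) for k, v in ledger.items()}
    return ArmResult(
        arm=arm,
        total_cost=float(sum(ledger.values())),
        total_qaly=float(qaly),
        total_cost_undiscounted=float(sum(ledger_undisc.values())),
        total_qaly_undiscounted=float(qaly_undisc),
        life_years=float(life_years),
        cost_breakdown=ledger,
    )


def compare(intervention: ArmResult, comparator: ArmResult, wtp: float = 150_000.0) -> CEResult:
    """Incremental cost, QALY, ICER and NMB of intervention vs comparator."""
    dc = float(intervention.total_cost - comparator.total_cost)
    de = float(intervention.total_qaly - comparator.total_qaly)
    icer = dc / de if de != 0.0 else math.nan
    nmb = wtp * de - dc
    return CEResult(
        delta_cost=dc,
        delta_qaly=de,
        icer=icer,
        nmb=nmb,
        wtp=wtp,
        dominant=bool(dc < 0.0 and de > 0.0),
        dominated=bool(dc > 0.0 and de < 0.0),
        intervention=intervention,
        comparator=comparator,
    )
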